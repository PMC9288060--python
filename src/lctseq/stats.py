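"""Cohort-level statistics on LCT event matrices.

Covers depth normalization, the two differential-calling strategies
(two-sample test on normalized expression, Fisher exact test on
presence/absence) and their union, sample-level LCT activity and its
correlates (gene expression, methylation M-values, copy-number burden),
univariate Cox survival, panel-gene selection and the two-threshold
risk stratification.

Calling thresholds follow the study design: expression calls at
p <= 0.05 with log2 fold change > 0, Fisher calls at p <= 0.05,
correlated genes at p <= 0.0001, survival-related events at p <= 0.05.
Raw p-values drive every call; BH-adjusted q-values are emitted for
information only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

P_DIFFERENTIAL = 0.05
P_CORRELATION = 1e-4
P_SURVIVAL = 0.05


def _check_depth(depth: pd.Series) -> None:
    if (depth <= 0).any():
        bad = depth.index[depth <= 0].tolist()
        raise ValueError(f"non-positive read depth for samples: {bad}")


def normalize_log_rpm(
    counts: pd.DataFrame, depth: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / depth * 1e6 + pseudocount), per event and sample."""
    _check_depth(depth)
    depth = depth.reindex(counts.columns)
    if depth.isna().any():
        raise ValueError("depth missing for some samples")
    rpm = counts.div(depth, axis=1) * 1e6
    return np.log2(rpm + pseudocount)


def diff_expression_test(
    normalized: pd.DataFrame, groups: pd.Series, alpha: float = P_DIFFERENTIAL
) -> pd.DataFrame:
    """Welch two-sample t-test per event, tumor vs normal.

    log2_fc = mean(tumor) - mean(normal) on the normalized scale;
    called_expression requires p <= alpha and log2_fc > 0. Events with
    zero variance in both groups and identical means get p = 1; an event
    that is degenerate (a group with < 2 samples) is skipped with NaN.
    """
    groups = groups.reindex(normalized.columns)
    tumor = normalized.loc[:, groups == "tumor"]
    normal = normalized.loc[:, groups == "normal"]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(tumor, normal, axis=1, equal_var=False)
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    p = pd.Series(p, index=normalized.index)
    degenerate = p.isna() & (lfc == 0)
    p[degenerate] = 1.0
    if p.isna().any():
        log.warning("%d events skipped (undefined t-statistic)", int(p.isna().sum()))
    out = pd.DataFrame(
        {
            "p_expression": p,
            "log2_fc": lfc,
            "called_expression": (p <= alpha) & (lfc > 0),
        }
    )
    out["q_expression"] = _bh(out["p_expression"])
    return out


def diff_occurrence_fisher(
    presence: pd.DataFrame, groups: pd.Series, alpha: float = P_DIFFERENTIAL
) -> pd.DataFrame:
    """Two-sided Fisher exact test on the 2x2 presence x group table."""
    groups = groups.reindex(presence.columns)
    n_t = int((groups == "tumor").sum())
    n_n = int((groups == "normal").sum())
    if n_t == 0 or n_n == 0:
        raise ValueError("both tumor and normal samples are required")
    pt = presence.loc[:, groups == "tumor"].sum(axis=1).astype(int)
    pn = presence.loc[:, groups == "normal"].sum(axis=1).astype(int)
    pvals = [
        sps.fisher_exact([[a, n_t - a], [b, n_n - b]], alternative="two-sided")[1]
        for a, b in zip(pt, pn)
    ]
    out = pd.DataFrame(
        {
            "present_tumor": pt,
            "present_normal": pn,
            "p_fisher": pvals,
            "called_fisher": pd.Series(pvals, index=presence.index) <= alpha,
        },
        index=presence.index,
    )
    out["q_fisher"] = _bh(out["p_fisher"])
    return out


def union_differential(
    expression_calls: pd.DataFrame, fisher_calls: pd.DataFrame
) -> pd.DataFrame:
    """Union of the two differential strategies, one row per event."""
    if set(expression_calls.index) != set(fisher_calls.index):
        raise ValueError("expression and Fisher tables cover different events")
    merged = expression_calls.join(fisher_calls.reindex(expression_calls.index))
    merged["called_union"] = merged["called_expression"] | merged["called_fisher"]
    return merged


def sample_activity(counts: pd.DataFrame, depth: pd.Series) -> pd.Series:
    """Per-sample LCT activity: summed support reads per million reads."""
    _check_depth(depth)
    act = counts.sum(axis=0) / depth.reindex(counts.columns) * 1e6
    act.name = "lct_activity"
    return act


def methylation_m(beta: pd.DataFrame | pd.Series | float) -> pd.DataFrame | pd.Series | float:
    """Logit-scale methylation: M = log2(beta / (1 - beta))."""
    return np.log2(beta / (1 - beta))


def sample_methylation(beta: pd.DataFrame) -> pd.Series:
    """Per-sample median M-value over all sites (rows = sites)."""
    m = methylation_m(beta)
    out = m.median(axis=0)
    out.name = "median_m"
    return out


def cnv_burden(gistic: pd.DataFrame) -> pd.Series:
    """Per-sample copy-number burden: sum of |GISTIC2 value| over genes."""
    out = gistic.abs().sum(axis=0)
    out.name = "cnv_burden"
    return out


def correlate_activity(
    activity: pd.Series, features: pd.DataFrame, alpha: float = P_CORRELATION
) -> pd.DataFrame:
    """Pearson correlation of each feature (row) with sample-level activity.

    Selected features have two-sided p <= alpha; the sign of r splits them
    into positively and negatively related sets. Constant features are
    skipped with a warning (r undefined).
    """
    common = [s for s in features.columns if s in activity.index]
    if len(common) < 3:
        raise ValueError("need >= 3 paired samples")
    act = activity[common].to_numpy(dtype=float)
    rows = []
    skipped = 0
    for feat, vals in features[common].iterrows():
        v = vals.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(act[ok]) == 0:
            skipped += 1
            rows.append((feat, np.nan, np.nan, False, ""))
            continue
        r, p = sps.pearsonr(act[ok], v[ok])
        sel = p <= alpha
        rows.append((feat, r, p, sel, "" if not sel else ("positive" if r > 0 else "negative")))
    if skipped:
        log.warning("%d constant/degenerate features skipped", skipped)
    return pd.DataFrame(
        rows, columns=["feature", "r", "p", "selected", "direction"]
    ).set_index("feature")


def fit_univariate_cox(
    x: np.ndarray | pd.Series,
    time: np.ndarray | pd.Series,
    status: np.ndarray | pd.Series,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> dict:
    """Univariate Cox proportional hazards fit.

    Newton-Raphson maximization of the Breslow partial likelihood; returns
    beta, its standard error, the hazard ratio exp(beta) and the Wald p.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    if status.sum() < 1:
        raise ValueError("no observed events")
    if np.std(x) == 0:
        raise ValueError("covariate is constant")
    order = np.argsort(-time, kind="stable")  # descending: risk sets by prefix
    x_o, t_o, s_o = x[order], time[order], status[order]
    beta = 0.0
    for _ in range(max_iter):
        eta = np.clip(beta * x_o, -500, 500)
        w = np.exp(eta)
        cw = np.cumsum(w)
        cwx = np.cumsum(w * x_o)
        cwx2 = np.cumsum(w * x_o**2)
        # risk set of subject i (descending time order) = prefix through the
        # last index sharing its time (Breslow: all tied deaths share it)
        idx = np.searchsorted(-t_o, -t_o, side="right") - 1
        d = s_o == 1
        U = np.sum(x_o[d] - cwx[idx[d]] / cw[idx[d]])
        I = np.sum(cwx2[idx[d]] / cw[idx[d]] - (cwx[idx[d]] / cw[idx[d]]) ** 2)
        if I <= 0:
            raise RuntimeError("singular information in Cox fit")
        step = U / I
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(step) < tol:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last beta={beta:.4g}, step={step:.2e})"
        )
    se = 1.0 / np.sqrt(I)
    z = beta / se
    p = 2 * sps.norm.sf(abs(z))
    return {"beta": beta, "se": se, "hazard_ratio": float(np.exp(beta)), "p": p}


def survival_related_events(
    normalized: pd.DataFrame,
    time: pd.Series,
    status: pd.Series,
    alpha: float = P_SURVIVAL,
) -> pd.DataFrame:
    """Per-event univariate Cox fits; events with p <= alpha are selected."""
    rows = []
    for ev, vals in normalized.iterrows():
        try:
            fit = fit_univariate_cox(
                vals.reindex(time.index), time, status.reindex(time.index)
            )
        except (ValueError, RuntimeError):
            rows.append((ev, np.nan, np.nan, np.nan, False))
            continue
        rows.append((ev, fit["beta"], fit["hazard_ratio"], fit["p"], fit["p"] <= alpha))
    return pd.DataFrame(
        rows, columns=["event_id", "beta", "hazard_ratio", "p", "survival_related"]
    ).set_index("event_id")


def km_by_lct_burden(
    lct_expression: pd.Series, time: pd.Series, status: pd.Series
) -> pd.DataFrame:
    """Median split of summed survival-LCT expression, for KM plotting.

    Returns a per-sample table with the group label; plotting is left to
    lifelines' KaplanMeierFitter on this table.
    """
    med = lct_expression.median()
    grp = np.where(lct_expression > med, "high", "low")
    return pd.DataFrame(
        {"lct_expression": lct_expression, "group": grp, "time": time, "status": status}
    )


def select_panel_genes(
    correlation: pd.DataFrame, sc_de_comparisons: pd.Series, min_comparisons: int = 3
) -> list[str]:
    """Candidate LCT-affected genes.

    A gene enters the panel when it correlates positively with LCT activity
    (p <= 0.0001 and r > 0 in the bulk cohort) and is differentially
    expressed between LCT+ and LCT- cells in strictly more than
    ``min_comparisons`` single-cell comparisons.
    """
    bulk_ok = correlation.index[(correlation["p"] <= P_CORRELATION) & (correlation["r"] > 0)]
    counts = sc_de_comparisons.reindex(bulk_ok).fillna(0)
    return sorted(counts.index[counts > min_comparisons])


@dataclass
class StratificationResult:
    score_threshold: float
    lct_threshold: float
    groups: pd.Series  # per-sample group 1..4 (4 = high score & high LCT)
    group_rates: dict[int, float]  # 36-month fatality rate per group
    group_counts: dict[int, int]
    target_met: bool


def aggregate_gene_score(panel_expression: pd.DataFrame) -> pd.Series:
    """Sum of per-gene z-scores (sample SD, ddof=1) across the panel."""
    z = panel_expression.sub(panel_expression.mean(axis=1), axis=0).div(
        panel_expression.std(axis=1, ddof=1), axis=0
    )
    score = z.sum(axis=0)
    score.name = "aggregate_score"
    return score


def _fatality_rate(time: np.ndarray, status: np.ndarray, horizon: float) -> float:
    return float(np.mean((status == 1) & (time <= horizon)))


def stratify_patients(
    panel_expression: pd.DataFrame,
    lct_expression: pd.Series,
    time: pd.Series,
    status: pd.Series,
    target_rate: float = 0.5,
    horizon_months: float = 36.0,
) -> StratificationResult:
    """Two-threshold patient stratification into four risk groups.

    The aggregate gene score (summed z-scores over the panel) and the
    survival-related LCT expression each get a threshold; every observed
    (score, LCT) value pair is tried exhaustively. Among pairs whose
    high/high group reaches the target 36-month fatality rate, the one
    with the largest high/high group wins (ties: higher rate, then lower
    score threshold, then lower LCT threshold). If no pair reaches the
    target, the best-rate pair is returned flagged ``target_met=False``.
    """
    samples = panel_expression.columns
    if len(samples) < 4:
        raise ValueError("need >= 4 samples")
    score = aggregate_gene_score(panel_expression)
    lct = lct_expression.reindex(samples)
    t = time.reindex(samples).to_numpy(dtype=float)
    s = status.reindex(samples).to_numpy(dtype=int)
    sc = score.to_numpy(dtype=float)
    lc = lct.to_numpy(dtype=float)
    best = None  # (met, size, rate, -s_thr, -l_thr) lexicographic preference
    for s_thr in np.unique(sc):
        hi_s = sc >= s_thr
        for l_thr in np.unique(lc):
            hh = hi_s & (lc >= l_thr)
            n = int(hh.sum())
            if n == 0:
                continue
            rate = _fatality_rate(t[hh], s[hh], horizon_months)
            met = rate >= target_rate
            key = (met, n if met else 0, rate, -s_thr, -l_thr)
            if best is None or key > best[0]:
                best = (key, s_thr, l_thr)
    _, s_thr, l_thr = best
    grp = 1 + (sc >= s_thr).astype(int) + 2 * (lc >= l_thr).astype(int)
    groups = pd.Series(grp, index=samples, name="group")
    rates, counts = {}, {}
    for g in (1, 2, 3, 4):
        mask = grp == g
        counts[g] = int(mask.sum())
        rates[g] = _fatality_rate(t[mask], s[mask], horizon_months) if mask.any() else float("nan")
    return StratificationResult(
        score_threshold=float(s_thr),
        lct_threshold=float(l_thr),
        groups=groups,
        group_rates=rates,
        group_counts=counts,
        target_met=bool(best[0][0]),
    )


def _bh(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (informational only)."""
    p = p.astype(float)
    ok = p.notna()
    n = int(ok.sum())
    q = pd.Series(np.nan, index=p.index)
    if n == 0:
        return q
    order = np.argsort(p[ok].to_numpy())
    ranked = p[ok].to_numpy()[order]
    adj = ranked * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    q[ok] = out
    return q
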