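"""Single-cell support: barcode extraction, error-tolerant clustering,
cell-level event assignment and LCT+/LCT- differential expression.

Detection itself reuses the bulk pipeline in single-end mode on the cDNA
read (the R2 file for 10x v2 chemistry, R1 for v3); this module takes the
supporting read ids it produces and resolves them to cells. Barcodes are
clustered greedily at end-to-end (ungapped) identity strictly greater than
0.85, emulating cd-hit's end-to-end mode on equal-length strings.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import read_fastq

log = logging.getLogger(__name__)

BARCODE_IDENTITY = 0.85
SC_P_THRESHOLD = 0.01
SC_LFC_THRESHOLD = 0.25

#: barcode geometry per chemistry: (offset, length) on the barcode read
CHEMISTRY = {"tenx_v2": (0, 16), "tenx_v3": (0, 16)}


@dataclass
class BarcodeCluster:
    members: dict[str, int]  # barcode -> read count
    representative: str
    whitelist_hit: bool = False


def barcode_identity(a: str, b: str) -> float:
    """End-to-end ungapped identity; any N counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError("barcodes differ in length")
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / len(a)


def extract_barcodes(
    supporting_read_ids: list[str],
    barcode_read_file: str | Path | list[tuple[str, str, str]],
    chemistry: str | tuple[int, int] = "tenx_v2",
) -> tuple[Counter, dict[str, str]]:
    """Pull the barcode of every LCT-supporting read from the barcode file.

    Returns (barcode counts, read_id -> barcode). Read ids absent from the
    barcode file are skipped with a warning; a barcode read shorter than
    offset+length is an error.
    """
    offset, length = CHEMISTRY[chemistry] if isinstance(chemistry, str) else chemistry
    wanted = set(supporting_read_ids)
    records = (
        barcode_read_file
        if isinstance(barcode_read_file, list)
        else read_fastq(barcode_read_file)
    )
    found: dict[str, str] = {}
    for rid, seq, _ in records:
        if rid in wanted:
            if len(seq) < offset + length:
                raise ValueError(
                    f"read {rid}: barcode read of {len(seq)} bp shorter than "
                    f"offset+length {offset + length}"
                )
            found[rid] = seq[offset : offset + length]
    missing = wanted - set(found)
    if missing:
        log.warning("%d supporting reads absent from barcode file", len(missing))
    return Counter(found.values()), found


def cluster_barcodes(
    barcode_counts: Counter | dict[str, int],
    identity_threshold: float = BARCODE_IDENTITY,
    whitelist: set[str] | None = None,
) -> list[BarcodeCluster]:
    """Greedy centroid clustering of equal-length barcodes.

    Barcodes are visited in descending read count (ties: lexical); one
    joins an existing cluster iff its identity to that cluster's centroid
    is strictly greater than the threshold. The representative is the
    member found in the whitelist (ties: highest count), else the
    highest-count member. Clusters sharing a whitelist representative are
    merged (and the merge logged).
    """
    items = sorted(barcode_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if not items:
        return []
    lengths = {len(b) for b, _ in items}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths: {sorted(lengths)}")
    clusters: list[dict[str, int]] = []
    centroids: list[str] = []
    for bc, n in items:
        for ci, cen in enumerate(centroids):
            if barcode_identity(bc, cen) > identity_threshold:
                clusters[ci][bc] = clusters[ci].get(bc, 0) + n
                break
        else:
            centroids.append(bc)
            clusters.append({bc: n})
    wl = whitelist or set()
    out: list[BarcodeCluster] = []
    for members in clusters:
        in_wl = [b for b in members if b in wl]
        if in_wl:
            rep = max(in_wl, key=lambda b: (members[b], b))
            out.append(BarcodeCluster(members, rep, True))
        else:
            rep = max(members, key=lambda b: (members[b], b))
            out.append(BarcodeCluster(members, rep, False))
    merged: dict[str, BarcodeCluster] = {}
    final: list[BarcodeCluster] = []
    for c in out:
        if c.whitelist_hit and c.representative in merged:
            host = merged[c.representative]
            log.info("merging two clusters sharing representative %s", c.representative)
            for b, n in c.members.items():
                host.members[b] = host.members.get(b, 0) + n
        else:
            if c.whitelist_hit:
                merged[c.representative] = c
            final.append(c)
    return final


def assign_lct_to_cells(
    event_supporting_reads: dict[str, list[str]],
    read_barcodes: dict[str, str],
    clusters: list[BarcodeCluster],
    cell_barcodes: list[str],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Map each LCT event onto the cells of an expression matrix.

    A cell is LCT+ for an event iff at least one supporting read's barcode
    belongs to a cluster whose representative is that cell's barcode.
    Events carried only by clusters without a whitelist representative are
    reported in the unassigned dict.
    """
    bc_to_rep: dict[str, str] = {}
    for c in clusters:
        for b in c.members:
            bc_to_rep[b] = c.representative
    cells = list(cell_barcodes)
    cell_set = set(cells)
    mat = pd.DataFrame(False, index=cells, columns=sorted(event_supporting_reads))
    unassigned: dict[str, list[str]] = {}
    for event, rids in event_supporting_reads.items():
        for rid in rids:
            bc = read_barcodes.get(rid)
            if bc is None:
                continue
            rep = bc_to_rep.get(bc)
            if rep in cell_set:
                mat.loc[rep, event] = True
            elif rep is not None:
                unassigned.setdefault(event, []).append(rep)
    return mat, {k: sorted(set(v)) for k, v in unassigned.items()}


def rank_sum_de(
    expression: pd.DataFrame,
    positive_cells: list[str],
    negative_cells: list[str],
    p_threshold: float = SC_P_THRESHOLD,
    lfc_threshold: float = SC_LFC_THRESHOLD,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test per gene, LCT+ cells vs LCT- cells.

    Exact p-values when the combined group size is <= ``exact_max_n`` and
    the data are tie-free, otherwise the tie-corrected normal
    approximation. log_fc is the mean log-expression difference (+ minus
    -); called_up requires p < 0.01 and log_fc > 0.25, called_down the
    mirror image.
    """
    if len(positive_cells) < 3 or len(negative_cells) < 3:
        raise ValueError("need >= 3 cells per group")
    pos = expression[positive_cells]
    neg = expression[negative_cells]
    n = len(positive_cells) + len(negative_cells)
    rows = []
    for gene in expression.index:
        a = pos.loc[gene].to_numpy(dtype=float)
        b = neg.loc[gene].to_numpy(dtype=float)
        ties = len(np.unique(np.concatenate([a, b]))) < n
        method = "exact" if (n <= exact_max_n and not ties) else "asymptotic"
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        lfc = float(a.mean() - b.mean())
        rows.append(
            (
                gene,
                p,
                lfc,
                p < p_threshold and lfc > lfc_threshold,
                p < p_threshold and lfc < -lfc_threshold,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "p", "log_fc", "called_up", "called_down"]
    ).set_index("gene")
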