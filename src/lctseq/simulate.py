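"""Ground-truthed synthetic data for every stage of the pipeline.

The generator emulates the structures the detector must resolve: spliced
transcripts with UTR/CDS annotation laid out on a toy genome, intergenic
LINE-1 elements near genes, chimeric transcripts joining a transcript
prefix to an L1 segment (a configurable fraction exactly at exon
boundaries), L1-Alu decoy fusions, substitution sequencing errors,
barcoded cells, and cohort-scale count matrices with tumor-enriched events
and exponential survival. Everything is a pure function of its parameters
and the seed, and every emitted artifact is described in a TruthManifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GeneModel, GenomicInterval, RepeatFeature

BASES = np.array(list("ACGT"))


@dataclass
class SimReferences:
    genome: dict[str, str]
    gene_models: list[GeneModel]
    transcripts: dict[str, str]  # spliced transcript sequences
    l1_library: dict[str, str]
    alu_library: dict[str, str]
    repeat_features: list[RepeatFeature]

    @property
    def repeat_library(self) -> dict[str, str]:
        return {**self.l1_library, **self.alu_library}


@dataclass
class ChimeraRecord:
    chimera_id: str
    transcript_id: str
    tx_junction_coord: int
    l1_id: str
    l1_junction_coord: int
    at_exon_boundary: bool
    sequence: str


@dataclass
class DecoyRecord:
    decoy_id: str
    decoy_type: str  # l1_alu_fusion | pure_l1 | pure_tx
    sequence: str


@dataclass
class TruthManifest:
    chimeras: list[ChimeraRecord] = field(default_factory=list)
    decoys: list[DecoyRecord] = field(default_factory=list)
    junction_reads: dict[str, int] = field(default_factory=dict)  # >=1 bp overhang
    junction_reads_10: dict[str, int] = field(default_factory=dict)  # >=10 bp overhang
    cell_events: dict[str, list[str]] = field(default_factory=dict)
    read_cells: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    m = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return m / n


def make_references(
    seed: int,
    n_transcripts: int = 200,
    n_l1: int = 30,
    transcript_length: tuple[int, int] = (500, 1500),
    l1_length: tuple[int, int] = (400, 800),
    utr_fractions: tuple[float, float] = (0.15, 0.25),
    n_exons: tuple[int, int] = (3, 8),
    n_alu: int = 8,
    alu_length: int = 300,
    l1_gap: tuple[int, int] = (200, 2000),
    max_pairwise_identity: float = 0.8,
) -> SimReferences:
    """Build a toy genome: one gene per chromosome, with a nearby L1.

    Each chromosome carries one spliced coding gene (UTR5/CDS/UTR3 by the
    given fractions) and, downstream of the gene, one L1 element drawn from
    a library whose members are kept below ``max_pairwise_identity`` by
    rejection sampling. A small Alu-like decoy library is emitted too.
    """
    if n_transcripts < 1 or n_l1 < 1:
        raise ValueError("need at least one transcript and one L1")
    if sum(utr_fractions) >= 1:
        raise ValueError("UTR fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    l1_library: dict[str, str] = {}
    attempts = 0
    while len(l1_library) < n_l1:
        attempts += 1
        if attempts > 50 * n_l1:
            raise RuntimeError("cannot satisfy L1 pairwise-identity constraint")
        cand = _random_seq(rng, int(rng.integers(l1_length[0], l1_length[1] + 1)))
        if all(_ungapped_identity(cand, s) < max_pairwise_identity for s in l1_library.values()):
            l1_library[f"L1sim_{len(l1_library)}"] = cand
    alu_library = {f"AluSim_{i}": _random_seq(rng, alu_length) for i in range(n_alu)}

    genome: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    repeat_features: list[RepeatFeature] = []
    l1_ids = sorted(l1_library)
    for i in range(n_transcripts):
        chrom = f"chr{i}"
        tlen = int(rng.integers(transcript_length[0], transcript_length[1] + 1))
        tx = _random_seq(rng, tlen)
        k = int(rng.integers(n_exons[0], n_exons[1] + 1))
        cuts = sorted(rng.choice(np.arange(60, tlen - 60, 1), size=k - 1, replace=False)) if k > 1 else []
        # enforce >= 60 bp between consecutive exon boundaries
        cuts = [int(c) for c in cuts]
        ok = all(b - a >= 60 for a, b in zip([0] + cuts, cuts + [tlen]))
        if not ok:
            step = max(60, tlen // k)
            cuts = [step * j for j in range(1, k)]
        exon_tx = list(zip([0] + cuts, cuts + [tlen]))
        upstream = 200
        pos = upstream
        exons = []
        parts = [_random_seq(rng, upstream)]
        for es, ee in exon_tx:
            parts.append(tx[es:ee])
            exons.append((pos, pos + (ee - es)))
            pos += ee - es
            intron = int(rng.integers(80, 300))
            parts.append(_random_seq(rng, intron))
            pos += intron
        # drop the trailing intron spacer from gene span accounting
        gene_end = exons[-1][1]
        u5 = int(utr_fractions[0] * tlen)
        u3 = int(utr_fractions[1] * tlen)
        cds_tx = (u5, tlen - u3)
        tid, gid = f"TX{i:04d}", f"GENE{i:04d}"
        seq_so_far = "".join(parts)
        gap = int(rng.integers(l1_gap[0], l1_gap[1] + 1))
        lid = l1_ids[i % len(l1_ids)]
        l1_start = len(seq_so_far) + gap
        chrom_seq = seq_so_far + _random_seq(rng, gap) + l1_library[lid] + _random_seq(rng, 100)
        genome[chrom] = chrom_seq
        exon_ivs = [GenomicInterval(chrom, s, e) for s, e in exons]
        # CDS span in genomic coordinates via the exon layout
        gm = GeneModel(
            gid,
            tid,
            GenomicInterval(chrom, exons[0][0], gene_end),
            exon_ivs,
        )
        cds_s = gm.transcript_to_genomic(cds_tx[0])
        cds_e = gm.transcript_to_genomic(cds_tx[1] - 1) + 1
        gm.cds = GenomicInterval(chrom, cds_s, cds_e)
        gene_models.append(gm)
        transcripts[tid] = tx
        repeat_features.append(
            RepeatFeature(
                GenomicInterval(chrom, l1_start, l1_start + len(l1_library[lid])),
                lid,
                "LINE/L1",
            )
        )
    return SimReferences(
        genome=genome,
        gene_models=gene_models,
        transcripts=transcripts,
        l1_library=l1_library,
        alu_library=alu_library,
        repeat_features=repeat_features,
    )


def implant_chimeras(
    refs: SimReferences,
    n_events: int = 20,
    fraction_at_exon_boundary: float = 0.5,
    seed: int = 0,
    l1_segment: int = 250,
    min_tx_prefix: int = 120,
) -> tuple[dict[str, str], TruthManifest]:
    """Create chimeric transcripts: a transcript prefix joined to an L1 segment.

    The stated fraction of junctions is placed exactly on an internal exon
    boundary (distance 0); the rest sit >= 5 bp inside an exon. Returns the
    chimeric sequences and a manifest recording every coordinate.
    """
    if n_events > len(refs.transcripts):
        raise ValueError("more events requested than transcripts available")
    rng = np.random.default_rng(seed)
    models = {m.transcript_id: m for m in refs.gene_models}
    tids = sorted(refs.transcripts)
    chosen = list(rng.choice(tids, size=n_events, replace=False))
    n_boundary = round(fraction_at_exon_boundary * n_events)
    l1_ids = sorted(refs.l1_library)
    manifest = TruthManifest()
    chimeras: dict[str, str] = {}
    for i, tid in enumerate(chosen):
        tx = refs.transcripts[tid]
        bounds = [
            b
            for b in models[tid].exon_boundaries_tx()
            if min_tx_prefix <= b <= len(tx) - 20
        ]
        at_boundary = i < n_boundary and bool(bounds)
        if at_boundary:
            txj = int(rng.choice(bounds))
        else:
            all_bounds = models[tid].exon_boundaries_tx()
            for _ in range(200):
                txj = int(rng.integers(min_tx_prefix, len(tx) - 20))
                if all(abs(txj - b) >= 5 for b in all_bounds):
                    break
            else:
                raise RuntimeError("cannot place interior junction")
        lid = l1_ids[int(rng.integers(0, len(l1_ids)))]
        l1_seq = refs.l1_library[lid]
        max_start = max(0, len(l1_seq) - l1_segment)
        l1j = int(rng.integers(0, max_start + 1))
        # keep the junction canonical (transcript-maximal): the first L1
        # base must differ from the transcript continuation, otherwise the
        # junction coordinate would be ambiguous
        while l1j < max_start and txj < len(tx) and l1_seq[l1j] == tx[txj]:
            l1j += 1
        seq = tx[:txj] + l1_seq[l1j : l1j + l1_segment]
        cid = f"chimera_{i:03d}"
        chimeras[cid] = seq
        manifest.chimeras.append(
            ChimeraRecord(cid, tid, txj, lid, l1j, at_boundary, seq)
        )
    return chimeras, manifest


def make_decoys(
    refs: SimReferences, n_fusions: int = 5, seed: int = 0, half: int = 150
) -> tuple[dict[str, str], list[DecoyRecord]]:
    """L1-Alu fusion decoys: half an L1 element joined to half an Alu."""
    rng = np.random.default_rng(seed)
    l1_ids, alu_ids = sorted(refs.l1_library), sorted(refs.alu_library)
    out, recs = {}, []
    for i in range(n_fusions):
        lid = l1_ids[int(rng.integers(0, len(l1_ids)))]
        aid = alu_ids[int(rng.integers(0, len(alu_ids)))]
        l1s = refs.l1_library[lid]
        s = int(rng.integers(0, max(1, len(l1s) - half)))
        seq = l1s[s : s + half] + refs.alu_library[aid][:half]
        did = f"decoy_fusion_{i:03d}"
        out[did] = seq
        recs.append(DecoyRecord(did, "l1_alu_fusion", seq))
    return out, recs


def simulate_reads(
    sources: dict[str, str],
    depth: dict[str, int] | int,
    read_length: int = 100,
    error_rate: float = 0.0,
    paired: bool = True,
    fragment_length: tuple[int, int] = (180, 280),
    junctions: dict[str, int] | None = None,
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], dict[str, int], dict[str, int]]:
    """Sample reads uniformly from each source sequence.

    ``depth`` is the number of fragments per source (int applies to all).
    Paired mode emits both fragment ends (mate 2 reverse-complemented) as
    separate single-end records; substitution errors are applied per base.
    When ``junctions`` maps a source to a junction offset, the realized
    junction-spanning read counts (>= 1 bp and >= 10 bp overhang each side)
    are returned alongside the reads.
    """
    rng = np.random.default_rng(seed)
    junctions = junctions or {}
    reads: list[tuple[str, str, str]] = []
    span1: dict[str, int] = {k: 0 for k in junctions}
    span10: dict[str, int] = {k: 0 for k in junctions}
    for src_id in sorted(sources):
        seq = sources[src_id]
        n = depth if isinstance(depth, int) else depth.get(src_id, 0)
        if read_length > len(seq):
            raise ValueError(f"read length {read_length} exceeds source {src_id}")
        for i in range(n):
            if paired:
                flen = int(rng.integers(fragment_length[0], min(fragment_length[1], len(seq)) + 1))
                flen = max(flen, read_length)
                start = int(rng.integers(0, len(seq) - flen + 1))
                segs = [
                    (start, start + read_length, False),
                    (start + flen - read_length, start + flen, True),
                ]
            else:
                start = int(rng.integers(0, len(seq) - read_length + 1))
                segs = [(start, start + read_length, bool(rng.integers(0, 2)))]
            for mate, (s, e, rc) in enumerate(segs, 1):
                sub = seq[s:e]
                sub = _apply_errors(rng, sub, error_rate)
                if rc:
                    from .models import reverse_complement

                    sub = reverse_complement(sub)
                rid = f"{id_prefix}:{src_id}:{i}:{mate}"
                reads.append((rid, sub, "I" * len(sub)))
                if src_id in junctions:
                    j = junctions[src_id]
                    if s + 1 <= j <= e - 1:
                        span1[src_id] += 1
                    if s + 10 <= j <= e - 10:
                        span10[src_id] += 1
    return reads, span1, span10


def targeted_junction_reads(
    sources: dict[str, str],
    junctions: dict[str, int],
    n_per_source: dict[str, int] | int,
    read_length: int = 100,
    min_overhang: int = 15,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "jread",
) -> list[tuple[str, str, str]]:
    """Reads guaranteed to span each source's junction.

    Start positions are sampled uniformly among those leaving at least
    ``min_overhang`` bp on each side of the junction, giving exact control
    over per-event junction coverage (e.g. for minimum-support scenes).
    """
    rng = np.random.default_rng(seed)
    reads = []
    for src_id in sorted(junctions):
        seq = sources[src_id]
        j = junctions[src_id]
        n = n_per_source if isinstance(n_per_source, int) else n_per_source.get(src_id, 0)
        lo = max(0, j - read_length + min_overhang)
        hi = min(len(seq) - read_length, j - min_overhang)
        if hi < lo:
            raise ValueError(f"{src_id}: cannot span junction with overhang {min_overhang}")
        for i in range(n):
            start = int(rng.integers(lo, hi + 1))
            sub = _apply_errors(rng, seq[start : start + read_length], error_rate)
            reads.append((f"{id_prefix}:{src_id}:{i}", sub, "I" * read_length))
    return reads


@dataclass
class DetectionScene:
    """A complete, ground-truthed input set for the detection pipeline."""

    refs: SimReferences
    chimeras: dict[str, str]
    decoys: dict[str, str]
    manifest: TruthManifest
    reads: list[tuple[str, str, str]]
    read_length: int


def make_detection_scene(
    seed: int,
    n_transcripts: int = 200,
    n_l1: int = 30,
    n_events: int = 20,
    fraction_at_exon_boundary: float = 0.5,
    n_decoys: int = 5,
    junction_reads_per_event: int = 12,
    background_depth: int = 5,
    n_background_transcripts: int = 50,
    read_length: int = 100,
    error_rate: float = 0.0,
) -> DetectionScene:
    """Assemble the standard detection test scene.

    Implanted chimeras each receive ``junction_reads_per_event`` reads that
    span the junction by >= 15 bp on each side, on top of uniform background
    fragments from chimeras, L1-Alu fusion decoys, plain transcripts
    (pure-transcript decoy reads) and raw L1 elements (pure-L1 decoy reads).
    """
    refs = make_references(seed=seed, n_transcripts=n_transcripts, n_l1=n_l1)
    chimeras, manifest = implant_chimeras(
        refs, n_events=n_events,
        fraction_at_exon_boundary=fraction_at_exon_boundary, seed=seed + 1,
    )
    decoys, decoy_recs = make_decoys(refs, n_fusions=n_decoys, seed=seed + 2)
    manifest.decoys = decoy_recs
    junctions = {c.chimera_id: c.tx_junction_coord for c in manifest.chimeras}
    background_tx = {
        t: refs.transcripts[t] for t in sorted(refs.transcripts)[:n_background_transcripts]
    }
    pure_l1 = dict(sorted(refs.l1_library.items())[:10])
    sources = {**chimeras, **decoys, **background_tx, **pure_l1}
    reads, span1, span10 = simulate_reads(
        sources, depth=background_depth, read_length=read_length,
        error_rate=error_rate, junctions=junctions, seed=seed + 3,
    )
    jr = targeted_junction_reads(
        chimeras, junctions, junction_reads_per_event,
        read_length=read_length, error_rate=error_rate, seed=seed + 4,
    )
    reads = reads + jr
    for cid in junctions:
        manifest.junction_reads[cid] = span1.get(cid, 0) + junction_reads_per_event
        manifest.junction_reads_10[cid] = span10.get(cid, 0) + junction_reads_per_event
    return DetectionScene(refs, chimeras, decoys, manifest, reads, read_length)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for idx in np.nonzero(mask)[0]:
        choices = [b for b in "ACGT" if b != arr[idx]]
        arr[idx] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_cells(
    chimeras: dict[str, str],
    junctions: dict[str, int],
    n_cells: int = 12,
    barcode_length: int = 16,
    events_per_cell: int = 2,
    reads_per_event: int = 12,
    barcode_error_rate: float = 0.0,
    read_length: int = 100,
    max_barcode_identity: float = 0.85,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], TruthManifest]:
    """Barcoded single-cell reads: a barcode FASTQ and a cDNA FASTQ.

    True cell barcodes are rejection-sampled to pairwise identity <=
    ``max_barcode_identity``; each cell carries ``events_per_cell`` chimeric
    events whose cDNA reads all span the junction. Barcode reads carry
    substitution errors at ``barcode_error_rate`` per base.
    """
    if 4**barcode_length < 100 * n_cells:
        raise ValueError("barcode space too small for the requested cells")
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_cells:
        attempts += 1
        if attempts > 1000 * n_cells:
            raise RuntimeError("cannot satisfy barcode identity constraint")
        cand = _random_seq(rng, barcode_length)
        if all(_ungapped_identity(cand, b) <= max_barcode_identity for b in barcodes):
            barcodes.append(cand)
    event_ids = sorted(chimeras)
    manifest = TruthManifest()
    bc_reads, cdna_reads = [], []
    for ci, bc in enumerate(barcodes):
        evs = [event_ids[(ci * events_per_cell + k) % len(event_ids)] for k in range(events_per_cell)]
        manifest.cell_events[bc] = sorted(set(evs))
        for ev in evs:
            seq = chimeras[ev]
            j = junctions[ev]
            for r in range(reads_per_event):
                lo = max(0, j - read_length + 15)
                hi = min(len(seq) - read_length, j - 15)
                start = int(rng.integers(lo, hi + 1))
                cdna = seq[start : start + read_length]
                rid = f"cell{ci}:{ev}:{r}"
                obs_bc = _apply_errors(rng, bc, barcode_error_rate)
                bc_reads.append((rid, obs_bc + _random_seq(rng, 10), "I" * (barcode_length + 10)))
                cdna_reads.append((rid, cdna, "I" * len(cdna)))
                manifest.read_cells[rid] = bc
    return bc_reads, cdna_reads, manifest


def simulate_cohort(
    n_tumor: int = 40,
    n_normal: int = 40,
    n_events: int = 60,
    enriched_fraction: float = 1 / 3,
    presence_tumor: float = 0.5,
    presence_normal: float = 0.05,
    null_presence: float = 0.20,
    mean_extra_support: float = 10.0,
    depth_range: tuple[int, int] = (800_000, 1_200_000),
    baseline_hazard: float = 0.02,
    risk_hazard_ratio: float = 3.0,
    censor_range: tuple[float, float] = (6.0, 60.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Simulate an LCT count matrix plus phenotypes for the cohort statistics.

    Enriched events are present in tumors at ``presence_tumor`` and in
    normals at ``presence_normal``; null events at ``null_presence`` in
    both. Present events get a support count of 5 + Poisson(mean extra).
    Tumor samples split into high/low risk; survival is exponential with
    hazard baseline x HR^is_high, censored uniformly.

    Returns (counts events x samples, per-sample depth, phenotype table,
    truth dict with enriched event ids and true risk labels).
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i:03d}" for i in range(n_tumor)] + [f"N{i:03d}" for i in range(n_normal)]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    n_enriched = round(enriched_fraction * n_events)
    events = [f"event_{i:03d}" for i in range(n_events)]
    enriched = set(events[:n_enriched])
    counts = np.zeros((n_events, len(samples)), dtype=int)
    for ei, ev in enumerate(events):
        for si, g in enumerate(groups):
            if ev in enriched:
                p = presence_tumor if g == "tumor" else presence_normal
            else:
                p = null_presence
            if rng.random() < p:
                counts[ei, si] = 5 + rng.poisson(mean_extra_support)
    depth = pd.Series(
        rng.integers(depth_range[0], depth_range[1] + 1, len(samples)),
        index=samples,
        name="depth",
    )
    is_high = np.zeros(len(samples), dtype=bool)
    tumor_idx = np.arange(n_tumor)
    high_idx = rng.choice(tumor_idx, size=n_tumor // 2, replace=False)
    is_high[high_idx] = True
    hazard = baseline_hazard * np.where(is_high, risk_hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(censor_range[0], censor_range[1], len(samples))
    time = np.minimum(t_event, t_censor)
    status = (t_event <= t_censor).astype(int)
    pheno = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "survival_time": np.round(time, 3),
            "event_status": status,
        }
    ).set_index("sample_id")
    truth = {
        "enriched_events": sorted(enriched),
        "risk_high": [s for s, h in zip(samples, is_high) if h],
    }
    return (
        pd.DataFrame(counts, index=events, columns=samples),
        depth,
        pheno,
        truth,
    )


def simulate_survival(
    n: int = 200,
    beta: float = 0.5,
    baseline_hazard: float = 0.05,
    censor_scale: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a known log-hazard for one covariate."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(beta * x)))
    t_censor = rng.uniform(0, censor_scale, n)
    return pd.DataFrame(
        {
            "x": x,
            "time": np.minimum(t_event, t_censor),
            "status": (t_event <= t_censor).astype(int),
        }
    )
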