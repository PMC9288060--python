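"""The detection core: from non-fully-aligned reads to quantified LCT events.

Stages (in pipeline order): classify reads against the unmasked
transcriptome, anchor the L1 side of each remaining read, short-anchor the
trimmed remainder in the repeat-masked transcriptome, extend each junction
read (read_length - 1) bp along both references into a candidate chimeric
sequence, deduplicate candidates (exact + substring containment), discard
repeat-repeat fusion artifacts, count junction-spanning support reads,
apply the minimum-support filter (>= 5 reads), and annotate each surviving
event with its transcript region class and splice-junction flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .align import (
    MIN_FRAGMENT,
    AlignParams,
    LocalAlignment,
    SequenceDB,
    align_local,
    align_short_anchor,
    classify_read,
    is_repeat_fusion,
)
from .models import GeneModel, MaskedTranscriptome, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 5
DEFAULT_J_MIN = 10  # bp a support read must overhang the junction, each side
DEFAULT_SUPPORT_IDENTITY = 0.95
MAX_JUNCTION_SLACK = 3  # bp of gap/overlap tolerated between the two segments
MAX_UNEXPLAINED = 10  # read bp covered by neither segment
SPLICE_DISTANCE = 3  # junction < 3 bp from an exon boundary => splice junction


@dataclass
class ChimericReadEvidence:
    """One read's split alignment: an L1-side hit plus a transcript-side hit.

    Coordinates are on the canonicalized read (reverse-complemented when
    needed so the transcript segment matches the transcript plus strand).
    """

    read_id: str
    l1_hit: LocalAlignment
    tx_hit: LocalAlignment
    junction_read_pos: int
    orientation: str  # 'right': read = tx ++ L1; 'left': read = L1 ++ tx
    tx_junction_coord: int  # transcript coordinate of the junction
    l1_junction_coord: int  # coordinate on the L1 element
    read_length: int


@dataclass
class LCTCandidate:
    """Junction-extended candidate chimeric sequence."""

    candidate_id: str
    sequence: str
    l1_id: str
    l1_junction_coord: int
    l1_strand: str
    transcript_id: str
    tx_junction_coord: int
    read_length_used: int
    tx_flank: int
    l1_flank: int
    orientation: str
    truncated: bool = False
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.tx_flank + self.l1_flank:
            raise ValueError(
                f"{self.candidate_id}: sequence length != tx_flank + l1_flank"
            )

    @property
    def junction_pos(self) -> int:
        """Junction offset within the candidate sequence."""
        return self.tx_flank if self.orientation == "right" else self.l1_flank


@dataclass
class LCTEvent:
    """A candidate with per-sample support and annotation."""

    candidate: LCTCandidate
    sample_id: str
    support_count: int
    region_class: str = "unannotated"  # coding | utr5 | utr3 | noncoding
    splice_junction: bool = False
    gene_id: str = ""


def detect_chimeric_reads(
    reads: list[tuple[str, str]],
    l1_db: SequenceDB,
    masked_db: SequenceDB,
    params: AlignParams = AlignParams(),
    min_fragment: int = MIN_FRAGMENT,
    transcripts_unmasked: dict[str, str] | None = None,
) -> tuple[list[ChimericReadEvidence], dict]:
    """Find reads split between an L1 element and a masked transcript.

    ``reads`` must already exclude fully aligned reads. Reads whose L1-side
    fragment or transcript-side fragment is too short, or whose segments
    overlap by more than the junction slack, are dropped (tallied in the
    returned stats dict). Junctions with microhomology between the two
    references are shifted to the transcript-maximal placement so that all
    reads of one event agree on coordinates.
    """
    evidence: list[ChimericReadEvidence] = []
    stats = {"input": len(reads), "no_l1_hit": 0, "no_tx_anchor": 0, "bad_geometry": 0}
    tx_seqs = transcripts_unmasked if transcripts_unmasked is not None else masked_db.sequences
    for read_id, seq in reads:
        ev = _evidence_for_read(
            read_id, seq.upper(), l1_db, masked_db, params, min_fragment, stats, tx_seqs
        )
        if ev is not None:
            evidence.append(ev)
    stats["evidence"] = len(evidence)
    return evidence, stats


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _evidence_for_read(
    read_id: str,
    seq: str,
    l1_db: SequenceDB,
    masked_db: SequenceDB,
    params: AlignParams,
    min_fragment: int,
    stats: dict,
    tx_seqs: dict[str, str] | None = None,
) -> ChimericReadEvidence | None:
    if len(seq) < params.word_size or set(seq) - set("ACGTN"):
        stats["no_l1_hit"] += 1
        return None
    l1_hits = align_local(seq, l1_db, params, query_id=read_id, best_only=True)
    if not l1_hits:
        stats["no_l1_hit"] += 1
        return None
    l1 = l1_hits[0]
    # canonicalize: flip the read so the L1 hit sits on the plus strand
    if l1.strand == "-":
        seq = reverse_complement(seq)
        L = len(seq)
        l1 = LocalAlignment(
            read_id, L - l1.query_end, L - l1.query_start, l1.ref_id,
            l1.ref_start, l1.ref_end, "+", l1.matches, l1.aligned_length, l1.score,
        )
    L = len(seq)
    remainders = []
    if l1.query_start >= min_fragment:
        remainders.append(("left", 0, l1.query_start))
    if L - l1.query_end >= min_fragment:
        remainders.append(("right", l1.query_end, L))
    best_tx: LocalAlignment | None = None
    best_side = None
    for side, fs, fe in remainders:
        res = align_short_anchor(
            seq[fs:fe], masked_db, min_fragment=min_fragment, query_id=read_id
        )
        for h in res.hits[:1]:
            shifted = LocalAlignment(
                read_id, fs + h.query_start, fs + h.query_end, h.ref_id,
                h.ref_start, h.ref_end, h.strand, h.matches, h.aligned_length, h.score,
            )
            if best_tx is None or shifted.score > best_tx.score:
                best_tx, best_side = shifted, side
    if best_tx is None:
        stats["no_tx_anchor"] += 1
        return None
    if best_tx.strand == "-":
        # transcript matched antisense: flip the whole frame so the
        # transcript segment reads sense; the L1 hit flips with it
        seq = reverse_complement(seq)
        tx = LocalAlignment(
            read_id, L - best_tx.query_end, L - best_tx.query_start, best_tx.ref_id,
            best_tx.ref_start, best_tx.ref_end, "+",
            best_tx.matches, best_tx.aligned_length, best_tx.score,
        )
        l1 = LocalAlignment(
            read_id, L - l1.query_end, L - l1.query_start, l1.ref_id,
            l1.ref_start, l1.ref_end, "-", l1.matches, l1.aligned_length, l1.score,
        )
    else:
        tx = best_tx
    T = (tx_seqs or {}).get(tx.ref_id) or masked_db.sequences[tx.ref_id]
    S = l1_db.sequences[l1.ref_id]
    return _finish_evidence(read_id, seq, L, l1, tx, T, S, stats)


def _finish_evidence(
    read_id: str,
    seq: str,
    L: int,
    l1: LocalAlignment,
    tx: LocalAlignment,
    T: str,
    S: str,
    stats: dict,
) -> ChimericReadEvidence | None:
    if tx.query_start < l1.query_start:
        orientation = "right"  # read = tx segment then L1 segment
        inner_left_end, inner_right_start = tx.query_end, l1.query_start
    else:
        orientation = "left"
        inner_left_end, inner_right_start = l1.query_end, tx.query_start
    gap = inner_right_start - inner_left_end  # negative => overlap
    union = max(tx.query_end, l1.query_end) - min(tx.query_start, l1.query_start)
    if abs(gap) > MAX_JUNCTION_SLACK or L - union > MAX_UNEXPLAINED:
        stats["bad_geometry"] += 1
        return None
    junction, tx_j, l1_j = _refine_junction(seq, l1, tx, T, S, orientation)
    return ChimericReadEvidence(
        read_id=read_id,
        l1_hit=l1,
        tx_hit=tx,
        junction_read_pos=junction,
        orientation=orientation,
        tx_junction_coord=tx_j,
        l1_junction_coord=l1_j,
        read_length=L,
    )


REFINE_WINDOW = 15  # bp scanned either side of the raw junction estimate


def _refine_junction(
    seq: str,
    l1: LocalAlignment,
    tx: LocalAlignment,
    T: str,
    S: str,
    orientation: str,
    window: int = REFINE_WINDOW,
) -> tuple[int, int, int]:
    """Place the junction by maximizing reference-projected matches.

    Local alignment edges are unreliable at the breakpoint: an anchor can
    extend through a mismatch into the other segment, and microhomology
    makes several placements equivalent. Every split position within a
    window around the anchors' meeting point is scored as (read bases
    matching the transcript projection on one side) + (read bases matching
    the L1 projection on the other); the best split wins, with ties broken
    toward the transcript-maximal placement. Returns (junction read
    position, transcript junction coordinate, L1 junction coordinate).
    """
    L = len(seq)

    def tx_base(p: int) -> str | None:
        if orientation == "right":
            c = tx.ref_end + (p - tx.query_end)
        else:
            c = tx.ref_start + (p - tx.query_start)
        return T[c] if 0 <= c < len(T) else None

    def l1_base(p: int) -> str | None:
        if orientation == "right":
            if l1.strand == "+":
                c = l1.ref_start + (p - l1.query_start)
            else:
                c = l1.ref_end - 1 - (p - l1.query_start)
        else:
            if l1.strand == "+":
                c = l1.ref_end + (p - l1.query_end)
            else:
                c = l1.ref_start - 1 - (p - l1.query_end)
        if not 0 <= c < len(S):
            return None
        base = S[c]
        return base if l1.strand == "+" else _COMP[base]

    if orientation == "right":
        raw = (tx.query_end + l1.query_start + 1) // 2
    else:
        raw = (l1.query_end + tx.query_start + 1) // 2
    lo = max(1, raw - window)
    hi = min(L - 1, raw + window)
    positions = range(lo, hi)
    mt = {p: seq[p] == tx_base(p) for p in positions}
    ml = {p: seq[p] == l1_base(p) for p in positions}
    best_j, best_score = raw, -1
    candidates = range(lo, hi + 1)
    # transcript-maximal tie-break: for 'right' the transcript is the
    # prefix (prefer the largest j), for 'left' the suffix (smallest j)
    if orientation == "right":
        candidates = reversed(list(candidates))
    for j in candidates:
        if orientation == "right":
            s = sum(mt[p] for p in range(lo, j)) + sum(ml[p] for p in range(j, hi))
        else:
            s = sum(ml[p] for p in range(lo, j)) + sum(mt[p] for p in range(j, hi))
        if s > best_score:
            best_j, best_score = j, s
    j = best_j
    if orientation == "right":
        tx_j = tx.ref_end + (j - tx.query_end)
        l1_j = (
            l1.ref_start + (j - l1.query_start)
            if l1.strand == "+"
            else l1.ref_end - (j - l1.query_start)
        )
    else:
        tx_j = tx.ref_start + (j - tx.query_start)
        l1_j = (
            l1.ref_end + (j - l1.query_end)
            if l1.strand == "+"
            else l1.ref_start - (j - l1.query_end)
        )
    return j, tx_j, l1_j


def build_candidate(
    evidence: ChimericReadEvidence,
    l1_library: dict[str, str],
    transcripts_unmasked: dict[str, str],
    read_length: int,
) -> LCTCandidate:
    """Extend a junction read (read_length - 1) bp along both references.

    The transcript flank comes from the unmasked transcript sequence (the
    masked one would truncate extensions through repeat-derived stretches);
    flanks running off a reference end are truncated and flagged.
    """
    flank = read_length - 1
    tid, txj = evidence.tx_hit.ref_id, evidence.tx_junction_coord
    lid, l1j = evidence.l1_hit.ref_id, evidence.l1_junction_coord
    T = transcripts_unmasked[tid]
    S = l1_library[lid]
    if not (0 <= txj <= len(T)):
        raise ValueError(f"tx junction {txj} outside transcript {tid}")
    if not (0 <= l1j <= len(S)):
        raise ValueError(f"L1 junction {l1j} outside element {lid}")
    strand = evidence.l1_hit.strand
    truncated = False
    if evidence.orientation == "right":
        tx_part = T[max(0, txj - flank) : txj]
        if strand == "+":
            l1_part = S[l1j : l1j + flank]
        else:
            l1_part = reverse_complement(S[max(0, l1j - flank) : l1j])
        sequence = tx_part + l1_part
    else:
        tx_part = T[txj : txj + flank]
        if strand == "+":
            l1_part = S[max(0, l1j - flank) : l1j]
        else:
            l1_part = reverse_complement(S[l1j : l1j + flank])
        sequence = l1_part + tx_part
    truncated = len(tx_part) < flank or len(l1_part) < flank
    cid = f"{tid}:{txj}|{lid}:{l1j}|{strand}{evidence.orientation[0]}"
    return LCTCandidate(
        candidate_id=cid,
        sequence=sequence,
        l1_id=lid,
        l1_junction_coord=l1j,
        l1_strand=strand,
        transcript_id=tid,
        tx_junction_coord=txj,
        read_length_used=read_length,
        tx_flank=len(tx_part),
        l1_flank=len(l1_part),
        orientation=evidence.orientation,
        truncated=truncated,
        read_ids=[evidence.read_id],
    )


def dedup_candidates(candidates: list[LCTCandidate]) -> list[LCTCandidate]:
    """Collapse duplicate candidates at 100% identity.

    Exact-duplicate sequences merge, and a candidate whose sequence is a
    substring of a longer one (an end-truncated flank) merges into the
    longer candidate; contributing read ids accumulate.
    """
    by_seq: dict[str, LCTCandidate] = {}
    for c in candidates:
        if c.sequence in by_seq:
            by_seq[c.sequence].read_ids.extend(c.read_ids)
        else:
            by_seq[c.sequence] = LCTCandidate(**{**c.__dict__, "read_ids": list(c.read_ids)})
    ordered = sorted(by_seq.values(), key=lambda c: (-len(c.sequence), c.candidate_id))
    kept: list[LCTCandidate] = []
    for c in ordered:
        host = next((k for k in kept if c.sequence in k.sequence), None)
        if host is not None:
            host.read_ids.extend(c.read_ids)
        else:
            kept.append(c)
    for c in kept:
        c.read_ids = sorted(set(c.read_ids))
    kept.sort(key=lambda c: c.candidate_id)
    return kept


def count_support(
    candidates: list[LCTCandidate],
    reads: list[tuple[str, str]],
    j_min: int = DEFAULT_J_MIN,
    support_identity: float = DEFAULT_SUPPORT_IDENTITY,
    max_end_trim: int = 3,
    params: AlignParams | None = None,
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Count junction-spanning support reads per candidate.

    A read supports a candidate when it aligns end-to-end within the
    candidate (at most ``max_end_trim`` bp trimmed at either read end) at
    >= ``support_identity`` identity, crossing the junction by >= ``j_min``
    bp on each side. Each read is credited to its single best candidate.
    Returns (per-candidate counts, per-candidate supporting read ids).
    """
    if not candidates:
        return {}, {}
    counts = {c.candidate_id: 0 for c in candidates}
    supporters: dict[str, list[str]] = {c.candidate_id: [] for c in candidates}
    db = SequenceDB({c.candidate_id: c.sequence for c in candidates})
    junction = {c.candidate_id: c.junction_pos for c in candidates}
    if params is None:
        params = AlignParams(mode="seeded")
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < params.word_size or set(seq) - set("ACGTN"):
            continue
        passing = []
        for h in align_local(seq, db, params, query_id=read_id):
            covered = h.query_end - h.query_start
            if covered < len(seq) - 2 * max_end_trim:
                continue
            if h.identity < support_identity:
                continue
            j = junction[h.ref_id]
            if h.ref_start <= j - j_min and h.ref_end >= j + j_min:
                passing.append(h)
        if passing:
            counts[passing[0].ref_id] += 1
            supporters[passing[0].ref_id].append(read_id)
    return counts, supporters


def apply_min_support(
    events: list[LCTEvent], min_support: int = DEFAULT_MIN_SUPPORT
) -> list[LCTEvent]:
    """Keep events covered by at least ``min_support`` junction reads."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return [e for e in events if e.support_count >= min_support]


def annotate_event(
    event: LCTEvent,
    gene_models: dict[str, GeneModel],
    splice_distance: int = SPLICE_DISTANCE,
) -> LCTEvent:
    """Assign region class and the splice-junction flag.

    Region class follows the junction position against the CDS span in
    transcript coordinates; the splice-junction flag is set when the
    junction lies strictly less than ``splice_distance`` bp (default 3)
    from an internal exon boundary.
    """
    tid = event.candidate.transcript_id
    if tid not in gene_models:
        raise KeyError(f"unknown transcript {tid}")
    model = gene_models[tid]
    txj = event.candidate.tx_junction_coord
    span = model.cds_span_tx()
    if span is None:
        event.region_class = "noncoding"
    else:
        lo, hi = span
        event.region_class = "utr5" if txj < lo else "utr3" if txj >= hi else "coding"
    bounds = model.exon_boundaries_tx()
    event.splice_junction = any(abs(txj - b) < splice_distance for b in bounds)
    event.gene_id = model.gene_id
    return event


def run_detection(
    reads: list[tuple[str, str]],
    l1_library: dict[str, str],
    masked_transcriptome: MaskedTranscriptome,
    gene_models: list[GeneModel],
    repeat_library: dict[str, str] | None = None,
    sample_id: str = "sample",
    read_length: int | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    j_min: int = DEFAULT_J_MIN,
    params: AlignParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full detection pipeline on one sample's reads.

    Returns the event table (one row per event) and a stage-statistics
    dict. Deterministic: identical inputs yield a byte-identical table.
    """
    if params is None:
        params = AlignParams()
    unmasked = masked_transcriptome.unmasked_dict()
    masked = masked_transcriptome.masked_dict()
    tx_db = SequenceDB(unmasked)
    masked_db = SequenceDB(masked)
    l1_db = SequenceDB(l1_library)
    if read_length is None:
        read_length = max((len(s) for _, s in reads), default=0)
    stats: dict = {"sample_id": sample_id, "reads_in": len(reads)}

    survivors = []
    for rid, seq in reads:
        rc = classify_read(rid, seq, tx_db, params)
        if rc.label != "fully_aligned":
            survivors.append((rid, seq))
    stats["non_fully_aligned"] = len(survivors)

    evidence, dstats = detect_chimeric_reads(
        survivors, l1_db, masked_db, params, transcripts_unmasked=unmasked
    )
    stats["detect"] = dstats

    candidates = [
        build_candidate(ev, l1_library, unmasked, read_length) for ev in evidence
    ]
    candidates = dedup_candidates(candidates)
    stats["candidates"] = len(candidates)

    if repeat_library:
        rep_db = SequenceDB(repeat_library)
        candidates = [c for c in candidates if not is_repeat_fusion(c.sequence, rep_db)]
    stats["candidates_after_fusion_filter"] = len(candidates)

    support, supporters = count_support(candidates, survivors, j_min=j_min)
    events = [
        LCTEvent(candidate=c, sample_id=sample_id, support_count=support[c.candidate_id])
        for c in candidates
    ]
    events = apply_min_support(events, min_support)
    stats["events"] = len(events)
    stats["supporting_reads"] = {
        e.candidate.candidate_id: supporters[e.candidate.candidate_id] for e in events
    }

    models = {m.transcript_id: m for m in gene_models}
    events = [annotate_event(e, models) for e in events]
    rows = [
        {
            "candidate_id": e.candidate.candidate_id,
            "gene_id": e.gene_id,
            "transcript_id": e.candidate.transcript_id,
            "tx_junction_coord": e.candidate.tx_junction_coord,
            "l1_id": e.candidate.l1_id,
            "l1_junction_coord": e.candidate.l1_junction_coord,
            "support_count": e.support_count,
            "region_class": e.region_class,
            "splice_junction": e.splice_junction,
            "sample_id": e.sample_id,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "candidate_id", "gene_id", "transcript_id", "tx_junction_coord",
            "l1_id", "l1_junction_coord", "support_count", "region_class",
            "splice_junction", "sample_id",
        ],
    )
    df = df.sort_values(
        ["gene_id", "transcript_id", "tx_junction_coord", "l1_id"]
    ).reset_index(drop=True)
    return df, stats
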