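"""Local alignment kernels and read classification.

The aligner is blastn-like: affine-gap Smith-Waterman on both strands with
a seed-and-extend strategy over a k-mer index for large references, and
exhaustive full-reference DP for small problems. Bio.Align.PairwiseAligner
provides the C-accelerated DP; this module owns seeding, strand handling,
coordinate bookkeeping and the filtering/tie-break contract.

Scoring convention: match +1, mismatch -2, and a gap of length k costs
5 + 2k (blastn existence/extension semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple

from Bio import Align

from .models import reverse_complement

log = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN")

# exhaustive DP is used when total_reference_bp * query_bp is below this
AUTO_EXHAUSTIVE_CELLS = 200_000


@dataclass(frozen=True)
class AlignParams:
    """Scoring and filtering parameters for local alignment."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5  # cost of gap existence; gap of length k costs open + extend*k
    gap_extend: int = 2
    min_score: int = 16
    min_length: int = 18
    word_size: int = 11
    mode: str = "auto"  # auto | exhaustive | seeded


#: reduced word size and floors for 18-30 bp fragments (blast-short analogue)
SHORT_ANCHOR_PARAMS = AlignParams(min_score=14, min_length=11, word_size=7)

#: minimum fragment length the direct anchoring step accepts
MIN_FRAGMENT = 18


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query against a named reference sequence.

    ``query_start``/``query_end`` are always on the original (plus) query;
    for strand '-' the reverse complement of that query interval matches
    the forward reference interval.
    """

    query_id: str
    query_start: int
    query_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    aligned_length: int
    score: float

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length

    def __post_init__(self) -> None:
        if not 0 <= self.query_start < self.query_end:
            raise ValueError("invalid query interval")
        if self.aligned_length <= 0 or not 0 < self.identity <= 1:
            raise ValueError("invalid identity")


@dataclass
class ReadClass:
    """Classification of one read against the unmasked transcriptome."""

    read_id: str
    label: str  # fully_aligned | soft_clipped | unmapped
    best_alignment: LocalAlignment | None = None
    clip_lengths: tuple[int, int] = (0, 0)


class ShortAnchorResult(NamedTuple):
    hits: list[LocalAlignment]
    too_short: bool


class SequenceDB:
    """A set of named reference sequences with lazy k-mer seed indexes."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("reference set is empty")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.total_length = sum(len(v) for v in self.sequences.values())
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            idx: dict[str, list[tuple[str, int]]] = {}
            for rid in sorted(self.sequences):
                seq = self.sequences[rid]
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" in kmer:
                        continue
                    idx.setdefault(kmer, []).append((rid, i))
            self._indexes[k] = idx
        return self._indexes[k]


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    # first gapped position costs open+extend, each further position extend
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


def _validate_query(query: str) -> str:
    query = query.upper()
    bad = set(query) - VALID_CHARS
    if bad:
        raise ValueError(f"non-ACGTN characters in query: {sorted(bad)}")
    return query


def _alignment_fields(aln) -> tuple[int, int, int, int, int, int]:
    """Extract (ref_start, ref_end, q_start, q_end, matches, aligned_length)."""
    coords = aln.coordinates
    rs, re_ = int(coords[0][0]), int(coords[0][-1])
    qs, qe = int(coords[1][0]), int(coords[1][-1])
    c = aln.counts()
    matches = c.identities
    aligned_length = aln.length
    return rs, re_, qs, qe, matches, aligned_length


def _align_pair(
    aligner: Align.PairwiseAligner,
    query_id: str,
    oriented_query: str,
    qlen: int,
    strand: str,
    ref_id: str,
    ref_seq: str,
    ref_offset: int,
) -> LocalAlignment | None:
    alns = aligner.align(ref_seq, oriented_query)
    if alns.score <= 0:
        return None
    best = next(iter(alns))
    rs, re_, qs, qe, matches, alen = _alignment_fields(best)
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    if matches == 0:
        return None
    return LocalAlignment(
        query_id=query_id,
        query_start=qs,
        query_end=qe,
        ref_id=ref_id,
        ref_start=ref_offset + rs,
        ref_end=ref_offset + re_,
        strand=strand,
        matches=matches,
        aligned_length=alen,
        score=float(alns.score),
    )


def _seed_windows(
    oriented_query: str, db: SequenceDB, word_size: int, band: int = 12, pad: int = 25
) -> dict[str, list[tuple[int, int]]]:
    """Candidate reference windows from exact k-mer seed hits.

    Seeds are grouped per reference by diagonal; nearby diagonals merge into
    one band, and each band yields a reference window wide enough to hold
    the whole query plus gap slack.
    """
    idx = db.index(word_size)
    qlen = len(oriented_query)
    diags: dict[str, list[int]] = {}
    for i in range(qlen - word_size + 1):
        for rid, pos in idx.get(oriented_query[i : i + word_size], ()):
            diags.setdefault(rid, []).append(pos - i)
    windows: dict[str, list[tuple[int, int]]] = {}
    for rid, ds in diags.items():
        ds.sort()
        ref_len = len(db.sequences[rid])
        groups: list[list[int]] = []
        for d in ds:
            if groups and d - groups[-1][-1] <= band:
                groups[-1].append(d)
            else:
                groups.append([d])
        ivs = []
        for g in groups:
            start = max(0, g[0] - pad)
            end = min(ref_len, g[-1] + qlen + pad)
            ivs.append((start, end))
        # merge overlapping windows
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        windows[rid] = [(s, e) for s, e in merged]
    return windows


def align_local(
    query: str,
    db: SequenceDB,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    best_only: bool = False,
) -> list[LocalAlignment]:
    """Local-align ``query`` against every reference on both strands.

    Returns alignments with score >= ``min_score`` and aligned length >=
    ``min_length``, sorted by score descending with ties broken by
    (ref_id lexical, ref_start ascending, strand '+'first).
    """
    query = _validate_query(query)
    if len(query) < params.word_size:
        raise ValueError(
            f"query length {len(query)} below word size {params.word_size}"
        )
    mode = params.mode
    if mode == "auto":
        mode = (
            "exhaustive"
            if db.total_length * len(query) <= AUTO_EXHAUSTIVE_CELLS
            else "seeded"
        )
    aligner = _aligner(params)
    qlen = len(query)
    hits: list[LocalAlignment] = []
    for strand in ("+", "-"):
        oq = query if strand == "+" else reverse_complement(query)
        if mode == "exhaustive":
            targets = [
                (rid, db.sequences[rid], 0, len(db.sequences[rid]))
                for rid in sorted(db.sequences)
            ]
        else:
            targets = [
                (rid, db.sequences[rid][s:e], s, e)
                for rid, wins in sorted(_seed_windows(oq, db, params.word_size).items())
                for s, e in wins
            ]
        for rid, refseq, off, _ in targets:
            la = _align_pair(aligner, query_id, oq, qlen, strand, rid, refseq, off)
            if la is not None:
                hits.append(la)
    hits = [
        h
        for h in hits
        if h.score >= params.min_score and h.aligned_length >= params.min_length
    ]
    seen = set()
    unique = []
    for h in hits:
        key = (h.ref_id, h.ref_start, h.ref_end, h.query_start, h.query_end, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    unique.sort(key=lambda h: (-h.score, h.ref_id, h.ref_start, h.strand))
    return unique[:1] if best_only and unique else unique


def align_short_anchor(
    fragment: str,
    masked_db: SequenceDB,
    params: AlignParams = SHORT_ANCHOR_PARAMS,
    min_fragment: int = MIN_FRAGMENT,
    query_id: str = "fragment",
) -> ShortAnchorResult:
    """Anchor a short trimmed fragment in the masked transcriptome.

    Fragments below ``min_fragment`` bp (default 18, the floor below which
    direct anchoring is unreliable) return no hits flagged ``too_short``;
    such reads are recovered later as candidate support reads. Alignments
    whose reference span touches masked (N) positions are discarded.
    """
    if len(fragment) < min_fragment:
        return ShortAnchorResult([], True)
    hits = align_local(fragment, masked_db, params, query_id=query_id)
    clean = [
        h
        for h in hits
        if "N" not in masked_db.sequences[h.ref_id][h.ref_start : h.ref_end]
    ]
    return ShortAnchorResult(clean, False)


def classify_read(
    read_id: str,
    sequence: str,
    transcriptome_db: SequenceDB,
    params: AlignParams = AlignParams(),
    clip_threshold: int = 20,
    full_clip_max: int = 5,
    full_identity: float = 0.95,
) -> ReadClass:
    """Classify a read as fully_aligned, soft_clipped or unmapped.

    fully_aligned: the best transcriptome alignment covers the read
    end-to-end (total clip < ``full_clip_max``) at >= ``full_identity``;
    these reads carry no chimeric signal and are discarded downstream.
    soft_clipped: an alignment exists and leaves >= ``clip_threshold`` bp
    unaligned on one side. Everything else is unmapped.
    """
    try:
        sequence = _validate_query(sequence)
    except ValueError:
        return ReadClass(read_id, "unmapped")
    if len(sequence) < params.word_size:
        return ReadClass(read_id, "unmapped")
    hits = align_local(sequence, transcriptome_db, params, query_id=read_id, best_only=True)
    if not hits:
        return ReadClass(read_id, "unmapped")
    best = hits[0]
    left = best.query_start
    right = len(sequence) - best.query_end
    clips = (left, right)
    if left + right < full_clip_max and best.identity >= full_identity:
        return ReadClass(read_id, "fully_aligned", best, clips)
    if max(clips) >= clip_threshold:
        return ReadClass(read_id, "soft_clipped", best, clips)
    return ReadClass(read_id, "unmapped", best, clips)


def is_repeat_fusion(
    candidate_sequence: str,
    repeat_db: SequenceDB,
    params: AlignParams = AlignParams(),
    min_flank: int = 20,
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
) -> bool:
    """Decide whether a candidate is a repeat-repeat fusion artifact.

    The candidate's best repeat hit is removed and each remaining flank is
    re-aligned against the full repeat library (all classes, not only L1);
    the candidate is a fusion artifact when any flank matches a repeat at
    >= ``min_identity`` identity over >= ``min_coverage`` of its length.
    Invariant under reverse complement because both strands are searched.
    """
    seq = _validate_query(candidate_sequence)
    hits = align_local(seq, repeat_db, params, query_id="candidate", best_only=True)
    if not hits:
        return False
    best = hits[0]
    flanks = [seq[: best.query_start], seq[best.query_end :]]
    for flank in flanks:
        if 0 < len(flank) < min_flank:
            log.warning(
                "repeat-fusion check: flank of %d bp below minimum %d, not testable",
                len(flank),
                min_flank,
            )
        if len(flank) < max(min_flank, SHORT_ANCHOR_PARAMS.min_length):
            continue
        fparams = replace(
            SHORT_ANCHOR_PARAMS, min_score=int(len(flank) * min_coverage * 0.5)
        )
        for h in align_local(flank, repeat_db, fparams, query_id="flank"):
            cov = (h.query_end - h.query_start) / len(flank)
            if h.identity >= min_identity and cov >= min_coverage:
                return True
    return False


def import_alignments(path: str | Path, dialect: str | None = None) -> Iterator:
    """Stream externally produced alignments.

    SAM records yield ReadClass (CIGAR soft clips populate clip_lengths);
    BLAST tabular outfmt 6 rows yield LocalAlignment with 1-based inclusive
    coordinates converted to 0-based half-open. Dialect is inferred from the
    extension when not given ('.sam' vs anything else).
    """
    path = Path(path)
    if dialect is None:
        dialect = "sam" if path.suffix.lower() == ".sam" else "blast6"
    if dialect == "sam":
        yield from _import_sam(path)
    elif dialect == "blast6":
        yield from _import_blast6(path)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


_CIGAR_CONSUMES_QUERY = set("MIS=X")
_CIGAR_KNOWN = set("MIDNSHP=X")


def _import_sam(path: Path) -> Iterator[ReadClass]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield ReadClass(rec.query_name, "unmapped")
                continue
            cigar = rec.cigarstring or ""
            for op in set(c for c in cigar if c.isalpha()):
                if op not in _CIGAR_KNOWN:
                    raise ValueError(
                        f"unknown CIGAR op {op!r} in record {rec.query_name}"
                    )
            left = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
            right = rec.cigartuples[-1][1] if rec.cigartuples[-1][0] == 4 else 0
            qlen = rec.query_length or (rec.infer_read_length() or 0)
            aligned = sum(n for op, n in rec.cigartuples if op in (0, 7, 8))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            matches = max(1, aligned - int(nm))
            la = LocalAlignment(
                query_id=rec.query_name,
                query_start=left,
                query_end=qlen - right,
                ref_id=rec.reference_name,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                matches=matches,
                aligned_length=max(1, aligned),
                score=float(rec.get_tag("AS")) if rec.has_tag("AS") else float(matches),
            )
            if max(left, right) >= 20:
                label = "soft_clipped"
            elif left + right < 5:
                label = "fully_aligned"
            else:
                label = "unmapped"
            yield ReadClass(rec.query_name, label, la, (left, right))


def _import_blast6(path: Path) -> Iterator[LocalAlignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 outfmt6 columns")
            qid, sid = f[0], f[1]
            pident, length = float(f[2]), int(f[3])
            qstart, qend = int(f[6]) - 1, int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if sstart <= send:
                strand, rs, re_ = "+", sstart - 1, send
            else:
                strand, rs, re_ = "-", send - 1, sstart
            yield LocalAlignment(
                query_id=qid,
                query_start=qstart,
                query_end=qend,
                ref_id=sid,
                ref_start=rs,
                ref_end=re_,
                strand=strand,
                matches=max(1, round(pident / 100 * length)),
                aligned_length=length,
                score=float(f[11]),
            )
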