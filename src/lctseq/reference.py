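"""Reference construction: the L1 library and the repeat-masked transcriptome.

The L1 library is the set of "LINE/L1" repeat annotations lying within a
window (default 50 kb) upstream or downstream of at least one coding gene,
with their genomic sequence extracted. The transcriptome is masked by
replacing repeat-derived stretches with Ns so that the transcript-side
anchor of a chimeric read can never itself land in repeat sequence.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .models import (
    GeneModel,
    GenomicInterval,
    L1Element,
    MaskedTranscript,
    MaskedTranscriptome,
    RepeatFeature,
    reverse_complement,
)

log = logging.getLogger(__name__)

L1_FAMILY = "LINE/L1"
DEFAULT_WINDOW = 50_000  # bp up/downstream of a coding gene

# internal masker thresholds: a transcript window is masked when it aligns
# to any library repeat at >= MASK_MIN_IDENTITY over >= MASK_MIN_LENGTH bp
MASK_MIN_IDENTITY = 0.90
MASK_MIN_LENGTH = 30


def parse_repeatmasker(path: str | Path) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` file or a BED6 repeat annotation.

    Dialect is auto-detected. ``.out`` rows are 1-based inclusive and use
    'C' for the minus strand; both are converted (0-based half-open, '-').
    BED rows are taken as-is with name column = ``repeat_name#class/family``
    or plain name (family then defaults to the name itself).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # detect dialect: RepeatMasker .out has a banner ("SW  perc ...") or
    # rows whose 2nd-4th whitespace fields are numeric percentages
    is_out = False
    for line in lines[:5]:
        low = line.lower()
        if "perc" in low and "score" in low.replace("sw", "score"):
            is_out = True
        if low.strip().startswith("sw"):
            is_out = True
    if not is_out:
        # heuristic: BED data rows are tab/space separated with int cols 2,3
        probe = next((l for l in lines if l.strip() and not l.startswith("#")), "")
        f = probe.split()
        if len(f) >= 6 and f[1].isdigit() and f[2].isdigit() and f[5] in "+-":
            is_out = False
        elif len(f) >= 6:
            is_out = True  # fall through to .out row parsing
        else:
            raise ValueError(f"{path}: unrecognized repeat annotation dialect")
    feats: list[RepeatFeature] = []
    for lineno, line in enumerate(lines, 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        f = s.split()
        low = s.lower()
        if low.startswith("sw") or low.startswith("score") or "perc" in low[:30]:
            continue  # .out banner lines
        try:
            if is_out:
                feats.append(_parse_out_row(f))
            else:
                feats.append(_parse_bed_row(f))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed repeat row ({exc})") from exc
    return feats


def _parse_out_row(f: list[str]) -> RepeatFeature:
    # tolerate both full 15-column RepeatMasker rows and the compact
    # 6-column form: chrom begin end strand name class/family
    if len(f) >= 11 and f[0].replace(".", "").isdigit():
        chrom, start, end, strand, name, family = f[4], f[5], f[6], f[8], f[9], f[10]
    elif len(f) >= 6:
        chrom, start, end, strand, name, family = f[0], f[1], f[2], f[3], f[4], f[5]
    else:
        raise ValueError("too few columns for .out row")
    strand = "-" if strand in ("C", "-") else "+"
    iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
    return RepeatFeature(iv, name, family)


def _parse_bed_row(f: list[str]) -> RepeatFeature:
    chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
    strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
    if "#" in name:
        name, family = name.split("#", 1)
    else:
        family = name
    return RepeatFeature(GenomicInterval(chrom, start, end, strand), name, family)


def select_l1_near_genes(
    repeats: list[RepeatFeature],
    genes: list[GeneModel],
    genome: dict[str, str],
    window: int = DEFAULT_WINDOW,
    stranded: bool = False,
) -> list[L1Element]:
    """Select LINE/L1 repeats within ``window`` bp of any coding gene.

    Any 1 bp intersection with ``[gene.start - window, gene.end + window)``
    on the same chromosome qualifies. Sequence is extracted as plus-strand
    genomic sequence by default (set ``stranded=True`` to reverse-complement
    minus-strand elements).
    """
    coding = [g for g in genes if g.is_coding]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    missing = sorted(
        {r.interval.chrom for r in repeats if r.repeat_class_family == L1_FAMILY}
        - set(genome)
    )
    if missing:
        raise KeyError(f"chromosomes absent from genome: {', '.join(missing)}")
    out: list[L1Element] = []
    for i, rep in enumerate(repeats):
        if rep.repeat_class_family != L1_FAMILY:
            continue
        iv = rep.interval
        neighbors = {
            g.gene_id
            for g in by_chrom.get(iv.chrom, [])
            if iv.start < g.interval.end + window and g.interval.start - window < iv.end
        }
        if not neighbors:
            continue
        seq = genome[iv.chrom][iv.start : iv.end].upper()
        if stranded and iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(
            L1Element(
                id=f"{rep.repeat_name}|{iv.chrom}:{iv.start}-{iv.end}({iv.strand})",
                feature=rep,
                sequence=seq,
                neighbor_genes=neighbors,
            )
        )
    log.info("selected %d/%d L1 elements near coding genes", len(out), i + 1 if repeats else 0)
    return out


def mask_intervals(sequence: str, intervals: list[tuple[int, int]]) -> str:
    """Replace the given half-open intervals of ``sequence`` with Ns."""
    seq = list(sequence)
    for s, e in intervals:
        if not 0 <= s < e <= len(seq):
            raise ValueError(f"masked interval [{s},{e}) exceeds transcript length {len(seq)}")
        seq[s:e] = "N" * (e - s)
    return "".join(seq)


def mask_transcriptome(
    transcripts: dict[str, str],
    repeat_intervals: dict[str, list[tuple[int, int]]] | None = None,
    repeat_library: dict[str, str] | None = None,
    min_identity: float = MASK_MIN_IDENTITY,
    min_length: int = MASK_MIN_LENGTH,
) -> MaskedTranscriptome:
    """Build the repeat-masked transcriptome.

    Either precomputed per-transcript repeat intervals are applied directly,
    or the internal masker aligns every transcript against a repeat sequence
    library and masks each window hit at >= ``min_identity`` identity over
    >= ``min_length`` aligned bp.
    """
    if repeat_intervals is None and repeat_library is None:
        repeat_intervals = {}
    mt = MaskedTranscriptome()
    for tid, seq in transcripts.items():
        seq = seq.upper()
        if repeat_intervals is not None:
            ivs = sorted(repeat_intervals.get(tid, []))
        else:
            ivs = _find_repeat_windows(seq, repeat_library, min_identity, min_length)
        mt.add(MaskedTranscript(tid, seq, mask_intervals(seq, ivs), ivs))
    return mt


def _find_repeat_windows(
    seq: str,
    library: dict[str, str],
    min_identity: float,
    min_length: int,
) -> list[tuple[int, int]]:
    from .align import AlignParams, SequenceDB, align_local

    db = SequenceDB(library)
    params = AlignParams(min_score=int(min_length * min_identity), min_length=min_length)
    ivs: list[tuple[int, int]] = []
    for aln in align_local(seq, db, params, best_only=False):
        if aln.identity >= min_identity and aln.aligned_length >= min_length:
            ivs.append((aln.query_start, aln.query_end))
    return _merge_intervals(ivs)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
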