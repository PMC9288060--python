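"""Core domain types shared across the package.

All genomic coordinates are 0-based half-open ``[start, end)`` internally;
format readers convert at the boundary (GTF and RepeatMasker ``.out`` are
1-based inclusive, BED is already half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat interval, e.g. a RepeatMasker row."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class_family: str  # slash-delimited, e.g. "LINE/L1", "SINE/Alu"

    @property
    def repeat_class(self) -> str:
        return self.repeat_class_family.split("/", 1)[0]


@dataclass
class GeneModel:
    """A transcript model: ordered exons plus an optional CDS span.

    ``exons`` are genomic intervals sorted by start and pairwise disjoint;
    ``cds`` is the genomic CDS span (absent for non-coding transcripts).
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds: GenomicInterval | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"{self.transcript_id}: exon on wrong chrom")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"{self.transcript_id}: exon outside transcript span")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end
        if self.cds is not None and (
            self.cds.start < self.interval.start or self.cds.end > self.interval.end
        ):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript span")

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    def transcript_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position onto spliced transcript coordinates.

        Returns None when the position falls in an intron. Exons are walked
        in plus-strand order; minus-strand transcripts are counted from the
        transcript 3' end, which is consistent for distance computations.
        """
        offset = 0
        for e in self.exons:
            if e.start <= gpos < e.end:
                return offset + (gpos - e.start)
            offset += len(e)
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        offset = 0
        for e in self.exons:
            if tpos < offset + len(e):
                return e.start + (tpos - offset)
            offset += len(e)
        raise ValueError(
            f"transcript position {tpos} outside {self.transcript_id} "
            f"(length {self.transcript_length()})"
        )

    def exon_boundaries_tx(self) -> list[int]:
        """Internal exon/exon junction positions in transcript coordinates."""
        bounds, offset = [], 0
        for e in self.exons[:-1]:
            offset += len(e)
            bounds.append(offset)
        return bounds

    def cds_span_tx(self) -> tuple[int, int] | None:
        """CDS span in transcript coordinates, or None for non-coding."""
        if self.cds is None:
            return None
        s = self.genomic_to_transcript(self.cds.start)
        e = self.genomic_to_transcript(self.cds.end - 1)
        if s is None or e is None:
            raise ValueError(f"{self.transcript_id}: CDS edge not exonic")
        lo, hi = min(s, e), max(s, e) + 1
        return lo, hi


@dataclass
class L1Element:
    """A selected LINE-1 repeat with its extracted sequence and the coding
    genes found within the selection window."""

    id: str
    feature: RepeatFeature
    sequence: str
    neighbor_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.feature.interval):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != interval "
                f"length {len(self.feature.interval)}"
            )
        if not self.neighbor_genes:
            raise ValueError(f"{self.id}: neighbor_genes must be non-empty")


@dataclass
class MaskedTranscript:
    """Unmasked/masked sequence pair for one transcript."""

    transcript_id: str
    unmasked: str
    masked: str
    masked_intervals: list[tuple[int, int]]  # transcript coordinates, half-open

    def __post_init__(self) -> None:
        if len(self.masked) != len(self.unmasked):
            raise ValueError(f"{self.transcript_id}: masked/unmasked length mismatch")
        for s, e in self.masked_intervals:
            if not 0 <= s < e <= len(self.unmasked):
                raise ValueError(f"{self.transcript_id}: bad masked interval [{s},{e})")
            if set(self.masked[s:e]) - {"N"}:
                raise ValueError(
                    f"{self.transcript_id}: masked interval [{s},{e}) not all N"
                )


class MaskedTranscriptome(dict):
    """Mapping transcript_id -> MaskedTranscript."""

    def add(self, mt: MaskedTranscript) -> None:
        self[mt.transcript_id] = mt

    def unmasked_dict(self) -> dict[str, str]:
        return {k: v.unmasked for k, v in self.items()}

    def masked_dict(self) -> dict[str, str]:
        return {k: v.masked for k, v in self.items()}
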