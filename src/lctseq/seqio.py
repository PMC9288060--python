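"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA/FASTQ go through Bio.SeqIO; GTF is parsed line-wise into GeneModel
records (exon and CDS features keyed by transcript_id). Output tables are
TSV with a comment-prefixed provenance header so they stay parseable by
standard TSV readers.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GenomicInterval

__version_tag__ = "lctseq"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in items)
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality-string) triples, streaming."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_tsv(path: str | Path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed provenance comment lines, then header."""
    with open(path, "w") as fh:
        if provenance:
            digest = hashlib.sha256(
                repr(sorted(provenance.items())).encode()
            ).hexdigest()[:12]
            for k, v in provenance.items():
                fh.write(f"# {k}={v}\n")
            fh.write(f"# config_digest={digest}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse GTF exon/CDS features into GeneModel records.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open.
    A transcript is coding iff it carries at least one CDS feature; the CDS
    span is the union of its CDS features. Exon order in the file is ignored
    (models sort by genomic start).
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: missing transcript_id")
            gid = a.get("gene_id", tid)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand if strand in "+-" else "+")
            meta.setdefault(tid, (gid, chrom, iv.strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, exon_list in exons.items():
        gid, chrom, strand = meta[tid]
        span = GenomicInterval(
            chrom, min(e.start for e in exon_list), max(e.end for e in exon_list), strand
        )
        cspan = None
        if tid in cds:
            cs, ce = min(c.start for c in cds[tid]), max(c.end for c in cds[tid])
            if cs < span.start or ce > span.end:
                raise ValueError(f"{tid}: CDS outside transcript exon span")
            cspan = GenomicInterval(chrom, cs, ce, strand)
        models.append(GeneModel(gid, tid, span, exon_list, cspan))
    return models


def write_gtf(path: str | Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for e in m.exons:
                fh.write(
                    f"{e.chrom}\tlctseq\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.interval.strand}\t.\t{attrs}\n"
                )
            if m.cds is not None:
                fh.write(
                    f"{m.cds.chrom}\tlctseq\tCDS\t{m.cds.start + 1}\t{m.cds.end}\t.\t"
                    f"{m.interval.strand}\t.\t{attrs}\n"
                )
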