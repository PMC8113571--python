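"""Readers and writers for the standard formats the pipeline touches.

Dialects are fixed so that outputs are bit-stable:

* FASTA — wrapped at 60 columns on write; sequences uppercased on read.
* SSR BED — six tab-separated columns ``chrom start end unit_len ref_units
  name`` with 0-based half-open coordinates.
* SAM/BAM — consumed through :mod:`pysam`; plain-text SAM is the canonical
  interchange form (diffable), BAM works wherever an index is available.
* VCF 4.2 — one record per SSR locus with full repeat-tract REF/ALT strings.
* GFF3 — 1-based inclusive coordinates preserved; only ``gene`` features are
  read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when a file violates its dialect."""


# ---------------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Wrapped lines are concatenated and lowercase bases uppercased. A file
    whose first non-blank line is not a header, or a record with an empty
    sequence, raises :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header line")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# SSR BED (custom six-column dialect)


@dataclass(frozen=True)
class SsrBedRecord:
    """One SSR locus interval: 0-based half-open, tract = unit_len x ref_units."""

    chrom: str
    start: int
    end: int
    unit_len: int
    ref_units: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"{self.name}: invalid interval [{self.start},{self.end})")
        if not 2 <= self.unit_len <= 6:
            raise FormatError(f"{self.name}: unit_len {self.unit_len} outside [2,6]")
        if self.end - self.start != self.unit_len * self.ref_units:
            raise FormatError(
                f"{self.name}: span {self.end - self.start} != "
                f"{self.unit_len} x {self.ref_units}"
            )


def write_ssr_bed(records: Iterable[SsrBedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit_len}\t{r.ref_units}\t{r.name}\n")


def read_ssr_bed(path: str | Path) -> list[SsrBedRecord]:
    """Read the six-column SSR BED; the exact inverse of :func:`write_ssr_bed`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, start, end, unit_len, ref_units, name = parts
            try:
                rec = SsrBedRecord(chrom, int(start), int(end), int(unit_len), int(ref_units), name)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            span = rec.end - rec.start
            if span % rec.unit_len != 0:
                raise FormatError(
                    f"{path}:{lineno}: span {span} not divisible by unit length {rec.unit_len}"
                )
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Alignments (SAM/BAM via pysam)

#: CIGAR operations that consume the reference.
_REF_OPS = frozenset("MDN=X")
#: CIGAR operations that consume the query sequence.
_QUERY_OPS = frozenset("MIS=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped (or unmapped) read alignment with parsed CIGAR."""

    query_name: str
    reference_name: str | None
    pos: int | None  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]  # (op, length) pairs
    seq: str
    mapped: bool

    def __post_init__(self) -> None:
        if self.mapped:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if self.seq and qlen != len(self.seq):
                raise FormatError(
                    f"{self.query_name}: CIGAR consumes {qlen} query bases "
                    f"but sequence is {len(self.seq)} nt"
                )

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def reference_end(self) -> int:
        """Exclusive end of the aligned reference interval."""
        assert self.pos is not None
        return self.pos + self.reference_span


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple(
        ("MIDNSHP=X"[op], length) for op, length in (seg.cigartuples or ())
    )
    return AlignmentRecord(
        query_name=seg.query_name or "",
        reference_name=seg.reference_name,
        pos=seg.reference_start if not seg.is_unmapped else None,
        cigar=cigar,
        seq=seg.query_sequence or "",
        mapped=not seg.is_unmapped,
    )


def read_alignments(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> list[AlignmentRecord]:
    """Read mapped alignments, optionally restricted to ``(chrom, start, end)``.

    Plain-text SAM is scanned linearly; indexed BAM uses random access. The
    region is 0-based half-open and matches alignments whose reference
    interval overlaps it. Unmapped records are skipped.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), mode) as af:
        if region is not None and mode == "rb" and af.has_index():
            it: Iterator[pysam.AlignedSegment] = af.fetch(region[0], region[1], region[2])
        else:
            it = af.fetch(until_eof=True)
        for seg in it:
            if seg.is_unmapped:
                continue
            rec = _from_pysam(seg)
            if region is not None:
                chrom, start, end = region
                if rec.reference_name != chrom:
                    continue
                if rec.reference_end <= start or rec.pos >= end:  # type: ignore[operator]
                    continue
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# VCF writer for repeat-count genotypes


def write_str_vcf(matrix, loci, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with full repeat-tract REF/ALT alleles.

    ``matrix`` is a :class:`ssrscape.genotyper.GenotypeMatrix`; ``loci`` the
    matching :class:`ssrscape.mining.SSRLocus` list (aligned by locus name).
    REF is the reference tract sequence; ALT alleles are the observed
    non-reference tracts ordered by repeat count. Each sample carries
    ``GT:Q:FT`` (genotype, call quality, filter reason); missing calls are
    ``./.``.
    """
    by_name = {loc.name: loc for loc in loci}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MOTIF,Number=1,Type=String,Description="Repeat motif">',
        '##INFO=<ID=RU,Number=1,Type=Integer,Description="Reference repeat units">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=Q,Number=1,Type=Float,Description="Posterior call quality">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Call filter status">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.accessions),
    ]
    for locus_name in matrix.locus_names:
        loc = by_name[locus_name]
        ref_units = loc.units
        observed: set[int] = set()
        for acc in matrix.accessions:
            call = matrix[locus_name, acc]
            if call.is_pass:
                observed.update(call.alleles)
        alts = sorted(u for u in observed if u != ref_units)
        for units in observed:
            if units <= 0:
                raise FormatError(f"{locus_name}: non-positive allele {units}")
        allele_index = {ref_units: 0}
        for i, u in enumerate(alts, start=1):
            allele_index[u] = i
        ref_seq = loc.motif * ref_units
        alt_field = ",".join(loc.motif * u for u in alts) if alts else "."
        samples = []
        for acc in matrix.accessions:
            call = matrix[locus_name, acc]
            if call.is_pass:
                a1, a2 = call.alleles
                gt = f"{allele_index[a1]}/{allele_index[a2]}"
                samples.append(f"{gt}:{call.quality:.4f}:PASS")
            else:
                samples.append(f"./.:.:{call.reason}")
        lines.append(
            f"{loc.chrom}\t{loc.start + 1}\t{locus_name}\t{ref_seq}\t{alt_field}"
            f"\t.\t.\tMOTIF={loc.motif};RU={ref_units}\tGT:Q:FT\t" + "\t".join(samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene features


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval in GFF3 convention (1-based, inclusive ends)."""

    chrom: str
    start: int
    end: int
    feature_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.feature_id}: start {self.start} > end {self.end}")

    def to_half_open(self) -> tuple[int, int]:
        """Convert to 0-based half-open coordinates."""
        return self.start - 1, self.end


def read_gff_genes(path: str | Path) -> list[GeneFeature]:
    """Read ``gene``-type features from a GFF3 file; other types are ignored."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            feature_id = attrs.get("ID", f"gene_{lineno}")
            try:
                genes.append(GeneFeature(parts[0], int(parts[3]), int(parts[4]), feature_id))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gff_genes(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tssrscape\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.feature_id}\n"
            )
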