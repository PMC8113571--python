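"""Panel-level polymorphism screening, the filter ledger, and genic annotation.

A genotyped locus is kept as polymorphic when at least ``min_nonref_accessions``
accessions (default 2) carry a non-reference repeat-count allele; loci whose
non-missing calls are all homozygous reference — or that are missing in every
accession — are removed as monomorphic/missing, and the remainder with too few
non-reference carriers are removed separately. Every stage of the discovery
cascade is recorded in a :class:`FilterLedger` whose conservation invariants
(kept + removed = input; each stage's input equals the previous stage's kept)
are enforced on every run.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import GeneFeature
from .genotyper import GenotypeMatrix
from .mining import SSRLocus


@dataclass(frozen=True)
class LedgerStage:
    name: str
    input: int
    kept: int
    removed: int


@dataclass
class FilterLedger:
    """Stage-by-stage locus accounting of the discovery cascade."""

    stages: list[LedgerStage]

    def __post_init__(self) -> None:
        prev_kept = None
        for st in self.stages:
            if st.kept + st.removed != st.input:
                raise ValueError(
                    f"stage {st.name!r}: kept {st.kept} + removed {st.removed} "
                    f"!= input {st.input}"
                )
            if prev_kept is not None and st.input != prev_kept:
                raise ValueError(
                    f"stage {st.name!r}: input {st.input} != previous kept {prev_kept}"
                )
            prev_kept = st.kept

    @property
    def final_kept(self) -> int:
        return self.stages[-1].kept

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tinput\tkept\tremoved\n")
            for st in self.stages:
                fh.write(f"{st.name}\t{st.input}\t{st.kept}\t{st.removed}\n")


def build_ledger(stages: Sequence[tuple[str, int, int]]) -> FilterLedger:
    """Build a ledger from ``(name, input, removed)`` tuples in pipeline order."""
    out = [LedgerStage(name, inp, inp - removed, removed) for name, inp, removed in stages]
    return FilterLedger(out)


def screen_polymorphic(
    matrix: GenotypeMatrix, min_nonref_accessions: int = 2
) -> tuple[list[str], list[str], list[str]]:
    """Partition loci into (kept, removed_mono_or_missing, removed_low_nonref).

    The partition is invariant to locus-row and accession-column order.
    """
    if not matrix.locus_names or not matrix.accessions:
        raise ValueError("matrix must have at least one locus and one accession")
    kept, mono_missing, low_nonref = [], [], []
    for locus in matrix.locus_names:
        ref = matrix.ref_units[locus]
        n_nonref_acc = 0
        n_called = 0
        for acc in matrix.accessions:
            call = matrix[(locus, acc)]
            if not call.is_pass:
                continue
            n_called += 1
            assert call.alleles is not None
            if any(a != ref for a in call.alleles):
                n_nonref_acc += 1
        if n_called == 0 or n_nonref_acc == 0:
            mono_missing.append(locus)
        elif n_nonref_acc < min_nonref_accessions:
            low_nonref.append(locus)
        else:
            kept.append(locus)
    return kept, mono_missing, low_nonref


def annotate_genic(
    loci: Sequence[SSRLocus], genes: Sequence[GeneFeature]
) -> tuple[dict[str, bool], float]:
    """Flag each locus genic iff it overlaps any gene by >= 1 bp.

    Gene intervals are converted from 1-based inclusive to 0-based half-open
    before the overlap test. Returns (per-locus flag by name, genic fraction).
    """
    # sort gene intervals per chromosome; loci are few enough for bisect scans
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.to_half_open())
    for ivs in by_chrom.values():
        ivs.sort()
    flags: dict[str, bool] = {}
    for loc in loci:
        ivs = by_chrom.get(loc.chrom, [])
        starts = [iv[0] for iv in ivs]
        genic = False
        # candidate genes start before locus end; scan back over overlaps
        idx = bisect_right(starts, loc.end - 1)
        for s, e in ivs[:idx]:
            if e > loc.start:
                genic = True
                break
        flags[loc.name] = genic
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, fraction


@dataclass(frozen=True)
class CatalogEntry:
    """One polymorphic locus as reported in the marker catalog."""

    name: str
    chrom: str
    position: int  # 1-based start
    motif: str
    ref_units: int
    forward_primer: str
    reverse_primer: str
    left_flank: str
    right_flank: str
    n_alleles: int
    genic: bool
    gene_id: str


def build_catalog(
    kept: Sequence[str],
    loci_by_name: Mapping[str, SSRLocus],
    matrix: GenotypeMatrix,
    flanks: Mapping[str, tuple[str, str]] | None = None,
    primers: Mapping[str, tuple[str, str]] | None = None,
    genic_flags: Mapping[str, bool] | None = None,
    gene_ids: Mapping[str, str] | None = None,
) -> list[CatalogEntry]:
    """Assemble the polymorphic-marker catalog for the kept loci."""
    entries = []
    for name in kept:
        loc = loci_by_name[name]
        alleles: set[int] = set()
        for acc in matrix.accessions:
            call = matrix[(name, acc)]
            if call.is_pass:
                assert call.alleles is not None
                alleles.update(call.alleles)
        if len(alleles) < 2:
            raise ValueError(f"catalog locus {name} has fewer than 2 alleles")
        fwd, rev = (primers or {}).get(name, ("", ""))
        lf, rf = (flanks or {}).get(name, ("", ""))
        entries.append(
            CatalogEntry(
                name=name,
                chrom=loc.chrom,
                position=loc.start + 1,
                motif=loc.motif,
                ref_units=loc.units,
                forward_primer=fwd,
                reverse_primer=rev,
                left_flank=lf,
                right_flank=rf,
                n_alleles=len(alleles),
                genic=(genic_flags or {}).get(name, False),
                gene_id=(gene_ids or {}).get(name, ""),
            )
        )
    return entries
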