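"""In-silico diploid repeat-count genotyping from read alignments.

For each SSR locus and accession, spanning reads are reduced to an observed
repeat count by CIGAR arithmetic: the observed tract length is the reference
tract span plus inserted minus deleted bases whose reference position falls
inside the tract. A diploid genotype is then called under a symmetric
geometric stutter likelihood,

    P(k | a) = 1 − p_s                       if k = a
             = p_s (1 − rho) rho^{|k−a|−1}/2  otherwise,

with per-read mixture P(k | a1, a2) = (P(k|a1) + P(k|a2)) / 2, a uniform
prior over all unordered pairs of candidate alleles, and posterior call
quality. Calls failing the quality, flank-indel, stutter-fraction or
spanning-read-count screens are reported MISSING with the reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentRecord
from .mining import SSRLocus


@dataclass(frozen=True)
class StutterModel:
    """Global symmetric geometric stutter noise model."""

    p_s: float = 0.05  # per-read probability of a stutter event
    rho: float = 0.8  # geometric decay of the unit-shift magnitude

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_s < 1.0:
            raise ValueError("p_s must be in [0, 1)")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")

    def log_p_read(self, k: int, a: int) -> float:
        """log P(observed units k | true allele a)."""
        if k == a:
            return math.log1p(-self.p_s)
        if self.p_s == 0.0:
            return -math.inf
        shift = abs(k - a)
        return (
            math.log(self.p_s)
            + math.log1p(-self.rho)
            + (shift - 1) * math.log(self.rho)
            - math.log(2.0)
        )


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at one locus."""

    spanning: bool
    units: int | None = None  # in-frame observed repeat count
    off_frame: bool = False  # tract-length change not a unit multiple
    flank_indel: bool = False  # indel touching an anchor window


@dataclass(frozen=True)
class CallFilters:
    min_call_qual: float = 0.9
    max_flank_indel: float = 0.15
    max_stutter: float = 0.15
    min_spanning_reads: int = 5

    def __post_init__(self) -> None:
        for name in ("min_call_qual", "max_flank_indel", "max_stutter"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: MISSING reasons, in the order they are checked.
REASONS = ("no_reads", "low_qual", "flank_indel", "stutter")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid repeat-count call, or a reasoned MISSING."""

    alleles: tuple[int, int] | None  # ordered (a1 <= a2); None when missing
    quality: float  # posterior of the MAP genotype (0.0 when no likelihood)
    reason: str  # "PASS" or a MISSING reason

    @property
    def is_pass(self) -> bool:
        return self.reason == "PASS"


def measure_read(
    alignment: AlignmentRecord, locus: SSRLocus, anchor_bp: int = 10
) -> ReadObservation:
    """Reduce one alignment to a :class:`ReadObservation` at ``locus``.

    The read spans the locus iff its aligned reference interval covers
    ``[start − anchor_bp, end + anchor_bp)``. Insertions count toward the
    tract when their insertion point lies strictly inside ``(start, end)``;
    deletions by their overlap with ``[start, end)``. Any indel touching the
    two anchor windows sets ``flank_indel``.
    """
    if alignment.pos is None:
        raise ValueError("unmapped alignment")
    start, end = locus.start, locus.end
    if alignment.reference_end <= start or alignment.pos >= end:
        raise ValueError(f"{alignment.query_name} does not overlap {locus.name}")
    spanning = alignment.pos <= start - anchor_bp and alignment.reference_end >= end + anchor_bp

    delta = 0  # inserted − deleted bp inside the tract
    flank_indel = False
    win_lo = (start - anchor_bp, start)  # left anchor window
    win_hi = (end, end + anchor_bp)  # right anchor window
    ref = alignment.pos
    for op, n in alignment.cigar:
        if op in "M=X":
            ref += n
        elif op == "D" or op == "N":
            if max(ref, start) < min(ref + n, end):
                delta -= min(ref + n, end) - max(ref, start)
            if max(ref, win_lo[0]) < min(ref + n, win_lo[1]) or max(ref, win_hi[0]) < min(
                ref + n, win_hi[1]
            ):
                flank_indel = True
            ref += n
        elif op == "I":
            if start < ref < end:
                delta += n
            if win_lo[0] <= ref <= win_lo[1] or win_hi[0] <= ref <= win_hi[1]:
                flank_indel = True
        # S/H/P consume no reference

    if not spanning:
        return ReadObservation(spanning=False, flank_indel=flank_indel)
    tract_bp = (end - start) + delta
    if tract_bp < 0 or tract_bp % locus.unit_len != 0:
        return ReadObservation(spanning=True, off_frame=True, flank_indel=flank_indel)
    return ReadObservation(
        spanning=True, units=tract_bp // locus.unit_len, flank_indel=flank_indel
    )


def genotype_likelihood(
    observations: Sequence[ReadObservation],
    genotype: tuple[int, int],
    stutter: StutterModel,
) -> float:
    """Log-likelihood of a diploid genotype given in-frame observations.

    Off-frame and flank-indel reads carry no repeat count and are excluded.
    """
    a1, a2 = genotype
    total = 0.0
    used = 0
    for obs in observations:
        if obs.units is None or obs.flank_indel:
            continue
        used += 1
        l1 = stutter.log_p_read(obs.units, a1)
        l2 = stutter.log_p_read(obs.units, a2)
        if l1 == -math.inf and l2 == -math.inf:
            return -math.inf
        m = max(l1, l2)
        total += m + math.log((math.exp(l1 - m) + math.exp(l2 - m)) / 2.0)
    if used == 0:
        raise ValueError("no usable in-frame observations")
    return total


def _posterior(
    observations: Sequence[ReadObservation],
    candidates: Sequence[int],
    stutter: StutterModel,
) -> dict[tuple[int, int], float]:
    """Posterior over all unordered candidate pairs under a uniform prior."""
    pairs = list(combinations_with_replacement(sorted(candidates), 2))
    logs = [genotype_likelihood(observations, g, stutter) for g in pairs]
    m = max(logs)
    if m == -math.inf:
        # all genotypes impossible: flat posterior
        return {g: 1.0 / len(pairs) for g in pairs}
    ws = [math.exp(l - m) for l in logs]
    z = sum(ws)
    return {g: w / z for g, w in zip(pairs, ws)}


def call_genotype(
    observations: Sequence[ReadObservation],
    stutter: StutterModel,
    filters: CallFilters,
    ref_units: int,
) -> GenotypeCall:
    """MAP diploid call with the quality/flank-indel/stutter screens.

    Candidate alleles are the distinct in-frame observed repeat counts plus
    the reference count. Ties in the posterior break toward the pair
    containing the reference allele, then lexicographically.
    """
    spanning = [o for o in observations if o.spanning]
    if len(spanning) < filters.min_spanning_reads:
        return GenotypeCall(None, 0.0, "no_reads")
    usable = [o for o in spanning if not o.flank_indel]
    in_frame = [o for o in usable if o.units is not None]
    off_frame = [o for o in usable if o.off_frame]
    if not in_frame:
        return GenotypeCall(None, 0.0, "no_reads")

    candidates = sorted({o.units for o in in_frame} | {ref_units})  # type: ignore[arg-type]
    post = _posterior(in_frame, candidates, stutter)
    best_q = max(post.values())
    # deterministic tie-break: ref-containing pairs first, then lexicographic
    tied = [g for g, q in post.items() if abs(q - best_q) <= 1e-12]
    tied.sort(key=lambda g: (ref_units not in g, g))
    genotype = tied[0]
    quality = post[genotype]

    if quality < filters.min_call_qual:
        return GenotypeCall(genotype, quality, "low_qual")
    flank_frac = sum(1 for o in spanning if o.flank_indel) / len(spanning)
    if flank_frac > filters.max_flank_indel:
        return GenotypeCall(genotype, quality, "flank_indel")
    n_frame = len(in_frame) + len(off_frame)
    mismatching = sum(1 for o in in_frame if o.units not in genotype) + len(off_frame)
    if n_frame > 0 and mismatching / n_frame > filters.max_stutter:
        return GenotypeCall(genotype, quality, "stutter")
    return GenotypeCall(genotype, quality, "PASS")


@dataclass
class GenotypeMatrix:
    """Loci x accessions grid of :class:`GenotypeCall` with reference counts."""

    locus_names: list[str]
    accessions: list[str]
    ref_units: dict[str, int]
    calls: dict[tuple[str, str], GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")

    def __getitem__(self, key: tuple[str, str]) -> GenotypeCall:
        return self.calls[key]

    def set(self, locus: str, accession: str, call: GenotypeCall) -> None:
        self.calls[(locus, accession)] = call

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for locus in self.locus_names:
            for acc in self.accessions:
                call = self.calls[(locus, acc)]
                a1, a2 = call.alleles if call.alleles else (".", ".")
                rows.append(
                    {
                        "locus": locus,
                        "accession": acc,
                        "a1": a1,
                        "a2": a2,
                        "quality": round(call.quality, 4),
                        "status": call.reason,
                    }
                )
        return rows


def genotype_panel(
    alignment_sets: Mapping[str, Sequence[AlignmentRecord]],
    loci: Sequence[SSRLocus],
    stutter: StutterModel | None = None,
    filters: CallFilters | None = None,
    anchor_bp: int = 10,
) -> GenotypeMatrix:
    """Call every locus in every accession from per-accession alignments.

    ``alignment_sets`` maps accession id to that accession's mapped reads
    (all against the same reference as ``loci``). Loci with no overlapping
    reads in an accession yield MISSING(no_reads) there.
    """
    stutter = stutter or StutterModel()
    filters = filters or CallFilters()
    accessions = list(alignment_sets)
    matrix = GenotypeMatrix(
        locus_names=[l.name for l in loci],
        accessions=accessions,
        ref_units={l.name: l.units for l in loci},
    )
    # bucket alignments by chromosome once per accession
    by_chrom: dict[str, dict[str, list[AlignmentRecord]]] = {}
    for acc, alns in alignment_sets.items():
        buckets: dict[str, list[AlignmentRecord]] = {}
        for a in alns:
            if a.mapped and a.reference_name is not None:
                buckets.setdefault(a.reference_name, []).append(a)
        for b in buckets.values():
            b.sort(key=lambda a: a.pos)  # type: ignore[arg-type, return-value]
        by_chrom[acc] = buckets
    for locus in loci:
        for acc in accessions:
            obs = []
            for aln in by_chrom[acc].get(locus.chrom, ()):
                if aln.reference_end <= locus.start or aln.pos >= locus.end:  # type: ignore[operator]
                    continue
                obs.append(measure_read(aln, locus, anchor_bp=anchor_bp))
            matrix.set(locus.name, acc, call_genotype(obs, stutter, filters, locus.units))
    return matrix
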