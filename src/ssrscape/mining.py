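"""Perfect-SSR mining and locus-level filtering.

Detects maximal perfect tandem repeats of primitive 2–6 bp motifs in a
reference sequence under per-unit-length minimum repeat-count thresholds
(defaults: di 6, tri 5, tetra/penta/hexa 4), then applies the marker-development filters: drop A/T-only motifs, drop
close pairs of loci, extract fixed-width flanks, and summarize counts and
densities per chromosome and per motif-length class.

Maximality convention: a run is a character-level maximal periodic interval
(it cannot be extended by one base in either direction while keeping period
``unit_len``); the reported tract is the leftmost whole-unit tiling of that
interval, i.e. ``floor(len / unit_len)`` units starting at its left edge.
Runs spanning an ``N`` are broken at the ``N``. A run representable at
several unit lengths is reported once, at its smallest primitive unit.
Mononucleotide repeats are never reported (an all-one-base motif is not
primitive at unit length >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import SequenceRecord, SsrBedRecord

#: Minimum repeat counts per unit length: di 6, tri 5, tetra/penta/hexa 4.
DEFAULT_MIN_UNITS: dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}

_CLASS_NAMES = {2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa"}


@dataclass(frozen=True)
class MiningConfig:
    min_units: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_UNITS))
    flank_len: int = 250
    min_gap: int = 100

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.min_units.values()):
            raise ValueError("all min_units thresholds must be >= 2")
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat on one chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    motif: str
    units: int

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def name(self) -> str:
        return name_locus(self)

    def to_bed(self) -> SsrBedRecord:
        return SsrBedRecord(self.chrom, self.start, self.end, self.unit_len, self.units, self.name)


@dataclass(frozen=True)
class FlankedLocus:
    locus: SSRLocus
    left_flank: str
    right_flank: str
    truncated: bool


def name_locus(locus: SSRLocus) -> str:
    """Locus name ``{chrom}_{unit_len}_{start+1}`` (1-based start)."""
    return f"{locus.chrom}_{locus.unit_len}_{locus.start + 1}"


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a tandem repetition of a shorter word."""
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside [1,6]")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(record: SequenceRecord, config: MiningConfig | None = None) -> list[SSRLocus]:
    """Find all qualifying perfect SSR loci in one sequence, sorted by start.

    Every maximal periodic run of a primitive motif with unit length in
    [2, 6] and at least ``min_units[unit_len]`` whole repeats is reported
    exactly once at its smallest primitive unit. Reported loci never overlap:
    the rare cross-unit-length collisions are resolved greedily by
    ``(start, unit_len)``.
    """
    config = config or MiningConfig()
    seq = record.seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    valid = arr != b"N"
    candidates: list[SSRLocus] = []
    for u in sorted(config.min_units):
        min_units = config.min_units[u]
        if len(seq) < u * min_units:
            continue
        eq = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        # run starts/ends over the boolean periodicity track
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in eq coordinates
        for a, b in zip(starts, ends):
            periodic_len = (b - a) + u  # bases in the periodic interval
            units = periodic_len // u
            if units < min_units:
                continue
            motif = seq[a : a + u]
            if not is_primitive(motif):
                continue
            candidates.append(SSRLocus(record.id, int(a), int(a + units * u), motif, int(units)))
    candidates.sort(key=lambda l: (l.start, l.unit_len))
    out: list[SSRLocus] = []
    last_end = -1
    for loc in candidates:
        if loc.start >= last_end:
            out.append(loc)
            last_end = loc.end
    return out


def filter_at_only(loci: Sequence[SSRLocus]) -> tuple[list[SSRLocus], list[SSRLocus]]:
    """Partition loci into (kept, removed) by the A/T-only motif rule."""
    kept, removed = [], []
    for loc in loci:
        (removed if set(loc.motif) <= {"A", "T"} else kept).append(loc)
    return kept, removed


def filter_proximal(
    loci: Sequence[SSRLocus], min_gap: int = 100
) -> tuple[list[SSRLocus], list[SSRLocus]]:
    """Remove BOTH members of every same-chromosome pair closer than ``min_gap``.

    Adjacency is evaluated on the original (sorted, non-overlapping) list, so
    a locus with any close neighbor is removed even if that neighbor is
    removed for the same reason.
    """
    by_pos = sorted(loci, key=lambda l: (l.chrom, l.start))
    if by_pos != list(loci):
        raise ValueError("loci must be sorted by (chrom, start)")
    doomed: set[int] = set()
    for i in range(len(by_pos) - 1):
        a, b = by_pos[i], by_pos[i + 1]
        if a.chrom != b.chrom:
            continue
        if b.start < a.end:
            raise ValueError(f"overlapping loci {a.name} and {b.name}")
        if b.start - a.end < min_gap:
            doomed.update((i, i + 1))
    kept = [loc for i, loc in enumerate(by_pos) if i not in doomed]
    removed = [loc for i, loc in enumerate(by_pos) if i in doomed]
    return kept, removed


def extract_flanks(
    loci: Sequence[SSRLocus],
    genome: Mapping[str, str] | Sequence[SequenceRecord],
    flank_len: int = 250,
) -> list[FlankedLocus]:
    """Extract up to ``flank_len`` bp of reference sequence on each side.

    Flanks are clipped at chromosome ends and flagged ``truncated``.
    """
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec.seq for rec in genome}
    out = []
    for loc in loci:
        seq = genome[loc.chrom]
        if loc.end > len(seq):
            raise ValueError(f"{loc.name} extends beyond chromosome end")
        left = seq[max(0, loc.start - flank_len) : loc.start]
        right = seq[loc.end : loc.end + flank_len]
        truncated = len(left) < flank_len or len(right) < flank_len
        out.append(FlankedLocus(loc, left, right, truncated))
    return out


def _round(value: float, ndigits: int) -> float:
    """Decimal half-up rounding for report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def density_per_mb(count: int, length_bp: int, ndigits: int = 1) -> float:
    """Loci per megabase, rounded half-up to ``ndigits`` decimals."""
    if length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    return _round(count / (length_bp / 1e6), ndigits)


def class_percentages(class_counts: Mapping[int, int], ndigits: int = 2) -> dict[int, float]:
    """Percent share of each motif-length class, rounded half-up."""
    total = sum(class_counts.values())
    if total == 0:
        return {u: 0.0 for u in class_counts}
    return {u: _round(100.0 * c / total, ndigits) for u, c in class_counts.items()}


@dataclass
class MiningSummary:
    """Per-chromosome and per-motif-length accounting of one mining run."""

    per_chrom: dict[str, dict[str, float]]  # chrom -> {length_bp, count, density}
    per_class: dict[int, dict[str, float]]  # unit_len -> {count, percent}
    total: int

    def to_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for chrom, d in self.per_chrom.items():
            rows.append({"chromosome": chrom, **d})
        return rows


def summarize(loci: Sequence[SSRLocus], chrom_lengths: Mapping[str, int]) -> MiningSummary:
    """Counts, densities per Mb (1 decimal) and class percentages (2 decimals)."""
    for loc in loci:
        if loc.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {loc.chrom!r}")
    per_chrom = {}
    for chrom, length in chrom_lengths.items():
        count = sum(1 for l in loci if l.chrom == chrom)
        per_chrom[chrom] = {
            "length_bp": length,
            "count": count,
            "density_per_mb": density_per_mb(count, length),
        }
    class_counts = {u: sum(1 for l in loci if l.unit_len == u) for u in range(2, 7)}
    pct = class_percentages(class_counts)
    per_class = {
        u: {"count": class_counts[u], "percent": pct[u], "label": _CLASS_NAMES[u]}
        for u in range(2, 7)
    }
    return MiningSummary(per_chrom=per_chrom, per_class=per_class, total=len(loci))
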