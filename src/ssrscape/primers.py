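"""Primer feasibility search over SSR locus flanks.

A deterministic stand-in for a full thermodynamic primer designer: it decides
which loci are "primer designable" under the marker-development constraints
(product 100–400 bp, annealing 60 °C within 59–61 °C, GC >= 40%, primer
length 20 bp within 18–25 nt) using a simple composition melting-temperature
formula, Tm = 64.9 + 41 (nGC − 16.4) / N. Two cheap secondary-structure
guards are applied: primers with a homopolymer run of five or more bases are
rejected, as are pairs whose 3'-terminal 4-mers are mutually complementary.
The search is exhaustive and deterministic, so identical inputs always give
identical pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mining import FlankedLocus

#: M13 tail prepended to forward primers for fluorescent-dye genotyping.
M13_TAIL = "CACGACGTTGTAAAACGAC"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    product_min: int = 100
    product_max: int = 400
    tm_opt: float = 60.0
    tm_lo: float = 59.0
    tm_hi: float = 61.0
    min_gc: float = 0.40
    len_opt: int = 20
    len_min: int = 18
    len_max: int = 25

    def __post_init__(self) -> None:
        if not (self.tm_lo <= self.tm_opt <= self.tm_hi):
            raise ValueError("require tm_lo <= tm_opt <= tm_hi")
        if self.product_min > self.product_max or self.len_min > self.len_max:
            raise ValueError("empty product-size or primer-length range")


@dataclass(frozen=True)
class PrimerPair:
    """An admissible primer pair; both primers are written 5'->3'."""

    forward: str
    reverse: str
    product_len: int
    forward_tm: float
    reverse_tm: float
    forward_gc: float
    reverse_gc: float


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length for a non-empty ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Composition Tm in °C: 64.9 + 41 (nGC − 16.4) / N, for 10–40 nt."""
    if not 10 <= len(seq) <= 40:
        raise ValueError(f"length {len(seq)} outside [10, 40]")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    ngc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (ngc - 16.4) / len(seq)


def has_homopolymer(seq: str, max_run: int = 4) -> bool:
    """True if any single base repeats more than ``max_run`` times in a row."""
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


def _admissible(seq: str, c: PrimerConstraints) -> tuple[float, float] | None:
    """Return (tm, gc) if the primer satisfies the single-primer constraints."""
    if "N" in seq:
        return None
    gc = gc_fraction(seq)
    if gc < c.min_gc:
        return None
    tm = melting_temp(seq)
    if not c.tm_lo <= tm <= c.tm_hi:
        return None
    if has_homopolymer(seq):
        return None
    return tm, gc


def _three_prime_clash(forward: str, reverse: str) -> bool:
    """True if the 3'-terminal 4-mers of the two primers are complementary."""
    return forward[-4:] == revcomp(reverse[-4:])


def design_primer_pair(
    flanked: FlankedLocus, constraints: PrimerConstraints | None = None
) -> PrimerPair | None:
    """Deterministic exhaustive scan for the best admissible primer pair.

    Candidate forward primers are substrings of the left flank ending at
    least one base before the repeat tract; reverse primers are reverse
    complements of right-flank substrings starting at least one base after
    it. Among admissible pairs (every constraint plus both guards) the
    winner minimizes (sum |Tm − opt|, sum |len − opt|, product length,
    positions); ``None`` means the locus is not primer-designable.
    """
    c = constraints or PrimerConstraints()
    left, right = flanked.left_flank, flanked.right_flank
    tract_len = flanked.locus.end - flanked.locus.start

    # Forward candidates: (tm_dev, len_dev, left_gap, seq, tm, gc).
    fwd: list[tuple[float, int, int, str, float, float]] = []
    for length in range(c.len_min, c.len_max + 1):
        for end in range(length, len(left)):  # end < len(left): >=1 bp before tract
            seq = left[end - length : end]
            res = _admissible(seq, c)
            if res is None:
                continue
            tm, gc = res
            left_gap = len(left) - end  # bases between primer 3' end and tract
            fwd.append((abs(tm - c.tm_opt), abs(length - c.len_opt), left_gap, seq, tm, gc))
    if not fwd:
        return None

    rev: list[tuple[float, int, int, str, float, float]] = []
    for length in range(c.len_min, c.len_max + 1):
        for start in range(1, len(right) - length + 1):  # start >= 1 bp after tract
            template = right[start : start + length]
            res = _admissible(revcomp(template), c)
            if res is None:
                continue
            tm, gc = res
            right_gap = start + length  # tract end to reverse primer 5' end
            rev.append((abs(tm - c.tm_opt), abs(length - c.len_opt), right_gap, revcomp(template), tm, gc))
    if not rev:
        return None

    fwd.sort()
    rev.sort()
    best: tuple | None = None
    best_pair: PrimerPair | None = None
    for ftd, fld, fgap, fseq, ftm, fgc in fwd:
        if best is not None and ftd > best[0]:
            break  # reverse tm_dev >= 0, cannot beat the incumbent
        for rtd, rld, rgap, rseq, rtm, rgc in rev:
            key0 = ftd + rtd
            if best is not None and key0 > best[0]:
                break
            product = fgap + len(fseq) + tract_len + rgap
            if not c.product_min <= product <= c.product_max:
                continue
            if _three_prime_clash(fseq, rseq):
                continue
            key = (key0, fld + rld, product, fgap, rgap, fseq, rseq)
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(
                    forward=fseq,
                    reverse=rseq,
                    product_len=product,
                    forward_tm=ftm,
                    reverse_tm=rtm,
                    forward_gc=fgc,
                    reverse_gc=rgc,
                )
    return best_pair


def add_m13_tail(primer: str) -> str:
    """Prepend the M13 tail CACGACGTTGTAAAACGAC to a non-empty primer."""
    if not primer:
        raise ValueError("empty primer")
    return M13_TAIL + primer
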