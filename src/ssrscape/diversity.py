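"""Marker characterization and panel genetics on binary band scores.

Dominant 1/0 band scoring cannot distinguish homozygotes from heterozygotes,
so allele frequencies are band-share frequencies: the count of accessions
carrying an allele divided by the total carrier count at the locus. On those
frequencies,

    He  = 1 − Σ p_i²                                (expected heterozygosity)
    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²          (Botstein convention)

Also provides PCA on the centred score matrix, Jaccard distances between
accessions, a Saitou–Nei neighbor-joining tree (exact on additive matrices),
and a STRUCTURE-format export of the binary data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyper import GenotypeMatrix

#: Missing-data mark in binary score frames (distinct from 0).
MISSING = np.nan


def genotypes_to_binary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Binary band-score frame: accessions x "locus:allele" columns.

    An accession scores 1 for an allele column iff either of its called
    alleles equals that repeat count; MISSING calls become NaN. Loci with no
    PASS calls contribute no columns.
    """
    columns: dict[str, list[float]] = {}
    for locus in matrix.locus_names:
        alleles: set[int] = set()
        for acc in matrix.accessions:
            call = matrix[(locus, acc)]
            if call.is_pass:
                assert call.alleles is not None
                alleles.update(call.alleles)
        for allele in sorted(alleles):
            col = []
            for acc in matrix.accessions:
                call = matrix[(locus, acc)]
                if not call.is_pass:
                    col.append(MISSING)
                else:
                    col.append(1.0 if allele in call.alleles else 0.0)  # type: ignore[operator]
            columns[f"{locus}:{allele}"] = col
    return pd.DataFrame(columns, index=list(matrix.accessions))


def _locus_of(column: str) -> str:
    return column.rsplit(":", 1)[0]


def loci_of(scores: pd.DataFrame) -> list[str]:
    """Distinct locus names, in column order."""
    seen: dict[str, None] = {}
    for c in scores.columns:
        seen.setdefault(_locus_of(c), None)
    return list(seen)


def allele_frequencies(locus_scores: pd.DataFrame) -> np.ndarray:
    """Band-share frequencies for one locus's allele columns.

    ``locus_scores`` holds the 1/0/NaN columns of a single locus; frequencies
    are carrier counts normalized to sum to one.
    """
    counts = np.nansum(locus_scores.to_numpy(dtype=float), axis=0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("locus has no scored carriers")
    return counts / total


def _check_freqs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return p


def expected_heterozygosity(p: Sequence[float] | np.ndarray) -> float:
    """He = 1 − Σ p_i²."""
    p = _check_freqs(np.asarray(p))
    return float(1.0 - np.sum(p**2))


def pic(p: Sequence[float] | np.ndarray) -> float:
    """PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²."""
    p = _check_freqs(np.asarray(p))
    sq = p**2
    sum_sq = float(np.sum(sq))
    cross = (sum_sq**2 - float(np.sum(sq**2))) / 2.0  # Σ_{i<j} p_i² p_j²
    return float(1.0 - sum_sq - 2.0 * cross)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MarkerStats:
    """Per-locus Na/He/PIC plus panel means (full precision)."""

    table: pd.DataFrame  # index locus, columns Na, He, PIC
    mean_na: float
    mean_he: float
    mean_pic: float

    def report(self) -> pd.DataFrame:
        """Report table rounded to 2 decimals (half-up), with a mean row."""
        rep = self.table.copy()
        rep["He"] = rep["He"].map(_round2)
        rep["PIC"] = rep["PIC"].map(_round2)
        rep.loc["Mean"] = [
            _round2(self.mean_na),
            _round2(self.mean_he),
            _round2(self.mean_pic),
        ]
        return rep


def marker_stats_table(scores: pd.DataFrame) -> MarkerStats:
    """Na, He and PIC per locus and their arithmetic panel means."""
    rows = {}
    for locus in loci_of(scores):
        cols = [c for c in scores.columns if _locus_of(c) == locus]
        p = allele_frequencies(scores[cols])
        rows[locus] = {
            "Na": int(len(p)),
            "He": expected_heterozygosity(p),
            "PIC": pic(p),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[["Na", "He", "PIC"]]
    return MarkerStats(
        table=table,
        mean_na=float(table["Na"].mean()),
        mean_he=float(table["He"].mean()),
        mean_pic=float(table["PIC"].mean()),
    )


def pca(scores: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centred binary matrix via SVD.

    Missing marks are mean-imputed per column before centring. Returns
    (coordinates, variance-explained per component). Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 accessions and 2 allele columns")
    x = scores.to_numpy(dtype=float)
    col_means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_means, inds[1])
    x = x - x.mean(axis=0)
    if not np.any(x):
        raise ValueError("constant score matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic signs: flip so each component's largest |loading| is positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u * s
    var_explained = s**2 / float(np.sum(s**2))
    frame = pd.DataFrame(
        coords,
        index=scores.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, var_explained


def distance_matrix(scores: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise Jaccard distances between accessions over co-scored columns."""
    if metric != "jaccard":
        raise ValueError(f"unsupported metric {metric!r}")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    x = scores.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not np.any(both):
                raise ValueError(
                    f"accessions {scores.index[i]!r} and {scores.index[j]!r} share no scored columns"
                )
            a, b = x[i, both] > 0, x[j, both] > 0
            union = np.sum(a | b)
            d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - np.sum(a & b) / union
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


# ---------------------------------------------------------------------------
# Neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[tuple[_Node, float]] = []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(d: pd.DataFrame) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted tree in Newick.

    Q-criterion ties break toward the smallest index pair; negative branch
    lengths are clamped to zero. Additive matrices are recovered exactly.
    """
    if d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError("need a square distance matrix with n >= 3")
    if not np.allclose(d.to_numpy(), d.to_numpy().T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    labels = list(d.index)
    nodes: list[_Node] = [_Node(str(l)) for l in labels]
    mat = d.to_numpy(dtype=float).copy()
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sums = {i: sum(mat[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n - 2) * mat[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        assert best is not None
        _, i, j = best
        li = 0.5 * mat[i, j] + (sums[i] - sums[j]) / (2 * (n - 2))
        lj = mat[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # distances from the new node to the remaining taxa
        new_row = np.zeros(mat.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (mat[i, k] + mat[j, k] - mat[i, j])
        mat = np.pad(mat, ((0, 1), (0, 1)))
        mat[-1, : len(new_row) - 1] = new_row[:-1]
        mat[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = _Node()
    root.children = [(nodes[i], max(mat[i, j], 0.0)), (nodes[j], 0.0)]
    return root.newick() + ";"


def export_structure(scores: pd.DataFrame, path: str | Path) -> None:
    """Write STRUCTURE input: one row per accession, −9 for missing data."""
    with open(path, "w") as fh:
        for acc in scores.index:
            vals = []
            for v in scores.loc[acc]:
                vals.append("-9" if pd.isna(v) else str(int(v)))
            fh.write(str(acc) + "\t" + "\t".join(vals) + "\n")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    """Read an accessions x "locus:allele" band-score TSV (NA = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", na_rep="NA")
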