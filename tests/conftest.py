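from __future__ import annotations

import numpy as np
import pytest

from ssrscape import simdata


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A small simulated panel with reads on disk, shared across tests."""
    out = tmp_path_factory.mktemp("panel")
    cfg = simdata.PanelSimConfig(
        n_chrom=1,
        chrom_len=30_000,
        n_loci_per_chrom=8,
        n_accessions=6,
        seed=5,
    )
    truth, paths = simdata.simulate_all(cfg, out)
    return cfg, truth, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_ssrs(seq: str, min_units: dict[int, int]) -> list[tuple[int, int, str]]:
    """Quadratic reference scanner for perfect SSR runs.

    Independent of the production detector: for every (start, unit length)
    pair it counts whole-unit repeats by string comparison, requires a
    primitive motif without N, left-maximality at character level (no base
    continues the periodicity to the left), and then applies the same greedy
    (start, unit_len) overlap resolution the package documents.
    """
    candidates = []
    n = len(seq)
    for u in range(2, 7):
        need = min_units[u]
        for i in range(0, n - u * need + 1):
            motif = seq[i : i + u]
            if "N" in motif:
                continue
            # primitive check by divisor enumeration
            primitive = all(
                not (u % d == 0 and motif == motif[:d] * (u // d)) for d in range(1, u)
            )
            if not primitive:
                continue
            # character-level left maximality
            if i >= 1 and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                continue
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == motif:
                k += 1
            if k >= need:
                candidates.append((i, i + k * u, motif))
    candidates.sort(key=lambda c: (c[0], len(c[2])))
    out: list[tuple[int, int, str]] = []
    last_end = -1
    for start, end, motif in candidates:
        if start >= last_end:
            out.append((start, end, motif))
            last_end = end
    return out


def random_repeat_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """Background sequence salted with tandem runs of assorted motifs and Ns."""
    seq = list(rng.choice(list("ACGT"), size=length))
    n_runs = max(3, length // 500)
    for _ in range(n_runs):
        u = int(rng.integers(1, 7))
        units = int(rng.integers(2, 12))
        motif = "".join(rng.choice(list("ACGT"), size=u))
        pos = int(rng.integers(0, max(1, length - u * units)))
        seq[pos : pos + u * units] = list(motif * units)
    for _ in range(length // 1000):
        seq[int(rng.integers(0, length))] = "N"
    return "".join(seq[:length])
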