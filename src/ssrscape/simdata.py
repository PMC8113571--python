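"""Synthetic reference, accession panel, and pre-aligned read generator.

Emulates the study design the pipeline targets: a multi-chromosome reference
with planted perfect di- to hexanucleotide SSR tracts, a diploid panel of
resequenced accessions differing in repeat counts at a configured polymorphic
fraction, and reads at a configured depth (default 30x) whose CIGARs already
encode the tract-length changes, with a geometric stutter noise process and
background substitution errors. Everything is driven by one seed and is
byte-deterministic.

The background sequence is rejection-screened so the mined locus set equals
the planted locus set exactly (planted-recovery tests are exact); planted
motifs are primitive and never A/T-only, so planted loci survive the
marker-development filters. Reads are emitted pre-aligned with correct
POS/CIGAR (single-end, FLAG 0): alignment itself is outside the pipeline, and
the genotyper consumes spanning reads only. Reads whose placement would
require clipping inside a length-changed tract are not emitted; they would be
non-spanning and carry no repeat-count information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .formats import GeneFeature, SequenceRecord, write_fasta, write_gff_genes, write_ssr_bed
from .genotyper import StutterModel
from .mining import DEFAULT_MIN_UNITS, MiningConfig, SSRLocus, find_ssrs, is_primitive

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PanelSimConfig:
    """Study-scale knobs for the synthetic panel.

    Defaults mirror the emulated study: 21 accessions resequenced at 30x,
    motif-length mix weighted like a plant genome survey (di most abundant),
    roughly 31% of mineable loci polymorphic, stutter probability 0.05 with
    geometric decay 0.8.
    """

    n_chrom: int = 2
    chrom_len: int = 60_000
    n_loci_per_chrom: int = 15
    motif_len_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.41, 3: 0.31, 4: 0.14, 5: 0.09, 6: 0.05}
    )
    units_range: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: {2: (6, 12), 3: (5, 10), 4: (4, 8), 5: (4, 7), 6: (4, 6)}
    )
    n_accessions: int = 21
    polymorphic_fraction: float = 0.31
    allele_offset_max: int = 3  # alt alleles at ref +/- 1..this many units
    depth: int = 30
    read_len: int = 150
    stutter: StutterModel = field(default_factory=StutterModel)
    sub_rate: float = 0.001
    gene_fraction: float = 0.365
    flank_len: int = 250
    min_gap: int = 100
    anchor_bp: int = 10
    seed: int = 0

    def validate(self) -> None:
        for u, (lo, hi) in self.units_range.items():
            if lo < DEFAULT_MIN_UNITS[u]:
                raise ValueError(f"units range for {u}-mers starts below mining threshold")
            max_tract = (hi + self.allele_offset_max) * u
            if max_tract + 2 * (self.anchor_bp + 1) > self.read_len:
                raise ValueError(
                    f"read_len {self.read_len} too short to span a {max_tract} bp tract"
                )
        slot = self.chrom_len // self.n_loci_per_chrom
        max_tract = max((hi + self.allele_offset_max) * u for u, (_, hi) in self.units_range.items())
        if slot < 2 * self.flank_len + self.min_gap + max_tract + 10:
            raise ValueError("infeasible packing: loci x spacing exceed chromosome length")

    @property
    def accessions(self) -> list[str]:
        return [f"acc{i + 1:02d}" for i in range(self.n_accessions)]


@dataclass
class TruthSet:
    """Ground truth for one simulated panel."""

    reference: list[SequenceRecord]
    loci: list[SSRLocus]
    genotypes: dict[str, dict[str, tuple[int, int]]]  # locus -> accession -> (a1, a2)
    polymorphic: dict[str, bool]
    genes: list[GeneFeature]
    accessions: list[str]

    @property
    def loci_by_name(self) -> dict[str, SSRLocus]:
        return {l.name: l for l in self.loci}


def _random_motif(rng: np.random.Generator, unit_len: int) -> str:
    """A primitive, non-A/T-only motif of the given length."""
    while True:
        motif = "".join(rng.choice(["A", "C", "G", "T"], size=unit_len))
        if set(motif) <= {"A", "T"}:
            continue
        if is_primitive(motif):
            return motif


def _fix_boundaries(seq: np.ndarray, locus: SSRLocus, rng: np.random.Generator) -> None:
    """Make the planted tract non-extendable by one base on either side."""
    u = locus.unit_len
    if locus.start > 0:
        bad = seq[locus.start + u - 1]  # extending left requires this base
        choices = _BASES[_BASES != bad]
        seq[locus.start - 1] = rng.choice(choices)
    if locus.end < len(seq):
        bad = seq[locus.end - u]
        choices = _BASES[_BASES != bad]
        seq[locus.end] = rng.choice(choices)


def simulate_reference(
    config: PanelSimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], list[SSRLocus], list[GeneFeature]]:
    """Plant SSR tracts in screened random background; also plant genes.

    The background is re-randomized wherever mining finds a locus that was
    not planted, so ``find_ssrs`` on the output recovers exactly the planted
    set. Genes are planted over ``gene_fraction`` of the loci (rounded to the
    nearest count per chromosome).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mining_cfg = MiningConfig(min_gap=config.min_gap, flank_len=config.flank_len)
    unit_lens = sorted(config.motif_len_weights)
    weights = np.array([config.motif_len_weights[u] for u in unit_lens], dtype=float)
    weights /= weights.sum()

    records: list[SequenceRecord] = []
    all_loci: list[SSRLocus] = []
    genes: list[GeneFeature] = []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1:02d}"
        seq = rng.choice(_BASES, size=config.chrom_len).copy()
        slot = config.chrom_len // config.n_loci_per_chrom
        planted: list[SSRLocus] = []
        for i in range(config.n_loci_per_chrom):
            u = int(rng.choice(unit_lens, p=weights))
            lo, hi = config.units_range[u]
            units = int(rng.integers(lo, hi + 1))
            motif = _random_motif(rng, u)
            start = i * slot + config.flank_len + int(rng.integers(0, 50))
            end = start + u * units
            tract = np.frombuffer((motif * units).encode(), dtype="S1")
            seq[start:end] = tract
            locus = SSRLocus(chrom, start, end, motif, units)
            _fix_boundaries(seq, locus, rng)
            planted.append(locus)
        planted_keys = {(l.start, l.end, l.motif) for l in planted}
        planted_spans = [(l.start, l.end) for l in planted]
        record = SequenceRecord(chrom, seq.tobytes().decode())
        for _ in range(200):
            found = find_ssrs(record, mining_cfg)
            accidental = [l for l in found if (l.start, l.end, l.motif) not in planted_keys]
            missing = planted_keys - {(l.start, l.end, l.motif) for l in found}
            if not accidental and not missing:
                break
            for acc_locus in accidental:
                for pos in range(acc_locus.start, acc_locus.end):
                    if any(s <= pos < e for s, e in planted_spans):
                        continue
                    seq[pos] = rng.choice(_BASES)
            for locus in planted:  # re-plant and re-guard in case rewrites touched edges
                tract = np.frombuffer((locus.motif * locus.units).encode(), dtype="S1")
                seq[locus.start : locus.end] = tract
                _fix_boundaries(seq, locus, rng)
            record = SequenceRecord(chrom, seq.tobytes().decode())
        else:
            raise RuntimeError(f"{chrom}: background screening did not converge")
        records.append(record)
        all_loci.extend(planted)

        n_genic = round(config.gene_fraction * len(planted))
        genic_idx = sorted(rng.choice(len(planted), size=n_genic, replace=False))
        for k, idx in enumerate(genic_idx):
            locus = planted[idx]
            g_start = max(1, locus.start + 1 - 100)  # 1-based inclusive
            g_end = min(config.chrom_len, locus.end + 100)
            genes.append(GeneFeature(chrom, g_start, g_end, f"{chrom}_gene{k + 1}"))
    return records, all_loci, genes


def simulate_panel(
    loci: Sequence[SSRLocus],
    config: PanelSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, tuple[int, int]]], dict[str, bool]]:
    """Draw diploid repeat-count genotypes for every accession at every locus.

    Each locus is polymorphic with probability ``polymorphic_fraction``; at
    polymorphic loci alleles are drawn from {ref, ref +/- offset} and the
    draw is repeated until at least two accessions carry a non-reference
    allele (the screen's keep-rule), so the polymorphic flag matches the
    screen definition by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    flags: dict[str, bool] = {}
    accs = config.accessions
    for locus in loci:
        ref = locus.units
        poly = bool(rng.random() < config.polymorphic_fraction)
        if not poly:
            genotypes[locus.name] = {a: (ref, ref) for a in accs}
            flags[locus.name] = False
            continue
        offsets = [o for o in range(-config.allele_offset_max, config.allele_offset_max + 1) if o != 0]
        valid_alts = [ref + o for o in offsets if ref + o >= 2]
        n_alt = int(rng.integers(1, min(2, len(valid_alts)) + 1))
        alts = list(rng.choice(valid_alts, size=n_alt, replace=False))
        pool = [ref] + [int(a) for a in alts]
        for _ in range(1000):
            table = {}
            n_nonref = 0
            for acc in accs:
                a1 = pool[0] if rng.random() < 0.6 else int(rng.choice(pool[1:]))
                a2 = pool[0] if rng.random() < 0.6 else int(rng.choice(pool[1:]))
                pair = (min(a1, a2), max(a1, a2))
                table[acc] = pair
                if pair[0] != ref or pair[1] != ref:
                    n_nonref += 1
            if n_nonref >= 2:
                break
        else:
            raise RuntimeError(f"{locus.name}: could not draw a polymorphic panel")
        genotypes[locus.name] = table
        flags[locus.name] = True
    return genotypes, flags


def _apply_substitutions(
    read: np.ndarray,
    ref_positions: np.ndarray,
    exclude: tuple[int, int],
    rate: float,
    rng: np.random.Generator,
) -> None:
    """Substitute bases in place, skipping the tract-plus-anchor window."""
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    for i in hits:
        p = ref_positions[i]
        if p >= 0 and exclude[0] <= p < exclude[1]:
            continue
        current = read[i]
        choices = _BASES[_BASES != current]
        read[i] = rng.choice(choices)


@dataclass
class ReadSimStats:
    """Bookkeeping from one read-simulation run."""

    n_reads: int = 0
    n_tract_spanning: int = 0
    n_stuttered: int = 0


def simulate_reads(
    truth_reference: Sequence[SequenceRecord],
    loci: Sequence[SSRLocus],
    genotypes: Mapping[str, Mapping[str, tuple[int, int]]],
    config: PanelSimConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Path], ReadSimStats]:
    """Emit per-accession coordinate-sorted SAM files around every locus.

    Reads are tiled uniformly to the configured depth over each locus plus a
    read-length margin on both sides. Reads fully covering the accession's
    tract carry an I/D CIGAR placed one unit into the tract; stutter perturbs
    a spanning read's apparent repeat count by a fair-signed geometric number
    of units with probability ``stutter.p_s``. Substitution errors are added
    outside the tract-plus-anchor window.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_by_chrom = {r.id: r.seq for r in truth_reference}
    stats = ReadSimStats()
    L = config.read_len
    paths: dict[str, Path] = {}

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in truth_reference],
    }
    tid = {r.id: i for i, r in enumerate(truth_reference)}

    for acc in config.accessions:
        sam_records: list[tuple[str, int, str, int, str, str]] = []
        serial = itertools.count()
        for locus in loci:
            ref_seq = ref_by_chrom[locus.chrom]
            u = locus.unit_len
            r_units = locus.units
            t_ref = r_units * u
            a1, a2 = genotypes[locus.name][acc]
            win_lo = max(0, locus.start - L)
            win_hi_ref = min(len(ref_seq), locus.end + L)
            n_reads = int(round(config.depth * (win_hi_ref - win_lo) / L))
            for _ in range(n_reads):
                allele = a1 if rng.random() < 0.5 else a2
                # stutter perturbs the apparent repeat count of this read
                apparent = allele
                stuttered = False
                if rng.random() < config.stutter.p_s:
                    shift = int(rng.geometric(1.0 - config.stutter.rho))
                    sign = 1 if rng.random() < 0.5 else -1
                    apparent = max(1, allele + sign * shift)
                    stuttered = apparent != allele
                t_hap = apparent * u
                delta = t_hap - t_ref
                hap_end = locus.start + t_hap
                hap_len = len(ref_seq) + delta
                lo = win_lo
                hi = min(hap_len, hap_end + L)
                if hi - lo < L:
                    continue
                h0 = int(rng.integers(lo, hi - L + 1))
                h1 = h0 + L

                def hap_base(h: int) -> str:
                    if h < locus.start:
                        return ref_seq[h]
                    if h < hap_end:
                        return locus.motif[(h - locus.start) % u]
                    return ref_seq[h - delta]

                read = np.frombuffer(
                    "".join(hap_base(h) for h in range(h0, h1)).encode(), dtype="S1"
                ).copy()

                if h0 <= locus.start - 1 and h1 >= hap_end + 1:
                    # full-tract read: M, I/D inside the tract, M
                    m1 = locus.start + u - h0
                    if delta > 0:
                        cigar = f"{m1}M{delta}I{L - m1 - delta}M"
                        ref_pos_of = list(range(h0, locus.start + u)) + [-1] * delta + list(
                            range(locus.start + u, locus.start + u + (L - m1 - delta))
                        )
                    elif delta < 0:
                        cigar = f"{m1}M{-delta}D{L - m1}M"
                        ref_pos_of = list(range(h0, locus.start + u)) + list(
                            range(locus.start + u - delta, locus.start + u - delta + (L - m1))
                        )
                    else:
                        cigar = f"{L}M"
                        ref_pos_of = list(range(h0, h1))
                    pos = h0
                    stats.n_tract_spanning += 1
                    if stuttered:
                        stats.n_stuttered += 1
                else:
                    # partial overlap (or clear of the tract): pure-M placement
                    if h1 <= locus.start:
                        pos = h0
                    elif h0 >= hap_end:
                        pos = h0 - delta
                    elif h1 <= locus.start + min(t_hap, t_ref):
                        pos = h0  # read ends inside the shared periodic prefix
                    elif h0 >= locus.start and hap_end - h0 <= t_ref:
                        pos = h0 - delta  # right-anchored within the tract
                    else:
                        continue  # would need clipping inside the tract; skip
                    cigar = f"{L}M"
                    ref_pos_of = list(range(pos, pos + L))
                ref_positions = np.array(ref_pos_of)
                _apply_substitutions(
                    read,
                    ref_positions,
                    (locus.start - config.anchor_bp - 1, locus.end + config.anchor_bp + 1),
                    config.sub_rate,
                    rng,
                )
                name = f"{acc}_{locus.name}_{next(serial)}"
                sam_records.append((locus.chrom, pos, cigar, tid[locus.chrom], read.tobytes().decode(), name))
                stats.n_reads += 1

        sam_records.sort(key=lambda r: (r[3], r[1], r[5]))
        path = out_dir / f"{acc}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for chrom, pos, cigar, t, seq, name in sam_records:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = name
                seg.flag = 0
                seg.reference_id = t
                seg.reference_start = pos
                seg.mapping_quality = 60
                seg.cigarstring = cigar
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(seg)
        paths[acc] = path
    return paths, stats


def simulate_all(
    config: PanelSimConfig, out_dir: str | Path | None = None
) -> tuple[TruthSet, dict[str, Path] | None]:
    """Run the full generator; optionally write FASTA/BED/GFF/SAM/TSV to disk."""
    rng = np.random.default_rng(config.seed)
    reference, loci, genes = simulate_reference(config, rng)
    genotypes, flags = simulate_panel(loci, config, rng)
    truth = TruthSet(
        reference=reference,
        loci=loci,
        genotypes=genotypes,
        polymorphic=flags,
        genes=genes,
        accessions=config.accessions,
    )
    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, out_dir / "reference.fa")
        write_ssr_bed([l.to_bed() for l in loci], out_dir / "truth_loci.bed")
        write_gff_genes(genes, out_dir / "genes.gff3")
        with open(out_dir / "truth_genotypes.tsv", "w") as fh:
            fh.write("locus\taccession\ta1\ta2\tpolymorphic\n")
            for locus in loci:
                for acc in config.accessions:
                    a1, a2 = genotypes[locus.name][acc]
                    fh.write(f"{locus.name}\t{acc}\t{a1}\t{a2}\t{int(flags[locus.name])}\n")
        paths, _ = simulate_reads(reference, loci, genotypes, config, out_dir / "reads", rng)
    return truth, paths


def end_to_end_truth_eval(
    mined_loci: Sequence[SSRLocus],
    matrix,
    kept_polymorphic: Sequence[str],
    truth: TruthSet,
) -> dict[str, float]:
    """Recovery metrics of a pipeline run against the generating truth.

    Returns mining precision/recall on exact (chrom, start, end, motif)
    identity, genotype concordance over all locus x accession cells (a PASS
    call matching the truth diploid genotype counts as concordant), and
    precision/recall of the polymorphic screen against the truth flags.
    """
    truth_keys = {(l.chrom, l.start, l.end, l.motif) for l in truth.loci}
    mined_keys = {(l.chrom, l.start, l.end, l.motif) for l in mined_loci}
    tp = len(truth_keys & mined_keys)
    mining_precision = tp / len(mined_keys) if mined_keys else 0.0
    mining_recall = tp / len(truth_keys) if truth_keys else 0.0

    n_cells = 0
    n_match = 0
    truth_names = {l.name for l in truth.loci}
    for locus in matrix.locus_names:
        if locus not in truth_names:
            raise ValueError(f"genotyped locus {locus} not in truth")
        for acc in matrix.accessions:
            n_cells += 1
            call = matrix[(locus, acc)]
            expected = tuple(sorted(truth.genotypes[locus][acc]))
            if call.is_pass and call.alleles == expected:
                n_match += 1
    concordance = n_match / n_cells if n_cells else 0.0

    kept = set(kept_polymorphic)
    genotyped = set(matrix.locus_names)
    true_poly = {name for name, f in truth.polymorphic.items() if f and name in genotyped}
    tp_poly = len(kept & true_poly)
    screen_precision = tp_poly / len(kept) if kept else 1.0
    screen_recall = tp_poly / len(true_poly) if true_poly else 1.0
    return {
        "mining_precision": mining_precision,
        "mining_recall": mining_recall,
        "genotype_concordance": concordance,
        "screen_precision": screen_precision,
        "screen_recall": screen_recall,
        "n_cells": float(n_cells),
    }
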