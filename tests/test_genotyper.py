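from __future__ import annotations

import math
from itertools import combinations_with_replacement

import pytest

from ssrscape.formats import AlignmentRecord
from ssrscape.genotyper import (
    CallFilters,
    GenotypeCall,
    GenotypeMatrix,
    ReadObservation,
    StutterModel,
    call_genotype,
    genotype_likelihood,
    genotype_panel,
    measure_read,
)
from ssrscape.mining import SSRLocus

LOCUS = SSRLocus("chr1", 100, 118, "ATG", 6)  # 18 bp tract


def _aln(pos: int, cigar: tuple[tuple[str, int], ...], name="r") -> AlignmentRecord:
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    return AlignmentRecord(name, "chr1", pos, cigar, "A" * qlen, True)


class TestMeasureRead:
    def test_reference_match_counts_ref_units(self):
        obs = measure_read(_aln(80, (("M", 60),)), LOCUS)
        assert obs.spanning and obs.units == 6 and not obs.flank_indel

    def test_insertion_inside_tract_adds_units(self):
        # 6 bp insertion at 109 (inside the tract): 18 + 6 = 24 = 3 x 8
        obs = measure_read(_aln(80, (("M", 29), ("I", 6), ("M", 31))), LOCUS)
        assert obs.units == 8

    def test_deletion_off_frame(self):
        # 2 bp deletion inside a 3 bp-unit tract: 16 bp not divisible by 3
        obs = measure_read(_aln(80, (("M", 29), ("D", 2), ("M", 31))), LOCUS)
        assert obs.off_frame and obs.units is None

    def test_anchor_rule_non_spanning(self):
        # starts 3 bp after (start - anchor) = 90: covers [93, ...) only
        obs = measure_read(_aln(93, (("M", 60),)), LOCUS)
        assert not obs.spanning

    def test_flank_indel_flagged(self):
        # deletion at 95-97, inside the left anchor window [90, 100)
        obs = measure_read(_aln(80, (("M", 15), ("D", 2), ("M", 45))), LOCUS)
        assert obs.flank_indel

    def test_non_overlap_rejected(self):
        with pytest.raises(ValueError):
            measure_read(_aln(0, (("M", 50),)), LOCUS)


def _obs(*units: int) -> list[ReadObservation]:
    return [ReadObservation(spanning=True, units=u) for u in units]


class TestLikelihood:
    def test_concordant_homozygote_closed_form(self):
        stutter = StutterModel(p_s=0.05, rho=0.8)
        ll = genotype_likelihood(_obs(*[6] * 10), (6, 6), stutter)
        assert ll == pytest.approx(10 * math.log(0.95))

    def test_het_beats_hom_on_balanced_reads(self):
        stutter = StutterModel(p_s=0.05, rho=0.8)
        reads = _obs(6, 6, 8, 8)
        assert genotype_likelihood(reads, (6, 8), stutter) > genotype_likelihood(
            reads, (6, 6), stutter
        )

    def test_symmetry_in_allele_order(self):
        stutter = StutterModel()
        reads = _obs(6, 7, 8)
        assert genotype_likelihood(reads, (6, 8), stutter) == genotype_likelihood(
            reads, (8, 6), stutter
        )

    def test_stutter_distribution_mass(self):
        # P(k|a) over k = a and a +/- 1..N converges to (1-p_s) + p_s
        stutter = StutterModel(p_s=0.05, rho=0.8)
        total = math.exp(stutter.log_p_read(6, 6))
        for d in range(1, 200):
            total += math.exp(stutter.log_p_read(6 + d, 6))
            total += math.exp(stutter.log_p_read(6 - d, 6))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_stutter_impossible_read(self):
        stutter = StutterModel(p_s=0.0, rho=0.8)
        assert genotype_likelihood(_obs(7), (6, 6), stutter) == -math.inf


def _enumeration_map(observations, candidates, stutter: StutterModel, ref_units: int):
    """Independent MAP oracle: direct probability products over all pairs."""
    best = None
    for g in combinations_with_replacement(sorted(candidates), 2):
        p = 1.0
        for obs in observations:
            if obs.units is None or obs.flank_indel:
                continue
            terms = []
            for a in g:
                if obs.units == a:
                    terms.append(1 - stutter.p_s)
                else:
                    d = abs(obs.units - a)
                    terms.append(stutter.p_s * (1 - stutter.rho) * stutter.rho ** (d - 1) / 2)
            p *= sum(terms) / 2
        key = (p, ref_units in g, tuple(-x for x in g))
        if best is None or key > best[0]:
            best = (key, g)
    return best[1]


class TestCallGenotype:
    FILTERS = CallFilters()
    STUTTER = StutterModel()

    def test_clean_homozygote(self):
        call = call_genotype(_obs(*[6] * 20), self.STUTTER, self.FILTERS, ref_units=6)
        assert call.is_pass and call.alleles == (6, 6) and call.quality > 0.99

    def test_balanced_heterozygote(self):
        call = call_genotype(_obs(*([6] * 10 + [8] * 10)), self.STUTTER, self.FILTERS, 6)
        assert call.is_pass and call.alleles == (6, 8)

    def test_flank_indel_fraction_filter(self):
        obs = _obs(*[6] * 15) + [
            ReadObservation(spanning=True, units=6, flank_indel=True) for _ in range(5)
        ]
        call = call_genotype(obs, self.STUTTER, self.FILTERS, 6)
        assert not call.is_pass and call.reason == "flank_indel"

    def test_min_spanning_reads(self):
        call = call_genotype(_obs(6, 6, 6), self.STUTTER, self.FILTERS, 6)
        assert call.reason == "no_reads"

    def test_stutter_fraction_filter(self):
        obs = _obs(*([6] * 15 + [7, 9, 11]))  # 3/18 > 0.15 mismatching reads
        call = call_genotype(obs, self.STUTTER, self.FILTERS, 6)
        assert call.reason == "stutter"

    def test_posterior_normalized_and_map_equals_enumeration(self, rng):
        from ssrscape.genotyper import _posterior

        for _ in range(50):
            ref = int(rng.integers(4, 12))
            n = int(rng.integers(5, 30))
            units = [int(rng.integers(max(1, ref - 3), ref + 4)) for _ in range(n)]
            obs = _obs(*units)
            candidates = sorted(set(units) | {ref})
            post = _posterior(obs, candidates, self.STUTTER)
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
            call = call_genotype(obs, self.STUTTER, self.FILTERS, ref)
            expected = _enumeration_map(obs, candidates, self.STUTTER, ref)
            assert call.alleles == expected


class TestPanel:
    def test_duplicate_accession_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(locus_names=["l1"], accessions=["a", "a"], ref_units={"l1": 6})

    def test_empty_accession_all_missing(self, small_panel):
        from ssrscape import formats

        cfg, truth, paths = small_panel
        acc0 = truth.accessions[0]
        sets = {
            acc0: formats.read_alignments(paths[acc0]),
            "empty_acc": [],
        }
        m = genotype_panel(sets, truth.loci[:3])
        for locus in m.locus_names:
            call = m[(locus, "empty_acc")]
            assert call.reason == "no_reads"

    def test_clean_panel_recovers_truth(self, tmp_path):
        from ssrscape import formats, simdata

        cfg = simdata.PanelSimConfig(
            n_chrom=1,
            chrom_len=20_000,
            n_loci_per_chrom=5,
            n_accessions=3,
            stutter=StutterModel(p_s=1e-12, rho=0.8),
            sub_rate=0.0,
            depth=10,
            seed=21,
        )
        truth, paths = simdata.simulate_all(cfg, tmp_path)
        sets = {a: formats.read_alignments(p) for a, p in paths.items()}
        m = genotype_panel(sets, truth.loci)
        for locus in truth.loci:
            for acc in truth.accessions:
                call = m[(locus.name, acc)]
                assert call.is_pass
                assert call.alleles == tuple(sorted(truth.genotypes[locus.name][acc]))
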