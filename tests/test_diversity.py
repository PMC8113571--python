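from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from ssrscape import diversity
from ssrscape.diversity import (
    allele_frequencies,
    distance_matrix,
    expected_heterozygosity,
    export_structure,
    genotypes_to_binary,
    marker_stats_table,
    nj_tree,
    pca,
    pic,
)
from ssrscape.genotyper import GenotypeCall, GenotypeMatrix


def _matrix() -> GenotypeMatrix:
    m = GenotypeMatrix(
        locus_names=["l1"],
        accessions=["s1", "s2", "s3"],
        ref_units={"l1": 6},
    )
    m.set("l1", "s1", GenotypeCall((6, 8), 0.99, "PASS"))
    m.set("l1", "s2", GenotypeCall((6, 6), 0.99, "PASS"))
    m.set("l1", "s3", GenotypeCall((9, 9), 0.99, "PASS"))
    return m


class TestBinaryScoring:
    def test_het_and_hom_rows(self):
        scores = genotypes_to_binary(_matrix())
        assert list(scores.columns) == ["l1:6", "l1:8", "l1:9"]
        assert scores.loc["s1"].tolist() == [1.0, 1.0, 0.0]
        assert scores.loc["s2"].tolist() == [1.0, 0.0, 0.0]

    def test_missing_call_marked(self):
        m = _matrix()
        m.set("l1", "s3", GenotypeCall(None, 0.0, "no_reads"))
        scores = genotypes_to_binary(m)
        assert scores.loc["s3"].isna().all()

    def test_column_count_per_locus_equals_allele_count(self, small_panel):
        from ssrscape import formats
        from ssrscape.genotyper import StutterModel, genotype_panel

        cfg, truth, paths = small_panel
        sets = {a: formats.read_alignments(p) for a, p in paths.items()}
        m = genotype_panel(sets, truth.loci)
        scores = genotypes_to_binary(m)
        for locus in truth.loci:
            observed = {
                a
                for acc in truth.accessions
                if m[(locus.name, acc)].is_pass
                for a in m[(locus.name, acc)].alleles
            }
            cols = [c for c in scores.columns if c.rsplit(":", 1)[0] == locus.name]
            assert len(cols) == len(observed)


class TestFrequenciesAndStats:
    def test_even_frequencies(self):
        scores = pd.DataFrame({"l:6": [1] * 10 + [0] * 10, "l:8": [0] * 10 + [1] * 10})
        assert allele_frequencies(scores).tolist() == [0.5, 0.5]

    def test_skewed_frequencies(self):
        scores = pd.DataFrame({"l:6": [1] * 30 + [0] * 10, "l:8": [0] * 30 + [1] * 10})
        assert allele_frequencies(scores).tolist() == [0.75, 0.25]

    def test_frequencies_normalized_random(self, rng):
        for _ in range(30):
            mat = (rng.random((12, 4)) < 0.5).astype(float)
            mat[0] = 1.0  # ensure every column carried
            p = allele_frequencies(pd.DataFrame(mat, columns=[f"l:{i}" for i in range(4)]))
            assert p.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("p,he", [([0.5, 0.5], 0.5), ([1.0], 0.0), ([0.25] * 4, 0.75)])
    def test_he_closed_forms(self, p, he):
        assert expected_heterozygosity(p) == pytest.approx(he)

    def test_he_equal_alleles_closed_form(self):
        for k in range(2, 8):
            assert expected_heterozygosity([1 / k] * k) == pytest.approx(1 - 1 / k)

    def test_pic_closed_forms(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375)
        assert pic([1.0]) == pytest.approx(0.0)

    def test_pic_bounded_by_he_on_simplex(self, rng):
        for _ in range(10_000):
            k = int(rng.integers(1, 6))
            p = rng.dirichlet(np.ones(k))
            he = expected_heterozygosity(p)
            v = pic(p)
            assert 0.0 - 1e-12 <= v <= he < 1.0
            if k == 1:
                assert v == pytest.approx(he)

    def test_relabeling_invariance(self, rng):
        p = rng.dirichlet(np.ones(5))
        q = p[rng.permutation(5)]
        assert expected_heterozygosity(p) == pytest.approx(expected_heterozygosity(q))
        assert pic(p) == pytest.approx(pic(q))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            expected_heterozygosity([0.5, 0.4])
        with pytest.raises(ValueError):
            pic([0.7, 0.7])

    def test_single_monomorphic_locus_stats(self):
        scores = pd.DataFrame({"l:6": [1.0] * 8})
        stats = marker_stats_table(scores)
        assert (stats.mean_na, stats.mean_he, stats.mean_pic) == (1.0, 0.0, 0.0)
        rep = stats.report()
        assert rep.loc["Mean"].tolist() == [1.0, 0.0, 0.0]


class TestPca:
    def _two_clusters(self):
        a = [1.0, 1.0, 0.0, 0.0]
        b = [0.0, 0.0, 1.0, 1.0]
        rows = [a] * 4 + [b] * 4
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(8)], columns=["l:1", "l:2", "l:3", "l:4"])

    def test_two_cluster_separation(self):
        coords, var = pca(self._two_clusters())
        pc1 = coords["PC1"]
        assert var[0] == pytest.approx(1.0)
        assert (pc1[:4] > 0).all() != (pc1[4:] > 0).all()  # clusters on opposite sides

    def test_duplicate_accessions_coincide(self):
        scores = self._two_clusters()
        coords, _ = pca(scores)
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_variance_explained_sums_to_one(self, rng):
        scores = pd.DataFrame((rng.random((10, 6)) < 0.5).astype(float))
        scores.columns = [f"l:{i}" for i in range(6)]
        _, var = pca(scores)
        assert var.sum() == pytest.approx(1.0)
        assert (np.diff(var) <= 1e-12).all()

    def test_constant_matrix_rejected(self):
        scores = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            pca(scores)


class TestDistance:
    def test_identical_rows_zero(self):
        s = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"], columns=["x", "y", "z"])
        assert distance_matrix(s).loc["a", "b"] == 0.0

    def test_disjoint_rows_one(self):
        s = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        assert distance_matrix(s).loc["a", "b"] == 1.0

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            s = pd.DataFrame((rng.random((5, 8)) < 0.5).astype(float))
            s.iloc[:, 0] = 1.0
            d = distance_matrix(s).to_numpy()
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def _path_lengths(newick: str) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths parsed with scikit-bio (independent parser)."""
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    leaves = [t.name for t in tree.tips()]
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            out[frozenset((a, b))] = tree.find(a).distance(tree.find(b))
    return out


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,C:3,D:4) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels,
            columns=labels,
            dtype=float,
        )
        newick = nj_tree(d)
        paths = _path_lengths(newick)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert paths[frozenset((a, b))] == pytest.approx(d.loc[a, b], abs=1e-9)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 4, 6], [4, 0, 8], [6, 8, 0]], index=labels, columns=labels, dtype=float
        )
        paths = _path_lengths(nj_tree(d))
        assert paths[frozenset(("A", "B"))] == pytest.approx(4.0)
        assert paths[frozenset(("A", "C"))] == pytest.approx(6.0)
        assert paths[frozenset(("B", "C"))] == pytest.approx(8.0)

    def test_leafset_preserved_on_random_matrices(self, rng):
        import skbio

        for _ in range(5):
            n = int(rng.integers(4, 9))
            pts = rng.random((n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"t{i}" for i in range(n)]
            frame = pd.DataFrame(d, index=labels, columns=labels)
            tree = skbio.TreeNode.read(io.StringIO(nj_tree(frame)))
            assert sorted(t.name for t in tree.tips()) == labels

    def test_matches_skbio_on_additive_matrix(self):
        """Cross-check against scikit-bio's neighbor joining on additive input."""
        import skbio
        from skbio import DistanceMatrix

        labels = ["A", "B", "C", "D", "E"]
        # caterpillar tree with distinct branch lengths
        d = np.array(
            [
                [0, 2, 7, 10, 11],
                [2, 0, 7, 10, 11],
                [7, 7, 0, 5, 6],
                [10, 10, 5, 0, 3],
                [11, 11, 6, 3, 0],
            ],
            dtype=float,
        )
        frame = pd.DataFrame(d, index=labels, columns=labels)
        mine = _path_lengths(nj_tree(frame))
        ref = skbio.tree.nj(DistanceMatrix(d, labels))
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert mine[frozenset((a, b))] == pytest.approx(
                    ref.find(a).distance(ref.find(b)), abs=1e-9
                )

    def test_too_small_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(d)


class TestStructureExport:
    def test_shape_and_missing_convention(self, tmp_path):
        s = pd.DataFrame(
            [[1.0, 0.0, np.nan], [0.0, 1.0, 1.0]],
            index=["a1", "a2"],
            columns=["l:6", "l:7", "l:8"],
        )
        out = tmp_path / "structure.txt"
        export_structure(s, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == ["a1", "1", "0", "-9"]
        assert len(lines[1].split("\t")) == 1 + 3
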