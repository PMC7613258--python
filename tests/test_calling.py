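"""Gene/miRNA calling: statistics, permutation nulls, FDR behaviour, intersections."""

import numpy as np
import pytest
from scipy import stats

import tadapipe as tp
from conftest import make_profile, make_uniform_map
from tadapipe.annotation import GeneAnnotation


def gene_over_fragments(frag_map, f0, n, gid="g", strand="+", biotype="protein_coding"):
    """A feature whose extent covers exactly fragments [f0, f0+n) of chr1."""
    b = frag_map.boundaries["chr1"]
    return GeneAnnotation(gid, gid, biotype, "chr1", strand, int(b[f0]), int(b[f0 + n]))


class TestMeanGeneOccupancy:
    def test_plain_mean(self, toy_map):
        prof = make_profile([1.0, 2.0, 3.0])
        g = gene_over_fragments(toy_map, 0, 3)
        assert tp.mean_gene_occupancy(prof, g, toy_map) == (2.0, 3)

    def test_one_bp_overlap_included(self, toy_map):
        prof = make_profile([1.0, 2.0, 3.0])
        g = GeneAnnotation("g", "g", "protein_coding", "chr1", "+", 3, 4)
        assert tp.mean_gene_occupancy(prof, g, toy_map) == (1.0, 1)

    def test_masked_fragments_excluded(self, toy_map):
        prof = make_profile([2.0, np.nan, 0.0])
        g = gene_over_fragments(toy_map, 0, 3)
        assert tp.mean_gene_occupancy(prof, g, toy_map) == (1.0, 2)

    def test_fully_masked_is_unscored(self, toy_map):
        prof = make_profile([np.nan, np.nan, np.nan])
        g = gene_over_fragments(toy_map, 0, 3)
        mean, n = tp.mean_gene_occupancy(prof, g, toy_map)
        assert n == 0 and np.isnan(mean)


class TestPermutationNull:
    @pytest.mark.parametrize("mode", ["shuffle", "block"])
    def test_degenerate_block_equals_global_mean(self, mode):
        frag_map = make_uniform_map(50)
        rng = np.random.default_rng(9)
        prof = make_profile(rng.normal(size=50))
        null = tp.permutation_null(frag_map=frag_map, profile=prof, n_fragments=50,
                                   n_permutations=200, rng=1, mode=mode)
        assert np.allclose(null, prof.scores.mean())

    @pytest.mark.parametrize("mode", ["shuffle", "block"])
    def test_iid_moments(self, mode):
        # means of 4 iid N(0,1) fragments: mean ~ 0, variance ~ 1/4
        frag_map = make_uniform_map(5000)
        rng = np.random.default_rng(10)
        prof = make_profile(rng.normal(size=5000))
        null = tp.permutation_null(prof, frag_map, 4, 10_000, rng=2, mode=mode)
        assert abs(null.mean()) < 0.05
        assert abs(null.var() - 0.25) < 0.025

    def test_seeded_determinism(self):
        frag_map = make_uniform_map(500)
        prof = make_profile(np.random.default_rng(11).normal(size=500))
        a = tp.permutation_null(prof, frag_map, 5, 1000, rng=42)
        b = tp.permutation_null(prof, frag_map, 5, 1000, rng=42)
        assert np.array_equal(a, b)

    def test_impossible_block_length_rejected(self):
        frag_map = make_uniform_map(10)
        prof = make_profile(np.ones(10))
        with pytest.raises(ValueError):
            tp.permutation_null(prof, frag_map, 11, 100)


def _null_calls(n_genes=500, n_frag=4000, seed=0, gene_sizes=(2, 3, 4, 5, 6)):
    """Genes over an iid-Normal profile: no gene is genuinely enriched."""
    frag_map = make_uniform_map(n_frag)
    rng = np.random.default_rng(seed)
    prof = make_profile(rng.normal(size=n_frag))
    stride = n_frag // n_genes
    genes = [
        gene_over_fragments(
            frag_map, i * stride, min(gene_sizes[i % len(gene_sizes)], stride),
            gid=f"g{i:04d}",
        )
        for i in range(n_genes)
    ]
    return tp.call_features(prof, genes, frag_map, seed=seed), genes, prof, frag_map


class TestCallFeatures:
    def test_pvalues_uniform_under_null(self):
        table, *_ = _null_calls(n_genes=1000, n_frag=6000, seed=12)
        ks = stats.kstest(table["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_no_calls_on_pure_null(self):
        table, *_ = _null_calls(seed=13)
        assert table["expressed"].sum() == 0

    def test_enrichment_raises_flag_monotonically(self):
        frag_map = make_uniform_map(2000)
        rng = np.random.default_rng(14)
        scores = rng.normal(size=2000)
        scores[100:106] += 3.0  # strongly enriched gene body
        genes = [gene_over_fragments(frag_map, 100, 6, gid="hot")] + [
            gene_over_fragments(frag_map, 50 + 10 * i, 4, gid=f"bg{i}") for i in range(20)
        ]
        t1 = tp.call_features(make_profile(scores), genes, frag_map, seed=3)
        assert t1.set_index("feature_id").loc["hot", "expressed"]
        scores2 = scores.copy()
        scores2[100:106] += 1.0  # raising the gene never loses the flag
        t2 = tp.call_features(make_profile(scores2), genes, frag_map, seed=3)
        row1 = t1.set_index("feature_id").loc["hot"]
        row2 = t2.set_index("feature_id").loc["hot"]
        assert row2["expressed"] and row2["p_value"] <= row1["p_value"]

    def test_input_order_invariance(self):
        _table, genes, prof, frag_map = _null_calls(n_genes=100, n_frag=1000, seed=15)
        fwd = tp.call_features(prof, genes, frag_map, seed=4)
        rev = tp.call_features(prof, genes[::-1], frag_map, seed=4)
        assert fwd.equals(rev)

    def test_metadata_recorded(self):
        table, *_ = _null_calls(n_genes=50, n_frag=500, seed=16)
        assert table.attrs["n_permutations"] == 10000
        assert table.attrs["fdr_threshold"] == 0.05
        assert table.attrs["null_mode"] == "shuffle"
        assert (table["p_value"] >= 1 / 10001).all()


class TestCallMirnas:
    def test_extension_window_covers_fragments(self):
        frag_map = make_uniform_map(100)  # 256 bp fragments
        prof = make_profile(np.zeros(100))
        b = frag_map.boundaries["chr1"]
        mirna = GeneAnnotation("mir1", "mir1", "miRNA", "chr1", "+", int(b[10]) + 100,
                               int(b[10]) + 121)
        # 21 bp feature inside fragment 10; +/-500 bp reaches fragments 8-12
        table = tp.call_mirnas(prof, [mirna], frag_map, seed=5)
        assert table.loc[0, "n_fragments"] == 5
        zero = tp.call_mirnas(prof, [mirna], frag_map, extension=0, seed=5)
        assert zero.loc[0, "n_fragments"] == 1

    def test_extension_strand_symmetric(self):
        frag_map = make_uniform_map(100)
        rng = np.random.default_rng(17)
        prof = make_profile(rng.normal(size=100))
        b = frag_map.boundaries["chr1"]
        args = ("mir", "mir", "miRNA", "chr1")
        plus = GeneAnnotation(*args, "+", int(b[20]) + 5, int(b[20]) + 26)
        minus = GeneAnnotation(*args, "-", int(b[20]) + 5, int(b[20]) + 26)
        tp_ = tp.call_mirnas(prof, [plus], frag_map, seed=6)
        tm = tp.call_mirnas(prof, [minus], frag_map, seed=6)
        assert tp_["mean_score"].iloc[0] == tm["mean_score"].iloc[0]

    def test_wrong_biotype_rejected(self, toy_map):
        g = GeneAnnotation("g", "g", "protein_coding", "chr1", "+", 0, 10)
        with pytest.raises(ValueError, match="miRNA"):
            tp.call_mirnas(make_profile([1.0, 1.0, 1.0]), [g], toy_map)


def _table(ids_expressed, universe):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": sorted(universe),
            "expressed": [f in ids_expressed for f in sorted(universe)],
        }
    )


class TestIntersectCalls:
    def test_identical_tables_single_region(self):
        u = {f"g{i}" for i in range(10)}
        on = {f"g{i}" for i in range(5)}
        membership, regions = tp.intersect_calls({"a": _table(on, u), "b": _table(on, u)})
        assert regions == {frozenset({"a", "b"}): sorted(on)}
        assert membership.shape == (5, 2)

    def test_disjoint_tables_singletons_only(self):
        u = {f"g{i}" for i in range(10)}
        membership, regions = tp.intersect_calls(
            {"a": _table({"g0", "g1"}, u), "b": _table({"g5"}, u)}
        )
        assert set(regions) == {frozenset({"a"}), frozenset({"b"})}

    def test_regions_partition_union(self):
        rng = np.random.default_rng(18)
        u = [f"g{i}" for i in range(200)]
        tables = {
            name: _table({g for g in u if rng.random() < 0.3}, set(u))
            for name in "abcd"
        }
        _m, regions = tp.intersect_calls(tables)
        union = set().union(*(set(t.loc[t.expressed, "feature_id"]) for t in tables.values()))
        members = [g for mem in regions.values() for g in mem]
        assert len(members) == len(set(members)) == len(union)


def test_calls_roundtrip(tmp_path):
    table, *_ = _null_calls(n_genes=50, n_frag=500, seed=19)
    p = tmp_path / "calls.tsv"
    tp.calling.write_calls(table, p)
    back = tp.calling.read_calls(p)
    assert back["feature_id"].tolist() == table["feature_id"].tolist()
    assert np.allclose(back["mean_score"], table["mean_score"])
    assert back["expressed"].tolist() == table["expressed"].tolist()
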