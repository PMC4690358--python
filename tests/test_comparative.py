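import numpy as np
import pandas as pd
import pytest
from skbio.tree import TreeNode

import cubkit as ck
from cubkit.codon_stats import CodonCountTable, RscuVector, rscu
from cubkit.comparative import (
    DegenerateDataError,
    build_rscu_matrix,
    codon_cub_correlations,
    distance_matrix,
    gene_level_correlates,
    hierarchical_cluster,
    pearson_regression,
    preferred_codon_tally,
    senc_enc_regressions,
)
from cubkit.genetic_code import INFORMATIVE_CODONS

from conftest import random_count_table


def _uniform_profile(jitter: float = 0.0, seed: int = 0) -> RscuVector:
    rng = np.random.default_rng(seed)
    values = {c: 1.0 + jitter * rng.normal() for c in INFORMATIVE_CODONS}
    values["ATG"] = 1.0
    values["TGG"] = 1.0
    return RscuVector(values=values)


class TestRscuMatrix:
    def test_shape_and_columns(self):
        rng = np.random.default_rng(1)
        profiles = {f"sp{i}": rscu(random_count_table(rng)) for i in range(5)}
        m = build_rscu_matrix(profiles)
        assert m.values.shape == (5, 59)
        assert list(m.values.columns) == list(INFORMATIVE_CODONS)
        assert not m.values.isna().any().any()

    def test_identical_profiles_identical_rows(self):
        p = _uniform_profile(jitter=0.1, seed=3)
        m = build_rscu_matrix({"a": p, "b": p, "c": _uniform_profile()})
        assert (m.values.loc["a"] == m.values.loc["b"]).all()

    def test_absent_family_imputed_with_column_mean(self):
        complete = _uniform_profile(jitter=0.2, seed=5)
        missing = RscuVector(
            values={c: v for c, v in complete.values.items() if c not in ("TGT", "TGC")},
            undefined_aas=frozenset({"C"}),
        )
        m = build_rscu_matrix({"a": complete, "b": complete, "c": missing})
        assert m.imputed.loc["c", ["TGT", "TGC"]].all()
        assert m.values.loc["c", "TGT"] == pytest.approx(complete.values["TGT"])

    def test_species_with_many_missing_excluded(self):
        complete = _uniform_profile(jitter=0.2, seed=5)
        sparse = RscuVector(values=dict(list(complete.values.items())[:20]))
        with pytest.warns(UserWarning, match="excluding"):
            m = build_rscu_matrix({"a": complete, "b": complete, "c": sparse})
        assert m.excluded_species == ("c",)


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        df = pd.DataFrame(
            [[0.0] * 5, [0.0] * 5, [3.0, 4.0, 0.0, 0.0, 0.0]],
            index=["a", "b", "c"],
        )
        d = hierarchical_cluster(df)
        assert d.heights[0] == pytest.approx(0.0)
        first = {d.labels[int(i)] for i in d.linkage[0, :2]}
        assert first == {"a", "b"}

    def test_two_rows_merge_at_euclidean_distance(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = hierarchical_cluster(df)
        assert d.heights[-1] == pytest.approx(5.0)

    def test_heights_monotone_under_complete_linkage(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"s{i}" for i in range(10)])
        d = hierarchical_cluster(df, method="complete")
        assert (np.diff(d.heights) >= -1e-12).all()

    def test_row_permutation_preserves_cophenetic_structure(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"s{i}" for i in range(8)])
        perm = df.sample(frac=1, random_state=9)
        d1, d2 = hierarchical_cluster(df), hierarchical_cluster(perm)
        t1 = TreeNode.read([d1.to_newick()])
        t2 = TreeNode.read([d2.to_newick()])
        names = sorted(df.index)
        m1 = t1.tip_tip_distances(names).data
        m2 = t2.tip_tip_distances(names).data
        assert np.allclose(m1, m2, atol=1e-9)

    def test_newick_round_trip_preserves_heights(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"s{i}" for i in range(6)])
        d = hierarchical_cluster(df)
        tree = TreeNode.read([d.to_newick()])
        assert sorted(t.name for t in tree.tips()) == sorted(df.index)
        # ultrametric: every tip sits at half the final merge height, so
        # tip-to-tip distance through the root equals that height
        depth = max(tree.distance(t) for t in tree.tips())
        assert depth == pytest.approx(d.heights[-1] / 2, abs=1e-9)
        names = list(df.index)
        coph = tree.tip_tip_distances(names).data
        assert coph.max() == pytest.approx(d.heights[-1], abs=1e-9)

    def test_distance_matrix_is_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"s{i}" for i in range(5)])
        dm = distance_matrix(df)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)


class TestPreferredCodonTally:
    def test_counts_species_with_rscu_above_one(self):
        biased = rscu(CodonCountTable.from_dict({"GGA": 9, "GGC": 1, "TTT": 2, "TTC": 2}))
        profiles = {f"sp{i}": biased for i in range(3)}
        tally = preferred_codon_tally(profiles)
        assert tally["GGA"] == 3
        assert tally["GGC"] == 0
        assert tally["TTT"] == 0  # RSCU exactly 1 is not preferred
        assert (tally <= 3).all()


class TestPearsonRegression:
    def test_identity(self):
        res = pearson_regression([0, 1, 2], [0, 1, 2])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_anti_identity(self):
        res = pearson_regression([0, 1, 2], [2, 1, 0])
        assert res.pearson_r == pytest.approx(-1.0)

    def test_hand_computed_normal_equations(self):
        res = pearson_regression([1, 2, 3, 4], [2, 4, 5, 9])
        assert res.slope == pytest.approx(2.2)
        assert res.intercept == pytest.approx(-0.5)
        assert res.pearson_r == pytest.approx(44 / np.sqrt(2080))
        assert res.r_squared == pytest.approx(res.pearson_r**2)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_regression([1, 1, 1], [0, 1, 2])


class TestCodonCubCorrelations:
    def _frames(self):
        species = [f"sp{i}" for i in range(6)]
        enc = pd.Series(np.linspace(60, 40, 6), index=species)
        rng = np.random.default_rng(8)
        freqs = pd.DataFrame(
            0.01 + 0.001 * rng.normal(size=(6, 59)),
            index=species,
            columns=list(INFORMATIVE_CODONS),
        )
        # an A-ending codon rising as ENC falls
        freqs["AAA"] = np.linspace(0.01, 0.03, 6)
        # a constant codon
        freqs["GGC"] = 0.015
        return freqs, enc

    def test_constructed_signs_and_ns_flags(self):
        freqs, enc = self._frames()
        out = codon_cub_correlations(freqs, enc)
        assert len(out) == 59
        assert out.loc["AAA", "pearson_r"] > 0.99
        assert bool(out.loc["AAA", "significant"])
        assert not bool(out.loc["GGC", "significant"])
        assert np.isnan(out.loc["GGC", "pearson_r"])


class TestSencEncRegressions:
    def test_negative_slopes_when_bias_rises_as_enc_falls(self):
        species = [f"sp{i}" for i in range(8)]
        enc = pd.Series(np.linspace(61, 40, 8), index=species)
        rng = np.random.default_rng(11)
        senc = pd.DataFrame(
            {aa: 0.9 - 0.01 * (enc - 40) + 0.005 * rng.normal(size=8)
             for aa in ck.DEGENERATE_AAS},
            index=species,
        )
        out = senc_enc_regressions(senc, enc)
        assert len(out) == 18
        assert (out["slope"] < 0).all()


class TestGeneLevelCorrelates:
    def test_constructed_selection_signs(self):
        rng = np.random.default_rng(13)
        n = 400
        length = rng.integers(100, 600, n).astype(float)
        expr = pd.DataFrame({"gills": 10 ** rng.normal(1, 1, n)}, index=range(n))
        noise = 0.01 * rng.normal(size=n)
        # GC-directed speed selection and AT-directed accuracy selection
        gc3 = 0.4 + 0.05 * np.log10(expr["gills"] + 1) - 0.0002 * length + noise
        enc = 55 + rng.normal(0, 1, n)
        genes = pd.DataFrame(
            {"enc": enc, "gc3": gc3, "length_codons": length}, index=range(n)
        )
        out = gene_level_correlates(genes, expression=expr)
        assert out.loc["gc3_vs_expression_gills", "pearson_r"] > 0
        assert bool(out.loc["gc3_vs_expression_gills", "significant"])
        assert out.loc["gc3_vs_length", "pearson_r"] < 0
        assert bool(out.loc["gc3_vs_length", "significant"])
        assert set(out.index) >= {"cub_vs_length", "gc3_vs_length", "cub_vs_gc3"}

    def test_missing_expression_rows_absent(self):
        genes = pd.DataFrame(
            {"enc": [50, 51, 52, 53], "gc3": [0.3, 0.4, 0.5, 0.45],
             "length_codons": [100, 200, 300, 250]}
        )
        out = gene_level_correlates(genes, expression=None)
        assert not any(a.startswith("cub_vs_expression") for a in out.index)
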