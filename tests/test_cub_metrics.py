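import numpy as np
import pytest

import cubkit as ck
from cubkit.codon_stats import CodonCountTable
from cubkit.cub_metrics import (
    CaiWeights,
    InsufficientDataError,
    cai,
    cai_weights,
    enc,
    enc_per_gene,
    family_homozygosity,
    preferred_codons,
    senc_x,
    tpm,
)
from cubkit.genetic_code import DEGENERATE_AAS, FAMILIES, SENSE_CODONS

from conftest import random_count_table


def _two_codons_per_family_table() -> CodonCountTable:
    """Every degenerate family uses exactly two codons equally -> F = 0.5."""
    counts = {}
    for aa in DEGENERATE_AAS:
        counts[FAMILIES[aa][0]] = 10
        counts[FAMILIES[aa][1]] = 10
    return CodonCountTable.from_dict(counts)


class TestFamilyHomozygosity:
    def test_wright_corrected_hand_value(self):
        t = CodonCountTable.from_dict({"TTT": 3, "TTC": 1})
        assert family_homozygosity(t, "F", mode="counts") == pytest.approx(0.5)

    def test_uniform_two_fold_frequencies(self):
        t = CodonCountTable.from_dict({"TTT": 7, "TTC": 7})
        assert family_homozygosity(t, "F", mode="frequencies") == pytest.approx(0.5)

    def test_single_codon_maximal(self):
        t = CodonCountTable.from_dict({"TTT": 9})
        assert family_homozygosity(t, "F", mode="frequencies") == pytest.approx(1.0)

    def test_insufficient_counts_raise(self):
        t = CodonCountTable.from_dict({"TTT": 1})
        with pytest.raises(InsufficientDataError):
            family_homozygosity(t, "F", mode="counts")


class TestEnc:
    def test_uniform_usage_is_61(self, uniform_table):
        assert enc(uniform_table, mode="frequencies").enc == pytest.approx(61.0)

    def test_single_codon_per_amino_acid_is_20(self):
        counts = {FAMILIES[aa][0]: 50 for aa in FAMILIES}
        t = CodonCountTable.from_dict(counts)
        assert enc(t, mode="frequencies").enc == pytest.approx(2 + 9 + 1 + 5 + 3)

    def test_half_homozygosity_composition_is_38(self):
        res = enc(_two_codons_per_family_table(), mode="frequencies")
        assert res.enc == pytest.approx(2 + 18 + 2 + 10 + 6)
        assert all(f == pytest.approx(0.5) for f in res.family_means.values())

    def test_counts_mode_applies_correction(self):
        # Phe-only style table in every 2-fold family; F_hat = 0.5 at (3,1)
        counts = {}
        for aa in DEGENERATE_AAS:
            counts[FAMILIES[aa][0]] = 3
            counts[FAMILIES[aa][1]] = 1
        res = enc(CodonCountTable.from_dict(counts), mode="counts")
        assert res.family_means[2] == pytest.approx(0.5)

    def test_missing_ile_imputed_from_classes_2_and_4(self):
        counts = {}
        for aa in DEGENERATE_AAS:
            if aa == "I":
                continue
            counts[FAMILIES[aa][0]] = 10
            counts[FAMILIES[aa][1]] = 10
        res = enc(CodonCountTable.from_dict(counts), mode="frequencies")
        assert 3 in res.missing_families
        assert res.family_means[3] == pytest.approx(0.5)
        assert res.enc == pytest.approx(38.0)

    def test_all_families_missing_errors(self):
        t = CodonCountTable.from_dict({"ATG": 5, "TGG": 5})
        with pytest.raises(ValueError, match="undefined"):
            enc(t, mode="frequencies")

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        matrix = np.stack([random_count_table(rng).counts for _ in range(20)])
        for mode in ("counts", "frequencies"):
            vec = enc_per_gene(matrix, mode=mode)
            scalar = [enc(CodonCountTable(row), mode=mode).enc for row in matrix]
            assert np.allclose(vec, scalar, atol=1e-12)


class TestSencX:
    def test_uniform_family_is_zero(self, uniform_table):
        values = senc_x(uniform_table, mode="frequencies").values
        assert len(values) == 18
        assert all(v == pytest.approx(0.0) for v in values.values())

    def test_single_codon_is_one(self):
        counts = {FAMILIES[aa][0]: 40 for aa in DEGENERATE_AAS}
        values = senc_x(CodonCountTable.from_dict(counts), mode="frequencies").values
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_two_fold_hand_value(self):
        # p = (0.75, 0.25) -> F = 0.625 -> ENC_x = 1.6 -> sENC-x = 0.4
        t = CodonCountTable.from_dict({"TTT": 3, "TTC": 1})
        assert senc_x(t, mode="frequencies").values["F"] == pytest.approx(0.4)

    def test_missing_family_key_absent(self):
        t = CodonCountTable.from_dict({"TTT": 4, "TTC": 4})
        values = senc_x(t, mode="frequencies").values
        assert set(values) == {"F"}


class TestTpm:
    def test_hand_value(self):
        out = tpm([10, 10], [1000, 2000])
        assert out == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        out = tpm(rng.integers(0, 500, 50) + 1, rng.integers(300, 3000, 50))
        assert out.sum() == pytest.approx(1e6)

    def test_symmetry(self):
        assert tpm([5, 5, 5, 5], [800] * 4) == pytest.approx([250000.0] * 4)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            tpm([0, 0], [100, 100])


class TestCai:
    def test_uniform_reference_gives_unit_weights(self, uniform_table):
        w = cai_weights(uniform_table)
        assert all(v == pytest.approx(1.0) for v in w.w.values())

    def test_weights_hand_value(self):
        ref = CodonCountTable.from_dict({"TTT": 30, "TTC": 10})
        with pytest.warns(UserWarning):  # other amino acids absent
            w = cai_weights(ref)
        assert w.w["TTT"] == pytest.approx(1.0)
        assert w.w["TTC"] == pytest.approx(1 / 3)

    def test_zero_count_codon_gets_pseudocount(self):
        ref = CodonCountTable.from_dict({"TTT": 30})
        with pytest.warns(UserWarning):
            w = cai_weights(ref)
        assert w.w["TTC"] == pytest.approx(0.5 / 30)

    def test_maximal_gene_has_cai_one(self, uniform_table):
        w = cai_weights(uniform_table)
        gene = CodonCountTable.from_dict({"TTT": 10, "GGA": 5})
        assert cai(gene, w) == pytest.approx(1.0)

    def test_geometric_mean_hand_value(self):
        w = {c: 1.0 for c in SENSE_CODONS}
        w["TTT"], w["GGA"] = 0.5, 0.125
        weights = CaiWeights(w=w, reference_n=100)
        gene = CodonCountTable.from_dict({"TTT": 1, "GGA": 1})
        assert cai(gene, weights) == pytest.approx(0.25)

    def test_start_and_trp_codons_excluded(self):
        ref = CodonCountTable.from_dict({"TTT": 30, "TTC": 10})
        with pytest.warns(UserWarning):
            w = cai_weights(ref)
        only_excluded = CodonCountTable.from_dict({"ATG": 3, "TGG": 2})
        with pytest.raises(ValueError, match="countable"):
            cai(only_excluded, w)


class TestPreferredCodons:
    def test_split_by_rscu(self):
        vec = ck.rscu(CodonCountTable.from_dict({"TTT": 30, "TTC": 10}))
        preferred, avoided = preferred_codons(vec)
        assert preferred == {"TTT"} and avoided == {"TTC"}

    def test_rscu_exactly_one_is_neither(self, uniform_table):
        preferred, avoided = preferred_codons(ck.rscu(uniform_table))
        assert not preferred and not avoided

    def test_four_fold_single_codon(self):
        vec = ck.rscu(CodonCountTable.from_dict({"GGA": 9}))
        preferred, avoided = preferred_codons(vec)
        assert preferred == {"GGA"}
        assert avoided == {"GGC", "GGG", "GGT"}
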