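"""Preference labels, family tests, reciprocal best hits, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from reduvenom import gland_specificity as gs
from reduvenom.synthdata import GeneratorConfig, generate_orthologue_tables


class TestClassifyGlandPreference:
    @pytest.mark.parametrize(
        "pmg,amg,label",
        [
            (5000.0, 10.0, "PMG-specific"),
            (50.0, 50.0, "shared"),
            (0.0, 500.0, "AMG-specific"),
        ],
    )
    def test_examples(self, pmg, amg, label):
        got, _ = gs.classify_gland_preference(pmg, amg)
        assert got == label

    def test_zero_tpm_pseudocount_fold(self):
        _, fold = gs.classify_gland_preference(0.0, 500.0)
        assert fold == pytest.approx(500.5 / 0.5)  # = 1001

    def test_shared_fold_is_one_for_equal(self):
        _, fold = gs.classify_gland_preference(50.0, 50.0)
        assert fold == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for pmg, amg in rng.uniform(0, 1e4, (50, 2)):
            l1, f1 = gs.classify_gland_preference(pmg, amg)
            l2, f2 = gs.classify_gland_preference(amg, pmg)
            assert f1 == pytest.approx(f2)
            swap = {"PMG-specific": "AMG-specific", "AMG-specific": "PMG-specific",
                    "shared": "shared"}
            assert l2 == swap[l1]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gs.classify_gland_preference(-1.0, 0.0)

    def test_housekeeping_flag(self):
        df = pd.DataFrame(
            {"tpm_pmg": [100.0, 5000.0, 3.0], "tpm_amg": [120.0, 10.0, 4.0]}
        )
        out = gs.classify_table(df)
        assert list(out["housekeeping"]) == [True, False, False]


class TestKruskalWallis:
    def test_worked_case(self):
        """{1,2,3} vs {4,5,6}: H = 3.857 by the rank formula; exact p = 2/20."""
        res = gs.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.h == pytest.approx(3.857, abs=1e-3)
        assert res.p_exact == pytest.approx(0.100, abs=1e-9)

    def test_identical_groups_degenerate(self):
        res = gs.kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert res.h == 0.0
        assert res.p_chi2 == 1.0

    def test_exact_matches_enumeration_oracle(self):
        """Exact p agrees with a from-scratch enumeration over all splits."""
        from scipy import stats

        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(1, 1, 4)
            res = gs.kruskal_wallis(a, b)
            pooled = np.concatenate([a, b])
            h_obs = stats.kruskal(a, b).statistic
            count = total = 0
            for idx in itertools.combinations(range(8), 4):
                sel = np.zeros(8, dtype=bool)
                sel[list(idx)] = True
                h = stats.kruskal(pooled[sel], pooled[~sel]).statistic
                count += h >= h_obs - 1e-12
                total += 1
            assert res.p_exact == pytest.approx(count / total, abs=1e-12)

    def test_monotone_transform_invariance(self):
        a = [3.0, 10.0, 41.0, 7.0]
        b = [100.0, 220.0, 55.0]
        h1 = gs.kruskal_wallis(a, b).h
        h2 = gs.kruskal_wallis(np.log(a), np.log(b)).h
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_biased_family_significant_at_n4(self):
        pmg = [4000.0, 5500.0, 4700.0, 6100.0]
        amg = [12.0, 9.0, 20.0, 15.0]
        res = gs.kruskal_wallis(pmg, amg)
        assert res.p_exact < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            gs.kruskal_wallis([1.0], [2.0, 3.0])


class TestFamilyPreferenceTests:
    def _table(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(14):  # PMG-biased family, study-sized
            rows.append(("redulysin_%d" % i, "redulysin",
                         float(rng.uniform(3000, 30000)), float(rng.uniform(5, 50))))
        for i in range(2):  # too small to test
            rows.append(("kazal_%d" % i, "kazal", 5.0, 800.0))
        return pd.DataFrame(rows, columns=["protein_id", "family", "tpm_pmg", "tpm_amg"])

    def test_direction_and_significance(self):
        out = gs.family_preference_tests(self._table()).set_index("family")
        red = out.loc["redulysin"]
        assert red["tested"]
        assert red["direction"] == "PMG"
        assert red["p"] < 0.05

    def test_small_family_untested(self):
        out = gs.family_preference_tests(self._table()).set_index("family")
        assert not out.loc["kazal", "tested"]
        assert np.isnan(out.loc["kazal", "p"])

    def test_null_p_values_roughly_uniform(self):
        """Shuffled gland labels give a flat p distribution (KS at alpha 0.01)."""
        from scipy import stats

        rng = np.random.default_rng(123)
        pvals = []
        for rep in range(200):
            n = 25
            vals = rng.lognormal(5, 1, size=(n, 2))  # no gland effect
            df = pd.DataFrame(
                {"protein_id": [f"p{i}" for i in range(n)], "family": "f",
                 "tpm_pmg": vals[:, 0], "tpm_amg": vals[:, 1]}
            )
            pvals.append(gs.family_preference_tests(df)["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bh_adjustment_present(self):
        out = gs.family_preference_tests(self._table())
        tested = out[out["tested"]]
        assert (tested["p_bh"] >= tested["p"] - 1e-12).all()


def double_argmax_rbh(score: np.ndarray):
    """Oracle: (i, j) is a pair iff j = argmax of row i and i = argmax of col j."""
    pairs = []
    for i in range(score.shape[0]):
        j = int(np.argmax(score[i]))
        if int(np.argmax(score[:, j])) == i:
            pairs.append((i, j))
    return pairs


class TestReciprocalBestHits:
    def _tables(self, score):
        na, nb = score.shape
        ab = [(f"a{i}", f"b{j}", score[i, j]) for i in range(na) for j in range(nb)]
        ba = [(f"b{j}", f"a{i}", score[i, j]) for i in range(na) for j in range(nb)]
        cols = ["query", "subject", "score"]
        return pd.DataFrame(ab, columns=cols), pd.DataFrame(ba, columns=cols)

    def test_simple_pair(self):
        ab = pd.DataFrame({"query": ["a1"], "subject": ["b1"], "score": [100.0]})
        ba = pd.DataFrame({"query": ["b1"], "subject": ["a1"], "score": [100.0]})
        pairs = gs.reciprocal_best_hits(ab, ba)
        assert pairs.values.tolist() == [["a1", "b1"]]

    def test_non_reciprocal_excluded(self):
        ab = pd.DataFrame({"query": ["a1"], "subject": ["b1"], "score": [90.0]})
        ba = pd.DataFrame(
            {"query": ["b1", "b1"], "subject": ["a1", "a2"], "score": [80.0, 95.0]}
        )
        assert len(gs.reciprocal_best_hits(ab, ba)) == 0

    def test_matches_double_argmax_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            score = rng.uniform(0, 100, (20, 20))
            ab, ba = self._tables(score)
            got = {
                (int(a[1:]), int(b[1:]))
                for a, b in gs.reciprocal_best_hits(ab, ba).itertuples(index=False)
            }
            assert got == set(double_argmax_rbh(score))

    def test_table_swap_transposes_pairs(self):
        rng = np.random.default_rng(8)
        score = rng.uniform(0, 100, (15, 15))
        ab, ba = self._tables(score)
        fwd = gs.reciprocal_best_hits(ab, ba)
        rev = gs.reciprocal_best_hits(ba, ab)
        assert set(map(tuple, fwd.values)) == {(b, a) for a, b in rev.values}

    def test_blast_tabular_columns_accepted(self):
        ab = pd.DataFrame({"qseqid": ["a1"], "sseqid": ["b1"], "bitscore": [50.0]})
        ba = pd.DataFrame({"qseqid": ["b1"], "sseqid": ["a1"], "bitscore": [50.0]})
        assert len(gs.reciprocal_best_hits(ab, ba)) == 1

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            gs.reciprocal_best_hits(pd.DataFrame({"x": [1]}), pd.DataFrame({"x": [1]}))


class TestOrthologueConcordance:
    def test_all_concordant(self):
        pairs = pd.DataFrame(
            {"label_a": ["PMG-specific"] * 4, "label_b": ["PMG-specific"] * 4}
        )
        assert gs.orthologue_concordance(pairs).fraction == 1.0

    def test_57_pair_worked_example(self, default_config):
        """51 concordant of 57 pairs gives the 89% concordance arithmetic."""
        pairs = generate_orthologue_tables(default_config, n_pairs=57, n_concordant=51)
        res = gs.orthologue_concordance(pairs)
        assert res.n_pairs == 57
        assert res.n_concordant == 51
        assert round(res.fraction, 2) == 0.89

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gs.orthologue_concordance(pd.DataFrame(columns=["label_a", "label_b"]))

    def test_missing_labels_excluded(self):
        pairs = pd.DataFrame(
            {"label_a": ["PMG-specific", None], "label_b": ["PMG-specific", "shared"]}
        )
        res = gs.orthologue_concordance(pairs)
        assert res.n_pairs == 1
        assert res.n_excluded == 1
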