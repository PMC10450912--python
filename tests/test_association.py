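import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gchap import (anova_across_haps, associate, call_gchaps,
                   compare_predominant_vs_unfavorable, favorable_hap,
                   favorable_frequency_table, letter_groups,
                   strong_association_flag, tally_percent, unfavorable_hap)
from gchap.io import PhenotypeTable, PopulationPartition

from conftest import make_variantset


def closed_form_anova(groups):
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = len(arrays) - 1, pooled.size - len(arrays)
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


class TestAnova:
    def test_two_group_example(self):
        """A=(1,2,3), B=(4,5,6): SSB=13.5, SSW=4, df=(1,4) -> F=13.5."""
        f, p, summary, testable = anova_across_haps({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert testable
        assert f == pytest.approx(13.5, abs=1e-12)
        assert p == pytest.approx(0.0213, abs=1e-3)
        assert summary.loc["B", "mean"] == 5.0

    def test_identical_groups(self):
        f, p, _, testable = anova_across_haps({"A": [2, 2, 2], "B": [2, 2, 2]})
        assert (f, p, testable) == (0.0, 1.0, True)

    def test_single_group_not_testable(self):
        f, p, _, testable = anova_across_haps({"A": [1, 2, 3]})
        assert not testable and np.isnan(f)

    def test_small_groups_dropped(self):
        f, p, summary, testable = anova_across_haps(
            {"A": [1, 2, 3], "B": [4, 5], "C": [9]}, min_group_n=2)
        assert testable and set(summary.index) == {"A", "B"}

    def test_matches_closed_form_random(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            groups = {f"H{i}": rng.normal(rng.normal(), 1.0,
                                          size=int(rng.integers(2, 20)))
                      for i in range(k)}
            f, p, _, _ = anova_across_haps(groups)
            ef, ep = closed_form_anova(groups)
            assert f == pytest.approx(ef, abs=1e-9)
            assert p == pytest.approx(ep, abs=1e-12)

    def test_p_matches_permutation_approximation(self):
        """The F-distribution p agrees with a label-permutation null on a
        small instance, within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 1.0, 8)
        f_obs, p_obs, _, _ = anova_across_haps({"A": a, "B": b})
        pooled = np.concatenate([a, b])
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f, _ = closed_form_anova({"A": perm[:8], "B": perm[8:]})
            hits += f >= f_obs
        assert p_obs == pytest.approx(hits / n_perm, abs=0.03)


class TestLetters:
    def test_all_identical_share_a(self):
        letters = letter_groups({"A": [5, 5, 5], "B": [5, 5, 5], "C": [5, 5, 5]})
        assert set(letters.values()) == {"a"}

    def test_far_separated_groups(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(10, 1, 10)
        letters = letter_groups({"low": g1, "high": g2})
        assert letters["high"] == "a" and letters["low"] == "b"

    @pytest.mark.parametrize("method", ["tukey", "duncan"])
    def test_overlapping_middle_group(self, method):
        """Middle group not separable from either extreme -> a / ab / b."""
        rng = np.random.default_rng(1)
        g_lo = rng.normal(0.0, 1.0, 10)
        g_mid = rng.normal(0.8, 1.0, 10)
        g_hi = rng.normal(1.6, 1.0, 10)
        letters = letter_groups({"lo": g_lo, "mid": g_mid, "hi": g_hi},
                                method=method)
        assert letters["hi"] == "a" and letters["lo"] == "b"
        assert set(letters["mid"]) == {"a", "b"}

    def test_letters_consistent_with_pairwise_tukey(self):
        """Two groups share a letter iff their Tukey-adjusted p >= alpha."""
        from gchap.association import _tukey_pairwise_p

        rng = np.random.default_rng(6)
        groups = {f"H{i}": rng.normal(i * 0.9, 1.0, size=12) for i in range(4)}
        clean = {k: np.asarray(v) for k, v in groups.items()}
        letters = letter_groups(groups, alpha=0.05)
        pair_p = _tukey_pairwise_p(clean)
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (pair_p[(a, b)] >= 0.05)


class TestFlagsAndCalls:
    @pytest.mark.parametrize("p,flag", [(1e-8, True), (1e-7, False), (0.04, False)])
    def test_strong_flag_strict(self, p, flag):
        assert strong_association_flag(p) is flag

    def test_favorable_direction_and_ties(self):
        summary = pd.DataFrame({"n": [40, 10], "mean": [20.0, 25.0]},
                               index=["H1", "H2"])
        assert favorable_hap(summary) == "H2"
        assert favorable_hap(summary, direction="min") == "H1"
        tied = pd.DataFrame({"n": [40, 10], "mean": [25.0, 25.0]},
                            index=["H1", "H2"])
        assert favorable_hap(tied) == "H1"  # larger n wins the tie

    def test_unfavorable_lowest_frequency_major(self):
        freqs = pd.Series({"H1": 0.5, "H2": 0.3, "H3": 0.02})
        assert unfavorable_hap(freqs, ["H1", "H2", "H3"]) == "H3"
        assert unfavorable_hap(freqs, []) is None
        tie = pd.Series({"Ha": 0.1, "Hb": 0.1, "Hc": 0.8})
        assert unfavorable_hap(tie, ["Ha", "Hb", "Hc"]) == "Ha"

    def test_predominant_vs_unfavorable_contrast(self):
        assert compare_predominant_vs_unfavorable([3, 3, 3], [3, 3, 3]) == (0.0, 1.0)
        diff, p = compare_predominant_vs_unfavorable([10, 11, 12], [20, 21, 22])
        assert diff == -10.0
        t, p_ref = sps.ttest_ind([10, 11, 12], [20, 21, 22], equal_var=False)
        assert p == pytest.approx(p_ref, abs=1e-12) and p < 0.01
        assert compare_predominant_vs_unfavorable([1, 2], [5]) is None


class TestAssociateAndFrequencies:
    def _panel(self):
        strings = ["0"] * 30 + ["1"] * 20
        t = call_gchaps(make_variantset(strings), "g")
        rng = np.random.default_rng(0)
        vals = np.where(np.array([s == "1" for s in strings]),
                        rng.normal(25, 1, 50), rng.normal(20, 1, 50))
        phenos = PhenotypeTable(values=pd.DataFrame(
            {"TGW": vals}, index=[f"acc{i+1}" for i in range(50)]))
        return t, phenos

    def test_full_association(self):
        t, phenos = self._panel()
        res = associate(t, phenos, "TGW")
        assert res.testable and res.p_value < 1e-7 and res.strong
        assert res.favorable == "Hap2"       # alt carriers have higher TGW
        assert res.unfavorable == "Hap2"     # and lower frequency
        assert res.letters["Hap1"] != res.letters["Hap2"]

    def test_favorable_frequency_table_conservation(self):
        t, _ = self._panel()
        part = PopulationPartition(
            population={f"acc{i+1}": ("XI" if i % 2 else "GJ") for i in range(50)},
            breeding_status={},
        )
        tab = favorable_frequency_table("Hap2", t, part)
        assert tab["n_carriers"].sum() == 20
        assert ((tab["frequency"] >= 0) & (tab["frequency"] <= 1)).all()

    def test_fixation_and_absence(self):
        t, _ = self._panel()
        part = PopulationPartition(
            population={f"acc{i+1}": ("REF" if i < 30 else "ALT") for i in range(50)},
            breeding_status={},
        )
        tab = favorable_frequency_table("Hap2", t, part).set_index("subpopulation")
        assert tab.loc["ALT", "frequency"] == 1.0   # fixation
        assert tab.loc["REF", "frequency"] == 0.0   # absent


def test_tally_percent():
    assert tally_percent(61, 96) == 63.5
    assert tally_percent(149, 360) == 41.4
    assert tally_percent(16, 24) == 66.7
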