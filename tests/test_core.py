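import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gchap import (GeneModel, InputError, call_gchaps, classify_diversity,
                   extract_cds_snps, major_gchaps, predominant_gchap,
                   shannon_equitability)
from gchap.core import MISSING_SYMBOL, POLICIES

from conftest import make_variantset


def brute_force_haplotypes(strings_by_acc):
    """Independent grouping oracle: bucket accessions by exact string."""
    groups = {}
    for acc, s in strings_by_acc.items():
        groups.setdefault(s, []).append(acc)
    return groups


def oracle_resolve(codes, sites, policy):
    """Re-derive allele strings with plain loops, independent of the
    vectorised implementation."""
    n_acc, n_sites = len(codes), len(codes[0]) if codes else 0
    major = []
    for j in range(n_sites):
        col = [codes[i][j] for i in range(n_acc)]
        major.append("1" if col.count("1") > col.count("0") else "0")
    out = {}
    for i in range(n_acc):
        chars = []
        skip = False
        for j in range(n_sites):
            c = codes[i][j]
            if c in "01":
                chars.append(sites[j].ref if c == "0" else sites[j].alt)
            elif policy == "major-allele":
                chars.append(sites[j].ref if major[j] == "0" else sites[j].alt)
            elif policy == "drop-accession":
                skip = True
                break
            else:
                chars.append(MISSING_SYMBOL)
        if not skip:
            out[f"acc{i+1}"] = "".join(chars)
    return out


class TestExtractCdsSnps:
    def test_position_boundaries(self):
        """1-based positions 101..200 fall inside the half-open internal
        interval (100, 200); 50 and 250 (and 201) do not."""
        positions = [50, 101, 150, 200, 250]
        vs = make_variantset(["0" * 5], start_pos=0)
        vs.sites = [s.__class__("chr1", p, "A", "T") for s, p in zip(vs.sites, positions)]
        gene = GeneModel("g", "chr1", "+", [(100, 200)])
        out = extract_cds_snps(vs, gene)
        assert [s.pos for s in out.sites] == [101, 150, 200]

    def test_empty_cds_and_identity(self):
        vs = make_variantset(["010", "101"], start_pos=100)
        empty = GeneModel("g0", "chr1", "+", [])
        assert extract_cds_snps(vs, empty).n_sites == 0
        whole = GeneModel("g1", "chr1", "+", [(0, 1000)])
        assert extract_cds_snps(vs, whole).n_sites == 3


class TestCallGchaps:
    def test_zero_sites_single_haplotype(self):
        """A gene without CDS SNPs yields one haplotype covering everyone."""
        vs = make_variantset([""] * 10)
        t = call_gchaps(vs, "hk")
        assert t.n_haplotypes == 1
        assert t.frequencies["Hap1"] == 1.0
        assert len(t.assignments) == 10

    def test_all_distinct(self):
        t = call_gchaps(make_variantset(["00", "01", "10", "11"]), "g")
        assert t.n_haplotypes == 4
        assert (t.frequencies == 0.25).all()

    def test_het_resolution_major_allele(self):
        """1 site, genotypes {0,0,1,H}: H goes to ref (the majority)."""
        t = call_gchaps(make_variantset(["0", "0", "1", "H"]), "g")
        assert t.frequencies.tolist() == [0.75, 0.25]
        assert t.haplotypes["Hap1"] == "A"  # ref base

    def test_drop_accession_policy(self):
        t = call_gchaps(make_variantset(["0", "0", "1", "H"]), "g",
                        policy="drop-accession")
        assert len(t.assignments) == 3
        assert t.frequencies.tolist() == [pytest.approx(2 / 3), pytest.approx(1 / 3)]

    def test_missing_code_policy_creates_new_haplotype(self):
        t = call_gchaps(make_variantset(["0", "0", "1", "."]), "g",
                        policy="missing-code")
        assert t.n_haplotypes == 3
        assert MISSING_SYMBOL in "".join(t.haplotypes.values())

    def test_label_order_and_ties(self):
        """Labels rank by descending frequency; ties break on the smaller
        allele string."""
        t = call_gchaps(make_variantset(["01", "01", "10", "10", "11"]), "g")
        assert t.haplotypes["Hap1"] == "AT"   # tie 2-2 with "TA": "AT" < "TA"
        assert t.haplotypes["Hap2"] == "TA"
        assert t.haplotypes["Hap3"] == "TT"
        freqs = t.frequencies.to_numpy()
        assert (freqs[:-1] >= freqs[1:]).all()

    def test_empty_input_rejected(self):
        vs = make_variantset(["0"])
        vs.accessions, vs.genotypes = [], np.empty((0, 1), dtype="<U1")
        with pytest.raises(InputError):
            call_gchaps(vs, "g")

    @pytest.mark.parametrize("policy", POLICIES)
    def test_matches_bruteforce_oracle(self, policy):
        """call_gchaps agrees with exact-string grouping on random instances
        (<=10 sites, <=50 accessions) under every policy."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_acc = int(rng.integers(2, 51))
            n_sites = int(rng.integers(1, 11))
            codes = rng.choice(list("01H."), p=[0.45, 0.35, 0.1, 0.1],
                               size=(n_acc, n_sites))
            strings = ["".join(row) for row in codes]
            if policy == "drop-accession" and all("H" in s or "." in s for s in strings):
                strings[0] = "0" * n_sites
            vs = make_variantset(strings)
            t = call_gchaps(vs, "g", policy=policy)
            expected = oracle_resolve(strings, vs.sites, policy)
            groups = brute_force_haplotypes(expected)
            # renamed accessions: oracle indexes 1..n in order
            assert len(t.assignments) == len(expected)
            assert t.n_haplotypes == len(groups)
            for s, members in groups.items():
                labels = {t.assignments[m] for m in members}
                assert len(labels) == 1
                assert t.haplotypes[labels.pop()] == s

    def test_disjoint_scope_union(self, simple_table):
        """Haplotype set of A|B equals union of the sets of A and B."""
        a, b = ["acc1", "acc3"], ["acc2", "acc4"]
        ha = set(simple_table.hap_frequencies(a).index)
        hb = set(simple_table.hap_frequencies(b).index)
        hab = set(simple_table.hap_frequencies(a + b).index)
        assert hab == ha | hb


class TestHapFrequencies:
    def test_basic_and_single(self, simple_table):
        f = simple_table.hap_frequencies()
        assert f.sum() == pytest.approx(1.0)
        assert f.tolist() == [0.5, 0.25, 0.25]
        single = simple_table.hap_frequencies(["acc3"])
        assert single.tolist() == [1.0]

    def test_absent_haplotype_omitted(self, simple_table):
        f = simple_table.hap_frequencies(["acc1", "acc2", "acc3"])
        assert "Hap3" not in f.index  # acc4's haplotype excluded

    def test_empty_scope_rejected(self, simple_table):
        with pytest.raises(InputError):
            simple_table.hap_frequencies([])


class TestShannonEquitability:
    @pytest.mark.parametrize("p,expected", [
        ([1.0], 0.0),
        ([0.25] * 4, 1.0),
        ([0.5, 0.25, 0.25], 0.9464),  # H=1.03972, ln3=1.09861
    ])
    def test_values(self, p, expected):
        assert shannon_equitability(p) == pytest.approx(expected, abs=1e-4)

    def test_non_normalized_rejected(self):
        with pytest.raises(InputError):
            shannon_equitability([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_permutation_invariant_and_bounds(self, weights):
        p = np.array(weights) / np.sum(weights)
        p = p / p.sum()
        e = shannon_equitability(p)
        rng = np.random.default_rng(0)
        assert shannon_equitability(rng.permutation(p)) == pytest.approx(e, abs=1e-12)
        assert 0.0 <= e <= 1.0
        if p.size == 1:
            assert e == 0.0

    def test_uniform_iff_one(self):
        assert shannon_equitability([1 / 7] * 7) == pytest.approx(1.0, abs=1e-12)
        assert shannon_equitability([0.6, 0.4]) < 1.0


class TestClassification:
    @pytest.mark.parametrize("e_h,n,expected", [
        (0.0, 1, "HK"),
        (0.02, 12, "low"),
        (0.171, 82, "medium-low"),
        (0.05, 10, "medium-low"),   # boundary: 0.05 belongs to medium-low
        (0.444, 498, "medium-high"),
        (0.3, 100, "medium-high"),
        (0.7, 500, "high"),
        (1.0, 4, "high"),
    ])
    def test_classes(self, e_h, n, expected):
        assert classify_diversity(e_h, n) == expected


class TestMajorPredominant:
    def test_major_threshold(self):
        p = pd.Series([0.5, 0.3, 0.15, 0.04, 0.009, 0.001],
                      index=[f"Hap{i}" for i in range(1, 7)])
        assert major_gchaps(p) == ["Hap1", "Hap2", "Hap3", "Hap4"]
        assert major_gchaps(pd.Series({"H": 0.01, "G": 0.99})) == ["G", "H"]  # >= incl.
        assert major_gchaps(pd.Series({"A": 0.005})) == []

    def test_absolute_count_mode(self):
        p = pd.Series({"Hap1": 0.9, "Hap2": 0.06, "Hap3": 0.04})
        assert major_gchaps(p, min_count=30, scope_size=500) == ["Hap1", "Hap2"]

    def test_predominant_and_tie(self):
        p = pd.Series({"Hap1": 0.6, "Hap2": 0.4})
        assert predominant_gchap(p) == ("Hap1", 0.6)
        tied = pd.Series({"HapA": 0.5, "HapB": 0.5})
        label, f = predominant_gchap(tied, {"HapA": "TA", "HapB": "AT"})
        assert (label, f) == ("HapB", 0.5)  # "AT" < "TA"
        single = pd.Series({"Hap1": 1.0})
        assert predominant_gchap(single) == ("Hap1", 1.0)
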