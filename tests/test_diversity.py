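"""Diversity statistics, HWE exact test, and exclusion probabilities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from panelpower import diversity as dv
from panelpower.markers_io import GenotypeTable
from panelpower.synthpop import frequencies_matching, simulate_purebreds
from panelpower.markers_io import AlleleFrequencyTable


def make_table(calls):
    calls = np.asarray(calls, dtype=np.int32)
    return GenotypeTable([f"i{k}" for k in range(calls.shape[0])],
                         [f"L{j}" for j in range(calls.shape[1])], calls)


class TestLocusSummary:
    @pytest.mark.parametrize("ho,he,fis", [
        (0.614, 0.950, 0.354),   # strong heterozygote deficit
        (0.800, 0.934, 0.144),   # mild deficit
        (0.800, 0.787, -0.017),  # slight excess
    ])
    def test_fixation_index_reproduces_published_rows(self, ho, he, fis):
        assert dv.fixation_index(ho, he) == pytest.approx(fis, abs=1e-3)

    def test_monomorphic_locus(self):
        t = make_table([[[7, 7]], [[7, 7]]])
        st = dv.locus_summary(t, "L0")
        assert st == (1, 0.0, 0.0, 0.0)

    def test_counts_on_small_table(self):
        t = make_table([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
        st = dv.locus_summary(t, "L0")
        assert st.na == 2 and st.ho == 0.5
        assert st.he == pytest.approx(0.5)
        assert st.fis == pytest.approx(0.0)

    def test_he_from_simulated_hwe_data_converges(self):
        p = frequencies_matching(8, 0.8)
        freqs = AlleleFrequencyTable(
            {"L": {100 + i: float(x) for i, x in enumerate(p)}})
        t = simulate_purebreds(freqs, 5000, seed=3)
        st = dv.locus_summary(t, "L")
        se = 0.8 / math.sqrt(5000)  # conservative scale for He noise
        assert abs(st.he - 0.8) < 3 * se


# ---------------------------------------------------------------------------
# HWE: exhaustive enumeration oracle over tables with fixed allele counts

def enumerate_tables(allele_counts):
    """All symmetric genotype-count tables consistent with allele counts,
    with their exact conditional probabilities under random pairing."""
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i + 1)]

    def rec(idx, remaining, table):
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield dict(table)
            return
        i, j = cells[idx]
        if i == j:
            mx = remaining[i] // 2
        else:
            mx = min(remaining[i], remaining[j])
        for c in range(mx + 1):
            rem = list(remaining)
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            if min(rem) >= 0:
                table[(i, j)] = c
                yield from rec(idx + 1, rem, table)
        table.pop((i, j), None)

    tables = list(rec(0, list(allele_counts), {}))
    logps = []
    for t in tables:
        h = sum(c for (i, j), c in t.items() if i != j)
        lp = h * math.log(2) - sum(
            math.lgamma(c + 1) for c in t.values())
        logps.append(lp)
    m = max(logps)
    w = [math.exp(x - m) for x in logps]
    z = sum(w)
    return tables, [x / z for x in w]


def exact_probability_p(table_counts, allele_counts):
    tables, probs = enumerate_tables(allele_counts)
    h_obs = sum(c for (i, j), c in table_counts.items() if i != j)
    lp_obs = h_obs * math.log(2) - sum(
        math.lgamma(c + 1) for c in table_counts.values())
    p = 0.0
    for t, pr in zip(tables, probs):
        h = sum(c for (i, j), c in t.items() if i != j)
        lp = h * math.log(2) - sum(math.lgamma(c + 1) for c in t.values())
        if lp <= lp_obs + 1e-12:
            p += pr
    return p


class TestHweExactTest:
    def test_single_possible_table_gives_one(self):
        assert dv.hwe_exact_test(np.array([[5]]), 1000, 100, seed=1) == 1.0

    def test_invalid_chain_length(self):
        with pytest.raises(ValueError):
            dv.hwe_exact_test(np.array([[5]]), 0)

    @pytest.mark.parametrize("counts,alleles", [
        # biallelic: (nAA, nAB, nBB) = (3, 14, 3)
        ({(0, 0): 3, (1, 0): 14, (1, 1): 3}, (20, 20)),
        # 3 alleles, n = 10
        ({(0, 0): 2, (1, 0): 3, (1, 1): 1, (2, 0): 1, (2, 1): 2,
          (2, 2): 1}, (8, 7, 5)),
    ])
    def test_monte_carlo_matches_enumeration(self, counts, alleles):
        k = len(alleles)
        mat = np.zeros((k, k), dtype=int)
        for (i, j), c in counts.items():
            mat[i, j] = c
        exact = exact_probability_p(counts, alleles)
        p, se = dv.hwe_exact_test(mat, 200_000, 10_000, seed=42,
                                  return_se=True)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_deficit_mode_matches_heterozygote_tail(self):
        counts = {(0, 0): 6, (1, 0): 8, (1, 1): 6}
        tables, probs = enumerate_tables((20, 20))
        exact = sum(pr for t, pr in zip(tables, probs)
                    if t[(1, 0)] <= 8)
        mat = np.array([[6, 0], [8, 6]])
        p, se = dv.hwe_exact_test(mat, 200_000, 10_000, seed=7,
                                  mode="deficit", return_se=True)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_reproducible_given_seed(self):
        mat = np.array([[3, 0], [14, 3]])
        a = dv.hwe_exact_test(mat, 20_000, 2_000, seed=5)
        b = dv.hwe_exact_test(mat, 20_000, 2_000, seed=5)
        assert a == b


class TestBonferroni:
    def test_family_of_fifty_thresholds_at_point_001(self):
        p = np.full(50, 0.0009)
        assert dv.bonferroni_flags(p, 0.05).all()
        p2 = np.full(50, 0.0011)
        assert not dv.bonferroni_flags(p2, 0.05).any()

    def test_boundary_is_strict(self):
        assert not dv.bonferroni_flags([0.05], 0.05).any()
        assert not dv.bonferroni_flags([0.025, 0.9], 0.05)[0]

    def test_single_test_reduces_to_alpha(self):
        assert dv.bonferroni_flags([0.049], 0.05)[0]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dv.bonferroni_flags([], 0.05)


# ---------------------------------------------------------------------------
# Exclusion probabilities

def brute_force_pe(p):
    """Enumerate offspring x candidate genotype pairs; excluded when the
    candidate shares no allele with the offspring."""
    k = len(p)
    pe = 0.0
    for a in range(k):
        for b in range(k):
            w_off = p[a] * p[b]
            miss = 1.0 - sum(p[x] for x in {a, b})
            pe += w_off * miss * miss
    return pe


class TestExclusionProbability:
    def test_single_allele_zero(self):
        assert dv.exclusion_probability([1.0]) == pytest.approx(0.0, abs=1e-15)

    def test_two_equifrequent_alleles(self):
        assert dv.exclusion_probability([0.5, 0.5]) == pytest.approx(0.125)

    def test_fifteen_equifrequent_closed_form(self):
        k = 15
        closed = (1 / k) * (1 - 1 / k) ** 2 + (1 - 1 / k) * (1 - 2 / k) ** 2
        pe = dv.exclusion_probability(np.full(k, 1 / k))
        assert pe == pytest.approx(closed, abs=1e-12)
        assert pe == pytest.approx(0.7591, abs=1e-4)

    def test_power_sum_formula_equals_brute_force(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 7))
            p = rng.dirichlet(np.ones(k))
            assert dv.exclusion_probability(p) == pytest.approx(
                brute_force_pe(p), abs=1e-12)

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValueError):
            dv.exclusion_probability([0.5, 0.4])

    def test_variant_ordering(self, rng):
        # knowing one parent, or testing a full pair, can only raise power
        for _ in range(10):
            p = rng.dirichlet(np.ones(4))
            pe = dv.exclusion_probability(p)
            pe1 = dv.exclusion_probability_one_parent_known(p)
            pep = dv.exclusion_probability_parent_pair(p)
            assert pe1 >= pe - 1e-12
            assert pep >= pe1 - 1e-12


class TestCumulativeExclusion:
    def test_published_kit_accumulation(self):
        cum = dv.cumulative_exclusion([0.768, 0.419])
        assert cum[-1] == pytest.approx(0.865, abs=5e-4)

    def test_single_element_identity(self):
        assert dv.cumulative_exclusion([0.5])[0] == 0.5

    def test_monotone_and_order_invariant_final_value(self, rng):
        pe = rng.uniform(0, 0.9, size=10)
        cum = dv.cumulative_exclusion(pe)
        assert (np.diff(cum) >= 0).all()
        perm = rng.permutation(pe)
        assert dv.cumulative_exclusion(perm)[-1] == pytest.approx(cum[-1])


class TestPanelSummary:
    def test_fixture_column_means_and_se(self, summary):
        leo = summary[summary.species == "P_leopardus"].rename(
            columns=str.lower)
        stats = dv.column_stats(leo, ("na", "ho", "pe"))
        assert stats.loc["na", "mean"] == pytest.approx(17.9, abs=0.05)
        assert stats.loc["na", "se"] == pytest.approx(1.6, abs=0.05)

    def test_constant_column_zero_se(self):
        df = pd.DataFrame({"na": [3, 3, 3]})
        assert dv.column_stats(df, ("na",)).loc["na", "se"] == 0.0

    def test_summary_on_simulated_data(self, species_model, panel):
        loci = ["Pma036", "Pma191", "Pma288"]
        freqs = species_model.freqs_a.subset_loci(loci)
        t = simulate_purebreds(freqs, 300, seed=21)
        df = dv.panel_summary(t, chain_length=5000, dememorization=1000,
                              seed=2)
        assert list(df["locus"]) == loci
        assert ((df["hwe_p"] >= 0) & (df["hwe_p"] <= 1)).all()
        # CumPE accumulates
        assert (df["cum_pe"].diff().dropna() >= -1e-12).all()
        # HWE data should rarely flag after Bonferroni
        assert df["hwe_significant"].sum() <= 1
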