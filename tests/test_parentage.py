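"""LOD scores against enumeration oracles and the assignment taxonomy."""

import math

import numpy as np
import pandas as pd
import pytest

from panelpower.markers_io import AlleleFrequencyTable, GenotypeTable, Pedigree
from panelpower import parentage as pr
from panelpower import synthpop as sp


BIALLELIC = AlleleFrequencyTable({"L": {1: 0.5, 2: 0.5}})


def oracle_transmission(go, gp, p):
    """T(g_o | g_p) by exhaustive summation over the unknown parent."""
    k = len(p)
    total = 0.0
    for c in range(k):
        for d in range(k):
            w = p[c] * p[d]
            s = 0.0
            for x in gp:
                for y in (c, d):
                    if tuple(sorted((x, y))) == tuple(sorted(go)):
                        s += 0.25
            total += w * s
    return total


class TestLodSingle:
    def test_uninformative_duo_scores_zero(self):
        assert pr.lod_single({"L": (1, 2)}, {"L": (1, 1)},
                             BIALLELIC, 0.0) == pytest.approx(0.0)

    def test_matching_homozygotes(self):
        lod = pr.lod_single({"L": (1, 1)}, {"L": (1, 1)}, BIALLELIC, 0.0)
        assert lod == pytest.approx(math.log10(2))

    def test_incompatible_duo(self):
        assert pr.lod_single({"L": (1, 1)}, {"L": (2, 2)},
                             BIALLELIC, 0.0) == -np.inf
        assert pr.lod_single({"L": (1, 1)}, {"L": (2, 2)},
                             BIALLELIC, 1e-4) == pytest.approx(-4.0)

    def test_per_locus_terms_match_unknown_parent_enumeration(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            freqs = AlleleFrequencyTable(
                {"L": {i + 1: float(x) for i, x in enumerate(p)}})
            go = tuple(sorted(rng.integers(1, k + 1, 2)))
            gp = tuple(sorted(rng.integers(1, k + 1, 2)))
            T = oracle_transmission(tuple(x - 1 for x in go),
                                    tuple(x - 1 for x in gp), p)
            pa, pb = p[go[0] - 1], p[go[1] - 1]
            P = 2 * pa * pb if go[0] != go[1] else pa * pb
            e = 1e-4
            expected = math.log10(((1 - e) * T + e * P) / P)
            assert pr.lod_single({"L": go}, {"L": gp}, freqs, e) \
                == pytest.approx(expected, abs=1e-10)

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            pr.lod_single({"L": (1, 3)}, {"L": (1, 1)}, BIALLELIC)

    def test_missing_locus_contributes_zero(self):
        from panelpower.markers_io import MISSING
        off = GenotypeTable(["o"], ["L"],
                            np.array([[[MISSING, MISSING]]], dtype=np.int32))
        cand = GenotypeTable(["c"], ["L"],
                             np.array([[[1, 1]]], dtype=np.int32))
        assert pr.single_lod_matrix(off, cand, BIALLELIC)[0, 0] == 0.0


class TestLodPair:
    def test_fully_informative_trio(self):
        lod = pr.lod_pair({"L": (1, 2)}, {"L": (1, 1)}, {"L": (2, 2)},
                          BIALLELIC, 0.0)
        assert lod == pytest.approx(math.log10(2))

    def test_incompatible_trio(self):
        assert pr.lod_pair({"L": (1, 1)}, {"L": (2, 2)}, {"L": (1, 2)},
                           BIALLELIC, 0.0) == -np.inf

    def test_identical_candidate_ids_rejected(self):
        with pytest.raises(ValueError):
            pr.lod_pair({"L": (1, 2)}, {"L": (1, 1)}, {"L": (2, 2)},
                        BIALLELIC, mother_id="x", father_id="x")

    def test_pair_lod_dominates_single_for_true_trios(self, species_model):
        freqs = species_model.freqs_a
        d = sp.ParentageDesign(n_adults=30, n_offspring=60, prop_known=1.0,
                               error_rate=0.0, seed=41)
        adults, kids, ped = sp.simulate_parentage_population(freqs, d)
        singles = pr.single_lod_matrix(kids, adults, freqs)
        pos = {ind: i for i, ind in enumerate(adults.individuals)}
        wins = 0
        for i, kid in enumerate(kids.individuals):
            m, f = ped.parents[kid]
            kid_t = GenotypeTable([kid], list(kids.loci),
                                  kids.calls[i:i + 1])
            mt = GenotypeTable([m], list(adults.loci),
                               adults.calls[pos[m]:pos[m] + 1])
            ft = GenotypeTable([f], list(adults.loci),
                               adults.calls[pos[f]:pos[f] + 1])
            plod = pr.lod_pair(kid_t, mt, ft, freqs)
            if plod > max(singles[i, pos[m]], singles[i, pos[f]]):
                wins += 1
        assert wins / kids.n_individuals >= 0.95


class TestAssignment:
    def test_sole_true_parent_assigned(self, species_model):
        freqs = species_model.freqs_a
        d = sp.ParentageDesign(n_adults=3, n_offspring=5, prop_known=1.0,
                               error_rate=0.0, seed=43)
        adults, kids, ped = sp.simulate_parentage_population(freqs, d)
        mother = ped.parents[kids.individuals[0]][0]
        sole = adults.subset_individuals([mother])
        out = pr.assign_parents(kids.subset_individuals(
            [kids.individuals[0]]), sole, freqs)
        assert out[0].decision == "single"
        assert out[0].parent_ids == (mother,)
        assert out[0].lod > 5

    def test_no_candidate_above_threshold_gives_none(self, species_model):
        freqs = species_model.freqs_a
        kids = sp.simulate_purebreds(freqs, 5, seed=44, prefix="O")
        unrelated = sp.simulate_purebreds(freqs, 5, seed=45, prefix="U")
        out = pr.assign_parents(kids, unrelated, freqs)
        assert all(o.decision == "none" for o in out)

    def test_both_parents_present_yields_pair_not_single(self,
                                                         species_model):
        freqs = species_model.freqs_a
        d = sp.ParentageDesign(n_adults=50, n_offspring=40, prop_known=1.0,
                               error_rate=0.0, seed=46)
        adults, kids, ped = sp.simulate_parentage_population(freqs, d)
        out = pr.assign_parents(kids, adults, freqs)
        for o in out:
            assert o.decision == "pair"
            assert set(o.parent_ids) == set(ped.parents[o.offspring])


class TestOutcomeTaxonomy:
    def _pedigree(self):
        return Pedigree({"o1": ("m1", "f1"),   # both sampled
                         "o2": ("m2", "f2"),   # only m2 sampled
                         "o3": ("m3", "f3")},  # neither sampled
                        sampled_adults={"m1", "f1", "m2", "x1"})

    def test_enumerated_fixture_covers_each_category(self):
        ped = self._pedigree()
        mk = pr.AssignmentOutcome
        cases = [
            (mk("o1", "pair", ("m1", "f1"), 20.0), "correct_pair"),
            (mk("o2", "single", ("m2",), 8.0), "correct_single"),
            (mk("o3", "none", (), -3.0), "correct_exclusion"),
            (mk("o1", "single", ("m1",), 9.0),
             "incorrect_single_when_pair_present"),
            (mk("o2", "none", (), 1.0), "type_II"),
            (mk("o3", "single", ("x1",), 6.0), "type_I"),
            (mk("o1", "pair", ("m1", "x1"), 15.0), "type_I"),
        ]
        for outcome, expected in cases:
            scored, _ = pr.classify_outcomes([outcome], ped)
            assert scored[0].category == expected, expected

    def test_all_excluded_when_nothing_sampled_scores_perfect(self):
        ped = Pedigree({"o1": ("m", "f"), "o2": ("m2", "f2")},
                       sampled_adults=set())
        outs = [pr.AssignmentOutcome("o1", "none", (), 0.0),
                pr.AssignmentOutcome("o2", "none", (), 0.0)]
        _, summary = pr.classify_outcomes(outs, ped)
        assert summary["overall_accuracy"] == 1.0
        assert summary["type_I_rate"] == 0.0

    def test_unknown_offspring_rejected(self):
        ped = self._pedigree()
        with pytest.raises(ValueError, match="unknown"):
            pr.classify_outcomes(
                [pr.AssignmentOutcome("zz", "none", (), 0.0)], ped)


class TestParentageReport:
    def test_noiseless_fully_sampled_limit(self, species_model):
        d = sp.ParentageDesign(n_adults=60, n_offspring=50, prop_known=1.0,
                               error_rate=0.0, seed=47)
        rep = pr.parentage_report(species_model.freqs_a, d, n_replicates=2)
        assert rep.shape == (6, 3)
        assert (rep.loc[["single_accuracy", "pair_accuracy",
                         "exclusion_accuracy", "overall_accuracy"]]
                == 1.0).all().all()
        assert (rep.loc[["type_I_rate", "type_II_rate"]] == 0.0).all().all()

    def test_accuracy_monotone_in_genotyping_error(self, species_model):
        freqs = species_model.freqs_a
        accs = []
        for rate in (0.0, 0.05, 0.25):
            vals = []
            for seed in (51, 52, 53):
                d = sp.ParentageDesign(n_adults=100, n_offspring=120,
                                       error_rate=rate, seed=seed)
                rep = pr.parentage_report(freqs, d, n_replicates=1)
                vals.append(rep.loc["overall_accuracy", "average"])
            accs.append(np.mean(vals))
        assert accs[0] >= accs[1] >= accs[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            pr.ParentageConfig(calc_error=1.5)
        with pytest.raises(ValueError):
            pr.ParentageConfig(lod_threshold_single=np.inf)
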