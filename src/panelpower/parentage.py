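"""Error-tolerant LOD parentage assignment and its accuracy taxonomy.

The pairwise likelihood score of a parentage hypothesis against
unrelatedness, summed over loci in log10:

    LOD_single = sum_l log10( ((1-e) T(g_o|g_p) + e P(g_o)) / P(g_o) )
    LOD_pair   = sum_l log10( ((1-e) T2(g_o|g_m,g_f) + e P(g_o)) / P(g_o) )

where T is the Mendelian transmission probability with the unknown parent
integrated over the population allele frequencies, T2 the two-parent
transmission probability, P(g_o) the HWE genotype probability, and e a
small "calculation error" mixture weight that keeps mismatching genotypes
at finite (strongly negative) likelihood, absorbing genotyping error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers_io import AlleleFrequencyTable, GenotypeTable, Pedigree
from .synthpop import ParentageDesign, simulate_parentage_population

CATEGORIES = ("correct_single", "correct_pair", "correct_exclusion",
              "type_I", "type_II", "incorrect_single_when_pair_present")


@dataclass
class ParentageConfig:
    """Assignment tuning: calculation error and LOD decision thresholds."""

    calc_error: float = 1e-4
    lod_threshold_single: float = 5.0
    lod_threshold_pair: float = 10.0
    pair_prescreen: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.calc_error < 1:
            raise ValueError("calc_error must lie in [0, 1)")
        for t in (self.lod_threshold_single, self.lod_threshold_pair):
            if not np.isfinite(t):
                raise ValueError("LOD thresholds must be finite")


@dataclass
class AssignmentOutcome:
    """Per-offspring decision and its truth category."""

    offspring: str
    decision: str  # "none" | "single" | "pair"
    parent_ids: tuple[str, ...]
    lod: float
    category: str | None = None


def _locus_data(table: GenotypeTable, freqs: AlleleFrequencyTable,
                locus: str):
    """(allele1, allele2, freq-of-1, freq-of-2, observed) arrays at a locus."""
    j = table.locus_index(locus)
    a = table.calls[:, j, 0].astype(np.int64)
    b = table.calls[:, j, 1].astype(np.int64)
    obs = a >= 0
    f = freqs.freqs[locus]
    fa = np.zeros(a.shape)
    fb = np.zeros(b.shape)
    seen = set(np.unique(table.calls[:, j, :][table.calls[:, j, :] >= 0]))
    unknown = {int(x) for x in seen} - set(f)
    if unknown:
        raise ValueError(
            f"alleles {sorted(unknown)} at {locus} absent from the "
            "frequency table")
    lut = {int(k): v for k, v in f.items()}
    fa[obs] = [lut[int(x)] for x in a[obs]]
    fb[obs] = [lut[int(x)] for x in b[obs]]
    return a, b, fa, fb, obs


def single_lod_matrix(offspring: GenotypeTable, candidates: GenotypeTable,
                      freqs: AlleleFrequencyTable,
                      calc_error: float = 1e-4) -> np.ndarray:
    """LOD of every (offspring, candidate) single-parent hypothesis.

    Vectorised per locus over the full cross; loci missing in either
    member contribute 0.  Returns shape (n_offspring, n_candidates).
    """
    if set(offspring.loci) != set(candidates.loci):
        raise ValueError("offspring and candidates must share a locus set")
    e = calc_error
    lod = np.zeros((offspring.n_individuals, candidates.n_individuals))
    for locus in offspring.loci:
        oa, ob, foa, fob, oobs = _locus_data(offspring, freqs, locus)
        ca, cb, _, _, cobs = _locus_data(candidates, freqs, locus)
        het = (oa != ob) & oobs
        p_o = np.where(het, 2 * foa * fob, foa * foa)
        # transmission prob of allele x from the candidate = (#x in cand)/2
        ta = 0.5 * ((ca[None, :] == oa[:, None]).astype(float)
                    + (cb[None, :] == oa[:, None]).astype(float))
        tb = 0.5 * ((ca[None, :] == ob[:, None]).astype(float)
                    + (cb[None, :] == ob[:, None]).astype(float))
        T = np.where(het[:, None],
                     ta * fob[:, None] + tb * foa[:, None],
                     ta * foa[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.log10(((1 - e) * T + e * p_o[:, None])
                            / p_o[:, None])
        term[~oobs, :] = 0.0
        term[:, ~cobs] = 0.0
        lod += term
    return lod


def lod_single(offspring_geno, candidate_geno, freqs: AlleleFrequencyTable,
               calc_error: float = 1e-4) -> float:
    """Single-parent LOD for one offspring/candidate duo.

    Genotypes are mappings locus -> (allele, allele) or single-row
    GenotypeTable objects.
    """
    off = _as_table(offspring_geno, freqs, "off")
    cand = _as_table(candidate_geno, freqs, "cand")
    return float(single_lod_matrix(off, cand, freqs, calc_error)[0, 0])


def _as_table(geno, freqs: AlleleFrequencyTable, name: str) -> GenotypeTable:
    if isinstance(geno, GenotypeTable):
        return geno
    loci = list(geno)
    calls = np.array([[list(geno[l]) for l in loci]], dtype=np.int32)
    return GenotypeTable([name], loci, calls)


def _pair_transmission(o_pair, m_pair, f_pair) -> float:
    """T2: P(offspring pair | mother's and father's genotypes)."""
    a, b = o_pair

    def give(par, x):
        return (int(par[0] == x) + int(par[1] == x)) / 2.0

    if a == b:
        return give(m_pair, a) * give(f_pair, a)
    return give(m_pair, a) * give(f_pair, b) + give(m_pair, b) * give(f_pair, a)


def lod_pair(offspring_geno, mother_geno, father_geno,
             freqs: AlleleFrequencyTable, calc_error: float = 1e-4,
             mother_id: str = "m", father_id: str = "f") -> float:
    """Parent-pair LOD for one trio; unordered in the two candidates."""
    if mother_id == father_id:
        raise ValueError("mother and father candidates must differ")
    e = calc_error
    off = _as_table(offspring_geno, freqs, "off")
    mot = _as_table(mother_geno, freqs, "m")
    fat = _as_table(father_geno, freqs, "f")
    total = 0.0
    for locus in off.loci:
        j = off.locus_index(locus)
        o = off.calls[0, j]
        m = mot.calls[0, mot.locus_index(locus)]
        f_ = fat.calls[0, fat.locus_index(locus)]
        if o[0] < 0 or m[0] < 0 or f_[0] < 0:
            continue
        fmap = freqs.freqs[locus]
        try:
            pa, pb = fmap[int(o[0])], fmap[int(o[1])]
        except KeyError as exc:
            raise ValueError(
                f"allele {exc} at {locus} absent from the frequency table"
            ) from None
        p_o = 2 * pa * pb if o[0] != o[1] else pa * pb
        t2 = _pair_transmission((int(o[0]), int(o[1])),
                                (int(m[0]), int(m[1])),
                                (int(f_[0]), int(f_[1])))
        with np.errstate(divide="ignore"):
            total += float(np.log10(((1 - e) * t2 + e * p_o) / p_o))
    return total


# ---------------------------------------------------------------------------
# Assignment

def assign_parents(offspring: GenotypeTable, candidates: GenotypeTable,
                   freqs: AlleleFrequencyTable,
                   config: ParentageConfig | None = None,
                   ) -> list[AssignmentOutcome]:
    """Best-candidate LOD assignment with pair-over-single precedence.

    For each offspring: all single LODs are computed; candidate pairs are
    enumerated among candidates whose single LOD exceeds the prescreen
    threshold (true parents virtually always pass at validated panel
    diversities, so this bounds the pair search).  The decision is the
    best pair if its LOD meets the pair threshold, else the best single if
    it meets the single threshold, else none.  Ties break by candidate
    order.
    """
    if candidates.n_individuals < 1:
        raise ValueError("need at least one candidate")
    cfg = config or ParentageConfig()
    lods = single_lod_matrix(offspring, candidates, freqs, cfg.calc_error)
    out: list[AssignmentOutcome] = []
    cand_tables: dict[int, GenotypeTable] = {}
    for i, kid in enumerate(offspring.individuals):
        row = lods[i]
        passing = np.flatnonzero(row > cfg.pair_prescreen)
        best_pair: tuple[float, int, int] | None = None
        if passing.size >= 2:
            kid_tab = GenotypeTable([kid], list(offspring.loci),
                                    offspring.calls[i:i + 1])
            for j1, j2 in itertools.combinations(passing.tolist(), 2):
                for j in (j1, j2):
                    if j not in cand_tables:
                        cand_tables[j] = GenotypeTable(
                            [candidates.individuals[j]],
                            list(candidates.loci),
                            candidates.calls[j:j + 1])
                pl = lod_pair(kid_tab, cand_tables[j1], cand_tables[j2],
                              freqs, cfg.calc_error,
                              mother_id=candidates.individuals[j1],
                              father_id=candidates.individuals[j2])
                if best_pair is None or pl > best_pair[0]:
                    best_pair = (pl, j1, j2)
        if best_pair is not None and best_pair[0] >= cfg.lod_threshold_pair:
            pl, j1, j2 = best_pair
            out.append(AssignmentOutcome(
                kid, "pair",
                (candidates.individuals[j1], candidates.individuals[j2]), pl))
            continue
        jbest = int(np.argmax(row))
        if row[jbest] >= cfg.lod_threshold_single:
            out.append(AssignmentOutcome(
                kid, "single", (candidates.individuals[jbest],),
                float(row[jbest])))
        else:
            out.append(AssignmentOutcome(kid, "none", (), float(row[jbest])))
    return out


# ---------------------------------------------------------------------------
# Outcome taxonomy

def classify_outcomes(assignments: list[AssignmentOutcome],
                      pedigree: Pedigree,
                      ) -> tuple[list[AssignmentOutcome], pd.Series]:
    """Score decisions against the truth pedigree.

    Categories: correct_single (the one sampled true parent assigned),
    correct_pair (both true parents assigned), correct_exclusion (no true
    parent sampled, no assignment), type_I (any assignment involving a
    non-parent, or a pair when the matching parent was the only one
    sampled), type_II (no assignment though a true parent was sampled),
    and incorrect_single_when_pair_present (a true single parent assigned
    while both parents were sampled -- scored as an error, pooled with
    type I in the rate).  Exactly one category per offspring.

    The summary reports accuracy within each decision type (an empty
    decision type is vacuously 1), error rates over all offspring, and
    overall accuracy = (correct_single + correct_pair + correct_exclusion)
    / N.
    """
    scored = []
    counts = {c: 0 for c in CATEGORIES}
    n_by_decision = {"single": 0, "pair": 0, "none": 0}
    for a in assignments:
        if a.offspring not in pedigree.parents:
            raise ValueError(f"unknown offspring {a.offspring!r}")
        true = set(pedigree.parents[a.offspring])
        sampled = true & pedigree.sampled_adults
        n_by_decision[a.decision] += 1
        if a.decision == "none":
            cat = "correct_exclusion" if not sampled else "type_II"
        elif a.decision == "single":
            pid = a.parent_ids[0]
            if pid in sampled and len(sampled) == 2:
                cat = "incorrect_single_when_pair_present"
            elif pid in sampled:
                cat = "correct_single"
            else:
                cat = "type_I"
        else:  # pair
            if set(a.parent_ids) == sampled and len(sampled) == 2:
                cat = "correct_pair"
            else:
                cat = "type_I"
        counts[cat] += 1
        scored.append(AssignmentOutcome(a.offspring, a.decision,
                                        a.parent_ids, a.lod, cat))
    n = len(assignments)
    if n == 0:
        raise ValueError("no assignments to score")

    def _acc(correct, total):
        return correct / total if total else 1.0

    summary = pd.Series({
        "single_accuracy": _acc(counts["correct_single"],
                                n_by_decision["single"]),
        "pair_accuracy": _acc(counts["correct_pair"], n_by_decision["pair"]),
        "exclusion_accuracy": _acc(counts["correct_exclusion"],
                                   n_by_decision["none"]),
        "type_I_rate": (counts["type_I"]
                        + counts["incorrect_single_when_pair_present"]) / n,
        "type_II_rate": counts["type_II"] / n,
        "overall_accuracy": (counts["correct_single"] + counts["correct_pair"]
                             + counts["correct_exclusion"]) / n,
    })
    return scored, summary


def parentage_report(freqs: AlleleFrequencyTable, design: ParentageDesign,
                     config: ParentageConfig | None = None,
                     n_replicates: int = 3, seed: int | None = None,
                     ) -> pd.DataFrame:
    """Accuracy table over simulation replicates.

    Each replicate simulates a fresh parentage population under the
    design, runs the LOD assignment, and scores the outcome taxonomy; the
    report has one row per metric, one column per replicate plus the
    average.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = config or ParentageConfig()
    base = design.seed if design.seed is not None else seed
    ss = np.random.SeedSequence(base)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(n_replicates)]
    cols = {}
    for r, s in enumerate(rep_seeds, start=1):
        d = ParentageDesign(design.n_adults, design.sex_ratio,
                            design.n_offspring, design.prop_known,
                            design.error_rate, design.error_scope,
                            design.sampling_mode, seed=s)
        adults, kids, ped = simulate_parentage_population(freqs, d)
        assignments = assign_parents(kids, adults, freqs, cfg)
        _, summary = classify_outcomes(assignments, ped)
        cols[f"sim-{r}"] = summary
    df = pd.DataFrame(cols)
    df["average"] = df.mean(axis=1)
    return df
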