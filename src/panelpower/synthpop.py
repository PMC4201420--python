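"""Synthetic genotype data emulating the study's statistical structure.

No genotype data are deposited for the two reference populations; only the
per-locus allele counts (Na) and expected heterozygosities (He) are
published.  This module therefore generates per-locus allele-frequency
profiles that exactly reproduce each species' (Na, He) pair, and from
them simulates purebred individuals, first-generation hybrids, and
parent-offspring populations with per-locus genotyping error.

Frequency profiles use a geometric series p_i proportional to r^i with the
ratio r solved by bisection: this hits any feasible (Na, He) pair
deterministically, including near-monomorphic diagnostic loci such as one
allele at frequency ~0.98 with nine rare alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers_io import (MISSING, AlleleFrequencyTable, GenotypeTable, Panel,
                         Pedigree)


def _geometric_he(r: float, na: int) -> float:
    if r == 1.0:
        return 1.0 - 1.0 / na
    w = r ** np.arange(na)
    p = w / w.sum()
    return float(1.0 - np.sum(p ** 2))


def frequencies_matching(na: int, he_target: float,
                         seed: int | None = None,
                         jitter: float = 0.0,
                         tol: float = 1e-6) -> np.ndarray:
    """A frequency vector with exactly ``na`` alleles and He ~= ``he_target``.

    Geometric-series frequencies p_i proportional to r^i, with r found by
    bisection so that ``|1 - sum p^2 - he_target| <= tol``.  Deterministic
    given the inputs.  With ``jitter > 0`` the vector is perturbed by a
    Dirichlet draw (concentration p/jitter) and re-tempered by a bisected
    exponent to restore He to tolerance, giving irregular but
    He-matched profiles.
    """
    if na < 1:
        raise ValueError("na must be >= 1")
    if na == 1:
        if he_target > tol:
            raise ValueError("He > 0 is infeasible with a single allele")
        return np.array([1.0])
    he_max = 1.0 - 1.0 / na
    if not 0.0 < he_target <= he_max + 1e-12:
        raise ValueError(
            f"(Na={na}, He={he_target}) infeasible: need 0 < He <= 1 - 1/Na")
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _geometric_he(mid, na) < he_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16:
            break
    r = 0.5 * (lo + hi)
    w = r ** np.arange(na)
    p = w / w.sum()
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        q = rng.dirichlet(np.maximum(p / jitter, 1e-3))
        q = np.sort(q)[::-1]
        q = np.maximum(q, 1e-300)
        lo_t, hi_t = 0.0, 60.0  # temper q^t to restore He
        logq = np.log(q)
        for _ in range(200):
            t = 0.5 * (lo_t + hi_t)
            v = np.exp(t * logq)
            v /= v.sum()
            if 1.0 - np.sum(v ** 2) < he_target:
                hi_t = t
            else:
                lo_t = t
        p = np.exp(0.5 * (lo_t + hi_t) * logq)
        p /= p.sum()
    if abs(1.0 - np.sum(p ** 2) - he_target) > tol:
        raise ValueError("He solver failed to reach tolerance")
    return p


@dataclass
class SpeciesPairModel:
    """Per-species allele frequency profiles for a two-species system."""

    freqs_a: AlleleFrequencyTable
    freqs_b: AlleleFrequencyTable
    divergence: float | None = None
    diagnostic_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.freqs_a.loci) != set(self.freqs_b.loci):
            raise ValueError("species must share a locus set")
        if self.divergence is not None and not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")


def _locus_labels(panel: Panel | None, locus: str, n_labels: int
                  ) -> np.ndarray:
    """Integer allele labels (bp) spaced by the repeat length."""
    if panel is not None:
        m = panel[locus]
        start, step = m.size_range[0], m.repeat_length
    else:
        start, step = 100, 4
    labels = start + step * np.arange(n_labels)
    if labels[-1] > 999:
        # keep GenePop 3-digit encodable
        labels = start + np.arange(n_labels)
    return labels.astype(np.int32)


def build_species_pair(summary: pd.DataFrame, panel: Panel | None = None,
                       divergence: float | None = None,
                       seed: int | None = None,
                       species: tuple[str, str] = ("P_leopardus",
                                                   "P_maculatus"),
                       jitter: float = 0.0) -> SpeciesPairModel:
    """Species frequency profiles matched to a per-species (Na, He) table.

    ``summary`` is long format with columns locus/species/Na/He (the
    packaged panel fixture works directly).  Both species draw allele
    labels from a shared ladder; species B's frequency ranks run opposite
    to species A's, so each species matches its own published diversity
    while the pair is strongly differentiated -- common alleles in one
    species are rare or absent in the other, the way diagnostic loci
    behave between the two reference species.

    With ``divergence`` set, species B is instead a Balding-Nichols draw
    around species A: Dirichlet with concentration p_A * (1 - c) / c, whose
    expected allele-frequency divergence (Fst against the ancestral
    frequencies) is c.  ``divergence=0`` copies A exactly.
    """
    rng = np.random.default_rng(seed)
    sp_a, sp_b = species
    a_rows = summary[summary["species"] == sp_a].set_index("locus")
    b_rows = summary[summary["species"] == sp_b].set_index("locus")
    loci = list(a_rows.index)
    fa: dict[str, dict[int, float]] = {}
    fb: dict[str, dict[int, float]] = {}
    diagnostic: list[str] = []
    for locus in loci:
        na_a, he_a = int(a_rows.loc[locus, "Na"]), float(a_rows.loc[locus, "He"])
        na_b, he_b = int(b_rows.loc[locus, "Na"]), float(b_rows.loc[locus, "He"])
        n_labels = max(na_a, na_b)
        labels = _locus_labels(panel, locus, n_labels)
        pa = frequencies_matching(na_a, he_a, seed=None if seed is None
                                  else int(rng.integers(2 ** 31)),
                                  jitter=jitter)
        fa[locus] = {int(labels[i]): float(pa[i]) for i in range(na_a)}
        if divergence is not None:
            if divergence == 0.0:
                fb[locus] = dict(fa[locus])
            else:
                conc = pa * (1.0 - divergence) / divergence
                pb = rng.dirichlet(conc)
                pb = np.maximum(pb, 1e-12)
                pb /= pb.sum()
                fb[locus] = {int(labels[i]): float(pb[i])
                             for i in range(na_a)}
        else:
            pb = frequencies_matching(na_b, he_b,
                                      seed=None if seed is None
                                      else int(rng.integers(2 ** 31)),
                                      jitter=jitter)
            # reversed label order: B's common alleles sit where A's rare ones do
            fb[locus] = {int(labels[n_labels - 1 - i]): float(pb[i])
                         for i in range(na_b)}
        if min(he_a, he_b) < 0.1 <= max(he_a, he_b):
            diagnostic.append(locus)
    return SpeciesPairModel(AlleleFrequencyTable(fa),
                            AlleleFrequencyTable(fb),
                            divergence, diagnostic)


# ---------------------------------------------------------------------------
# Individual-level simulation

def simulate_purebreds(freqs: AlleleFrequencyTable, n: int,
                       seed: int | None = None,
                       prefix: str = "ind") -> GenotypeTable:
    """n individuals drawn under HWE: two independent alleles per locus."""
    rng = np.random.default_rng(seed)
    loci = freqs.loci
    calls = np.empty((n, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        labels, probs = freqs.locus_arrays(locus)
        calls[:, j, :] = rng.choice(labels, size=(n, 2), p=probs)
    ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeTable(ids, list(loci), calls)


def simulate_f1(freqs_a: AlleleFrequencyTable, freqs_b: AlleleFrequencyTable,
                n: int, seed: int | None = None, prefix: str = "f1",
                return_origins: bool = False):
    """n first-generation hybrids: one parental-species allele each per locus.

    With ``return_origins`` also returns an int array (n, n_loci, 2) whose
    slot 0 is the species-A-origin allele and slot 1 the species-B-origin
    allele (before within-call sorting), for audit purposes.
    """
    if set(freqs_a.loci) != set(freqs_b.loci):
        raise ValueError("species must share a locus set")
    rng = np.random.default_rng(seed)
    loci = freqs_a.loci
    origins = np.empty((n, len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        la, pa = freqs_a.locus_arrays(locus)
        lb, pb = freqs_b.locus_arrays(locus)
        origins[:, j, 0] = rng.choice(la, size=n, p=pa)
        origins[:, j, 1] = rng.choice(lb, size=n, p=pb)
    ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
    table = GenotypeTable(ids, list(loci), origins.copy())
    if return_origins:
        return table, origins
    return table


def apply_genotyping_error(table: GenotypeTable, rate: float,
                           freqs: AlleleFrequencyTable,
                           seed: int | None = None) -> GenotypeTable:
    """Per-(individual, locus) mistyping at the given rate.

    With probability ``rate`` one of the two alleles (chosen uniformly) is
    replaced by a fresh draw from the population frequencies; the
    replacement may coincide with the original, so the realised mismatch
    rate against the true genotype is below the nominal rate.  Missing
    calls are untouched.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    if rate > 0:
        miss = table.missing_mask()
        for j, locus in enumerate(table.loci):
            labels, probs = freqs.locus_arrays(locus)
            hit = (rng.random(table.n_individuals) < rate) & ~miss[:, j]
            n_hit = int(hit.sum())
            if n_hit == 0:
                continue
            slot = rng.integers(0, 2, size=n_hit)
            repl = rng.choice(labels, size=n_hit, p=probs)
            idx = np.flatnonzero(hit)
            calls[idx, j, slot] = repl
    return GenotypeTable(list(table.individuals), list(table.loci), calls,
                         None if table.populations is None
                         else list(table.populations))


# ---------------------------------------------------------------------------
# Parentage population simulation

@dataclass
class ParentageDesign:
    """Study design for the parentage accuracy simulation.

    Defaults mirror the validation study: 500 candidate adults at a 2:1
    female:male ratio, 1000 offspring of which 20% have sampled parents,
    and 1% per-locus genotyping error.
    """

    n_adults: int = 500
    sex_ratio: tuple[int, int] = (2, 1)  # females : males
    n_offspring: int = 1000
    prop_known: float = 0.20
    error_rate: float = 0.01
    error_scope: str = "both"  # "offspring" | "both" | "none"
    sampling_mode: str = "paired"  # "paired" | "independent"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_adults < 3:
            raise ValueError("need at least 3 adults for a valid pair")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be positive")
        if not 0 <= self.prop_known <= 1:
            raise ValueError("prop_known must lie in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.error_scope not in ("offspring", "both", "none"):
            raise ValueError(f"unknown error_scope {self.error_scope!r}")
        if self.sampling_mode not in ("paired", "independent"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")


def _mendelian_offspring(mother_calls: np.ndarray, father_calls: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One allele per parent per locus; shapes (n, L, 2) -> (n, L, 2)."""
    n, L, _ = mother_calls.shape
    mi = rng.integers(0, 2, size=(n, L))
    fi = rng.integers(0, 2, size=(n, L))
    out = np.empty((n, L, 2), dtype=np.int32)
    out[:, :, 0] = np.take_along_axis(mother_calls, mi[:, :, None],
                                      axis=2)[:, :, 0]
    out[:, :, 1] = np.take_along_axis(father_calls, fi[:, :, None],
                                      axis=2)[:, :, 0]
    return out


def simulate_parentage_population(freqs: AlleleFrequencyTable,
                                  design: ParentageDesign,
                                  ) -> tuple[GenotypeTable, GenotypeTable,
                                             Pedigree]:
    """Adults, offspring, and the truth pedigree for one replicate.

    In the default ``"paired"`` sampling mode, ``prop_known`` of the
    offspring have BOTH true parents in the sampled candidate pool and the
    rest have neither (their parents are unsampled adults drawn from the
    same frequencies).  ``"independent"`` mode instead samples candidates
    from a larger adult universe so that each true parent is in the pool
    independently with probability ``prop_known``, which also produces
    single-parent-sampled offspring.  Mating pairs are drawn uniformly
    with replacement (polygamy allowed); the sex ratio shapes the pool
    composition only.
    """
    rng = np.random.default_rng(design.seed)
    loci = freqs.loci
    L = len(loci)
    fr, mr = design.sex_ratio
    n_f = int(round(design.n_adults * fr / (fr + mr)))
    n_m = design.n_adults - n_f

    if design.sampling_mode == "paired":
        females = simulate_purebreds(freqs, n_f,
                                     int(rng.integers(2 ** 31)), prefix="F")
        males = simulate_purebreds(freqs, n_m,
                                   int(rng.integers(2 ** 31)), prefix="M")
        sampled = set(females.individuals) | set(males.individuals)
        n_known = int(round(design.prop_known * design.n_offspring))
        n_unknown = design.n_offspring - n_known
        mom_idx = rng.integers(0, n_f, size=n_known)
        dad_idx = rng.integers(0, n_m, size=n_known)
        kid_calls = _mendelian_offspring(females.calls[mom_idx],
                                         males.calls[dad_idx], rng)
        moms = [females.individuals[i] for i in mom_idx]
        dads = [males.individuals[i] for i in dad_idx]
        if n_unknown:
            uf = simulate_purebreds(freqs, n_unknown,
                                    int(rng.integers(2 ** 31)), prefix="UF")
            um = simulate_purebreds(freqs, n_unknown,
                                    int(rng.integers(2 ** 31)), prefix="UM")
            unk_calls = _mendelian_offspring(uf.calls, um.calls, rng)
            kid_calls = np.concatenate([kid_calls, unk_calls], axis=0)
            moms += list(uf.individuals)
            dads += list(um.individuals)
        adults = GenotypeTable(females.individuals + males.individuals,
                               list(loci),
                               np.concatenate([females.calls, males.calls]))
    else:
        n_uf = max(n_f, int(round(n_f / max(design.prop_known, 1e-9))))
        n_um = max(n_m, int(round(n_m / max(design.prop_known, 1e-9))))
        females = simulate_purebreds(freqs, n_uf,
                                     int(rng.integers(2 ** 31)), prefix="F")
        males = simulate_purebreds(freqs, n_um,
                                   int(rng.integers(2 ** 31)), prefix="M")
        f_keep = rng.choice(n_uf, size=n_f, replace=False)
        m_keep = rng.choice(n_um, size=n_m, replace=False)
        sampled = ({females.individuals[i] for i in f_keep}
                   | {males.individuals[i] for i in m_keep})
        mom_idx = rng.integers(0, n_uf, size=design.n_offspring)
        dad_idx = rng.integers(0, n_um, size=design.n_offspring)
        kid_calls = _mendelian_offspring(females.calls[mom_idx],
                                         males.calls[dad_idx], rng)
        moms = [females.individuals[i] for i in mom_idx]
        dads = [males.individuals[i] for i in dad_idx]
        keep_ids = ([females.individuals[i] for i in sorted(f_keep)]
                    + [males.individuals[i] for i in sorted(m_keep)])
        pool = np.concatenate([females.calls[sorted(f_keep)],
                               males.calls[sorted(m_keep)]])
        adults = GenotypeTable(keep_ids, list(loci), pool)

    kid_ids = [f"O{i + 1:05d}" for i in range(design.n_offspring)]
    offspring = GenotypeTable(kid_ids, list(loci), kid_calls)
    pedigree = Pedigree({k: (m, d) for k, m, d in zip(kid_ids, moms, dads)},
                        sampled)

    if design.error_rate > 0 and design.error_scope != "none":
        offspring = apply_genotyping_error(
            offspring, design.error_rate, freqs,
            seed=int(rng.integers(2 ** 31)))
        if design.error_scope == "both":
            adults = apply_genotyping_error(
                adults, design.error_rate, freqs,
                seed=int(rng.integers(2 ** 31)))
    return adults, offspring, pedigree


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    rows = [{"offspring": k, "mother": m, "father": f,
             "mother_sampled": m in pedigree.sampled_adults,
             "father_sampled": f in pedigree.sampled_adults}
            for k, (m, f) in pedigree.parents.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path)
    parents = {r.offspring: (r.mother, r.father) for r in df.itertuples()}
    sampled = set(df.loc[df.mother_sampled, "mother"]) \
        | set(df.loc[df.father_sampled, "father"])
    return Pedigree(parents, sampled)


def realized_fst(freqs_a: AlleleFrequencyTable,
                 freqs_b: AlleleFrequencyTable) -> pd.Series:
    """Per-locus allele-frequency divergence of B from A.

    F = sum_a (pA_a - pB_a)^2 / sum_a pA_a (1 - pA_a), which has
    expectation c when B is a Balding-Nichols draw with drift c around the
    ancestral frequencies A.
    """
    out = {}
    for locus in freqs_a.loci:
        fa, fb = freqs_a.freqs[locus], freqs_b.freqs[locus]
        alleles = sorted(set(fa) | set(fb))
        pa = np.array([fa.get(a, 0.0) for a in alleles])
        pb = np.array([fb.get(a, 0.0) for a in alleles])
        out[locus] = float(np.sum((pa - pb) ** 2) / np.sum(pa * (1 - pa)))
    return pd.Series(out, name="fst")
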