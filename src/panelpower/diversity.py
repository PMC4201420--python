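"""Per-locus diversity statistics and panel power analysis.

Covers the classical panel-characterisation quantities for codominant
markers: allele counts, observed/expected heterozygosity and the fixation
index; a Monte-Carlo exact test for Hardy-Weinberg equilibrium conditional
on allele counts; per-locus exclusion probability for parentage (and its
known-parent and parent-pair variants); and the cumulative exclusion
probability of a multiplex kit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .markers_io import (AlleleFrequencyTable, GenotypeTable, Panel,
                         estimate_frequencies)

_LOG2 = math.log(2.0)


class LocusStats(NamedTuple):
    na: int
    ho: float
    he: float
    fis: float


@dataclass
class LocusSummary:
    """One row of a panel summary table."""

    locus: str
    na: int
    ho: float
    he: float
    fis: float
    hwe_p: float
    hwe_significant: bool
    pe: float
    cum_pe: float


def fixation_index(ho: float, he: float) -> float:
    """Fis = (He - Ho) / He, defined as 0 for a monomorphic locus."""
    if he == 0:
        return 0.0
    return (he - ho) / he


def locus_summary(table: GenotypeTable, locus: str,
                  corrected: bool = False) -> LocusStats:
    """Na, Ho, He and Fis at one locus.

    ``corrected=True`` applies the small-sample factor 2n/(2n-1) to He.
    """
    j = table.locus_index(locus)
    ok = ~table.missing_mask()[:, j]
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    calls = table.calls[ok, j, :]
    na = int(np.unique(calls).size)
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    _, counts = np.unique(calls.ravel(), return_counts=True)
    p = counts / (2 * n)
    he = float(1.0 - np.sum(p ** 2))
    if corrected and n > 0:
        he *= 2 * n / (2 * n - 1)
    return LocusStats(na, ho, he, fixation_index(ho, he))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Guo & Thompson Monte-Carlo chain)

def _hwe_chain_py(genes, pairs, k, demem, steps, s_obs, seed,
                  batch_p, batch_d, nbatch):
    """Random-transposition walk over arrangements of the 2n gene copies.

    A uniformly random arrangement of the gene copies into n ordered pairs
    induces exactly the conditional distribution of genotype tables given
    the allele counts under random union of gametes, so unweighted
    transposition moves need no acceptance step.  The running statistic is
    log P(table | allele counts) up to an additive constant:
    s = H*log2 - sum log(n_ij!) with H the heterozygote count.
    """
    np.random.seed(seed)
    n2 = genes.shape[0]
    counts = np.zeros((k, k), dtype=np.int64)
    h = 0
    for t in range(0, n2, 2):
        a, b = genes[t], genes[t + 1]
        i, j = (a, b) if a <= b else (b, a)
        counts[i, j] += 1
        if i != j:
            h += 1
    s = s_obs
    batch_len = steps // nbatch
    for t in range(demem + steps):
        u = np.random.randint(0, n2)
        v = np.random.randint(0, n2)
        a, b = genes[u], genes[v]
        if (u >> 1) != (v >> 1) and a != b:
            pu, pv = (u >> 1) << 1, (v >> 1) << 1
            for w in (pu, pv):
                x, y = genes[w], genes[w + 1]
                i, j = (x, y) if x <= y else (y, x)
                s += math.log(counts[i, j])
                counts[i, j] -= 1
                if i != j:
                    s -= _LOG2
                    h -= 1
            genes[u], genes[v] = b, a
            for w in (pu, pv):
                x, y = genes[w], genes[w + 1]
                i, j = (x, y) if x <= y else (y, x)
                counts[i, j] += 1
                s -= math.log(counts[i, j])
                if i != j:
                    s += _LOG2
                    h += 1
        if t >= demem:
            b_idx = (t - demem) // batch_len
            if b_idx >= nbatch:
                b_idx = nbatch - 1
            if s <= s_obs + 1e-12:
                batch_p[b_idx] += 1
            if h <= pairs:
                batch_d[b_idx] += 1
    return batch_p, batch_d


try:  # numba is an optional speedup; the pure-python walk is the reference
    from numba import njit as _njit

    _hwe_chain = _njit(cache=False)(_hwe_chain_py)
except ImportError:  # pragma: no cover
    _hwe_chain = _hwe_chain_py


def _canonical_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("genotype counts must be a square matrix")
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    lower = np.tril(counts) + np.triu(counts, 1).T
    return lower


def table_log_prob(counts: np.ndarray) -> float:
    """log P(genotype table | allele counts) up to an additive constant."""
    lower = _canonical_counts(counts)
    h = int(lower.sum() - np.trace(lower))
    return h * _LOG2 - float(
        sum(math.lgamma(c + 1) for c in lower[np.tril_indices_from(lower)]))


def hwe_exact_test(counts: np.ndarray, chain_length: int = 100_000,
                   dememorization: int = 10_000, seed: int | None = None,
                   mode: str = "probability",
                   return_se: bool = False):
    """Monte-Carlo exact test of Hardy-Weinberg genotype proportions.

    ``counts`` is a square genotype-count matrix (lower triangle, or a
    symmetric/ordered matrix which is folded).  The chain is a
    random-transposition walk over arrangements of the gene copies, whose
    stationary law is the exact conditional distribution given allele
    counts.  ``mode="probability"`` estimates the two-sided probability
    test (mass of tables no more probable than the observed one);
    ``mode="deficit"`` the one-sided heterozygote-deficiency test
    (tables with no more heterozygotes than observed).

    Returns the p-value, or ``(p, se)`` with a batch-means standard error
    when ``return_se`` is set.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if mode not in ("probability", "deficit"):
        raise ValueError(f"unknown mode {mode!r}")
    lower = _canonical_counts(counts)
    k = lower.shape[0]
    n = int(lower.sum())
    if n == 0:
        raise ValueError("empty genotype table")
    genes = np.empty(2 * n, dtype=np.int64)
    pos = 0
    for i in range(k):
        for j in range(i + 1):
            for _ in range(lower[i, j]):
                genes[pos], genes[pos + 1] = j, i
                pos += 2
    h_obs = int(lower.sum() - np.trace(lower))
    s_obs = h_obs * _LOG2 - float(
        sum(math.lgamma(c + 1) for c in lower[np.tril_indices_from(lower)]))
    nbatch = min(20, chain_length)
    batch_p = np.zeros(nbatch, dtype=np.int64)
    batch_d = np.zeros(nbatch, dtype=np.int64)
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
    _hwe_chain(genes, h_obs, k, dememorization, chain_length,
               s_obs, seed, batch_p, batch_d, nbatch)
    batches = batch_p if mode == "probability" else batch_d
    per_batch = batches / (chain_length / nbatch)
    p = float(batches.sum() / chain_length)
    if return_se:
        se = float(per_batch.std(ddof=1) / math.sqrt(nbatch)) if nbatch > 1 else 0.0
        return p, se
    return p


def genotype_counts(table: GenotypeTable, locus: str) -> tuple[np.ndarray,
                                                               np.ndarray]:
    """(allele labels, lower-triangular genotype count matrix) at a locus."""
    j = table.locus_index(locus)
    ok = ~table.missing_mask()[:, j]
    calls = table.calls[ok, j, :]
    labels = np.unique(calls)
    idx = {int(a): i for i, a in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in calls:
        i1, i2 = idx[int(a)], idx[int(b)]
        lo, hi = min(i1, i2), max(i1, i2)
        counts[hi, lo] += 1
    return labels, counts


def bonferroni_flags(p_values: Sequence[float],
                     alpha: float = 0.05) -> np.ndarray:
    """Strict Bonferroni: flag p < alpha/m over the m tests supplied."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return p < alpha / p.size


# ---------------------------------------------------------------------------
# Exclusion probabilities

def _check_freq_vector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    if (p <= 0).any():
        raise ValueError("frequencies must be positive")
    return p


def exclusion_probability(freqs) -> float:
    """Single-parent exclusion probability, other parent unknown.

    The chance that a random unrelated individual shares no allele with a
    random offspring of the population (HWE), i.e. is genetically excluded
    as its parent.  Power-sum form with a_k = sum_i p_i^k:

        PE = 1 - 4 a2 + 2 a2^2 + 4 a3 - 3 a4
    """
    p = _check_freq_vector(freqs)
    a2 = float(np.sum(p ** 2))
    a3 = float(np.sum(p ** 3))
    a4 = float(np.sum(p ** 4))
    return 1.0 - 4.0 * a2 + 2.0 * a2 ** 2 + 4.0 * a3 - 3.0 * a4


def exclusion_probability_one_parent_known(freqs) -> float:
    """Exclusion probability for the second parent when one is known.

    Exact enumeration: the known mother is two iid draws from the
    frequencies, the offspring receives one maternal allele (uniform) and
    one paternal allele from the population; a random candidate is excluded
    when it carries none of the alleles it could have transmitted.
    """
    p = _check_freq_vector(freqs)
    k = p.size
    total = 0.0
    for a in range(k):
        for b in range(k):
            w_mother = p[a] * p[b]
            for x in (a, b):  # maternal allele actually transmitted
                for y in range(k):  # paternal allele
                    w = w_mother * 0.5 * p[y]
                    # alleles the candidate father could have contributed:
                    # t in {x, y} with the partner allele present in mother
                    t_mass = 0.0
                    seen = set()
                    for t, partner in ((y, x), (x, y)):
                        if partner in (a, b) and t not in seen:
                            t_mass += p[t]
                            seen.add(t)
                    total += w * (1.0 - t_mass) ** 2
    return total


def exclusion_probability_parent_pair(freqs) -> float:
    """Probability a random unrelated pair is excluded as the parent pair."""
    p = _check_freq_vector(freqs)
    carry = 1.0 - (1.0 - p) ** 2  # P(random individual carries allele i)
    total = 0.0
    k = p.size
    for g in range(k):
        # homozygous offspring (g,g): both candidates must carry g
        total += p[g] ** 2 * (1.0 - carry[g] ** 2)
        for h in range(g + 1, k):
            w = 2 * p[g] * p[h]
            both = 1.0 - (1 - p[g]) ** 2 - (1 - p[h]) ** 2 \
                + (1 - p[g] - p[h]) ** 2
            compat = 2 * carry[g] * carry[h] - both ** 2
            total += w * (1.0 - compat)
    return total


def cumulative_exclusion(pe_values) -> np.ndarray:
    """CumPE_j = 1 - prod_{l<=j} (1 - PE_l) along a kit's locus order."""
    pe = np.asarray(pe_values, dtype=float)
    if ((pe < 0) | (pe >= 1)).any():
        raise ValueError("PE values must lie in [0, 1)")
    return 1.0 - np.cumprod(1.0 - pe)


# ---------------------------------------------------------------------------
# Panel-level summaries

def column_stats(df: pd.DataFrame,
                 columns: Sequence[str] = ("na", "ho", "he", "fis", "pe"),
                 ) -> pd.DataFrame:
    """Column means and standard errors (SE = sd / sqrt(n_loci))."""
    rows = {}
    for c in columns:
        x = df[c].astype(float)
        n = x.notna().sum()
        rows[c] = {"mean": x.mean(),
                   "se": x.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0}
    return pd.DataFrame(rows).T


def panel_summary(table: GenotypeTable, panel: Panel | None = None,
                  chain_length: int = 100_000, dememorization: int = 10_000,
                  alpha: float = 0.05, seed: int | None = None,
                  hwe_mode: str = "probability") -> pd.DataFrame:
    """Per-locus Na/Ho/He/Fis, HWE exact p, PE and within-kit CumPE.

    The Bonferroni family size is the number of loci tested here; when the
    same loci are tested in several populations, collect the p-values and
    re-flag with :func:`bonferroni_flags`.
    """
    loci = panel.locus_names if panel is not None else table.loci
    if panel is not None:
        missing = set(loci) - set(table.loci)
        if missing:
            raise ValueError(f"table lacks panel loci: {sorted(missing)}")
    freqs = estimate_frequencies(table.subset_loci(loci))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(len(loci))]
    rows = []
    for locus, s in zip(loci, seeds):
        st = locus_summary(table, locus)
        _, counts = genotype_counts(table, locus)
        pval = hwe_exact_test(counts, chain_length, dememorization,
                              seed=s, mode=hwe_mode)
        _, pvec = freqs.locus_arrays(locus)
        pe = exclusion_probability(pvec)
        kit = panel[locus].kit if panel is not None else "all"
        rows.append({"locus": locus, "kit": kit, "na": st.na, "ho": st.ho,
                     "he": st.he, "fis": st.fis, "hwe_p": pval, "pe": pe})
    df = pd.DataFrame(rows)
    df["hwe_significant"] = bonferroni_flags(df["hwe_p"].to_numpy(), alpha)
    df["cum_pe"] = np.concatenate([
        cumulative_exclusion(g["pe"].to_numpy())
        for _, g in df.groupby("kit", sort=False)])
    return df


def fixture_summary_checks(summary: pd.DataFrame) -> pd.DataFrame:
    """Recompute Fis and CumPE from the printed per-locus columns.

    Returns the fixture with ``fis_check`` ((He-Ho)/He) and ``cum_pe_check``
    (within-kit accumulation of the printed PE) columns appended, one pair
    of recomputed values per (species, locus).
    """
    out = summary.copy()
    out["fis_check"] = [
        fixation_index(ho, he) for ho, he in zip(out["Ho"], out["He"])]
    parts = []
    for (_, _), g in out.groupby(["species", "kit"], sort=False):
        parts.append(pd.Series(cumulative_exclusion(g["PE"].to_numpy()),
                               index=g.index))
    out["cum_pe_check"] = pd.concat(parts)
    return out
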