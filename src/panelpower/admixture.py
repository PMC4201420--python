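"""Bayesian admixture clustering for species discrimination (K = 2).

A Gibbs sampler over the no-admixture-LD, uncorrelated-frequencies
admixture model: each allele copy carries a latent cluster-of-origin z,
each cluster has Dirichlet(lambda=1) allele frequencies per locus, and
each individual a Dirichlet(alpha) admixture proportion q.  The posterior
mean of q is the assignment probability used for three-class
purebred/hybrid classification with data-driven thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .markers_io import (AlleleFrequencyTable, GenotypeTable, Panel,
                         concat_tables)
from .synthpop import SpeciesPairModel, simulate_f1, simulate_purebreds

CLASS_A = "A"
CLASS_B = "B"
CLASS_HYBRID = "hybrid"


@dataclass
class AdmixtureFit:
    """Posterior-mean admixture proportions from one chain."""

    individuals: list[str]
    q: np.ndarray  # (n, K) posterior means, rows sum to 1
    K: int
    alpha: float
    burnin: int
    iters: int
    seed: int | None
    cluster_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")

    @property
    def q_a(self) -> np.ndarray:
        """q on the species-A axis (column 0 after label alignment)."""
        return self.q[:, 0]


def _encode(table: GenotypeTable,
            cluster_freqs: Sequence[AlleleFrequencyTable] | None):
    """Map allele labels to dense per-locus indices."""
    n, L = table.n_individuals, table.n_loci
    universes: list[np.ndarray] = []
    for j, locus in enumerate(table.loci):
        obs = np.unique(table.calls[:, j, :])
        obs = obs[obs >= 0]
        if cluster_freqs is not None:
            lab = set(int(a) for a in obs)
            for f in cluster_freqs:
                lab |= set(f.freqs[locus])
            missing = set(int(a) for a in obs) - set(
                a for f in cluster_freqs for a in f.freqs[locus])
            if missing:
                raise ValueError(
                    f"alleles {sorted(missing)} at {locus} absent from the "
                    "supplied cluster frequencies")
            universes.append(np.array(sorted(lab), dtype=np.int64))
        else:
            universes.append(obs.astype(np.int64))
    maxk = max(len(u) for u in universes)
    A = np.zeros((n, L, 2), dtype=np.int64)
    for j, u in enumerate(universes):
        lut = {int(a): i for i, a in enumerate(u)}
        col = table.calls[:, j, :]
        for slot in (0, 1):
            A[:, j, slot] = [lut.get(int(v), 0) for v in col[:, slot]]
    obs_mask = ~table.missing_mask()
    return A, obs_mask, universes, maxk


def fit_admixture(table: GenotypeTable, K: int = 2, burnin: int = 5000,
                  iters: int = 5000, alpha: float = 1.0,
                  alpha_mode: str = "infer", seed: int | None = None,
                  cluster_freqs: Sequence[AlleleFrequencyTable] | None = None,
                  freq_lambda: float = 1.0) -> AdmixtureFit:
    """Gibbs sampler for the admixture model; returns posterior-mean q.

    ``alpha_mode="fixed"`` keeps the admixture concentration at ``alpha``;
    ``"infer"`` updates it by a Metropolis step (uniform prior on (0, 10],
    normal proposal sd 0.05).  Supplying ``cluster_freqs`` (one frequency
    table per cluster) clamps the cluster allele frequencies instead of
    sampling them, which reduces the model to independent per-individual
    q estimation given known frequencies.  Missing calls are skipped.
    """
    if burnin < 0 or iters < 1:
        raise ValueError("need burnin >= 0 and iters >= 1")
    if table.n_individuals < 1:
        raise ValueError("empty table")
    if alpha_mode not in ("fixed", "infer"):
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    rng = np.random.default_rng(seed)
    A, obs, universes, maxk = _encode(table, cluster_freqs)
    n, L, _ = A.shape
    obs2 = np.repeat(obs[:, :, None], 2, axis=2)
    valid = np.zeros((L, maxk))
    for j, u in enumerate(universes):
        valid[j, :len(u)] = 1.0

    if cluster_freqs is not None:
        if len(cluster_freqs) != K:
            raise ValueError("need one frequency table per cluster")
        p = np.full((K, L, maxk), 1e-300)
        for k, f in enumerate(cluster_freqs):
            for j, locus in enumerate(table.loci):
                lut = {int(a): i for i, a in enumerate(universes[j])}
                for a, pr in f.freqs[locus].items():
                    p[k, j, lut[int(a)]] = pr
        fixed_p = True
    else:
        p = rng.dirichlet(np.ones(maxk), size=(K, L)) * valid[None]
        p /= p.sum(axis=2, keepdims=True)
        fixed_p = False

    q = np.full((n, K), 1.0 / K)
    lgrid = np.arange(L)[None, :, None]
    q_sum = np.zeros((n, K))
    cur_alpha = float(alpha)
    n_kept = 0
    for it in range(burnin + iters):
        # z: cluster of origin per allele copy
        pg = p[:, lgrid, A]  # (K, n, L, 2)
        W = np.moveaxis(pg, 0, -1) * q[:, None, None, :]
        cum = np.cumsum(W, axis=-1)
        tot = cum[..., -1:]
        u = rng.random((n, L, 2, 1))
        z = (u * tot > cum).sum(axis=-1)
        # q per individual
        m = np.empty((n, K))
        zin = np.where(obs2, z, -1)
        for k in range(K):
            m[:, k] = (zin == k).sum(axis=(1, 2))
        q = rng.gamma(cur_alpha + m)
        q /= q.sum(axis=1, keepdims=True)
        # p per cluster x locus
        if not fixed_p:
            codes = ((z * L + lgrid) * maxk + A)[obs2]
            counts = np.bincount(codes.ravel(), minlength=K * L * maxk
                                 ).reshape(K, L, maxk)
            p = rng.gamma(freq_lambda + counts) * valid[None]
            p = np.maximum(p, 1e-300) * valid[None]
            p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)
            p = np.maximum(p, 1e-300)
        if alpha_mode == "infer":
            prop = cur_alpha + rng.normal(0.0, 0.05)
            if 0.0 < prop <= 10.0:
                logq = np.log(np.maximum(q, 1e-300)).sum()

                def lp(a):
                    return n * (gammaln(K * a) - K * gammaln(a)) \
                        + (a - 1.0) * logq
                if np.log(rng.random()) < lp(prop) - lp(cur_alpha):
                    cur_alpha = prop
        if it >= burnin:
            q_sum += q
            n_kept += 1
    return AdmixtureFit(list(table.individuals), q_sum / n_kept, K,
                        cur_alpha, burnin, iters, seed)


def align_labels(fit: AdmixtureFit,
                 references: Mapping[str, Sequence[str]],
                 species_a: str | None = None) -> AdmixtureFit:
    """Resolve label switching against reference individuals.

    ``references`` maps each species name to known purebred individual
    ids present in the fit; both species must be represented.  The cluster
    with the higher mean q among species-A references becomes column 0, so
    ``fit.q_a`` reads as the probability of species-A membership.
    Idempotent.
    """
    if len(references) < 2:
        raise ValueError("references from both species are required")
    species = list(references)
    if species_a is None:
        species_a = species[0]
    pos = {ind: i for i, ind in enumerate(fit.individuals)}
    for sp, ids in references.items():
        missing = [i for i in ids if i not in pos]
        if missing or not list(ids):
            raise ValueError(f"reference ids missing from fit for {sp!r}")
    idx_a = [pos[i] for i in references[species_a]]
    mean_a = fit.q[idx_a].mean(axis=0)
    order = np.argsort(-mean_a, kind="stable")
    others = [s for s in species if s != species_a]
    labels = {0: species_a}
    for r, s in enumerate(others[:fit.K - 1], start=1):
        labels[r] = s
    return AdmixtureFit(list(fit.individuals), fit.q[:, order], fit.K,
                        fit.alpha, fit.burnin, fit.iters, fit.seed, labels)


# ---------------------------------------------------------------------------
# Threshold optimisation and classification

@dataclass(frozen=True)
class ClassThresholds:
    """Cutpoints on the species-A assignment axis.

    q <= t_low reads species B, q > t_high species A, hybrid between --
    the boundary conventions follow the assignment rule of the validation
    study (B inclusive at t_low, A strict above t_high).
    """

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.t_low < self.t_high < 1.0:
            raise ValueError("need 0 < t_low < t_high < 1")


def classify_individuals(q_values, thresholds: ClassThresholds) -> np.ndarray:
    q = np.asarray(q_values, dtype=float)
    out = np.full(q.shape, CLASS_HYBRID, dtype=object)
    out[q <= thresholds.t_low] = CLASS_B
    out[q > thresholds.t_high] = CLASS_A
    return out


def optimize_thresholds(q_values, true_classes, grid_step: float = 0.005,
                        ) -> tuple[ClassThresholds, pd.DataFrame]:
    """Grid search for the threshold pair minimising misclassifications.

    Ties are broken toward the widest hybrid interval, then the lowest
    t_low.  Returns the thresholds and a per-class error table (n,
    n_incorrect, pct_incorrect).
    """
    q = np.asarray(q_values, dtype=float)
    cls = np.asarray(true_classes, dtype=object)
    for c in (CLASS_A, CLASS_HYBRID, CLASS_B):
        if not (cls == c).any():
            raise ValueError(f"class {c!r} absent from true_classes")
    grid = np.arange(grid_step, 1.0, grid_step)
    grid = grid[(grid > 0) & (grid < 1)]
    qa, qh, qb = q[cls == CLASS_A], q[cls == CLASS_HYBRID], q[cls == CLASS_B]
    # errors split additively: t_low governs B and the hybrid lower edge,
    # t_high governs A and the hybrid upper edge
    low_cost = np.array([(qb > t).sum() + (qh <= t).sum() for t in grid])
    high_cost = np.array([(qa <= t).sum() + (qh > t).sum() for t in grid])
    total = low_cost[:, None] + high_cost[None, :]
    iu = np.triu_indices(len(grid), k=1)
    vals = total[iu]
    best = vals.min()
    cand = np.flatnonzero(vals == best)
    widths = grid[iu[1][cand]] - grid[iu[0][cand]]
    widest = cand[widths == widths.max()]
    pick = widest[np.argmin(grid[iu[0][widest]])]
    thr = ClassThresholds(float(grid[iu[0][pick]]), float(grid[iu[1][pick]]))
    pred = classify_individuals(q, thr)
    rows = []
    for c in (CLASS_A, CLASS_HYBRID, CLASS_B):
        sel = cls == c
        n = int(sel.sum())
        bad = int((pred[sel] != c).sum())
        rows.append({"class": c, "n": n, "n_incorrect": bad,
                     "pct_incorrect": 100.0 * bad / n})
    return thr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end discrimination report

def discrimination_report(model: SpeciesPairModel, panel: Panel,
                          kit_sets: Sequence[Sequence[str]] = (
                              ("kit-1",), ("kit-2",), ("kit-3",),
                              ("kit-1", "kit-2"), ("kit-2", "kit-3"),
                              ("kit-1", "kit-2", "kit-3")),
                          n_per_class: int = 500, burnin: int = 5000,
                          iters: int = 5000, seed: int | None = None,
                          grid_step: float = 0.005) -> pd.DataFrame:
    """Percent incorrect assignments per class for each kit combination.

    Simulates purebreds of both species and F1 hybrids once over the full
    panel, then for every kit combination restricts to that kit's loci,
    fits the admixture model, optimises thresholds against the known
    classes, and tabulates percent incorrect per class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in ss.spawn(3 + len(kit_sets))]
    pure_a = simulate_purebreds(model.freqs_a, n_per_class, seeds[0], "A")
    pure_b = simulate_purebreds(model.freqs_b, n_per_class, seeds[1], "B")
    hybrids = simulate_f1(model.freqs_a, model.freqs_b, n_per_class,
                          seeds[2], "H")
    loci_order = panel.locus_names
    full = concat_tables(
        [t.subset_loci([l for l in loci_order if l in t.loci])
         for t in (pure_a, pure_b, hybrids)],
        populations=[CLASS_A, CLASS_B, CLASS_HYBRID])
    truth = np.asarray(full.populations, dtype=object)
    refs = {CLASS_A: pure_a.individuals, CLASS_B: pure_b.individuals}
    rows = []
    for kit_seed, kits in zip(seeds[3:], kit_sets):
        loci = panel.loci_for_kits(kits)
        sub = full.subset_loci(loci)
        fit = fit_admixture(sub, K=2, burnin=burnin, iters=iters,
                            seed=kit_seed)
        fit = align_labels(fit, refs, species_a=CLASS_A)
        thr, errs = optimize_thresholds(fit.q_a, truth, grid_step)
        row = {"kits": "+".join(kits), "n_loci": len(loci),
               "t_low": thr.t_low, "t_high": thr.t_high}
        for cls_name, pct in zip(errs["class"], errs["pct_incorrect"]):
            row[f"pct_incorrect_{cls_name}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
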