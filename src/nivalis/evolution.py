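"""Realized genetic change: Robertson-Price differentials, breeding-value
trends, a gene-dropping drift null, and rate conversions.

The secondary theorem of selection states that the per-generation change
in the mean breeding value of a trait equals its additive genetic
covariance with relative fitness, ``sigma_A(z, omega)``.  Posterior
samples of that covariance from a multivariate animal model therefore
estimate the realized rate of adaptive genetic change.  An independent
estimate regresses cohort-mean breeding values on cohort year *within
each posterior sample*, which propagates both the non-independence of
predicted breeding values and their sampling variance; computing the
trend on posterior-mean (BLUP-like) values alone would understate the
uncertainty.

Whether an observed trend exceeds what random Mendelian sampling alone
can produce is judged by gene dropping: neutral breeding values are
simulated down the observed pedigree (founders ``N(0, V_A)``, offspring
mid-parent plus Mendelian noise) and the cohort-mean slope of each
replicate forms the drift null.  Replicates are paired with the
posterior ``V_A`` draws that generated them, so posterior uncertainty in
the amount of genetic variance propagates into the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, mendelian_sampling_variance, inbreeding_coefficients
from .animal import VarCompPosterior
from .stats import posterior_mode, hpd_interval, pmcmc

__all__ = [
    "price_genetic_change",
    "GeneticTrend",
    "blup_trend",
    "DriftNull",
    "gene_drop_drift",
    "drop_breeding_values",
    "to_darwins",
]


def price_genetic_change(
    post: VarCompPosterior,
    trait: str = "mass",
    T: float = 1.0,
    fitness_measure: str = "omega",
) -> dict:
    """Posterior of the genetic differential sigma_A(trait, omega).

    Returns per-generation and per-year (divided by the generation time
    ``T``) sample arrays with mode, HPD interval and tail probability.
    """
    if T <= 0:
        raise ValueError("generation time T must be positive")
    t = post.trait_index(trait)
    w = post.trait_index(fitness_measure)
    per_gen = post.samples["G"][:, t, w].copy()
    per_year = per_gen / T
    lo, hi = hpd_interval(per_year)
    return {
        "per_generation": per_gen,
        "per_year": per_year,
        "mode_per_year": posterior_mode(per_year),
        "hpd_per_year": (lo, hi),
        "p_mcmc": pmcmc(per_year),
        "T": T,
    }


def _cohort_design(ped: Pedigree):
    cohorts = np.unique(ped.cohort)
    masks = [ped.cohort == c for c in cohorts]
    return cohorts, masks


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc @ y) / (xc @ xc))


@dataclass
class GeneticTrend:
    """Posterior trend of cohort-mean breeding values."""

    cohorts: np.ndarray
    cohort_means: np.ndarray  # (S, n_cohorts)
    slopes: np.ndarray  # (S,)

    @property
    def mode(self) -> float:
        return posterior_mode(self.slopes)

    @property
    def hpd(self) -> tuple:
        return hpd_interval(self.slopes)

    @property
    def p_mcmc(self) -> float:
        return pmcmc(self.slopes)

    def cohort_summary(self) -> pd.DataFrame:
        rows = []
        for j, c in enumerate(self.cohorts):
            lo, hi = hpd_interval(self.cohort_means[:, j])
            rows.append(
                {
                    "cohort": int(c),
                    "mean_bv": float(self.cohort_means[:, j].mean()),
                    "hpd_low": lo,
                    "hpd_high": hi,
                }
            )
        return pd.DataFrame(rows)


def blup_trend(
    post: VarCompPosterior, ped: Pedigree, trait: str = "mass"
) -> GeneticTrend:
    """Per-year slope of cohort-mean breeding values, per posterior sample.

    The least-squares slope of cohort means on cohort year is computed
    within each stored breeding-value sample, never on the posterior
    means, so the slope posterior carries the full uncertainty.
    """
    if post.bv is None:
        raise ValueError("posterior holds no breeding-value samples (store_bv=False?)")
    t = post.trait_index(trait)
    cohorts, masks = _cohort_design(ped)
    if len(cohorts) < 3:
        raise ValueError(f"trend undefined with {len(cohorts)} cohorts (need >= 3)")
    bv = post.bv[:, :, t]  # (S, n)
    means = np.column_stack([bv[:, m].mean(axis=1) for m in masks])  # (S, C)
    x = cohorts.astype(float)
    xc = x - x.mean()
    slopes = (means @ xc) / (xc @ xc)
    return GeneticTrend(cohorts=cohorts, cohort_means=means, slopes=slopes)


def drop_breeding_values(
    ped: Pedigree,
    vA: float | np.ndarray,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Neutral (drift-only) breeding values dropped down a pedigree.

    ``vA`` may be a scalar (shared by all replicates) or a vector of
    per-replicate additive variances (one per posterior draw for the
    paired construction).  Returns an (n_individuals, n_reps) array.
    Founders draw ``N(0, vA)``; offspring draw mid-parent plus Mendelian
    noise with variance ``d_i vA`` where ``d_i`` accounts for parental
    inbreeding.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vA = np.broadcast_to(np.asarray(vA, dtype=float), (n_reps,))
    if np.any(vA < 0):
        raise ValueError("vA must be non-negative")
    F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    n = len(ped)
    sd = np.sqrt(vA)  # per-replicate scale
    bv = np.zeros((n + 1, n_reps))  # last row: unknown-parent contribution = 0
    z = rng.standard_normal((n, n_reps))
    depth = ped.depths()
    for lvl in range(1, depth.max() + 1):
        ix = np.where(depth == lvl)[0]
        mid = 0.5 * bv[ped.sire[ix]] + 0.5 * bv[ped.dam[ix]]
        bv[ix] = mid + np.sqrt(d[ix])[:, None] * z[ix] * sd[None, :]
    return bv[:-1]


@dataclass
class DriftNull:
    """Gene-dropping drift null for the cohort-mean breeding-value slope."""

    drift_slopes: np.ndarray
    observed_slopes: np.ndarray | None
    vA: np.ndarray

    def exceedance(self, tail: str = "observed") -> float:
        """Probability that drift produces change as or more extreme.

        ``"observed"`` — one-tailed in the direction of the (paired)
        observed slope; ``"two"`` — two-tailed on absolute value.
        Pairing means drift replicate ``r`` is compared against observed
        posterior draw ``r``; drift replicates simulated from large
        posterior V_A draws are naturally more variable.
        """
        if self.observed_slopes is None:
            raise ValueError("no observed slopes attached")
        obs = self.observed_slopes
        dr = self.drift_slopes
        if tail == "two":
            p = np.mean(np.abs(dr) >= np.abs(obs))
        elif tail == "observed":
            direction = np.sign(np.median(obs)) or -1.0
            if direction < 0:
                p = np.mean(dr <= obs)
            else:
                p = np.mean(dr >= obs)
        else:
            raise ValueError("tail must be 'observed' or 'two'")
        return float(max(p, 1.0 / dr.size))


def gene_drop_drift(
    ped: Pedigree,
    vA_samples: np.ndarray,
    observed_slopes: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
) -> DriftNull:
    """Drift null distribution of the cohort-mean breeding-value slope.

    For each of ``n_sims`` replicates, a posterior ``V_A`` draw is taken
    (cycled in order, keeping the replicate paired with the observed
    slope draw of the same index), neutral breeding values are dropped
    down the pedigree, and the cohort-mean slope is recorded.
    """
    vA_samples = np.asarray(vA_samples, dtype=float).ravel()
    if vA_samples.size == 0:
        raise ValueError("vA_samples is empty")
    take = np.arange(n_sims) % vA_samples.size
    vA = vA_samples[take]
    obs = None
    if observed_slopes is not None:
        observed_slopes = np.asarray(observed_slopes, dtype=float).ravel()
        obs = observed_slopes[np.arange(n_sims) % observed_slopes.size]
    bv = drop_breeding_values(ped, vA, n_reps=n_sims, rng=np.random.default_rng(seed))
    cohorts, masks = _cohort_design(ped)
    means = np.vstack([bv[m].mean(axis=0) for m in masks])  # (C, n_sims)
    x = cohorts.astype(float)
    xc = x - x.mean()
    slopes = (xc @ means) / (xc @ xc)
    return DriftNull(drift_slopes=slopes, observed_slopes=obs, vA=vA)


def to_darwins(rate: float, mean_trait: float) -> float:
    """Convert a per-year trait change into Darwins.

    One Darwin is an e-fold (natural-log) proportional change per
    million years; here the one-year step ``ln((z + rate) / z)`` is
    scaled to a million years:  ``d = |ln((z + rate)/z)| * 1e6``.
    """
    if mean_trait <= 0:
        raise ValueError("mean trait value must be positive for a log rate")
    if mean_trait + rate <= 0:
        raise ValueError("rate implies non-positive trait value within one year")
    return float(abs(np.log((mean_trait + rate) / mean_trait)) * 1e6)
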