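"""Selection analysis: relative fitness, differentials, gradients, and
predicted responses.

The phenotypic selection differential on a trait ``z`` is its covariance
with relative fitness ``omega``.  Estimated inside a multivariate animal
model, it decomposes per posterior sample into additive-genetic and
environmental parts,

    sigma_P(z, w) = sigma_A(z, w) + sigma_E(z, w),

where the environmental part sums the maternal, permanent-environment
and residual covariances.  The among-year covariance is excluded
throughout: year-level covariation between trait and fitness does not
act among individuals, and cohort-wise fitness standardization drives it
to zero anyway.

Selection gradients follow beta = (G' + P' + R')^{-1} S with the
fitness row/column removed from each matrix; response predictions come
as the univariate breeder's equation h^2 S, the multivariate breeder's
equation G' beta, its correlation-free variant (G' * I) beta, and the
Robertson-Price (secondary-theorem) genetic differential sigma_A(z, w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal import (
    AnimalModel,
    MCMCSettings,
    ModelSpec,
    PriorSpec,
    VarCompPosterior,
    heritability,
)
from .stats import posterior_mode, hpd_interval, pmcmc

__all__ = [
    "relativize_fitness",
    "SelectionDecomposition",
    "selection_differential",
    "selection_gradients",
    "ResponsePrediction",
    "predict_response",
    "decompose_by_component",
    "bootstrap_covariance",
]

_ENV_LEVELS = ("maternal", "pe", "R")  # year deliberately excluded


def relativize_fitness(
    fitness: pd.DataFrame,
    measure: str = "lrs",
    by: tuple = ("sex", "cohort"),
    out: str | None = None,
) -> pd.DataFrame:
    """Divide a fitness measure by its group (cell) mean.

    For lifetime measures use ``by=("sex", "cohort")``; for annual
    measures (ARS, survival) use ``by=("sex", "year")``.  Cells whose
    members are all zero have no defined relative fitness and raise.
    The operation is idempotent: relativizing twice equals once.
    """
    df = fitness.copy()
    for col in by + (measure,):
        if col not in df.columns:
            raise ValueError(f"fitness table lacks column {col!r}")
    cell_mean = df.groupby(list(by))[measure].transform("mean")
    bad = cell_mean == 0
    if bad.any():
        cells = df.loc[bad, list(by)].drop_duplicates().to_dict(orient="records")
        raise ValueError(f"all-zero fitness cells, relative fitness undefined: {cells}")
    if out is None:
        out = "omega" if measure == "lrs" else f"rel_{measure}"
    df[out] = df[measure] / cell_mean
    return df


def cell_sizes(fitness: pd.DataFrame, by: tuple = ("sex", "cohort")) -> pd.DataFrame:
    return fitness.groupby(list(by)).size().rename("n").reset_index()


@dataclass
class SelectionDecomposition:
    """Posterior decomposition of a trait x fitness-measure covariance."""

    trait: str
    fitness_measure: str
    sigma_P: np.ndarray
    sigma_A: np.ndarray
    sigma_E: np.ndarray
    parts: dict  # level -> samples

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, s in (
            ("sigma_P", self.sigma_P),
            ("sigma_A", self.sigma_A),
            ("sigma_E", self.sigma_E),
        ):
            lo, hi = hpd_interval(s)
            rows.append(
                {
                    "trait": self.trait,
                    "fitness": self.fitness_measure,
                    "component": label,
                    "mode": posterior_mode(s),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "p_mcmc": pmcmc(s),
                }
            )
        return pd.DataFrame(rows)


def selection_differential(
    post: VarCompPosterior, trait: str = "mass", fitness_measure: str = "omega"
) -> SelectionDecomposition:
    """Posterior of S = sigma_P(trait, omega) and its A/E decomposition.

    Per posterior sample, S sums the additive, maternal,
    permanent-environment and residual covariances between the trait and
    the fitness measure; the year-level covariance is excluded.  The
    closure S = sigma_A + sigma_E holds exactly per sample.
    """
    t = post.trait_index(trait)
    w = post.trait_index(fitness_measure)
    sigma_A = post.samples["G"][:, t, w].copy()
    parts = {"a": sigma_A}
    sigma_E = np.zeros_like(sigma_A)
    for level in _ENV_LEVELS:
        if level in post.samples:
            part = post.samples[level][:, t, w]
            parts[level] = part
            sigma_E = sigma_E + part
    return SelectionDecomposition(
        trait=trait,
        fitness_measure=fitness_measure,
        sigma_P=sigma_A + sigma_E,
        sigma_A=sigma_A,
        sigma_E=sigma_E,
        parts=parts,
    )


def _submatrices(post: VarCompPosterior, fitness_measure: str, include_maternal: bool):
    """Per-sample (G', P'(+M'), R', S) with the fitness row/col removed."""
    w = post.trait_index(fitness_measure)
    keep = [i for i in range(len(post.traits)) if i != w]
    G = post.samples["G"]
    Gp = G[np.ix_(range(G.shape[0]), keep, keep)]
    Pp = post.samples["pe"][np.ix_(range(G.shape[0]), keep, keep)]
    Rp = post.samples["R"][np.ix_(range(G.shape[0]), keep, keep)]
    denom = Gp + Pp + Rp
    if include_maternal and "maternal" in post.samples:
        denom = denom + post.samples["maternal"][np.ix_(range(G.shape[0]), keep, keep)]
    S = G[:, keep, w] + post.samples["pe"][:, keep, w] + post.samples["R"][:, keep, w]
    if "maternal" in post.samples:
        S = S + post.samples["maternal"][:, keep, w]
    return Gp, denom, S, keep


def selection_gradients(
    post: VarCompPosterior,
    fitness_measure: str = "omega",
    include_maternal: bool = False,
) -> dict:
    """Posterior of the selection-gradient vector beta.

    beta = (G' + P' + R')^{-1} S per sample.  The maternal covariance is
    excluded from the denominator by default (matching the differential's
    published form); ``include_maternal`` adds M', since where maternal
    (co)variance sits is a modelling choice.  Singular draws are skipped
    and counted.
    """
    Gp, denom, S, keep = _submatrices(post, fitness_measure, include_maternal)
    n = Gp.shape[0]
    betas = np.full((n, len(keep)), np.nan)
    skipped = 0
    for s in range(n):
        try:
            betas[s] = np.linalg.solve(denom[s], S[s])
        except np.linalg.LinAlgError:
            skipped += 1
    ok = ~np.isnan(betas[:, 0])
    return {
        "samples": betas[ok],
        "traits": [post.traits[i] for i in keep],
        "S_samples": S[ok],
        "mode": np.array([posterior_mode(betas[ok, j]) for j in range(len(keep))]),
        "n_skipped": skipped,
    }


@dataclass
class ResponsePrediction:
    """Posterior predicted evolutionary change, per generation and per year."""

    mode_label: str
    trait: str
    per_generation: np.ndarray
    per_year: np.ndarray
    generation_time: float

    def summary(self) -> dict:
        lo, hi = hpd_interval(self.per_year)
        return {
            "estimator": self.mode_label,
            "trait": self.trait,
            "per_generation_mode": posterior_mode(self.per_generation),
            "per_year_mode": posterior_mode(self.per_year),
            "per_year_hpd_low": lo,
            "per_year_hpd_high": hi,
            "p_mcmc": pmcmc(self.per_year),
        }


def predict_response(
    post: VarCompPosterior,
    mode: str = "UBE",
    T: float = 1.0,
    trait: str = "mass",
    fitness_measure: str = "omega",
    include_maternal: bool = False,
) -> ResponsePrediction:
    """Predicted rate of evolutionary change for one trait.

    mode:
      * ``UBE``      — h^2(trait) * S(trait), the univariate breeder's equation;
      * ``MBE``      — the trait's element of G' beta;
      * ``MBE_rho0`` — same with G' off-diagonals zeroed (G' * I) beta;
      * ``Price``    — sigma_A(trait, omega), the secondary-theorem estimate.

    Per-year values divide the per-generation prediction by the
    generation time ``T`` for every posterior sample.
    """
    if T <= 0:
        raise ValueError("generation time T must be positive")
    if mode == "UBE":
        h2 = heritability(post, trait)
        S = selection_differential(post, trait, fitness_measure).sigma_P
        per_gen = h2 * S
    elif mode in ("MBE", "MBE_rho0"):
        Gp, denom, S, keep = _submatrices(post, fitness_measure, include_maternal)
        names = [post.traits[i] for i in keep]
        j = names.index(trait)
        n = Gp.shape[0]
        per_gen = np.full(n, np.nan)
        for s in range(n):
            try:
                beta = np.linalg.solve(denom[s], S[s])
            except np.linalg.LinAlgError:
                continue
            Gs = np.diag(np.diag(Gp[s])) if mode == "MBE_rho0" else Gp[s]
            per_gen[s] = (Gs @ beta)[j]
        per_gen = per_gen[~np.isnan(per_gen)]
    elif mode == "Price":
        t = post.trait_index(trait)
        w = post.trait_index(fitness_measure)
        per_gen = post.samples["G"][:, t, w].copy()
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return ResponsePrediction(
        mode_label=mode,
        trait=trait,
        per_generation=per_gen,
        per_year=per_gen / T,
        generation_time=T,
    )


_COMPONENTS = {
    "ars_male": dict(measure="ars", by=("sex", "year"), sex="M", age="adult"),
    "ars_female": dict(measure="ars", by=("sex", "year"), sex="F", age="adult"),
    "phi_juv": dict(measure="survived", by=("sex", "year"), sex=None, age="juvenile"),
    "phi_ad": dict(measure="survived", by=("sex", "year"), sex=None, age="adult"),
}


def decompose_by_component(
    phenotypes: pd.DataFrame,
    fitness: pd.DataFrame,
    pedigree,
    component: str,
    trait: str = "mass",
    mcmc: MCMCSettings | None = None,
    prior: PriorSpec | None = None,
    family: str = "fixed_residual",
    min_records: int = 30,
) -> SelectionDecomposition:
    """Genetic/environmental decomposition of one fitness component.

    Refits a bivariate trait x component animal model on the appropriate
    subset: male or female annual reproductive success (adults), or
    juvenile / adult annual survival.  Annual components are relativized
    by sex-and-year means.  ``family="threshold"`` switches the component
    to a probit-liability model (covariances on the latent scale);
    the default treats the relativized component as Gaussian.
    """
    if component not in _COMPONENTS:
        raise ValueError(f"unknown component {component!r}; have {sorted(_COMPONENTS)}")
    cdef = _COMPONENTS[component]
    fit = fitness.copy()
    # age split: juvenile records are those in the individual's cohort year
    age_class = np.where(fit["year"] == fit["cohort"], "juvenile", "adult")
    fit = fit[age_class == cdef["age"]]
    if cdef["sex"]:
        fit = fit[fit["sex"].astype(str).str.upper().str.startswith(cdef["sex"])]
    if len(fit) < min_records:
        raise ValueError(
            f"component {component}: only {len(fit)} records (< {min_records})"
        )
    measure = cdef["measure"]
    col = f"rel_{measure}"
    if family == "threshold":
        fit[col] = fit[measure].astype(float)  # raw 0/1 on the liability route
    else:
        fit = relativize_fitness(fit, measure=measure, by=cdef["by"], out=col)
    ids = set(fit["id"])
    phe = phenotypes[phenotypes["id"].isin(set(pedigree.index))]
    spec = ModelSpec(
        traits=[
            __import__("nivalis.animal", fromlist=["TraitDef"]).TraitDef(trait),
            __import__("nivalis.animal", fromlist=["TraitDef"]).TraitDef(
                col, source="fitness", family=family
            ),
        ]
    )
    model = AnimalModel(spec=spec, prior=prior, mcmc=mcmc or MCMCSettings())
    model.fit(phe, pedigree, fitness=fit)
    dec = selection_differential(model.posterior_, trait, col)
    dec.fitness_measure = component
    return dec


def bootstrap_covariance(
    trait_values: np.ndarray,
    fitness_values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Nonparametric bootstrap of the raw trait-fitness covariance.

    Individuals are the resampling unit; returns the bootstrap
    distribution, a percentile CI and a two-sided sign test.
    """
    x = np.asarray(trait_values, dtype=float)
    y = np.asarray(fitness_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trait and fitness vectors differ in length")
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        i = idx[b]
        boots[b] = np.cov(x[i], y[i])[0, 1]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    point = float(np.cov(x, y)[0, 1])
    p = 2.0 * min(np.mean(boots > 0), np.mean(boots < 0))
    return {
        "estimate": point,
        "boot": boots,
        "ci": (float(lo), float(hi)),
        "p_sign": float(max(p, 1.0 / n_boot)),
    }
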