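"""Bayesian animal models: pedigree-structured Gaussian mixed models.

The "animal model" treats each individual's breeding value as a random
effect whose covariance across individuals is the additive relationship
matrix ``A`` scaled by the additive genetic (co)variance ``G``:

    y = X b + Z_a a + Z_m mu + Z_p p + Z_y yr + e,     a ~ N(0, A kron G)

with maternal (``mu``), permanent-environment (``p``), year (``yr``) and
residual levels each carrying their own (co)variance matrix.  Fitting is
by Gibbs sampling:

* all location effects (fixed effects and every random effect) are drawn
  jointly from their multivariate-normal full conditional using the
  simulation trick of Garcia-Cortes & Sorensen: simulate a pseudo-record
  vector from the current variances, solve the mixed-model equations for
  the difference, and shift — one sparse factorization per iteration,
  no explicit posterior Cholesky;
* each covariance matrix is drawn from its conditional inverse-Wishart.

Fitness, when modelled as a Gaussian trait alongside the phenotypes, has
its residual variance fixed to (nearly) zero so that its non-additive
repeatable variance is carried by the permanent-environment level; the
additive and permanent-environment covariances between a trait and
fitness are then directly the genetic and environmental components of
the selection differential.

Binary responses (e.g. annual survival) can be attached as threshold
traits: a latent Gaussian liability with unit residual variance is
sampled by data augmentation, and covariances involving the trait are
reported on the liability scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import ndtr, ndtri

from .pedigree import (
    Pedigree,
    inbreeding_coefficients,
    mendelian_sampling_variance,
    a_inverse,
)
from .stats import posterior_mode, hpd_interval, lag1_autocorr, pmcmc

__all__ = [
    "TraitDef",
    "ModelSpec",
    "PriorSpec",
    "MCMCSettings",
    "VarCompPosterior",
    "AnimalModel",
    "fit_animal_model",
    "heritability",
    "genetic_correlation",
]

_DEFAULT_PHENO_TERMS = ("1", "sex", "age", "sex:age", "date", "date2", "age:date", "f")
_DEFAULT_FITNESS_TERMS = ("1",)


def _rinvwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (seeded rng).

    The degrees of freedom are floored just above ``k - 1`` so that the
    conditional stays numerically proper when a term has fewer levels
    than traits; the draw is built from triangular factors of ``scale``
    (never an explicit inverse), which keeps near-singular conditionals
    stable.
    """
    from scipy.linalg import solve_triangular

    scale = np.atleast_2d(scale)
    k = scale.shape[0]
    df = max(df, k - 1 + 0.5)
    if k == 1:
        return np.array([[scale[0, 0] / rng.chisquare(df)]])
    Ls = np.linalg.cholesky(scale + 1e-12 * np.trace(scale) / k * np.eye(k))
    A = np.zeros((k, k))
    for i in range(k):
        A[i, i] = np.sqrt(max(rng.chisquare(df - i), 1e-300))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    # W ~ Wishart(df, inv(scale)); inv(W) = (Ls B')(Ls B')' with B = A^-1
    B = solve_triangular(A, np.eye(k), lower=True)
    M = Ls @ B.T
    return M @ M.T


@dataclass
class TraitDef:
    """One response trait of an animal model.

    Parameters
    ----------
    name : str
        Trait label used in posteriors.
    column : str
        Source column; defaults to ``name``.
    source : {"phenotypes", "fitness"}
        Which input table the records come from.
    subset : dict or None
        Row filter on the source table, e.g. ``{"age_class": "juvenile"}``.
    family : {"gaussian", "fixed_residual", "threshold"}
        ``fixed_residual`` pins the residual variance to a tiny fraction
        of the observed variance (the fitness convention); ``threshold``
        treats 0/1 records as a probit liability with unit residual.
    dedupe_by_id : bool
        Keep one record per individual (for lifetime measures).
    residual_group : int
        Traits in different groups have residual covariance fixed at 0
        (used e.g. for juvenile- vs adult-expressed trait splits).
    fixed_effects : tuple of str or None
        Terms among {"1","sex","age","sex:age","date","date2","age:date",
        "sex:date","f"}; ``None`` selects a per-source default.
    """

    name: str
    column: str | None = None
    source: str = "phenotypes"
    subset: dict | None = None
    family: str = "gaussian"
    dedupe_by_id: bool = False
    residual_group: int = 0
    fixed_effects: tuple | None = None

    def __post_init__(self):
        if self.column is None:
            self.column = self.name
        if self.fixed_effects is None:
            self.fixed_effects = (
                _DEFAULT_PHENO_TERMS if self.source == "phenotypes" else _DEFAULT_FITNESS_TERMS
            )


@dataclass
class ModelSpec:
    """Response traits and random structure of an animal model."""

    traits: list = field(default_factory=lambda: [TraitDef("mass")])
    random_terms: tuple = ("a", "pe", "maternal", "year")

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.traits]

    @classmethod
    def univariate(cls, trait: str = "mass", **kw) -> "ModelSpec":
        return cls(traits=[TraitDef(trait)], **kw)

    @classmethod
    def multivariate(
        cls,
        traits: tuple = ("mass", "length", "tail"),
        fitness: str | None = "omega",
        **kw,
    ) -> "ModelSpec":
        """Morphological traits plus a Gaussian fitness trait whose
        residual variance is fixed near zero."""
        colmap = {"length": "body_length", "tail": "tail_length"}
        tds = [TraitDef(t, column=colmap.get(t, t)) for t in traits]
        if fitness is not None:
            tds.append(
                TraitDef(fitness, source="fitness", family="fixed_residual", dedupe_by_id=True)
            )
        return cls(traits=tds, **kw)

    @classmethod
    def bivariate_component(
        cls,
        component: str,
        trait: str = "mass",
        subset: dict | None = None,
        family: str = "fixed_residual",
        dedupe_by_id: bool = False,
        **kw,
    ) -> "ModelSpec":
        """Trait x fitness-component model (for selection decomposition)."""
        return cls(
            traits=[
                TraitDef(trait, subset=subset),
                TraitDef(
                    component,
                    source="fitness",
                    family=family,
                    subset=subset if subset and "sex" in subset else None,
                    dedupe_by_id=dedupe_by_id,
                ),
            ],
            **kw,
        )


@dataclass
class PriorSpec:
    """Inverse-Wishart priors per random term.

    Each term gets scale ``V * nu`` (V defaults to the identity) and
    degree of belief ``nu``; the conditional posterior for a term with
    ``n`` levels and sum-of-squares ``S`` is ``IW(V nu + S, nu + n)``.
    """

    variance: float = 1.0
    nu: float = 0.002
    term_overrides: dict = field(default_factory=dict)  # term -> (V, nu)

    def psi_nu(self, term: str, k: int) -> tuple[np.ndarray, float]:
        v, nu = self.term_overrides.get(term, (self.variance, self.nu))
        V = np.eye(k) * v if np.isscalar(v) else np.asarray(v, dtype=float)
        return V * nu, float(nu)


@dataclass
class MCMCSettings:
    """Chain settings.  The default is a scaled-down preset suitable for
    simulation studies; ``long()`` is the heavy preset used for real-data
    runs (1.3M iterations, 300k burn-in, thinning 1000)."""

    iterations: int = 6000
    burnin: int = 1000
    thin: int = 5
    seed: int = 0

    @classmethod
    def long(cls, seed: int = 0) -> "MCMCSettings":
        return cls(iterations=1_300_000, burnin=300_000, thin=1000, seed=seed)

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burnin) // self.thin


class VarCompPosterior:
    """Thinned MCMC samples from an animal model.

    Attributes
    ----------
    traits : list of str
    samples : dict
        "G", "pe", "maternal", "year", "R" -> (S, k, k) arrays;
        "fixed" -> (S, p).
    bv : (S, n_ped, k) array or None
        Breeding-value samples for every pedigree individual.
    ids : list of str
        Pedigree ids indexing ``bv``.
    """

    def __init__(self, traits, samples, bv, ids, fixed_names, meta):
        self.traits = list(traits)
        self.samples = samples
        self.bv = bv
        self.ids = list(ids) if ids is not None else None
        self.fixed_names = list(fixed_names)
        self.meta = dict(meta)

    def trait_index(self, name: str) -> int:
        try:
            return self.traits.index(name)
        except ValueError:
            raise KeyError(f"trait {name!r} not in model (has {self.traits})") from None

    def vcv(self, level: str) -> np.ndarray:
        if level not in self.samples:
            raise KeyError(f"no samples for level {level!r}")
        return self.samples[level]

    @property
    def n_samples(self) -> int:
        return self.samples["G"].shape[0] if "G" in self.samples else len(
            next(iter(self.samples.values()))
        )

    def save(self, outdir) -> None:
        """Persist thinned samples (one tabular file of flattened named
        parameters + JSON metadata; breeding values in a wide table)."""
        from pathlib import Path
        import json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cols = {}
        k = len(self.traits)
        for level, arr in self.samples.items():
            if arr.ndim == 3 and arr.shape[1:] == (k, k):
                for i, ti in enumerate(self.traits):
                    for j, tj in enumerate(self.traits):
                        if j >= i:
                            cols[f"{level}[{ti},{tj}]"] = arr[:, i, j]
            elif level == "fixed":
                for j, name in enumerate(self.fixed_names):
                    cols[f"fixed[{name}]"] = arr[:, j]
        pd.DataFrame(cols).to_csv(out / "samples.csv", index=False)
        meta = {"traits": self.traits, "fixed_names": self.fixed_names, **self.meta}
        (out / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
        if self.bv is not None:
            k = len(self.traits)
            bv_cols = {
                f"{iid}:{t}": self.bv[:, n, j]
                for n, iid in enumerate(self.ids)
                for j, t in enumerate(self.traits)
            } if len(self.ids) * k <= 40000 else None
            if bv_cols is not None:
                pd.DataFrame(bv_cols).to_csv(out / "breeding_values.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "VarCompPosterior":
        from pathlib import Path
        import json
        import re

        out = Path(outdir)
        meta = json.loads((out / "meta.json").read_text())
        traits = meta.pop("traits")
        fixed_names = meta.pop("fixed_names")
        df = pd.read_csv(out / "samples.csv")
        k = len(traits)
        S = len(df)
        samples: dict = {}
        for col in df.columns:
            m = re.match(r"(\w+)\[(.+)\]$", col)
            if not m:
                continue
            level, inner = m.groups()
            if level == "fixed":
                samples.setdefault("fixed", np.zeros((S, len(fixed_names))))
                samples["fixed"][:, fixed_names.index(inner)] = df[col]
            else:
                ti, tj = inner.split(",")
                i, j = traits.index(ti), traits.index(tj)
                samples.setdefault(level, np.zeros((S, k, k)))
                samples[level][:, i, j] = df[col]
                samples[level][:, j, i] = df[col]
        bv = None
        ids = None
        bv_path = out / "breeding_values.csv"
        if bv_path.exists():
            bdf = pd.read_csv(bv_path)
            ids = sorted({c.rsplit(":", 1)[0] for c in bdf.columns},
                         key=list(dict.fromkeys(
                             c.rsplit(":", 1)[0] for c in bdf.columns)).index)
            bv = np.zeros((S, len(ids), k))
            for n, iid in enumerate(ids):
                for j, t in enumerate(traits):
                    bv[:, n, j] = bdf[f"{iid}:{t}"]
        return cls(traits, samples, bv, ids, fixed_names, meta)

    def summary(self) -> pd.DataFrame:
        rows = []
        for level, arr in self.samples.items():
            if arr.ndim != 3 or level == "year_eff":
                continue
            for i, ti in enumerate(self.traits):
                for j, tj in enumerate(self.traits):
                    if j < i:
                        continue
                    ch = arr[:, i, j]
                    lo, hi = hpd_interval(ch)
                    rows.append(
                        {
                            "level": level,
                            "row": ti,
                            "col": tj,
                            "mode": posterior_mode(ch),
                            "mean": float(np.mean(ch)),
                            "hpd_low": lo,
                            "hpd_high": hi,
                            "p_mcmc": pmcmc(ch),
                        }
                    )
        return pd.DataFrame(rows)


def _design_terms(terms, df, date_center, date_scale, F, trait):
    """Fixed-effect design columns for one trait."""
    n = len(df)
    cols, names = [], []
    sex = (df["sex"].astype(str).str.upper().str[:1] == "M").to_numpy(float)
    if "age_class" in df:
        juv = (df["age_class"].astype(str).str.lower().str.startswith("juv")).to_numpy(float)
    else:
        juv = np.zeros(n)
    if "date" in df:
        d = (df["date"].to_numpy(float) - date_center) / date_scale
    else:
        d = np.zeros(n)
    feats = {
        "1": np.ones(n),
        "sex": sex,
        "age": juv,
        "sex:age": sex * juv,
        "date": d,
        "date2": d**2,
        "age:date": juv * d,
        "sex:date": sex * d,
        "f": F,
    }
    for t in terms:
        if t not in feats:
            raise ValueError(f"unknown fixed-effect term {t!r}")
        cols.append(feats[t])
        names.append(f"{trait}:{t}")
    return np.column_stack(cols), names


def _check_identifiable(X, names):
    if X.shape[0] == 0:
        raise ValueError("trait has no observations")
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [names[p] for p in piv[rank:]]
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")


class AnimalModel:
    """Gibbs-sampler animal model with an sklearn-style interface.

    Parameters are set at construction, ``fit`` consumes the data tables
    and the pedigree, and fitted state lands in trailing-underscore
    attributes, chiefly ``posterior_``.

    Parameters
    ----------
    spec : ModelSpec
    prior : PriorSpec
    mcmc : MCMCSettings
    store_bv : bool
        Keep thinned breeding-value samples for all pedigree individuals.
    use_sparse : bool
        Use the sparse A-inverse path (dense fallback exists only inside
        the relationship algebra; the sampler is always sparse).
    """

    def __init__(self, spec=None, prior=None, mcmc=None, store_bv=True, progress=False):
        self.spec = spec
        self.prior = prior
        self.mcmc = mcmc
        self.store_bv = store_bv
        self.progress = progress

    # -- sklearn-style parameter plumbing ------------------------------
    def get_params(self, deep=True):
        return {
            "spec": self.spec,
            "prior": self.prior,
            "mcmc": self.mcmc,
            "store_bv": self.store_bv,
            "progress": self.progress,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- data assembly --------------------------------------------------
    def _assemble(self, phenotypes, fitness, ped: Pedigree):
        spec = self.spec
        k = len(spec.traits)
        idx = ped.index

        # canonical ordering makes results invariant to input row order
        if phenotypes is not None and len(phenotypes):
            phenotypes = phenotypes.sort_values(
                ["id", "year", "date"] if "date" in phenotypes else ["id", "year"]
            ).reset_index(drop=True)
        if fitness is not None and len(fitness):
            sort_cols = [c for c in ("id", "year") if c in fitness.columns]
            fitness = fitness.sort_values(sort_cols).reset_index(drop=True)

        if phenotypes is not None and "date" in phenotypes:
            self.date_center_ = float(phenotypes["date"].mean())
            self.date_scale_ = float(phenotypes["date"].std() or 1.0)
        else:
            self.date_center_, self.date_scale_ = 0.0, 1.0
        Fped = inbreeding_coefficients(ped)

        # units: one per source row (phenotype rows may observe several
        # traits; fitness rows are singletons)
        units = []  # dicts: ind, year, traits [(t_ix, value)], Xrows per trait
        pheno_traits = [(i, t) for i, t in enumerate(spec.traits) if t.source == "phenotypes"]
        fit_traits = [(i, t) for i, t in enumerate(spec.traits) if t.source == "fitness"]

        def _subset_ok(row, t: TraitDef):
            if not t.subset:
                return True
            for col, val in t.subset.items():
                allowed = val if isinstance(val, (list, tuple, set)) else (val,)
                if row[col] not in allowed:
                    return False
            return True

        if pheno_traits:
            if phenotypes is None or not len(phenotypes):
                raise ValueError("model has phenotype traits but no phenotype table")
            for row in phenotypes.to_dict(orient="records"):
                if row["id"] not in idx:
                    raise ValueError(f"phenotyped individual {row['id']!r} not in pedigree")
                obs = []
                for t_ix, t in pheno_traits:
                    v = row.get(t.column)
                    if v is None or (isinstance(v, float) and np.isnan(v)):
                        continue
                    if _subset_ok(row, t):
                        obs.append((t_ix, float(v)))
                if obs:
                    units.append({"row": row, "ind": idx[row["id"]], "obs": obs})
        for t_ix, t in fit_traits:
            if fitness is None or not len(fitness):
                raise ValueError(f"trait {t.name!r} needs a fitness table")
            ftab = fitness
            if t.subset:
                mask = np.ones(len(ftab), dtype=bool)
                for col, val in t.subset.items():
                    allowed = val if isinstance(val, (list, tuple, set)) else (val,)
                    mask &= ftab[col].isin(allowed).to_numpy()
                ftab = ftab[mask]
            if t.dedupe_by_id:
                ftab = ftab.drop_duplicates(subset="id", keep="first")
            for row in ftab.to_dict(orient="records"):
                if row["id"] not in idx:
                    raise ValueError(f"individual {row['id']!r} not in pedigree")
                v = row.get(t.column)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                if t.dedupe_by_id and "cohort" in row:
                    row = {**row, "year": row["cohort"]}
                units.append({"row": row, "ind": idx[row["id"]], "obs": [(t_ix, float(v))]})

        for t_ix, t in enumerate(spec.traits):
            if not any(o[0] == t_ix for u in units for o in u["obs"]):
                raise ValueError(
                    f"trait {t.name!r} (column {t.column!r}) has no observations"
                )
        if not units:
            raise ValueError("no observations after filtering")

        # fixed-effect designs per trait, evaluated on each trait's records
        self.fixed_names_ = []
        fx_offsets = []
        fx_widths = []
        for t_ix, t in enumerate(spec.traits):
            rows_t = [u["row"] for u in units if any(o[0] == t_ix for o in u["obs"])]
            if not rows_t:
                raise ValueError(
                    f"trait {t.name!r} (column {t.column!r}) has no observations"
                )
            df_t = pd.DataFrame(rows_t)
            Fcol = np.array([Fped[idx[r]] for r in df_t["id"]])
            X_t, names_t = _design_terms(
                t.fixed_effects, df_t, self.date_center_, self.date_scale_, Fcol, t.name
            )
            _check_identifiable(X_t, names_t)
            fx_offsets.append(sum(fx_widths))
            fx_widths.append(X_t.shape[1])
            self.fixed_names_.extend(names_t)
        nb = sum(fx_widths)

        # random-effect levels
        n_ped = len(ped)
        obs_inds = sorted({u["ind"] for u in units})
        pe_map = {i: j for j, i in enumerate(obs_inds)}
        mothers = sorted({ped.dam[u["ind"]] for u in units if ped.dam[u["ind"]] >= 0})
        mo_map = {i: j for j, i in enumerate(mothers)}
        years = sorted({int(u["row"].get("year", 0)) for u in units})
        yr_map = {y: j for j, y in enumerate(years)}

        terms = list(spec.random_terms)
        sizes = {"a": n_ped, "pe": len(obs_inds), "maternal": len(mothers), "year": len(years)}
        offsets = {}
        off = nb
        for term in terms:
            offsets[term] = off
            off += sizes[term] * k
        dim = off

        # scalar-observation bookkeeping (unit-contiguous ordering)
        rows_W, cols_W, vals_W = [], [], []
        y_list, trait_ix, unit_len = [], [], []
        unit_pattern = []
        counters = [0] * k  # per-trait record counter, for X row lookup
        Xmats = []
        for t_ix, t in enumerate(spec.traits):
            rows_t = [u["row"] for u in units if any(o[0] == t_ix for o in u["obs"])]
            df_t = pd.DataFrame(rows_t)
            Fcol = np.array([Fped[idx[r]] for r in df_t["id"]])
            X_t, _ = _design_terms(
                t.fixed_effects, df_t, self.date_center_, self.date_scale_, Fcol, t.name
            )
            Xmats.append(X_t)

        r = 0
        for u in units:
            ind = u["ind"]
            year = int(u["row"].get("year", 0))
            unit_len.append(len(u["obs"]))
            unit_pattern.append(tuple(o[0] for o in u["obs"]))
            for t_ix, val in u["obs"]:
                y_list.append(val)
                trait_ix.append(t_ix)
                xrow = Xmats[t_ix][counters[t_ix]]
                counters[t_ix] += 1
                for c, xv in enumerate(xrow):
                    if xv != 0.0:
                        rows_W.append(r)
                        cols_W.append(fx_offsets[t_ix] + c)
                        vals_W.append(float(xv))
                if "a" in offsets:
                    rows_W.append(r)
                    cols_W.append(offsets["a"] + ind * k + t_ix)
                    vals_W.append(1.0)
                if "pe" in offsets:
                    rows_W.append(r)
                    cols_W.append(offsets["pe"] + pe_map[ind] * k + t_ix)
                    vals_W.append(1.0)
                if "maternal" in offsets and ped.dam[ind] >= 0:
                    rows_W.append(r)
                    cols_W.append(offsets["maternal"] + mo_map[ped.dam[ind]] * k + t_ix)
                    vals_W.append(1.0)
                if "year" in offsets:
                    rows_W.append(r)
                    cols_W.append(offsets["year"] + yr_map[year] * k + t_ix)
                    vals_W.append(1.0)
                r += 1

        N = r
        W = sparse.csr_matrix(
            (vals_W, (rows_W, cols_W)), shape=(N, dim)
        )
        y = np.asarray(y_list, dtype=float)

        self._W = W
        self._y = y
        self._trait_ix = np.asarray(trait_ix)
        self._unit_len = np.asarray(unit_len)
        self._unit_start = np.concatenate([[0], np.cumsum(unit_len)])[:-1]
        self._patterns = unit_pattern
        self._offsets = offsets
        self._sizes = sizes
        self._nb = nb
        self._dim = dim
        self._k = k
        self._n_ped = n_ped
        self._terms = terms
        self._obs_inds = obs_inds
        self._mothers = mothers
        self._years = years
        self._ped = ped
        self._Fped = Fped

        # per-trait observed variance (for fixed-residual scaling) and
        # family bookkeeping
        self._trait_var = np.array(
            [np.var(y[self._trait_ix == t]) if np.any(self._trait_ix == t) else 1.0
             for t in range(k)]
        )
        self._families = [t.family for t in spec.traits]
        self._res_groups = [t.residual_group for t in spec.traits]
        self._binary = {
            t_ix: (y[self._trait_ix == t_ix] > 0.5)
            for t_ix, fam in enumerate(self._families)
            if fam == "threshold"
        }

    # -- fitting --------------------------------------------------------
    def fit(self, phenotypes, pedigree: Pedigree, fitness=None):
        if self.spec is None:
            self.spec = ModelSpec()
        if self.prior is None:
            self.prior = PriorSpec()
        if self.mcmc is None:
            self.mcmc = MCMCSettings()
        spec, prior, mcmc = self.spec, self.prior, self.mcmc
        k = len(spec.traits)
        rng = np.random.default_rng(mcmc.seed)

        self._assemble(phenotypes, fitness, pedigree)
        W, y = self._W, self._y
        N, dim, nb = len(y), self._dim, self._nb
        offsets, sizes, terms = self._offsets, self._sizes, self._terms
        ped = self._ped

        # pedigree structures for the genetic term
        if "a" in terms:
            Ainv = a_inverse(ped, self._Fped)
            dmend = mendelian_sampling_variance(ped, self._Fped)
            depth = ped.depths()
            levels = [np.where(depth == lvl)[0] for lvl in range(1, depth.max() + 1)]
            sire_e = ped.sire.copy()
            dam_e = ped.dam.copy()

        # residual bookkeeping: groups of gaussian traits
        groups = sorted({g for t_ix, g in enumerate(self._res_groups)
                         if self._families[t_ix] == "gaussian"})
        group_traits = {
            g: [t_ix for t_ix in range(k)
                if self._res_groups[t_ix] == g and self._families[t_ix] == "gaussian"]
            for g in groups
        }
        eps = 1e-8 * self._trait_var  # fixed residual variances

        # pattern grouping for fast R-block assembly
        pat_ids = {}
        pat_of_unit = np.empty(len(self._patterns), dtype=int)
        for uix, p in enumerate(self._patterns):
            pat_ids.setdefault(p, len(pat_ids))
            pat_of_unit[uix] = pat_ids[p]
        patterns = [None] * len(pat_ids)
        for p, pid in pat_ids.items():
            patterns[pid] = p
        units_of_pat = [np.where(pat_of_unit == pid)[0] for pid in range(len(patterns))]

        # precompute the CSR structure of the block-diagonal R^-1 (data
        # layout is unit-major, row-major within a unit's block)
        blk_slices = []
        pos = 0
        indptr = [0]
        indices: list[int] = []
        for uix, p in enumerate(self._patterns):
            s = self._unit_start[uix]
            m = len(p)
            blk_slices.append((pos, pos + m * m))
            pos += m * m
            for _ in range(m):
                indices.extend(range(s, s + m))
                indptr.append(indptr[-1] + m)
        nval = pos
        rbig_indices = np.asarray(indices, dtype=np.int32)
        rbig_indptr = np.asarray(indptr, dtype=np.int32)
        # entries grouped per pattern for vectorized filling
        pat_entry_ix = [
            np.concatenate([np.arange(*blk_slices[u]) for u in units_of_pat[pid]])
            if len(units_of_pat[pid]) else np.empty(0, dtype=int)
            for pid in range(len(patterns))
        ]

        # initial values
        def init_cov(term):
            return np.eye(k)

        G = init_cov("a")
        Pcov = init_cov("pe")
        Mcov = init_cov("maternal")
        Ycov = init_cov("year")
        Rfull = np.eye(k)
        for t_ix in range(k):
            if self._families[t_ix] == "fixed_residual":
                Rfull[t_ix, t_ix] = eps[t_ix]
            elif self._families[t_ix] == "threshold":
                Rfull[t_ix, t_ix] = 1.0
        theta = np.zeros(dim)
        y_work = y.copy()
        for t_ix, obs1 in self._binary.items():
            m = self._trait_ix == t_ix
            y_work[m] = np.where(obs1, 0.5, -0.5)

        n_store = mcmc.n_samples
        store = {
            "G": np.empty((n_store, k, k)),
            "pe": np.empty((n_store, k, k)),
            "maternal": np.empty((n_store, k, k)),
            "year": np.empty((n_store, k, k)),
            "R": np.empty((n_store, k, k)),
            "fixed": np.empty((n_store, nb)),
        }
        for term in ("a", "pe", "maternal", "year"):
            if term not in terms:
                store.pop({"a": "G", "pe": "pe", "maternal": "maternal", "year": "year"}[term], None)
        bv_store = (
            np.empty((n_store, self._n_ped, k)) if (self.store_bv and "a" in terms) else None
        )
        if "year" in terms:
            store["year_eff"] = np.empty((n_store, sizes["year"], k))

        def chol_or_eig(M):
            try:
                return np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                w, V = np.linalg.eigh(M)
                return V * np.sqrt(np.clip(w, 0, None))

        # static sparsity template for the prior-precision part of the MME:
        # kron(structure, k x k) per random term plus a tiny fixed-effect
        # ridge; only the data vector changes across iterations.
        struct = {}
        if "a" in terms:
            Acoo = Ainv.tocsr().tocoo()
            struct["a"] = (Acoo.row, Acoo.col, Acoo.data)
        for term in ("pe", "maternal", "year"):
            if term in terms and sizes[term]:
                n_t = sizes[term]
                struct[term] = (np.arange(n_t), np.arange(n_t), np.ones(n_t))
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        term_order = [t for t in ("a", "pe", "maternal", "year") if t in struct]
        prows, pcols = [], []
        for term in term_order:
            r0, c0, _ = struct[term]
            o = offsets[term]
            prows.append((o + r0[:, None] * k + ii.ravel()[None, :]).ravel())
            pcols.append((o + c0[:, None] * k + jj.ravel()[None, :]).ravel())
        prows.append(np.arange(nb))
        pcols.append(np.arange(nb))
        prows = np.concatenate(prows)
        pcols = np.concatenate(pcols)
        probe = sparse.coo_matrix(
            (np.arange(1, len(prows) + 1, dtype=float), (prows, pcols)), shape=(dim, dim)
        ).tocsr()
        if probe.nnz != len(prows):  # duplicate entries would break the trick
            raise RuntimeError("internal error: prior sparsity template has duplicates")
        perm_p = probe.data.astype(np.int64) - 1
        prior_csr = probe

        def prior_data(Ginv, Pinv, Minv, Yinv):
            invs = {"a": Ginv, "pe": Pinv, "maternal": Minv, "year": Yinv}
            parts = [
                np.multiply.outer(struct[t][2], invs[t].ravel()).ravel() for t in term_order
            ]
            parts.append(np.full(nb, 1e-10))
            return np.concatenate(parts)

        s_ix = 0
        WT = W.T.tocsr()
        for it in range(mcmc.iterations):
            LG = chol_or_eig(G) if "a" in terms else None
            LP = chol_or_eig(Pcov)
            LM = chol_or_eig(Mcov)
            LY = chol_or_eig(Ycov)

            # current residual matrix and per-pattern inverses / factors
            Rinv_pat = []
            Lr_pat = []
            for p in patterns:
                sub = Rfull[np.ix_(p, p)]
                Rinv_pat.append(np.linalg.inv(sub))
                Lr_pat.append(chol_or_eig(sub))

            # ---- 1. threshold liabilities --------------------------------
            if self._binary:
                mu_all = W @ theta
                for t_ix, obs1 in self._binary.items():
                    m = self._trait_ix == t_ix
                    mu = mu_all[m]
                    u = rng.random(mu.size)
                    lo = ndtr(-mu)  # P(liability < 0)
                    p_draw = np.where(obs1, lo + u * (1 - lo), u * lo)
                    p_draw = np.clip(p_draw, 1e-12, 1 - 1e-12)
                    y_work[m] = mu + ndtri(p_draw)

            # ---- 2. joint location draw ----------------------------------
            theta_star = np.zeros(dim)
            if "a" in terms:
                z = rng.standard_normal((self._n_ped, k))
                a_star = np.zeros((self._n_ped + 1, k))  # last row = unknown parent
                for lvl in levels:
                    mid = 0.5 * a_star[sire_e[lvl]] + 0.5 * a_star[dam_e[lvl]]
                    a_star[lvl] = mid + np.sqrt(dmend[lvl])[:, None] * (z[lvl] @ LG.T)
                theta_star[offsets["a"]: offsets["a"] + self._n_ped * k] = a_star[:-1].ravel()
            if "pe" in terms:
                theta_star[offsets["pe"]: offsets["pe"] + sizes["pe"] * k] = (
                    rng.standard_normal((sizes["pe"], k)) @ LP.T
                ).ravel()
            if "maternal" in terms:
                theta_star[offsets["maternal"]: offsets["maternal"] + sizes["maternal"] * k] = (
                    rng.standard_normal((sizes["maternal"], k)) @ LM.T
                ).ravel()
            if "year" in terms:
                theta_star[offsets["year"]: offsets["year"] + sizes["year"] * k] = (
                    rng.standard_normal((sizes["year"], k)) @ LY.T
                ).ravel()

            e_star = np.empty(N)
            for pid, p in enumerate(patterns):
                uix = units_of_pat[pid]
                if not len(uix):
                    continue
                m = len(p)
                draws = rng.standard_normal((len(uix), m)) @ Lr_pat[pid].T
                rows = (self._unit_start[uix][:, None] + np.arange(m)[None, :]).ravel()
                e_star[rows] = draws.ravel()
            y_star = W @ theta_star + e_star

            # block-diagonal R^-1
            vals = np.empty(nval)
            for pid in range(len(patterns)):
                ix = pat_entry_ix[pid]
                if len(ix):
                    vals[ix] = np.tile(Rinv_pat[pid].ravel(), len(units_of_pat[pid]))
            Rbig_inv = sparse.csr_matrix(
                (vals, rbig_indices, rbig_indptr), shape=(N, N)
            )

            WtRi = WT @ Rbig_inv
            prior_csr.data[:] = prior_data(
                np.linalg.inv(G) if "a" in terms else None,
                np.linalg.inv(Pcov),
                np.linalg.inv(Mcov),
                np.linalg.inv(Ycov),
            )[perm_p]
            C = (WtRi @ W) + prior_csr

            rhs = WtRi @ (y_work - y_star)
            # C is symmetric positive definite: a symmetric fill-reducing
            # ordering with diagonal pivoting is both safe and much sparser
            lu = splu(
                C.tocsc(),
                permc_spec="MMD_AT_PLUS_A",
                options=dict(DiagPivotThresh=0.0, SymmetricMode=True),
            )
            theta = theta_star + lu.solve(rhs)

            # ---- 3. covariance draws -------------------------------------
            if "a" in terms:
                a_mat = theta[offsets["a"]: offsets["a"] + self._n_ped * k].reshape(
                    self._n_ped, k
                )
                S = a_mat.T @ (Ainv @ a_mat)
                Psi, nu = prior.psi_nu("a", k)
                G = _rinvwishart(rng, nu + self._n_ped, Psi + S)
            if "pe" in terms:
                p_mat = theta[offsets["pe"]: offsets["pe"] + sizes["pe"] * k].reshape(-1, k)
                Psi, nu = prior.psi_nu("pe", k)
                Pcov = _rinvwishart(rng, nu + sizes["pe"], Psi + p_mat.T @ p_mat)
            if "maternal" in terms and sizes["maternal"]:
                m_mat = theta[
                    offsets["maternal"]: offsets["maternal"] + sizes["maternal"] * k
                ].reshape(-1, k)
                Psi, nu = prior.psi_nu("maternal", k)
                Mcov = _rinvwishart(rng, nu + sizes["maternal"], Psi + m_mat.T @ m_mat)
            if "year" in terms:
                y_mat = theta[offsets["year"]: offsets["year"] + sizes["year"] * k].reshape(
                    -1, k
                )
                Psi, nu = prior.psi_nu("year", k)
                Ycov = _rinvwishart(rng, nu + sizes["year"], Psi + y_mat.T @ y_mat)

            # ---- scale moves -------------------------------------------
            # jointly rescale a term's effects and covariance (u' =
            # e^{eps/2} u, V' = e^eps V).  The u-prior ratio cancels
            # against the u-Jacobian, leaving likelihood x IW-prior x
            # e^{eps k(k+1)/2}.  This traverses the near-absorbing
            # direction at small variances, where plain Gibbs gets stuck.
            e_cur = y_work - W @ theta
            Ri_e = Rbig_inv @ e_cur
            for term in ("a", "pe"):
                if term not in terms or not sizes[term]:
                    continue
                o = offsets[term]
                nt = sizes[term] * k
                u = theta[o: o + nt]
                eps = 0.3 * rng.standard_normal()
                c = W[:, o: o + nt] @ u
                s_fac = np.exp(eps / 2.0) - 1.0
                e_new = e_cur - s_fac * c
                dll = -0.5 * (e_new @ (Rbig_inv @ e_new) - e_cur @ Ri_e)
                V = G if term == "a" else Pcov
                Psi, nu = prior.psi_nu(term, k)
                dlp = (
                    -(nu + k + 1) / 2.0 * k * eps
                    - 0.5 * np.trace(Psi @ np.linalg.inv(V)) * (np.exp(-eps) - 1.0)
                )
                logr = dll + dlp + eps * k * (k + 1) / 2.0
                if np.log(rng.random()) < logr:
                    theta[o: o + nt] = np.exp(eps / 2.0) * u
                    if term == "a":
                        G = np.exp(eps) * G
                    else:
                        Pcov = np.exp(eps) * Pcov
                    e_cur = e_new
                    Ri_e = Rbig_inv @ e_cur

            e_all = y_work - W @ theta
            for g in groups:
                tg = group_traits[g]
                kg = len(tg)
                Sg = np.zeros((kg, kg))
                n_units_g = 0
                for pid, p in enumerate(patterns):
                    pg = [t for t in p if t in tg]
                    if not pg:
                        continue
                    uix = units_of_pat[pid]
                    n_units_g += len(uix)
                    # residuals of this pattern's group traits (+ augmentation)
                    pos_in_p = [p.index(t) for t in pg]
                    rows = (
                        self._unit_start[uix][:, None] + np.asarray(pos_in_p)[None, :]
                    )
                    E_obs = e_all[rows]  # (n_units, len(pg))
                    obs_set = [tg.index(t) for t in pg]
                    mis_set = [j for j in range(kg) if j not in obs_set]
                    Rg = Rfull[np.ix_(tg, tg)]
                    if mis_set:
                        Roo = Rg[np.ix_(obs_set, obs_set)]
                        Rmo = Rg[np.ix_(mis_set, obs_set)]
                        Rmm = Rg[np.ix_(mis_set, mis_set)]
                        K = Rmo @ np.linalg.inv(Roo)
                        cond_cov = Rmm - K @ Rmo.T
                        Lc = chol_or_eig(cond_cov)
                        E_mis = E_obs @ K.T + rng.standard_normal(
                            (len(uix), len(mis_set))
                        ) @ Lc.T
                        E_full = np.empty((len(uix), kg))
                        E_full[:, obs_set] = E_obs
                        E_full[:, mis_set] = E_mis
                    else:
                        E_full = np.empty((len(uix), kg))
                        E_full[:, obs_set] = E_obs
                    Sg += E_full.T @ E_full
                Psi, nu = prior.psi_nu("residual", kg)
                Rg_new = _rinvwishart(rng, max(nu + n_units_g, kg), Psi + Sg)
                for ai, ti in enumerate(tg):
                    for bi, tj in enumerate(tg):
                        Rfull[ti, tj] = Rg_new[ai, bi]

            # ---- 4. store -----------------------------------------------
            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and s_ix < n_store:
                if "a" in terms:
                    store["G"][s_ix] = G
                if "pe" in terms:
                    store["pe"][s_ix] = Pcov
                if "maternal" in terms:
                    store["maternal"][s_ix] = Mcov if sizes["maternal"] else np.zeros((k, k))
                if "year" in terms:
                    store["year"][s_ix] = Ycov
                    store["year_eff"][s_ix] = theta[
                        offsets["year"]: offsets["year"] + sizes["year"] * k
                    ].reshape(-1, k)
                store["R"][s_ix] = Rfull
                store["fixed"][s_ix] = theta[:nb]
                if bv_store is not None:
                    bv_store[s_ix] = theta[
                        offsets["a"]: offsets["a"] + self._n_ped * k
                    ].reshape(self._n_ped, k)
                s_ix += 1
            if self.progress and (it + 1) % max(mcmc.iterations // 10, 1) == 0:
                print(f"  iteration {it + 1}/{mcmc.iterations}")

        diag = {}
        for key in ("G", "pe", "year", "R"):
            if key in store:
                for t_ix in range(k):
                    diag[f"{key}[{self.spec.traits[t_ix].name}] lag1"] = lag1_autocorr(
                        store[key][:s_ix, t_ix, t_ix]
                    )
        meta = {
            "iterations": mcmc.iterations,
            "burnin": mcmc.burnin,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
            "years": list(self._years),
            "n_records": int(N),
            "n_pedigree": int(self._n_ped),
            "diagnostics": diag,
            "date_center": self.date_center_,
            "date_scale": self.date_scale_,
        }
        self.posterior_ = VarCompPosterior(
            traits=self.spec.trait_names,
            samples={kk: vv[:s_ix] for kk, vv in store.items()},
            bv=bv_store[:s_ix] if bv_store is not None else None,
            ids=ped.ids,
            fixed_names=self.fixed_names_,
            meta=meta,
        )
        self.n_records_ = int(N)
        return self

    @property
    def posterior(self) -> VarCompPosterior:
        return self.posterior_


def fit_animal_model(
    phenotypes,
    pedigree: Pedigree,
    fitness=None,
    spec: ModelSpec | None = None,
    prior: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    **kw,
) -> VarCompPosterior:
    """Functional wrapper: fit and return the posterior."""
    model = AnimalModel(spec=spec, prior=prior, mcmc=mcmc, **kw)
    model.fit(phenotypes, pedigree, fitness=fitness)
    return model.posterior_


def heritability(
    post: VarCompPosterior, trait: str = "mass", include_year: bool = True
) -> np.ndarray:
    """Posterior samples of h^2 = V_A / V_P for one trait.

    ``V_P`` sums the additive, maternal, permanent-environment, residual
    and (by default) year variances; excluding the year variance is a
    legitimate alternative definition and is exposed via ``include_year``.
    """
    t = post.trait_index(trait)
    va = post.samples["G"][:, t, t]
    vp = va.copy()
    for level in ("pe", "maternal", "R"):
        if level in post.samples:
            vp = vp + post.samples[level][:, t, t]
    if include_year and "year" in post.samples:
        vp = vp + post.samples["year"][:, t, t]
    return va / vp


def genetic_correlation(
    post: VarCompPosterior, trait_pair: tuple = ("mass", "omega")
) -> dict:
    """Posterior of the additive genetic correlation between two traits.

    Draws with a zero variance for either trait are skipped; the count of
    skipped draws is reported alongside mode, HPD interval, and tail
    probabilities against 0 and 1.
    """
    i = post.trait_index(trait_pair[0])
    j = post.trait_index(trait_pair[1])
    G = post.samples["G"]
    denom = G[:, i, i] * G[:, j, j]
    ok = denom > 0
    rho = G[ok, i, j] / np.sqrt(denom[ok])
    lo, hi = hpd_interval(rho)
    return {
        "samples": rho,
        "mode": posterior_mode(rho),
        "hpd": (lo, hi),
        "p_vs_0": pmcmc(rho, 0.0),
        "p_vs_1": float(max(np.mean(rho < 1.0), 1.0 / rho.size)),
        "n_skipped": int(np.sum(~ok)),
    }
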