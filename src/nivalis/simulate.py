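"""Synthetic study-shaped data generator.

Emulates a small alpine rodent population monitored over ~9 years:
an overlapping-generations pedigree (~900 individuals), repeated
morphological measurements (mass, body length, tail length) with
additive-genetic / maternal / permanent-environment / year / residual
(co)variance structure, a Gaussian relative-fitness trait whose genetic
and environmental covariances with the morphological traits are set by
configuration, monomolecular juvenile growth with litter structure, and
snow-season-dependent overwinter survival of juveniles.

Every simulated quantity is recorded in a :class:`SyntheticTruth` ledger
so that downstream estimators can be tested by parameter recovery.

Design notes
------------
* Relative fitness (omega) is generated directly as a Gaussian trait:
  ``omega = 1 + a_omega + pe_omega`` with the environmental trait-fitness
  covariance injected at the permanent-environment level and zero
  residual variance.  This mirrors the convention used when fitness is
  included as a response in a multivariate animal model (residual
  variance of fitness fixed to zero, the permanent-environment term
  carrying its non-additive variance).  The stored ``lrs`` column is a
  scaled version of this trait; it emulates relative fitness on the
  analysis scale, not an integer offspring count.  A "demographic" mode
  instead takes lifetime reproductive success from the realized pedigree,
  which is what the Robertson-Price forward-consistency checks need.
* Juvenile overwinter survival defaults to the growth-based logistic
  model (asymptotic mass, sex, days to first snowfall, and their
  interaction), so the generator's default world has snowfall-dependent
  viability selection on potential adult mass.
* A single seed drives named substreams per stage, so adding a stage
  never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree, validate_pedigree

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "SimulationExtinctError",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes_and_fitness",
    "simulate_growth_histories",
    "simulate_dataset",
    "stage_rng",
]

TRAITS = ("mass", "length", "tail", "omega")


class SimulationExtinctError(RuntimeError):
    """The simulated population died out before the requested horizon."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for a named stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def _default_G() -> np.ndarray:
    # order: mass (g), length (mm), tail (mm), omega (relative fitness)
    vm, vl, vt, vw = 4.34, 8.0, 5.0, 0.10
    rho_ml, rho_mt, rho_lt = 0.79, 0.40, 0.56
    cov_mw, cov_lw, cov_tw = -0.35, -0.12, -0.05
    G = np.array(
        [
            [vm, rho_ml * np.sqrt(vm * vl), rho_mt * np.sqrt(vm * vt), cov_mw],
            [0, vl, rho_lt * np.sqrt(vl * vt), cov_lw],
            [0, 0, vt, cov_tw],
            [0, 0, 0, vw],
        ]
    )
    return G + np.triu(G, 1).T


def _default_maternal() -> np.ndarray:
    return np.diag([1.0, 2.0, 1.0, 0.0])


def _default_pe() -> np.ndarray:
    # environmental trait-fitness covariance lives here (residual variance
    # of omega is zero); cov(mass, omega) chosen so the phenotypic
    # differential is positive while the genetic one is negative.
    P = np.diag([4.0, 6.0, 4.0, 1.57])
    P[0, 3] = P[3, 0] = 1.21
    P[0, 1] = P[1, 0] = 1.5
    return P


def _default_year() -> np.ndarray:
    return np.diag([2.0, 3.0, 2.0, 0.0])


def _default_residual() -> np.ndarray:
    R = np.diag([10.0, 12.0, 8.0, 0.0])
    R[0, 1] = R[1, 0] = 3.0
    R[0, 2] = R[2, 0] = 1.5
    R[1, 2] = R[2, 1] = 2.0
    return R


@dataclass
class SimulationConfig:
    """Declared parameter set for a synthetic dataset.

    Covariance matrices are 4x4 over (mass, length, tail, omega).
    Defaults target the scale of the study system: ~80 founders, 9
    yearly cohorts, ~900 individuals, 3 trapping sessions per season,
    adult mass ~41.7 g, measurement-error SD 2.05 g, reproduction
    starting ~40 d after snowmelt, max 5 litters per female-year spaced
    >= 20 d apart, and overwinter survival of juveniles following a
    logistic model in potential adult mass with a days-to-first-snowfall
    interaction.
    """

    n_founders: int = 70
    n_years: int = 9
    start_year: int = 2006
    seed: int = 0

    # demography (high turnover: most breeders are yearlings, so the
    # realized generation time is short, as in the study system)
    adult_survival: float = 0.3
    litter_probs: tuple = (0.1, 0.45, 0.45)  # P(0, 1, 2... litters) per female-year
    litter_size_mean: float = 1.2  # size = 1 + Poisson(mean), capped
    litter_size_max: int = 6
    max_litters: int = 5
    fecundity_bv_slope: float = 0.0  # log-scale fecundity weight per g of mass BV
    fecundity_pe_slope: float = 0.0  # same, per g of mass permanent-environment
    # deviation: a positive value makes good sites boost both mass and
    # reproduction, creating a non-causal mass-fitness association
    juvenile_survival_mode: str = "growth"  # "growth" | "demographic"
    juvenile_survival: float = 0.45  # demographic-mode mean
    juvenile_survival_bv_slope: float = 0.0  # demographic-mode logit slope per g BV
    adult_survival_bv_slope: float = 0.0
    max_individuals: int = 20000

    # trait (co)variances at each level
    G: np.ndarray = field(default_factory=_default_G)
    maternal_cov: np.ndarray = field(default_factory=_default_maternal)
    pe_cov: np.ndarray = field(default_factory=_default_pe)
    year_cov: np.ndarray = field(default_factory=_default_year)
    residual_cov: np.ndarray = field(default_factory=_default_residual)

    # fixed effects for (mass, length, tail); intercepts are adult female
    # means, chosen so the population mean adult mass is ~41.7 g
    intercepts: tuple = (41.5, 110.0, 55.0)
    sex_effects: tuple = (2.0, 3.0, 1.0)  # male - female
    juvenile_offsets: tuple = (-15.0, -20.0, -8.0)
    date_lin: tuple = (0.5, 0.5, 0.2)  # per SD of Julian date
    date_quad: tuple = (-0.8, -0.5, -0.2)
    inbreeding_depression: tuple = (0.0, 0.0, 0.0)

    # linear trend injected into the mass year effects (g per year).  The
    # default emulates cryptic evolution: a plastic increase of ~0.15 g/y
    # partly masks the genetic decline produced by viability selection,
    # leaving a small positive phenotypic trend.
    year_trend_mass: float = 0.15

    # fitness bookkeeping
    fitness_mode: str = "gaussian"  # "gaussian" | "demographic"
    omega_mean: float = 1.0
    lrs_base: float = 2.0
    ars_pe_slope: float = 0.1
    ars_noise_sd: float = 0.3

    # capture schedule (Julian day of year, 1-based); five sessions per
    # season, as in the denser monitoring years
    session_days: tuple = (150, 175, 200, 225, 250)
    juvenile_min_capture_age: float = 25.0

    # growth curves
    growth_asym_env_sd: float = 3.5
    growth_rate_log_mean: float = float(np.log(0.023))
    growth_rate_log_sd: float = 0.25
    growth_corr_a_logk: float = -0.08
    measurement_error_sd: float = 2.05

    # phenology and litter placement
    birth_lag_after_snowmelt: float = 40.0
    birth_lag_jitter: float = 12.0  # exponential mean, first litter
    litter_spacing_min: float = 20.0
    litter_spacing_jitter: float = 8.0  # exponential mean on top of the minimum

    # overwinter survival (logit scale)
    surv_intercept: float = 12.3
    surv_sex_male: float = -0.2
    surv_mass: float = -0.33
    surv_days: float = -0.09
    surv_interaction: float = 0.0025

    # snow seasons: explicit lists override the two-era pattern
    snowmelt_days: tuple | None = None
    snowfall_days: tuple | None = None
    n_long_years: int = 2
    snowmelt_long: float = 110.0
    snowfall_long: float = 300.0
    snowmelt_short: float = 125.0
    snowfall_short: float = 268.0
    snow_jitter_sd: float = 4.0

    def __post_init__(self):
        for name in ("G", "maternal_cov", "pe_cov", "year_cov", "residual_cov"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        for name in ("G", "maternal_cov", "pe_cov", "year_cov", "residual_cov"):
            M = getattr(self, name)
            if M.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4 over {TRAITS}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} is not symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-8:
                raise ValueError(f"{name} is not positive semi-definite")
        if self.n_founders < 4:
            raise ValueError("need at least 2 founders of each sex")
        if self.residual_cov[3, 3] != 0 or np.any(self.residual_cov[3, :3] != 0):
            raise ValueError("omega residual (co)variances must be zero by convention")
        melt, fall = self.snow_schedule()
        if np.any(fall <= melt):
            raise ValueError("first snowfall before snowmelt in at least one year")
        out = [d for d in self.session_days if np.any(d < melt) or np.any(d > fall)]
        if out:
            raise ValueError(f"capture sessions outside the snow-free season: {out}")

    def snow_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-year (snowmelt_day, first_snowfall_day), deterministic in seed."""
        if self.snowmelt_days is not None and self.snowfall_days is not None:
            melt = np.asarray(self.snowmelt_days, dtype=float)
            fall = np.asarray(self.snowfall_days, dtype=float)
            if len(melt) != self.n_years or len(fall) != self.n_years:
                raise ValueError("snow schedules must have one entry per year")
            return melt, fall
        rng = stage_rng(self.seed, "snow")
        long = np.arange(self.n_years) < self.n_long_years
        melt = np.where(long, self.snowmelt_long, self.snowmelt_short)
        fall = np.where(long, self.snowfall_long, self.snowfall_short)
        melt = melt + rng.normal(0, self.snow_jitter_sd, self.n_years)
        fall = fall + rng.normal(0, self.snow_jitter_sd, self.n_years)
        return melt, fall

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("G", "maternal_cov", "pe_cov", "year_cov", "residual_cov"):
            if k in d:
                d[k] = np.asarray(d[k], dtype=float)
        for k in ("litter_probs", "session_days", "intercepts", "sex_effects",
                  "juvenile_offsets", "date_lin", "date_quad", "inbreeding_depression",
                  "snowmelt_days", "snowfall_days"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Generating-parameter ledger for a simulated dataset."""

    config: SimulationConfig
    ids: list
    bv: np.ndarray  # (n, 4) true breeding values
    pe: np.ndarray  # (n, 4) permanent-environment deviations
    maternal: np.ndarray  # (n, 4) maternal deviation received by each individual
    year_effects: np.ndarray  # (n_years, 4)
    omega: np.ndarray  # (n,) generating relative fitness
    lrs: np.ndarray  # (n,) realized offspring counts from the pedigree
    alive_years: dict  # id -> list of years alive (observed)
    survived: dict  # (id, year) -> 0/1 survival to the next year
    litters: pd.DataFrame  # mother, year, litter, t0
    growth: pd.DataFrame  # id, mother, year, litter, t0, a, k, sex, days_to_snowfall, survived
    snowmelt: np.ndarray
    snowfall: np.ndarray

    @property
    def index(self) -> dict:
        return {i: k for k, i in enumerate(self.ids)}

    def realized_level_cov(self, level: str) -> np.ndarray:
        """Realized covariance matrix of the stored draws at one level."""
        mat = {"a": self.bv, "pe": self.pe, "maternal": self.maternal}[level]
        return np.cov(mat.T)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "ids": list(self.ids),
            "bv": self.bv.tolist(),
            "pe": self.pe.tolist(),
            "maternal": self.maternal.tolist(),
            "year_effects": self.year_effects.tolist(),
            "omega": self.omega.tolist(),
            "lrs": self.lrs.tolist(),
            "alive_years": {k: list(map(int, v)) for k, v in self.alive_years.items()},
            "survived": {f"{i}|{y}": int(s) for (i, y), s in self.survived.items()},
            "litters": self.litters.to_dict(orient="list"),
            "growth": self.growth.to_dict(orient="list"),
            "snowmelt": self.snowmelt.tolist(),
            "snowfall": self.snowfall.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            p = json.load(fh)
        survived = {}
        for key, s in p["survived"].items():
            i, y = key.rsplit("|", 1)
            survived[(i, int(y))] = s
        return cls(
            config=SimulationConfig.from_dict(p["config"]),
            ids=list(p["ids"]),
            bv=np.asarray(p["bv"]),
            pe=np.asarray(p["pe"]),
            maternal=np.asarray(p["maternal"]),
            year_effects=np.asarray(p["year_effects"]),
            omega=np.asarray(p["omega"]),
            lrs=np.asarray(p["lrs"]),
            alive_years={k: list(v) for k, v in p["alive_years"].items()},
            survived=survived,
            litters=pd.DataFrame(p["litters"]),
            growth=pd.DataFrame(p["growth"]),
            snowmelt=np.asarray(p["snowmelt"]),
            snowfall=np.asarray(p["snowfall"]),
        )


def _psd_chol(M: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of zero eigenvalues."""
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Drop multivariate breeding values down a pedigree.

    Founders (and unknown parental contributions) draw from ``N(0, G)``;
    offspring draw ``N(midparent, d_i G)`` where ``d_i`` is the Mendelian
    sampling variance adjusted for parental inbreeding.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if not np.allclose(G, G.T) or np.min(np.linalg.eigvalsh(G)) < -1e-10:
        raise ValueError("G must be symmetric positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .pedigree import inbreeding_coefficients, mendelian_sampling_variance

    F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    L = _psd_chol(G)
    k = G.shape[0]
    n = len(ped)
    bv = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        mid = np.zeros(k)
        if s >= 0:
            mid += 0.5 * bv[s]
        if dm >= 0:
            mid += 0.5 * bv[dm]
        bv[i] = mid + np.sqrt(d[i]) * (L @ z[i])
    return bv


class _Simulator:
    """One integrated pass: demography, breeding values, growth, survival."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = stage_rng(config.seed, "pedigree")
        n_max = config.max_individuals
        self.A = np.zeros((0, 0))  # grown incrementally for inbreeding
        self.ids: list[str] = []
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.sex: list[str] = []
        self.cohort: list[int] = []
        self.bv: list[np.ndarray] = []
        self.pe: list[np.ndarray] = []
        self.maternal: list[np.ndarray] = []
        self.omega_latent: list[float] = []
        self.n_offspring: list[int] = []
        self.alive_years: dict[str, list[int]] = {}
        self.survived: dict[tuple, int] = {}
        self.litters: list[dict] = []
        self.growth: list[dict] = []
        self.L_G = _psd_chol(config.G)
        self.L_pe = _psd_chol(config.pe_cov)
        self.L_mat = _psd_chol(config.maternal_cov)
        self.n_max = n_max

    # -- incremental pedigree bookkeeping ------------------------------
    def _grow_A(self) -> None:
        n = len(self.ids)
        if self.A.shape[0] < n:
            newA = np.zeros((max(2 * n, 64), max(2 * n, 64)))
            m = self.A.shape[0]
            newA[:m, :m] = self.A
            self.A = newA

    def add_individual(self, sire: int, dam: int, sex: str, cohort: int) -> int:
        i = len(self.ids)
        if i >= self.n_max:
            raise RuntimeError("simulation exceeded max_individuals")
        self.ids.append(f"I{i:05d}")
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex.append(sex)
        self.cohort.append(cohort)
        self._grow_A()
        A = self.A
        row = np.zeros(i)
        for p in (sire, dam):
            if p >= 0:
                row += 0.5 * A[p, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[sire, dam] if sire >= 0 and dam >= 0 else 0.0)
        # Mendelian sampling
        Fs = A[sire, sire] - 1.0 if sire >= 0 else None
        Fd = A[dam, dam] - 1.0 if dam >= 0 else None
        if Fs is not None and Fd is not None:
            d_i = 0.5 - 0.25 * (Fs + Fd)
        elif Fs is not None:
            d_i = 0.75 - 0.25 * Fs
        elif Fd is not None:
            d_i = 0.75 - 0.25 * Fd
        else:
            d_i = 1.0
        mid = np.zeros(4)
        if sire >= 0:
            mid += 0.5 * self.bv[sire]
        if dam >= 0:
            mid += 0.5 * self.bv[dam]
        self.bv.append(mid + np.sqrt(max(d_i, 0.0)) * (self.L_G @ self.rng.standard_normal(4)))
        self.pe.append(self.L_pe @ self.rng.standard_normal(4))
        self.maternal.append(
            self.maternal_of(dam) if dam >= 0 else np.zeros(4)
        )
        self.n_offspring.append(0)
        return i

    def maternal_of(self, dam: int) -> np.ndarray:
        # each female carries one maternal deviation, drawn on first use
        if not hasattr(self, "_mat_dev"):
            self._mat_dev: dict[int, np.ndarray] = {}
        if dam not in self._mat_dev:
            self._mat_dev[dam] = self.L_mat @ self.rng.standard_normal(4)
        return self._mat_dev[dam]

    # -- growth and survival -------------------------------------------
    def growth_params(self, i: int) -> tuple[float, float]:
        cfg = self.cfg
        a = (
            cfg.intercepts[0]
            + cfg.sex_effects[0] * (self.sex[i] == "M")
            + self.bv[i][0]
            + self.rng.normal(0, cfg.growth_asym_env_sd)
        )
        a = max(a, 5.0)
        z = self.rng.standard_normal()
        rho = cfg.growth_corr_a_logk
        a_std = (a - cfg.intercepts[0]) / max(
            np.sqrt(cfg.G[0, 0] + cfg.growth_asym_env_sd**2), 1e-9
        )
        logk = cfg.growth_rate_log_mean + cfg.growth_rate_log_sd * (
            rho * a_std + np.sqrt(max(1 - rho**2, 0.0)) * z
        )
        return a, float(np.exp(logk))

    def juvenile_survives(self, i: int, a: float, t0: float, year_ix: int) -> tuple[int, float]:
        cfg = self.cfg
        days = self.snowfall[year_ix] - t0
        if cfg.juvenile_survival_mode == "growth":
            eta = (
                cfg.surv_intercept
                + cfg.surv_sex_male * (self.sex[i] == "M")
                + cfg.surv_mass * a
                + cfg.surv_days * days
                + cfg.surv_interaction * a * days
            )
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            base = np.log(cfg.juvenile_survival / (1 - cfg.juvenile_survival))
            eta = base + cfg.juvenile_survival_bv_slope * self.bv[i][0]
            p = 1.0 / (1.0 + np.exp(-eta))
        return int(self.rng.random() < p), days

    def adult_survives(self, i: int) -> int:
        cfg = self.cfg
        base = np.log(cfg.adult_survival / (1 - cfg.adult_survival))
        eta = base + cfg.adult_survival_bv_slope * self.bv[i][0]
        return int(self.rng.random() < 1.0 / (1.0 + np.exp(-eta)))

    # -- main loop ------------------------------------------------------
    def run(self) -> None:
        cfg = self.cfg
        self.snowmelt, self.snowfall = cfg.snow_schedule()
        rng = self.rng
        n_f = cfg.n_founders
        founder_cohort = cfg.start_year - 1
        for j in range(n_f):
            sex = "F" if j < n_f // 2 else "M"
            self.add_individual(-1, -1, sex, founder_cohort)
        adults = list(range(n_f))

        for y in range(cfg.n_years):
            year = cfg.start_year + y
            females = [i for i in adults if self.sex[i] == "F"]
            males = [i for i in adults if self.sex[i] == "M"]
            if not females or not males:
                raise SimulationExtinctError(
                    f"population extinct in year {year}: "
                    f"{len(females)} females, {len(males)} males"
                )
            for i in adults:
                self.alive_years.setdefault(self.ids[i], []).append(year)

            male_w = np.array(
                [np.exp(cfg.fecundity_bv_slope * self.bv[i][0]
                        + cfg.fecundity_pe_slope * self.pe[i][0]) for i in males]
            )
            male_w = male_w / male_w.sum()

            juveniles_born: list[int] = []
            for f in females:
                fec = np.exp(cfg.fecundity_bv_slope * self.bv[f][0]
                             + cfg.fecundity_pe_slope * self.pe[f][0])
                probs = np.asarray(cfg.litter_probs, dtype=float)
                n_lit = min(int(rng.choice(len(probs), p=probs / probs.sum())), cfg.max_litters)
                t0 = self.snowmelt[y] + cfg.birth_lag_after_snowmelt + rng.exponential(
                    cfg.birth_lag_jitter
                )
                for li in range(n_lit):
                    if li > 0:
                        t0 = t0 + cfg.litter_spacing_min + rng.exponential(
                            cfg.litter_spacing_jitter
                        )
                    if t0 > self.snowfall[y] - 5:
                        break
                    size = 1 + rng.poisson(cfg.litter_size_mean * fec)
                    size = min(size, cfg.litter_size_max)
                    sire = males[rng.choice(len(males), p=male_w)]
                    self.litters.append(
                        {"mother": self.ids[f], "year": year, "litter": li, "t0": float(t0)}
                    )
                    for _ in range(size):
                        sex = "F" if rng.random() < 0.5 else "M"
                        i = self.add_individual(sire, f, sex, year)
                        self.n_offspring[sire] += 1
                        self.n_offspring[f] += 1
                        a, kk = self.growth_params(i)
                        surv, days = self.juvenile_survives(i, a, t0, y)
                        self.alive_years.setdefault(self.ids[i], []).append(year)
                        self.survived[(self.ids[i], year)] = surv
                        self.growth.append(
                            {
                                "id": self.ids[i],
                                "mother": self.ids[f],
                                "year": year,
                                "litter": li,
                                "t0": float(t0),
                                "a": float(a),
                                "k": float(kk),
                                "sex": sex,
                                "days_to_snowfall": float(days),
                                "survived": surv,
                            }
                        )
                        if surv:
                            juveniles_born.append(i)

            survivors = []
            for i in adults:
                s = self.adult_survives(i)
                self.survived[(self.ids[i], year)] = s
                if s:
                    survivors.append(i)
            adults = survivors + juveniles_born

    def finish(self) -> tuple[Pedigree, SyntheticTruth]:
        cfg = self.cfg
        n = len(self.ids)
        frame = pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s >= 0 else "" for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else "" for d in self.dam],
                "sex": self.sex,
                "cohort": self.cohort,
            }
        )
        ped = validate_pedigree(frame)
        # generator order == topological order (parents added first), but
        # re-index defensively through the validated pedigree
        order = [self.ids.index(i) for i in ped.ids] if list(ped.ids) != self.ids else None
        bv = np.vstack(self.bv)
        pe = np.vstack(self.pe)
        mat = np.vstack(self.maternal)
        if order is not None:
            bv, pe, mat = bv[order], pe[order], mat[order]
        year_eff = stage_rng(cfg.seed, "year-effects").standard_normal(
            (cfg.n_years, 4)
        ) @ _psd_chol(cfg.year_cov).T
        tt = np.arange(cfg.n_years, dtype=float)
        year_eff[:, 0] += cfg.year_trend_mass * (tt - tt.mean())
        lrs = np.asarray(self.n_offspring, dtype=float)
        if order is not None:
            lrs = lrs[order]
        omega = cfg.omega_mean + bv[:, 3] + pe[:, 3]
        truth = SyntheticTruth(
            config=cfg,
            ids=list(ped.ids),
            bv=bv,
            pe=pe,
            maternal=mat,
            year_effects=year_eff,
            omega=omega,
            lrs=lrs,
            alive_years=self.alive_years,
            survived=self.survived,
            litters=pd.DataFrame(self.litters),
            growth=pd.DataFrame(self.growth),
            snowmelt=self.snowmelt,
            snowfall=self.snowfall,
        )
        return ped, truth


def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, SyntheticTruth]:
    """Simulate the overlapping-generations pedigree and its truth ledger.

    The pass also draws breeding values, growth parameters and survival
    outcomes, because demography may depend on all of them.
    """
    sim = _Simulator(config)
    sim.run()
    return sim.finish()


def _scaled_date(day, cfg: SimulationConfig) -> np.ndarray:
    center = float(np.mean(cfg.session_days))
    scale = float(np.std(cfg.session_days)) or 1.0
    return (np.asarray(day, dtype=float) - center) / scale


def simulate_phenotypes_and_fitness(
    ped: Pedigree, truth: SyntheticTruth, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the long-format phenotype table and the fitness table.

    Phenotype records follow the additive decomposition
    ``fixed + breeding value + maternal + permanent environment + year +
    residual`` at each scheduled capture.  Fitness carries the generating
    relative-fitness trait (``gaussian`` mode) or realized relative LRS
    (``demographic`` mode), plus annual reproduction and survival columns.
    """
    cfg = config or truth.config
    rng = stage_rng(cfg.seed, "phenotypes")
    ix = truth.index
    L_R = _psd_chol(cfg.residual_cov[:3, :3])
    years = [cfg.start_year + t for t in range(cfg.n_years)]
    growth_by_id = (
        truth.growth.set_index("id") if len(truth.growth) else pd.DataFrame()
    )

    rows = []
    for iid, alive in truth.alive_years.items():
        i = ix[iid]
        sex = ped.sex[i]
        born = ped.cohort[i]
        for year in alive:
            t = year - cfg.start_year
            if t < 0 or t >= cfg.n_years:
                continue
            is_juv = year == born
            for day in cfg.session_days:
                if is_juv:
                    if iid not in getattr(growth_by_id, "index", []):
                        continue
                    t0 = growth_by_id.loc[iid, "t0"]
                    if day < t0 + cfg.juvenile_min_capture_age:
                        continue
                d = _scaled_date(day, cfg)
                resid = L_R @ rng.standard_normal(3)
                vals = []
                for j in range(3):
                    mu = (
                        cfg.intercepts[j]
                        + cfg.sex_effects[j] * (sex == "M")
                        + cfg.juvenile_offsets[j] * is_juv
                        + cfg.date_lin[j] * d
                        + cfg.date_quad[j] * d**2
                        + truth.bv[i, j]
                        + truth.maternal[i, j]
                        + truth.pe[i, j]
                        + truth.year_effects[t, j]
                        + resid[j]
                    )
                    vals.append(float(mu))
                rows.append(
                    {
                        "id": iid,
                        "date": int(day),
                        "age_class": "juvenile" if is_juv else "adult",
                        "sex": sex,
                        "mass": vals[0],
                        "body_length": vals[1],
                        "tail_length": vals[2],
                        "year": year,
                    }
                )
    phenotypes = pd.DataFrame(rows)

    # fitness table: one row per individual-year alive
    frows = []
    if cfg.fitness_mode == "demographic":
        lrs_vec = truth.lrs
    else:
        lrs_vec = cfg.lrs_base * truth.omega
    for iid, alive in truth.alive_years.items():
        i = ix[iid]
        for year in alive:
            ars = (
                1.0
                + 0.5 * (truth.omega[i] - 1.0)
                + cfg.ars_pe_slope * truth.pe[i, 0]
                + rng.normal(0, cfg.ars_noise_sd)
            )
            frows.append(
                {
                    "id": iid,
                    "sex": ped.sex[i],
                    "cohort": int(ped.cohort[i]),
                    "lrs": float(lrs_vec[i]),
                    "year": int(year),
                    "ars": float(ars),
                    "survived": int(truth.survived.get((iid, year), 0)),
                }
            )
    fitness = pd.DataFrame(frows)
    return phenotypes, fitness


def simulate_growth_histories(
    ped: Pedigree, truth: SyntheticTruth, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Capture-history table for juveniles plus the snow-season table.

    Observed masses follow the monomolecular curve
    ``m(t) = a_i (1 - exp(-k_i (t - t0)))`` with Gaussian measurement
    error (SD ``measurement_error_sd``) at every scheduled session the
    juvenile is old enough to be trapped at.
    """
    cfg = config or truth.config
    rng = stage_rng(cfg.seed, "growth-observations")
    rows = []
    for rec in truth.growth.itertuples():
        for day in cfg.session_days:
            age = day - rec.t0
            if age < cfg.juvenile_min_capture_age:
                continue
            mu = rec.a * (1.0 - np.exp(-rec.k * age))
            rows.append(
                {
                    "id": rec.id,
                    "mother": rec.mother,
                    "year": int(rec.year),
                    "julian_day": int(day),
                    "mass": float(mu + rng.normal(0, cfg.measurement_error_sd)),
                }
            )
    captures = pd.DataFrame(rows)
    snow = pd.DataFrame(
        {
            "year": [cfg.start_year + t for t in range(cfg.n_years)],
            "snowmelt_day": truth.snowmelt,
            "first_snowfall_day": truth.snowfall,
        }
    )
    return captures, snow


@dataclass
class SyntheticDataset:
    """A complete simulated dataset plus its truth ledger."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    fitness: pd.DataFrame
    captures: pd.DataFrame
    snow: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_csv(out / "pedigree.csv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        self.fitness.to_csv(out / "fitness.csv", index=False)
        self.captures.to_csv(out / "captures.csv", index=False)
        self.snow.to_csv(out / "snow.csv", index=False)
        self.truth.to_json(out / "truth.json")


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """One-call generation of a full study-shaped dataset."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    ped, truth = simulate_pedigree(cfg)
    phenotypes, fitness = simulate_phenotypes_and_fitness(ped, truth, cfg)
    captures, snow = simulate_growth_histories(ped, truth, cfg)
    return SyntheticDataset(ped, phenotypes, fitness, captures, snow, truth)
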