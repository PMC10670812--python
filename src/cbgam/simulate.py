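"""Synthetic-cohort generator.

Emulates the tabular structure of a newly diagnosed breast-cancer staging
cohort: clinical variables (age, BMI, TNM, histology, molecular subtype,
ki-67), PET semiquantitative primary-tumor (PT) features (volume, SUVmax,
SUVmean, MTV, TLG with the definitional coupling TLG = SUVmean x MTV), and
outcome endpoints (clinical benefit, death, progression, OS, PFS).

The generator's defaults reproduce the published cohort's marginal moments
(e.g. age 63.3 +/- 15.4 y, PT volume 12.8 +/- 30.4 cm^3, CB prevalence
55/70) and encode a known ground-truth outcome model — saturating
(piecewise-linear plateau) effects of PT volume and TLG on the CB log-odds,
a dominant M-stage shift, and minor age/BMI terms — so that every
downstream estimation stage can be tested against generator truth.

Distributional choices
----------------------
* PT volume is log-normal, moment-matched to mean/sd: with sd more than
  twice the mean a normal cannot stay positive; the log-normal reproduces
  the heavy right tail.
* MTV is volume times a log-normal noise factor near 1 (the two are
  numerically indistinguishable on real measurements), giving a
  configurable correlation (default > 0.99) that exercises the
  correlation-filtering stage.
* SUVmean is SUVmax times a Beta-distributed ratio with mean set by the
  configured marginal means, enforcing SUVmean <= SUVmax by construction.
* Bounded normals (age, BMI, glucose, ki-67, ...) are truncated normals
  whose underlying parameters are solved so the *truncated* mean and sd
  equal the configured ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort import attach_cb

__all__ = [
    "ContinuousMarginal",
    "EffectSpec",
    "SurvivalSpec",
    "GeneratorConfig",
    "TrueEffect",
    "true_partial_effect",
    "assign_outcome",
    "generate_cohort",
]


@dataclass
class ContinuousMarginal:
    """Target mean/sd of one continuous variable with optional bounds."""

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TrueEffect:
    """Piecewise-linear saturating ground-truth effect on the CB log-odds.

    f(x) = slope * min(x, plateau_onset): linear below the plateau onset,
    constant beyond it (the generator's notion of "influence becoming
    negligible beyond a cutoff").
    """

    variable: str
    slope: float
    plateau_onset: float

    def __post_init__(self):
        if self.plateau_onset <= 0:
            raise ValueError("plateau_onset must be > 0")

    def __call__(self, x):
        return self.slope * np.minimum(np.asarray(x, dtype=float), self.plateau_onset)


def true_partial_effect(effect: TrueEffect, x_grid) -> np.ndarray:
    """Ground-truth effect on a grid, centered to mean zero over the grid."""
    f = effect(x_grid)
    return f - f.mean()


@dataclass
class EffectSpec:
    """True outcome model on the log-odds scale.

    Volume/TLG act through saturating raw-unit effects; M stage through a
    log-odds shift; age and BMI through small per-SD coefficients.  The
    intercept default is calibrated so the default cohort's CB prevalence
    matches 55/70.
    """

    intercept: float = 3.4754
    volume_slope: float = -0.09       # per cm^3, below the plateau
    volume_plateau: float = 30.0      # cm^3
    tlg_slope: float = -0.015         # per SUV*cm^3, below the plateau
    tlg_plateau: float = 160.0        # SUV*cm^3
    m1_shift: float = -2.5            # log-odds shift for M1 vs M0
    age_coef: float = 0.1             # per SD of age
    bmi_coef: float = -0.1            # per SD of BMI

    def __post_init__(self):
        if self.volume_plateau <= 0 or self.tlg_plateau <= 0:
            raise ValueError("plateau onsets must be > 0")

    def true_effects(self) -> dict[str, TrueEffect]:
        return {
            "pt_volume": TrueEffect("pt_volume", self.volume_slope, self.volume_plateau),
            "tlg": TrueEffect("tlg", self.tlg_slope, self.tlg_plateau),
        }


@dataclass
class SurvivalSpec:
    """Event-time model conditional on CB status.

    CB patients reach last follow-up event-free (OS = PFS = follow-up).
    No-CB patients progress at a truncated-exponential time within the
    follow-up window; a third of them (the published death fraction among
    no-CB, 5/15) additionally die at a uniform time between progression and
    follow-up.
    """

    progression_scale: float = 60.0          # months (exponential scale)
    death_prob_no_cb: float = 1.0 / 3.0
    follow_up_window: tuple[float, float] = (12.0, 56.0)  # months

    def __post_init__(self):
        lo, hi = self.follow_up_window
        if not (0 < lo <= hi):
            raise ValueError("follow-up window must satisfy 0 < lo <= hi")
        if not 0 <= self.death_prob_no_cb <= 1:
            raise ValueError("death_prob_no_cb must be a probability")


def _default_continuous() -> dict[str, ContinuousMarginal]:
    return {
        "age": ContinuousMarginal(63.3, 15.4, lower=18.0),
        "bmi": ContinuousMarginal(26.5, 5.7, lower=12.0),
        "blood_glucose": ContinuousMarginal(5.7, 0.9, lower=2.0),
        "injected_activity": ContinuousMarginal(304.8, 102.1, lower=50.0),
        "dlp": ContinuousMarginal(833.6, 388.5, lower=50.0),
        "ki67": ContinuousMarginal(35.1, 24.5, lower=0.0, upper=100.0),
        "suv_max": ContinuousMarginal(8.1, 7.2, lower=0.0),
        "suv_mean": ContinuousMarginal(4.9, 4.4, lower=0.0),
        # upper bound: primary breast tumors beyond ~400 cm^3 are anatomically
        # implausible; truncation also tames the log-normal's extreme kurtosis
        "pt_volume": ContinuousMarginal(12.8, 30.4, lower=0.0, upper=400.0),
        "mtv": ContinuousMarginal(12.7, 30.4, lower=0.0, upper=400.0),
    }


def _default_categorical() -> dict[str, dict]:
    # frequencies of the published 70-patient cohort; scanner split reflects
    # the two acquisition eras (~2017-2020 vs 2020-2021)
    return {
        "site": {"right": 33 / 70, "left": 37 / 70},
        "quadrant": {
            "central": 7 / 70,
            "upper-inner": 11 / 70,
            "lower-inner": 7 / 70,
            "upper-outer": 28 / 70,
            "lower-outer": 16 / 70,
            "unspecified": 1 / 70,
        },
        "histology": {
            "ductal": 62 / 70,
            "lobular": 5 / 70,
            "papillary": 1 / 70,
            "mucinous": 1 / 70,
            "apocrine": 1 / 70,
        },
        "subtype": {"A": 13 / 70, "B": 36 / 70, "H": 6 / 70, "N": 15 / 70},
        "t_stage": {1: 21 / 70, 2: 34 / 70, 3: 2 / 70, 4: 13 / 70},
        "n_stage": {0: 19 / 70, 1: 34 / 70, 2: 6 / 70, 3: 11 / 70},
        "m_stage": {0: 58 / 70, 1: 12 / 70},
        "margin": {"sharp": 10 / 70, "irregular": 55 / 70, "spiculated": 5 / 70},
        "morphology": {"solid": 66 / 70, "inflammatory": 4 / 70},
        "scanner": {"biograph40": 0.6, "dmi64": 0.4},
    }


@dataclass
class GeneratorConfig:
    n_patients: int = 70
    seed: int = 0
    continuous_marginals: dict[str, ContinuousMarginal] = field(
        default_factory=_default_continuous
    )
    categorical_marginals: dict[str, dict] = field(default_factory=_default_categorical)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    mtv_noise_sd: float = 0.02        # log-sd of the MTV/volume ratio
    suv_ratio_concentration: float = 20.0  # Beta a+b for SUVmean/SUVmax
    # SUVmean/SUVmax ratio declines with tumor volume (necrotic cores lower
    # mean uptake in bulky tumors); the published moments themselves imply
    # negative SUVmean-MTV covariance (E[TLG] < E[SUVmean]*E[MTV]).
    suv_ratio_level: float = 0.591    # Beta mean of the base ratio (calibrated)
    suv_volume_exponent: float = 0.15  # gamma in ratio ~ (V / median V)^-gamma
    suv_ratio_cap: float = 0.98       # keeps SUVmean < SUVmax

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name, table in self.categorical_marginals.items():
            probs = np.array(list(table.values()), dtype=float)
            if (probs < 0).any():
                raise ValueError(f"negative probability in table {name!r}")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"probability table {name!r} sums to {probs.sum()!r}, not 1"
                )
        for name, marg in self.continuous_marginals.items():
            if marg.sd < 0:
                raise ValueError(f"negative sd for {name!r}")

    # -- lossless config-file round trip (YAML) ---------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["survival_spec"]["follow_up_window"] = list(
            self.survival_spec.follow_up_window
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["continuous_marginals"] = {
            k: ContinuousMarginal(**v) for k, v in d["continuous_marginals"].items()
        }
        d["effect_spec"] = EffectSpec(**d["effect_spec"])
        sv = dict(d["survival_spec"])
        sv["follow_up_window"] = tuple(sv["follow_up_window"])
        d["survival_spec"] = SurvivalSpec(**sv)
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)


def _truncnorm_moment_matched(marg: ContinuousMarginal):
    """Underlying (mu, sigma) so the truncated normal has the target moments.

    Without this correction a hard bound drags the realized mean away from
    the configured one (severely so for ki-67, whose lower bound sits only
    1.4 SD below the mean).
    """
    lo = -np.inf if marg.lower is None else marg.lower
    hi = np.inf if marg.upper is None else marg.upper
    if marg.sd == 0:
        return marg.mean, 0.0, lo, hi

    def resid(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - marg.mean, np.sqrt(v) - marg.sd]

    sol = optimize.root(resid, [marg.mean, np.log(marg.sd)], method="hybr")
    mu, sig = sol.x[0], float(np.exp(sol.x[1]))
    return mu, sig, lo, hi


def _sample_truncnorm(marg: ContinuousMarginal, n: int, rng: np.random.Generator):
    mu, sig, lo, hi = _truncnorm_moment_matched(marg)
    if sig == 0:
        return np.full(n, mu)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    u = rng.random(n)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sig)


def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _sample_lognormal(marg: ContinuousMarginal, n: int, rng: np.random.Generator):
    """Log-normal draw moment-matched to the target mean/sd, optionally
    truncated above with the underlying (mu, sigma) re-solved so the
    *truncated* moments still match."""
    if marg.upper is None:
        mu, sig = _lognormal_params(marg.mean, marg.sd)
        return rng.lognormal(mu, sig, n)
    b = np.log(marg.upper)

    def moments(mu, sig):
        # E[X^k | X <= U] for X log-normal
        z = (b - mu) / sig
        denom = stats.norm.cdf(z)
        m1 = np.exp(mu + sig**2 / 2) * stats.norm.cdf(z - sig) / denom
        m2 = np.exp(2 * mu + 2 * sig**2) * stats.norm.cdf(z - 2 * sig) / denom
        return m1, np.sqrt(max(m2 - m1**2, 1e-300))

    def resid(p):
        m1, s1 = moments(p[0], np.exp(p[1]))
        return [m1 - marg.mean, s1 - marg.sd]

    mu0, sig0 = _lognormal_params(marg.mean, marg.sd)
    sol = optimize.root(resid, [mu0, np.log(sig0)], method="hybr")
    mu, sig = sol.x[0], float(np.exp(sol.x[1]))
    # inverse-CDF sampling from the truncated log-normal
    z_hi = stats.norm.cdf((b - mu) / sig)
    u = rng.random(n) * z_hi
    return np.exp(mu + sig * stats.norm.ppf(u))


def assign_outcome(linear_predictor, survival_spec: SurvivalSpec, follow_up, rng):
    """Draw (cb, death, progression, os, pfs) given the CB log-odds.

    cb ~ Bernoulli(expit(lp)).  CB implies an event-free course to last
    follow-up; no-CB implies progression within follow-up (with optional
    death between progression and follow-up), so pfs <= os <= follow_up
    always holds.  Vectorized; scalars in, scalars out.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    scalar = lp.ndim == 0
    lp = np.atleast_1d(lp)
    fu = np.broadcast_to(np.asarray(follow_up, dtype=float), lp.shape).copy()
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor contains non-finite values")
    if (fu <= 0).any():
        raise ValueError("follow_up must be > 0")

    p_cb = 1.0 / (1.0 + np.exp(-lp))
    cb = (rng.random(lp.shape) < p_cb).astype(int)

    scale = survival_spec.progression_scale
    # inverse-CDF draw from an exponential truncated to (0, follow_up)
    u = rng.random(lp.shape)
    t_prog = -scale * np.log1p(-u * (1.0 - np.exp(-fu / scale)))
    dies = (rng.random(lp.shape) < survival_spec.death_prob_no_cb).astype(int)
    t_death = t_prog + rng.random(lp.shape) * (fu - t_prog)

    death = np.where(cb == 1, 0, dies)
    progression = np.where(cb == 1, 0, 1)
    pfs = np.where(cb == 1, fu, t_prog)
    os_ = np.where(cb == 1, fu, np.where(death == 1, t_death, fu))

    out = cb, death, progression, os_, pfs
    if scalar:
        return tuple(x.item() for x in out)
    return out


def generate_cohort(config: GeneratorConfig | None = None, **overrides):
    """Generate a synthetic cohort as a validated pandas DataFrame.

    Identical (config, seed) yields a bit-identical cohort.  ``overrides``
    are convenience keyword replacements for top-level config fields, e.g.
    ``generate_cohort(n_patients=2000, seed=7)``.
    """
    if config is None:
        config = GeneratorConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    cm = config.continuous_marginals

    cols: dict[str, np.ndarray] = {}
    cols["patient_id"] = np.array([f"P{i + 1:05d}" for i in range(n)])
    for var in ["age", "bmi", "blood_glucose", "injected_activity", "dlp", "ki67"]:
        cols[var] = _sample_truncnorm(cm[var], n, rng)

    for var, table in config.categorical_marginals.items():
        levels = list(table.keys())
        probs = np.array(list(table.values()), dtype=float)
        probs = probs / probs.sum()
        cols[var] = rng.choice(np.array(levels, dtype=object), size=n, p=probs)

    # PET features: heavy-tailed volume, MTV tied to volume, SUV pair coupled
    volume = _sample_lognormal(cm["pt_volume"], n, rng)
    noise_mean = cm["mtv"].mean / cm["pt_volume"].mean
    mtv = volume * rng.lognormal(
        np.log(noise_mean) - config.mtv_noise_sd**2 / 2.0, config.mtv_noise_sd, n
    )
    suv_max = _sample_lognormal(cm["suv_max"], n, rng)
    r = config.suv_ratio_level
    conc = config.suv_ratio_concentration
    base_ratio = rng.beta(r * conc, (1.0 - r) * conc, n)
    damp = (volume / np.median(volume)) ** (-config.suv_volume_exponent)
    ratio = np.minimum(base_ratio * damp, config.suv_ratio_cap)
    suv_mean = suv_max * ratio
    tlg = suv_mean * mtv
    cols.update(pt_volume=volume, mtv=mtv, suv_max=suv_max, suv_mean=suv_mean, tlg=tlg)

    eff = config.effect_spec
    effects = eff.true_effects()
    m1 = (cols["m_stage"] == 1).astype(float)
    lp = (
        eff.intercept
        + effects["pt_volume"](volume)
        + effects["tlg"](tlg)
        + eff.m1_shift * m1
        + eff.age_coef * (cols["age"] - cm["age"].mean) / cm["age"].sd
        + eff.bmi_coef * (cols["bmi"] - cm["bmi"].mean) / cm["bmi"].sd
    )

    lo, hi = config.survival_spec.follow_up_window
    follow_up = lo + rng.random(n) * (hi - lo)
    cb, death, progression, os_, pfs = assign_outcome(
        lp, config.survival_spec, follow_up, rng
    )

    import pandas as pd

    df = pd.DataFrame(
        {
            **{k: cols[k] for k in [
                "patient_id", "age", "bmi", "blood_glucose",
                "injected_activity", "dlp", "site", "quadrant", "histology",
                "ki67", "subtype",
            ]},
            "t_stage": cols["t_stage"].astype(int),
            "n_stage": cols["n_stage"].astype(int),
            "m_stage": cols["m_stage"].astype(int),
            "pt_volume": volume,
            "suv_max": suv_max,
            "suv_mean": suv_mean,
            "mtv": mtv,
            "tlg": tlg,
            "margin": cols["margin"],
            "morphology": cols["morphology"],
            "scanner": cols["scanner"],
            "follow_up": follow_up,
            "os": os_,
            "pfs": pfs,
            "death": np.asarray(death, dtype=int),
            "progression": np.asarray(progression, dtype=int),
        }
    )
    df = attach_cb(df)
    df.attrs["provenance"] = f"synthetic:seed={config.seed},n={n}"
    # tuple, not ndarray: DataFrame.attrs must stay equality-comparable
    df.attrs["true_linear_predictor"] = tuple(lp)
    return df
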