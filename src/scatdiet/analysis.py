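"""Derived quantities from the fitted detection model.

Detection-probability curves over the feeding lag, inversion of the
logistic for the meal proportion required to reach a target detection
probability, the spike-diet gut-transit window, and forest-plot style
coefficient tables.

Default conditioning for curves is a fresh scat (degradation day 0) from
the reference individual (coded 0); the per-scat random intercept is
marginalised by drawing a fresh alpha ~ N(0, sigma_alpha) for every
posterior draw (seeded, so curves are reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import InputError, ScatDietError, SpikeNeverDetectedError
from .model import PosteriorDraws, summarize_posterior

__all__ = [
    "DetectionCurve",
    "species_detection_vs_day",
    "proportion_for_target_probability",
    "spike_diet_window",
    "SpikeWindow",
    "coefficient_forest",
]

#: Feeding lags (days before defecation) the model resolves.
LAGS = (0, 1, 2, 3)

_DEFAULT_CONDITIONING = {"degradation_day": 0.0, "individual": 0.0}

#: Mean daily ration (grams) across the two study individuals; used to
#: convert a required diet proportion into grams of prey.
DEFAULT_DAILY_INTAKE_G = 1750.0


def _coef(draws: PosteriorDraws, family: int, species: str | None) -> np.ndarray:
    """Pooled draws of beta_family for one species, or of the hyper-mean
    (species-averaged coefficient) when species is None."""
    if species is None:
        name = f"mu_beta{family}"
        if name not in draws.names:
            raise InputError("species-averaged curves need a hierarchical fit")
        return draws.pooled(name)
    name = f"beta{family}[{species}]"
    if name not in draws.names:
        raise InputError(f"species {species!r} was not modelled")
    return draws.pooled(name)


def _eta_no_alpha(draws: PosteriorDraws, species: str | None, lag: int,
                  proportion: float, conditioning: dict) -> np.ndarray:
    """Per-draw linear predictor excluding the scat random intercept."""
    if lag not in LAGS:
        raise InputError(f"feeding lag must be one of {LAGS}")
    eta = _coef(draws, 0, species).copy()
    eta += _coef(draws, lag + 1, species) * proportion
    eta += draws.pooled("beta5") * conditioning["degradation_day"]
    eta += draws.pooled("beta6") * conditioning["individual"]
    return eta


@dataclass
class DetectionCurve:
    """Posterior detection probability along a swept covariate."""

    covariate: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    q2_5: np.ndarray
    q25: np.ndarray
    q50: np.ndarray
    q75: np.ndarray
    q97_5: np.ndarray
    conditioning: dict = field(default_factory=dict)

    def __post_init__(self):
        for lohi in ((self.q2_5, self.q97_5), (self.q25, self.q75)):
            if np.any(lohi[0] > lohi[1]):
                raise ScatDietError("interval bounds out of order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.covariate: self.grid,
            "mean": self.mean, "sd": self.sd,
            "q2.5": self.q2_5, "q25": self.q25, "q50": self.q50,
            "q75": self.q75, "q97.5": self.q97_5,
        })


def species_detection_vs_day(
    draws: PosteriorDraws,
    species: str | None,
    proportion: float,
    conditioning: dict | None = None,
    seed: int = 0,
) -> DetectionCurve:
    """Posterior detection probability of one species at feeding lags 0-3.

    At each lag d the per-draw probability is
    inverse-logit(beta0 + beta_{d+1} * proportion + beta5 * degradation
    + beta6 * individual + alpha), with alpha drawn fresh from
    N(0, sigma_alpha) per posterior draw (marginalising over scats).
    ``species=None`` sweeps the species-averaged (hyper-mean)
    coefficients instead.
    """
    if not 0.0 <= proportion <= 1.0:
        raise InputError("proportion must be in [0, 1]")
    cond = dict(_DEFAULT_CONDITIONING, **(conditioning or {}))
    rng = np.random.default_rng(seed)
    sigma_alpha = (draws.pooled("sigma_alpha") if "sigma_alpha" in draws.names
                   else np.zeros(draws.n_chains * draws.n_kept))
    alpha = rng.normal(0.0, 1.0, size=sigma_alpha.shape[0]) * sigma_alpha

    stats = {k: [] for k in ("mean", "sd", "q2.5", "q25", "q50", "q75", "q97.5")}
    for lag in LAGS:
        p = expit(_eta_no_alpha(draws, species, lag, proportion, cond) + alpha)
        qs = np.quantile(p, (0.025, 0.25, 0.50, 0.75, 0.975))
        stats["mean"].append(p.mean())
        stats["sd"].append(p.std(ddof=1))
        for q, v in zip(("q2.5", "q25", "q50", "q75", "q97.5"), qs):
            stats[q].append(v)
    return DetectionCurve(
        covariate="feeding_lag",
        grid=np.array(LAGS, dtype=float),
        mean=np.array(stats["mean"]), sd=np.array(stats["sd"]),
        q2_5=np.array(stats["q2.5"]), q25=np.array(stats["q25"]),
        q50=np.array(stats["q50"]), q75=np.array(stats["q75"]),
        q97_5=np.array(stats["q97.5"]),
        conditioning=cond,
    )


def proportion_for_target_probability(
    draws: PosteriorDraws,
    species: str | None = None,
    lag_day: int = 1,
    target_p: float = 0.5,
    conditioning: dict | None = None,
    daily_intake_g: float = DEFAULT_DAILY_INTAKE_G,
    slope_tol: float = 1e-8,
) -> dict:
    """Meal proportion required to reach ``target_p`` detection probability.

    Inverts the logistic per posterior draw:
    proportion = (logit(target_p) - beta0 - beta5*degradation
    - beta6*individual) / slope, where slope is the lag-``lag_day``
    proportion coefficient.  Draws with |slope| < ``slope_tol`` are
    excluded and counted.  The scat intercept is conditioned at alpha = 0
    (a typical scat), so composing with the forward curve at alpha = 0
    returns ``target_p`` exactly per draw.

    Returns a dict with the posterior median and 95% interval of the
    required proportion, tallies of draws outside [0, 1], and the grams
    equivalent at ``daily_intake_g``.
    """
    if not 0.0 < target_p < 1.0:
        raise InputError("target_p must be in (0, 1)")
    cond = dict(_DEFAULT_CONDITIONING, **(conditioning or {}))
    slope = _coef(draws, lag_day + 1, species)
    other = (_coef(draws, 0, species)
             + draws.pooled("beta5") * cond["degradation_day"]
             + draws.pooled("beta6") * cond["individual"])
    ok = np.abs(slope) >= slope_tol
    if not ok.any():
        raise InputError("all slope draws below tolerance; proportion undefined")
    prop = (logit(target_p) - other[ok]) / slope[ok]
    med, lo97, hi97 = np.quantile(prop, (0.5, 0.025, 0.975))
    return {
        "median": float(med),
        "q2.5": float(lo97),
        "q97.5": float(hi97),
        "n_draws": int(ok.sum()),
        "n_excluded": int((~ok).sum()),
        "n_below_0": int((prop < 0).sum()),
        "n_above_1": int((prop > 1).sum()),
        "grams_median": float(med * daily_intake_g),
        "daily_intake_g": daily_intake_g,
        "lag_day": lag_day,
        "target_p": target_p,
    }


@dataclass
class SpikeWindow:
    """Gut-transit bounds from a single spike feeding.

    ``min_hours`` is an interval because the first post-spike scat is
    typically deposited overnight with unknown exact time; ``max_hours``
    is the latest fresh-scat detection, at day resolution converted to
    hours.
    """

    min_hours: tuple[float, float]
    max_hours: float
    n_detections: int
    feeding_date: pd.Timestamp


def spike_diet_window(
    matrix: pd.DataFrame,
    schedule: pd.DataFrame,
    spike_species: str,
) -> SpikeWindow:
    """Detection window of a prey species fed exactly once.

    Only fresh subsamples (degradation day 0) of the spike-fed
    individual's scats count.  The minimum-bound interval assumes
    morning feeding and morning scat collection with overnight
    deposition: a first detection k days after feeding brackets the
    minimum passage time as ((k-1)*24 + 8, k*24 - 2) hours (clamped at
    0), i.e. (8, 22) h for a next-day first detection.
    """
    schedule = schedule.copy()
    schedule["date"] = pd.to_datetime(schedule["date"])
    fed = schedule[(schedule["species"] == spike_species) & (schedule["proportion"] > 0)]
    if len(fed) == 0:
        raise InputError(f"spike species {spike_species!r} never fed")
    if len(fed) > 1:
        raise InputError(
            f"spike species {spike_species!r} fed {len(fed)} times; window undefined"
        )
    fed_date = pd.Timestamp(fed.iloc[0]["date"])
    individual = fed.iloc[0]["individual_id"]

    m = matrix.copy()
    m["defecation_date"] = pd.to_datetime(m["defecation_date"])
    hits = m[
        (m["species"] == spike_species)
        & (m["individual_id"] == individual)
        & (m["degradation_day"] == 0)
        & (m["detected"] == 1)
        & (m["defecation_date"] >= fed_date)
    ]
    if hits.empty:
        raise SpikeNeverDetectedError(
            f"{spike_species!r} never detected in fresh scats after the spike feeding"
        )
    offsets = (hits["defecation_date"] - fed_date).dt.days
    k_min, k_max = int(offsets.min()), int(offsets.max())
    lo = max(0.0, (k_min - 1) * 24.0 + 8.0)
    hi = max(0.0, k_min * 24.0 - 2.0)
    return SpikeWindow(
        min_hours=(lo, hi),
        max_hours=float(k_max * 24),
        n_detections=int(len(hits)),
        feeding_date=fed_date,
    )


def coefficient_forest(draws: PosteriorDraws) -> pd.DataFrame:
    """Forest-plot table: posterior mean with 50% and 95% intervals for
    every monitored scalar (a superset of the headline summary)."""
    full = summarize_posterior(draws)
    return full[["mean", "q50", "q25", "q75", "q2.5", "q97.5"]]
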