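"""Synthetic feeding-trial data generator.

Emulates the statistical structure of a captive feeding experiment read out
by scat DNA metabarcoding:

* a feeding schedule in which each individual's daily ration is split among
  a few prey species with Dirichlet(1, ..., 1) proportions;
* binary prey detections drawn from the Bernoulli-logit detection model
  (per-species intercepts, lag-0..3 meal-proportion effects, a linear
  degradation-day effect, an individual effect and a per-scat random
  intercept), with the generating probability stored next to each draw;
* amplicon read tables in which the consumer dominates the library
  (defaults to a 54% read share), detected prey split the remainder, and
  negative controls carry low-level contamination.

All three generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import N_LAGS, _fed_days, _schedule_lookup, has_feeding_history, lag_proportions
from .exceptions import ConfigurationError, InputError
from .studydata import CONSUMER_TAXON

__all__ = [
    "TrueParameters",
    "example_true_parameters",
    "generate_feeding_schedule",
    "simulate_detections",
    "simulate_read_table",
]

logger = logging.getLogger(__name__)


@dataclass
class TrueParameters:
    """Generating coefficients of the detection model.

    ``beta0`` .. ``beta4`` are per-species arrays aligned with ``species``
    (intercept and lag-0..3 meal-proportion slopes); ``beta5`` is the
    degradation-day slope, ``beta6`` the individual contrast.  ``alpha``
    holds per-scat random intercepts; when None, they are drawn
    N(0, sigma_alpha^2) inside :func:`simulate_detections`.
    """

    species: list[str]
    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    beta4: np.ndarray
    beta5: float
    beta6: float
    sigma_alpha: float = 1.0
    alpha: np.ndarray | None = None

    def __post_init__(self):
        S = len(self.species)
        for k in range(5):
            arr = np.asarray(getattr(self, f"beta{k}"), dtype=float)
            if arr.shape != (S,):
                raise ConfigurationError(f"beta{k} must have one entry per species")
            setattr(self, f"beta{k}", arr)
        if self.sigma_alpha < 0:
            raise ConfigurationError("sigma_alpha must be >= 0")

    def linear_predictor(self, s: int, pr: np.ndarray, degradation_day: float,
                         individual: float, alpha_i: float) -> float:
        """Logit detection probability for species index ``s`` (0-based)."""
        return float(
            self.beta0[s]
            + self.beta1[s] * pr[0] + self.beta2[s] * pr[1]
            + self.beta3[s] * pr[2] + self.beta4[s] * pr[3]
            + self.beta5 * degradation_day + self.beta6 * individual + alpha_i
        )


#: Hyper-means of the lag effects used by :func:`example_true_parameters`:
#: weak effect of same-day meals, a strong peak one day after consumption,
#: declining on days 2-3; detection decays slowly with scat age and the
#: second individual detects slightly worse.
EXAMPLE_HYPER = {
    "mu_beta0": -1.0,
    "mu_beta1": 0.01,
    "mu_beta2": 4.43,
    "mu_beta3": 1.82,
    "mu_beta4": 1.04,
    "beta5": -0.16,
    "beta6": -1.19,
    "sigma_beta": 1.0,
    "sigma_alpha": 1.0,
}


def example_true_parameters(species: list[str], seed: int = 0) -> TrueParameters:
    """Draw per-species coefficients around the documented hyper-means.

    Species-level coefficients are drawn N(mu_k, sigma_beta^2) so the
    generated data has the between-species heterogeneity the hierarchical
    model assumes.
    """
    rng = np.random.default_rng(seed)
    S = len(species)
    h = EXAMPLE_HYPER
    betas = {
        f"beta{k}": rng.normal(h[f"mu_beta{k}"], h["sigma_beta"], size=S)
        for k in range(5)
    }
    return TrueParameters(
        species=list(species),
        beta5=h["beta5"],
        beta6=h["beta6"],
        sigma_alpha=h["sigma_alpha"],
        **betas,
    )


def generate_feeding_schedule(
    n_days: int,
    individuals: list[str],
    species: list[str],
    max_species_per_day: int = 3,
    seed: int = 0,
    start_date: str | pd.Timestamp = "2017-11-03",
) -> pd.DataFrame:
    """Random daily rations: 1..max_species_per_day species per individual
    per day, proportions from a flat Dirichlet (they sum to exactly 1).

    Returns a tidy DataFrame (``date``, ``individual_id``, ``species``,
    ``proportion``), deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    if not species:
        raise ConfigurationError("species list is empty")
    if not individuals:
        raise ConfigurationError("individuals list is empty")
    if not 1 <= max_species_per_day <= len(species):
        raise ConfigurationError("max_species_per_day must be in 1..len(species)")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start_date)
    rows = []
    for d in range(n_days):
        date = start + pd.Timedelta(days=d)
        for ind in individuals:
            k = int(rng.integers(1, max_species_per_day + 1))
            chosen = rng.choice(np.asarray(species, dtype=object), size=k, replace=False)
            props = rng.dirichlet(np.ones(k))
            for sp, p in zip(chosen, props):
                rows.append({"date": date, "individual_id": ind,
                             "species": sp, "proportion": float(p)})
    return pd.DataFrame(rows)


def simulate_detections(
    schedule: pd.DataFrame,
    params: TrueParameters,
    scat_days: list,
    degradation_days: list[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw Bernoulli prey detections from the logit detection model.

    One scat is produced per (scat day, individual) for every individual
    present in the schedule; scats whose individual lacks feeding records
    on the 3 preceding days are skipped and logged.  Each scat is
    subsampled at every degradation day; each subsample yields one row per
    species in ``params.species`` with the generating probability stored in
    ``true_p`` alongside the Bernoulli draw ``detected``.

    The random-number consumption order is fixed (scat-major, then
    degradation day, then species), so output is reproducible byte for
    byte given the seed.
    """
    degradation_days = [int(d) for d in degradation_days]
    if any(d < 0 for d in degradation_days):
        raise InputError("degradation days must be >= 0")
    schedule = schedule.copy()
    schedule["date"] = pd.to_datetime(schedule["date"])
    days = _fed_days(schedule)
    lookup = _schedule_lookup(schedule)
    individuals = sorted(schedule["individual_id"].unique())
    ind_code = {ind: i for i, ind in enumerate(individuals)}

    scats = []  # (scat_id, individual, date)
    for day in sorted(pd.to_datetime(pd.Series(scat_days)).unique()):
        for ind in individuals:
            if has_feeding_history(schedule, ind, day, _days=days):
                scats.append((f"{ind}-{pd.Timestamp(day):%Y%m%d}", ind, pd.Timestamp(day)))
            else:
                logger.warning("scat day %s for %s skipped: incomplete feeding history",
                               pd.Timestamp(day).date(), ind)

    rng = np.random.default_rng(seed)
    if params.alpha is not None:
        alpha = np.asarray(params.alpha, dtype=float)
        if alpha.shape != (len(scats),):
            raise ConfigurationError(
                f"params.alpha has length {alpha.shape[0]} but {len(scats)} scats were formed"
            )
    else:
        alpha = rng.normal(0.0, params.sigma_alpha, size=len(scats))

    rows = []
    for i, (scat_id, ind, date) in enumerate(scats):
        pr_by_species = np.stack([
            lag_proportions(schedule, ind, date, sp, _lookup=lookup)
            for sp in params.species
        ])  # (S, N_LAGS)
        for deg in sorted(degradation_days):
            subsample_id = f"{scat_id}-D{deg:02d}"
            for s, sp in enumerate(params.species):
                eta = params.linear_predictor(s, pr_by_species[s], float(deg),
                                              float(ind_code[ind]), float(alpha[i]))
                p = float(expit(eta))
                y = int(rng.random() < p)
                rows.append({
                    "scat_id": scat_id,
                    "subsample_id": subsample_id,
                    "individual_id": ind,
                    "defecation_date": date,
                    "degradation_day": deg,
                    "species": sp,
                    "detected": y,
                    "true_p": p,
                })
    return pd.DataFrame(rows)


def simulate_read_table(
    detections: pd.DataFrame,
    consumer_fraction: float = 0.54,
    mean_depth: int = 10_000,
    control_contamination_rate: float = 0.0,
    seed: int = 0,
    batch_size: int = 10,
    short_read_fraction: float = 0.0,
    consumer_taxon: str = CONSUMER_TAXON,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn binary detections into contaminated amplicon read tables.

    Per subsample, the total read count is Poisson(``mean_depth``) and is
    split multinomially: the consumer taxon takes weight
    ``consumer_fraction`` and each detected prey species an equal share of
    the remainder (undetected prey get no reads).  Subsamples are grouped
    into extraction batches of ``batch_size``, each with one negative
    control whose per-taxon counts are Poisson(``control_contamination_rate``).
    A fraction ``short_read_fraction`` of rows gets sequence lengths below
    80 bp to exercise the length filter; all others are ~90-120 bp.

    Returns
    -------
    (reads, controls)
        ``reads``: subsample_id, control_id, taxon, read_count,
        sequence_length.  ``controls``: control_id, taxon, read_count,
        sequence_length (only taxa with at least one read appear; an
        absent row means zero reads).
    """
    if detections is None or len(detections) == 0:
        raise InputError("detections table is empty")
    if not 0.0 < consumer_fraction < 1.0:
        raise ConfigurationError("consumer_fraction must be in (0, 1)")
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be > 0")
    if not 0.0 <= short_read_fraction <= 1.0:
        raise ConfigurationError("short_read_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    species = sorted(detections["species"].unique())
    sub_order = detections["subsample_id"].drop_duplicates().tolist()
    detected = detections[detections["detected"] == 1].groupby("subsample_id")["species"].agg(list)

    def draw_length() -> int:
        if short_read_fraction > 0 and rng.random() < short_read_fraction:
            return int(rng.integers(30, 80))
        return int(rng.integers(90, 121))

    read_rows = []
    control_of = {}
    for j, sub in enumerate(sub_order):
        control_of[sub] = f"NC{j // batch_size:03d}"
        prey = sorted(detected.get(sub, []))
        total = int(rng.poisson(mean_depth))
        if prey:
            probs = np.concatenate(([consumer_fraction],
                                    np.full(len(prey), (1 - consumer_fraction) / len(prey))))
        else:
            probs = np.array([1.0])
        counts = rng.multinomial(total, probs)
        for taxon, count in zip([consumer_taxon] + prey, counts):
            read_rows.append({
                "subsample_id": sub,
                "control_id": control_of[sub],
                "taxon": taxon,
                "read_count": int(count),
                "sequence_length": draw_length(),
            })

    control_rows = []
    for cid in sorted(set(control_of.values())):
        for taxon in [consumer_taxon] + species:
            count = int(rng.poisson(control_contamination_rate))
            if count > 0:
                control_rows.append({
                    "control_id": cid,
                    "taxon": taxon,
                    "read_count": count,
                    "sequence_length": draw_length(),
                })
    reads = pd.DataFrame(read_rows)
    controls = pd.DataFrame(
        control_rows,
        columns=["control_id", "taxon", "read_count", "sequence_length"],
    )
    return reads, controls
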