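"""Build the detection model's covariates from a feeding schedule.

Each row of the model input is one (scat, degradation day, prey species)
observation.  The covariates are the proportion of that species in the
individual's daily ration on the defecation day (``pr0``) and on each of
the three preceding days (``pr1``–``pr3``), the number of days the scat
degraded outdoors before subsampling, and a 0/1 individual indicator.

Scats whose individual lacks feeding records on all three days preceding
defecation are dropped (pre-trial diet is unknown); a missing record on the
defecation day itself simply yields ``pr0 = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = ["ModelInput", "lag_proportions", "build_model_input", "empirical_meal_size_curve"]

logger = logging.getLogger(__name__)

#: Number of feeding-lag covariates (day of defecation + 3 preceding days).
N_LAGS = 4


@dataclass
class ModelInput:
    """Response and covariates for the hierarchical detection model.

    Arrays are row-aligned; ``species_index`` and ``scat_index`` are dense
    and 1-based (matching the usual BUGS-style indexing of hierarchical
    models), with label lookup through ``species_labels`` / ``scat_labels``.
    """

    y: np.ndarray
    species_index: np.ndarray
    scat_index: np.ndarray
    pr0: np.ndarray
    pr1: np.ndarray
    pr2: np.ndarray
    pr3: np.ndarray
    degradation_day: np.ndarray
    individual: np.ndarray
    species_labels: list[str]
    scat_labels: list[str]
    individual_labels: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def n_scats(self) -> int:
        return len(self.scat_labels)

    def validate(self) -> None:
        n = self.n_rows
        for name in ("species_index", "scat_index", "pr0", "pr1", "pr2", "pr3",
                     "degradation_day", "individual"):
            if getattr(self, name).shape != (n,):
                raise InputError(f"ModelInput field {name} has wrong length")
        if not np.isin(self.y, (0, 1)).all():
            raise InputError("y must be 0/1")
        for name in ("pr0", "pr1", "pr2", "pr3"):
            v = getattr(self, name)
            if ((v < 0) | (v > 1)).any():
                raise InputError(f"{name} outside [0,1]")
        if self.species_index.min(initial=1) < 1 or self.species_index.max(initial=1) > self.n_species:
            raise InputError("species_index not dense 1-based")
        if self.scat_index.min(initial=1) < 1 or self.scat_index.max(initial=1) > self.n_scats:
            raise InputError("scat_index not dense 1-based")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": self.y,
                "species_index": self.species_index,
                "scat_index": self.scat_index,
                "species": [self.species_labels[i - 1] for i in self.species_index],
                "scat_id": [self.scat_labels[i - 1] for i in self.scat_index],
                "pr0": self.pr0,
                "pr1": self.pr1,
                "pr2": self.pr2,
                "pr3": self.pr3,
                "degradation_day": self.degradation_day,
                "individual": self.individual,
            }
        )


def _schedule_lookup(schedule: pd.DataFrame) -> dict:
    """(individual, date, species) -> proportion, summing duplicate rows."""
    g = schedule.groupby(["individual_id", "date", "species"])["proportion"].sum()
    return g.to_dict()


def _fed_days(schedule: pd.DataFrame) -> set:
    """Set of (individual, date) pairs with at least one feeding record."""
    return set(zip(schedule["individual_id"], schedule["date"]))


def lag_proportions(
    schedule: pd.DataFrame,
    individual_id: str,
    date: pd.Timestamp,
    species: str,
    _lookup: dict | None = None,
) -> np.ndarray:
    """Proportions of ``species`` fed to ``individual_id`` at lags 0..3.

    Lag 0 is the defecation date itself; lag d is d days before.  Days on
    which the species was not fed contribute 0.
    """
    lookup = _lookup if _lookup is not None else _schedule_lookup(schedule)
    out = np.zeros(N_LAGS)
    for lag in range(N_LAGS):
        day = pd.Timestamp(date) - pd.Timedelta(days=lag)
        out[lag] = lookup.get((individual_id, day, species), 0.0)
    return out


def has_feeding_history(
    schedule: pd.DataFrame, individual_id: str, date: pd.Timestamp, _days: set | None = None
) -> bool:
    """True when the individual has feeding records on each of the 3 days
    preceding ``date`` (the window over which lagged covariates are defined)."""
    days = _days if _days is not None else _fed_days(schedule)
    date = pd.Timestamp(date)
    return all((individual_id, date - pd.Timedelta(days=lag)) in days for lag in (1, 2, 3))


def build_model_input(matrix: pd.DataFrame, schedule: pd.DataFrame) -> ModelInput:
    """Join a detection matrix to the feeding schedule.

    Parameters
    ----------
    matrix
        Detection matrix with columns ``scat_id``, ``individual_id``,
        ``defecation_date``, ``degradation_day``, ``species``, ``detected``.
    schedule
        Tidy feeding schedule (``date``, ``individual_id``, ``species``,
        ``proportion``).

    Returns
    -------
    ModelInput sorted canonically by (scat, degradation day, species); the
    result is invariant to the input row order.

    Raises
    ------
    InputError
        If the matrix contains species never present in the schedule, or
        more than two individuals (the model codes the individual as a
        single 0/1 covariate).
    """
    required = {"scat_id", "individual_id", "defecation_date", "degradation_day",
                "species", "detected"}
    missing = required - set(matrix.columns)
    if missing:
        raise InputError(f"detection matrix missing columns: {sorted(missing)}")
    matrix = matrix.copy()
    matrix["defecation_date"] = pd.to_datetime(matrix["defecation_date"])
    schedule = schedule.copy()
    schedule["date"] = pd.to_datetime(schedule["date"])

    unknown = sorted(set(matrix["species"]) - set(schedule["species"]))
    if unknown:
        raise InputError(f"species in detection matrix but never in schedule: {unknown}")
    individuals = sorted(matrix["individual_id"].unique())
    if len(individuals) > 2:
        raise InputError(
            f"model codes the individual as one 0/1 covariate; got {len(individuals)} individuals"
        )

    days = _fed_days(schedule)
    lookup = _schedule_lookup(schedule)

    scat_info = matrix[["scat_id", "individual_id", "defecation_date"]].drop_duplicates("scat_id")
    keep_scats = []
    for _, r in scat_info.iterrows():
        if has_feeding_history(schedule, r["individual_id"], r["defecation_date"], _days=days):
            keep_scats.append(r["scat_id"])
        else:
            logger.warning("scat %s dropped: incomplete 3-day feeding history", r["scat_id"])
    matrix = matrix[matrix["scat_id"].isin(keep_scats)]
    if matrix.empty:
        raise InputError("no scats with a complete 3-day feeding history")

    species_labels = sorted(matrix["species"].unique())
    scat_labels = sorted(matrix["scat_id"].unique())
    sp_idx = {s: i + 1 for i, s in enumerate(species_labels)}
    sc_idx = {s: i + 1 for i, s in enumerate(scat_labels)}
    ind_code = {ind: i for i, ind in enumerate(individuals)}

    matrix = matrix.sort_values(["scat_id", "degradation_day", "species"], kind="mergesort")

    pr = np.zeros((len(matrix), N_LAGS))
    for j, (_, r) in enumerate(matrix.iterrows()):
        pr[j] = lag_proportions(schedule, r["individual_id"], r["defecation_date"],
                                r["species"], _lookup=lookup)

    mi = ModelInput(
        y=matrix["detected"].to_numpy(dtype=np.int8),
        species_index=matrix["species"].map(sp_idx).to_numpy(dtype=np.int64),
        scat_index=matrix["scat_id"].map(sc_idx).to_numpy(dtype=np.int64),
        pr0=pr[:, 0], pr1=pr[:, 1], pr2=pr[:, 2], pr3=pr[:, 3],
        degradation_day=matrix["degradation_day"].to_numpy(dtype=float),
        individual=matrix["individual_id"].map(ind_code).to_numpy(dtype=float),
        species_labels=species_labels,
        scat_labels=scat_labels,
        individual_labels=individuals,
    )
    mi.validate()
    return mi


def empirical_meal_size_curve(
    matrix: pd.DataFrame | None, model_input: ModelInput, n_bins: int
) -> pd.DataFrame:
    """Raw (model-free) detection fraction as a function of meal size.

    Each observation's meal size is the largest proportion of the species
    fed over the 4-day covariate window (max of pr0..pr3).  Observations
    are pooled into ``n_bins`` equal-width bins on [0, 1].

    Returns a DataFrame with ``bin_left``, ``bin_right``, ``n``,
    ``fraction_detected`` (NaN for empty bins) and ``mean_proportion``.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    meal = np.maximum.reduce([model_input.pr0, model_input.pr1,
                              model_input.pr2, model_input.pr3])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-inclusive last bin so meal == 1.0 is counted
    which = np.clip(np.digitize(meal, edges, right=False) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        rows.append({
            "bin_left": edges[b],
            "bin_right": edges[b + 1],
            "n": n,
            "fraction_detected": float(model_input.y[sel].mean()) if n else np.nan,
            "mean_proportion": float(meal[sel].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)
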