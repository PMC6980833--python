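"""Presence/absence calling from taxon-assigned amplicon read tables.

The pipeline order is fixed: :func:`filter_reads` (length and abundance
thresholds) -> :func:`reassign_taxa` (collapse family-level assignments to
the known target species, drop non-targets) -> :func:`call_presence`
(binary detection against matched negative controls) ->
:func:`exclude_burnin_scats` (drop scats deposited before the lagged diet
is known, and species fed only during that window).

Thresholds follow the common metabarcoding conventions for this kind of
data: sequences shorter than 80 bp or with fewer than 10 reads are treated
as likely sequencing error/chimaera, and a species is called present in a
subsample when it has any reads there while its negative control has fewer
than 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError, MissingControlError
from .studydata import CONSUMER_TAXON

__all__ = [
    "TaxonMapping",
    "DEFAULT_TAXON_MAPPING",
    "filter_reads",
    "reassign_taxa",
    "call_presence",
    "exclude_burnin_scats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonMapping:
    """Collapse a higher-rank assignment onto a species-level label."""

    pattern: str
    target: str
    rank: str = "family"


#: Family-level assignments collapsed onto the known consumer/prey species.
DEFAULT_TAXON_MAPPING = [
    TaxonMapping("Felidae", "Acinonyx jubatus"),
    TaxonMapping("Leporidae", "Oryctolagus cuniculus"),
    TaxonMapping("Equidae", "Equus caballus"),
    TaxonMapping("Cervidae", "Cervus spp"),
]


def filter_reads(table: pd.DataFrame, min_length: int = 80, min_abundance: int = 10) -> pd.DataFrame:
    """Drop rows shorter than ``min_length`` bp or with fewer than
    ``min_abundance`` reads.

    Boundary behaviour: rows at exactly the thresholds (length 80,
    count 10) are retained.  Row order is preserved; counts are untouched.
    An all-rows-fail result is an empty table, not an error.
    """
    if min_length < 0 or min_abundance < 0:
        raise ConfigurationError("filter thresholds must be non-negative")
    if table is None or "read_count" not in table.columns:
        raise InputError("read table must have read_count / sequence_length columns")
    keep = (table["sequence_length"] >= min_length) & (table["read_count"] >= min_abundance)
    return table[keep].reset_index(drop=True)


def reassign_taxa(
    table: pd.DataFrame,
    mapping: list[TaxonMapping] | None = None,
    target_species: list[str] | None = None,
    consumer_taxon: str = CONSUMER_TAXON,
) -> tuple[pd.DataFrame, dict]:
    """Collapse higher-rank assignments to species and drop non-targets.

    Rows whose taxon matches a mapping pattern are relabelled to the
    mapped species; rows already labelled with a target species (or the
    consumer) pass through; everything else is dropped and tallied.  Rows
    that end up sharing a (subsample, taxon) have their read counts summed
    (the longest sequence length is retained for the merged row).

    Returns ``(table, report)`` where the report tallies reassigned rows,
    dropped rows/reads and the per-taxon drop counts.
    """
    if mapping is None:
        mapping = DEFAULT_TAXON_MAPPING
    if target_species is None:
        raise ConfigurationError("target_species list is required")
    allowed = set(target_species) | {consumer_taxon}
    for m in mapping:
        if m.target not in allowed:
            raise ConfigurationError(
                f"mapping target {m.target!r} not in target species list"
            )
    pattern_to_target = {m.pattern: m.target for m in mapping}

    table = table.copy()
    table["taxon"] = table["taxon"].map(lambda t: pattern_to_target.get(t, t))
    reassigned = int(table["taxon"].isin(pattern_to_target.values()).sum())

    keep = table["taxon"].isin(allowed)
    dropped = table[~keep]
    report = {
        "reassigned_rows": reassigned,
        "dropped_rows": int((~keep).sum()),
        "dropped_reads": int(dropped["read_count"].sum()),
        "dropped_taxa": dropped.groupby("taxon")["read_count"].count().to_dict(),
    }
    table = table[keep]

    group_cols = ["subsample_id", "taxon"]
    if "control_id" in table.columns:
        group_cols = ["subsample_id", "control_id", "taxon"]
    agg = {"read_count": "sum"}
    if "sequence_length" in table.columns:
        agg["sequence_length"] = "max"
    merged = table.groupby(group_cols, as_index=False).agg(agg)
    return merged, report


def call_presence(
    table: pd.DataFrame,
    controls: pd.DataFrame,
    control_max: int = 10,
    *,
    target_species: list[str],
    consumer_taxon: str = CONSUMER_TAXON,
    sample_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binary presence/absence of each target species per subsample.

    A species is detected (1) in a subsample iff it has at least one read
    there and its matched negative control carries fewer than
    ``control_max`` reads of that species (an absent control row counts as
    zero).  The consumer taxon is never emitted as a prey row.  Every
    (subsample, target species) pair appears in the output with an
    explicit 0/1.

    ``sample_info`` optionally supplies per-subsample metadata
    (``subsample_id``, ``scat_id``, ``individual_id``, ``defecation_date``,
    ``degradation_day``) and, when given, defines the subsample universe —
    a listed subsample with no reads at all is an error (its control
    cannot be resolved).
    """
    if control_max < 0:
        raise ConfigurationError("control_max must be non-negative")
    control_counts = {}
    if len(controls):
        g = controls.groupby(["control_id", "taxon"])["read_count"].sum()
        control_counts = g.to_dict()

    sub_control = (
        table[["subsample_id", "control_id"]]
        .drop_duplicates("subsample_id")
        .set_index("subsample_id")["control_id"]
    )
    if sample_info is not None:
        universe = sample_info["subsample_id"].drop_duplicates().tolist()
    else:
        universe = sub_control.index.tolist()

    sample_counts = (
        table.groupby(["subsample_id", "taxon"])["read_count"].sum().to_dict()
    )

    rows = []
    for sub in universe:
        if sub not in sub_control.index or pd.isna(sub_control[sub]):
            raise MissingControlError(sub)
        cid = sub_control[sub]
        for sp in sorted(target_species):
            if sp == consumer_taxon:
                continue
            n_sample = sample_counts.get((sub, sp), 0)
            n_control = control_counts.get((cid, sp), 0)
            rows.append({
                "subsample_id": sub,
                "species": sp,
                "detected": int(n_sample >= 1 and n_control < control_max),
            })
    out = pd.DataFrame(rows)
    if sample_info is not None:
        meta_cols = [c for c in ("subsample_id", "scat_id", "individual_id",
                                 "defecation_date", "degradation_day")
                     if c in sample_info.columns]
        out = out.merge(sample_info[meta_cols].drop_duplicates("subsample_id"),
                        on="subsample_id", how="left")
        front = [c for c in ("scat_id", "subsample_id", "individual_id",
                             "defecation_date", "degradation_day", "species", "detected")
                 if c in out.columns]
        out = out[front]
    return out.reset_index(drop=True)


def exclude_burnin_scats(
    matrix: pd.DataFrame,
    schedule: pd.DataFrame,
    burnin_days: int = 3,
    excluded_species: tuple[str, ...] = ("Meleagris gallopavo",),
) -> tuple[pd.DataFrame, dict]:
    """Drop scats from the first ``burnin_days`` of each individual's trial
    and all rows for ``excluded_species``.

    The lagged-diet covariates are undefined for scats deposited before
    the feeding history spans the covariate window, so those scats cannot
    enter the model; species fed only within that window are dropped with
    them.  Returns ``(matrix, report)`` with dropped-row tallies.
    """
    if burnin_days < 0:
        raise ConfigurationError("burnin_days must be >= 0")
    matrix = matrix.copy()
    matrix["defecation_date"] = pd.to_datetime(matrix["defecation_date"])
    schedule = schedule.copy()
    schedule["date"] = pd.to_datetime(schedule["date"])
    first_fed = schedule.groupby("individual_id")["date"].min()

    offsets = matrix.apply(
        lambda r: (r["defecation_date"] - first_fed.get(r["individual_id"], r["defecation_date"])).days,
        axis=1,
    ) if len(matrix) else pd.Series(dtype=int)
    burnin_mask = offsets < burnin_days if len(matrix) else pd.Series(dtype=bool)
    species_mask = matrix["species"].isin(excluded_species)

    report = {
        "burnin_rows_dropped": int(burnin_mask.sum()),
        "burnin_scats_dropped": sorted(matrix.loc[burnin_mask, "scat_id"].unique())
        if "scat_id" in matrix.columns else [],
        "excluded_species_rows_dropped": int((species_mask & ~burnin_mask).sum()),
        "excluded_species": list(excluded_species),
    }
    out = matrix[~(burnin_mask | species_mask)].reset_index(drop=True)
    if out.empty:
        logger.warning("exclude_burnin_scats removed every row")
    return out, report
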