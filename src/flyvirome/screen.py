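"""Reads-per-million threshold screening of sequencing-run count tables.

Public sequencing runs mapped against a virus panel give one read count per
(run, virus).  Counts are converted to reads per million total mappable
reads (rpm); a virus is recorded as present in a run when its rpm reaches a
detection threshold (100 rpm by default, chosen well above typical
mismapping levels).  Runs group into samples and samples into submitted
projects, so positivity can be summarised at any of the three levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

META_COLUMNS = ["run_id", "sample_id", "project_id", "total_reads"]
DEFAULT_THRESHOLD_RPM = 100.0


def _split(table: pd.DataFrame):
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"run table missing column(s): {missing}")
    viruses = [c for c in table.columns if c not in META_COLUMNS]
    return table.set_index("run_id"), viruses


def rpm_matrix(table: pd.DataFrame, segment_map: dict | None = None,
               drop_zero_total: bool = True) -> pd.DataFrame:
    """Reads-per-million matrix (runs x viruses) from a run-count table.

    ``segment_map`` (segment column -> virus) sums multi-segment counts per
    virus before conversion.  Runs with zero total reads are excluded when
    ``drop_zero_total`` (no denominator), else raise.
    """
    meta, viruses = _split(table)
    totals = meta["total_reads"].astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        if not drop_zero_total:
            raise ValueError(f"run(s) with zero total reads: {bad}")
        meta = meta[totals > 0]
        totals = totals[totals > 0]
    counts = meta[viruses].astype(float)
    if segment_map:
        counts = counts.T.groupby(lambda c: segment_map.get(c, c)).sum().T
    return counts.mul(1e6 / totals, axis=0)


@dataclass
class PresenceMatrix:
    presence: pd.DataFrame  # boolean, runs x viruses
    threshold_rpm: float


def presence(rpm: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD_RPM,
             strict: bool = False) -> PresenceMatrix:
    """Detection matrix at an rpm threshold (inclusive by default)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mat = rpm.gt(threshold) if strict else rpm.ge(threshold)
    return PresenceMatrix(mat, threshold)


def positive_fraction(pres: PresenceMatrix, table: pd.DataFrame,
                      group_by: str = "run") -> float:
    """Fraction of runs/samples/projects with at least one virus present.

    A sample or project is positive when any member run is positive.
    """
    if group_by not in ("run", "sample", "project"):
        raise ValueError(f"unknown grouping {group_by!r}")
    meta, _ = _split(table)
    run_positive = pres.presence.any(axis=1)
    if group_by == "run":
        return float(run_positive.mean())
    key = meta.loc[run_positive.index, f"{group_by}_id"]
    return float(run_positive.groupby(key).any().mean())


def threshold_curve(rpm: pd.DataFrame, thresholds, table: pd.DataFrame | None = None,
                    group_by: str = "run") -> pd.Series:
    """Positive fraction as a function of detection threshold.

    Monotone non-increasing in the threshold by construction.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    fractions = []
    for t in thresholds:
        pres = presence(rpm, t)
        if group_by == "run" or table is None:
            fractions.append(float(pres.presence.any(axis=1).mean()))
        else:
            fractions.append(positive_fraction(pres, table, group_by))
    return pd.Series(fractions, index=thresholds, name="positive_fraction")


def virus_dataset_counts(pres: PresenceMatrix) -> pd.Series:
    """Number of positive runs per virus (column sums of presence)."""
    return pres.presence.sum(axis=0)


def project_mean_rpm(rpm: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Mean rpm per (project, virus) across member runs."""
    meta, _ = _split(table)
    projects = meta.loc[rpm.index, "project_id"]
    return rpm.groupby(projects).mean()


def cooccurrence(pres: PresenceMatrix) -> pd.DataFrame:
    """Pairwise presence correlation between viruses across runs.

    Used to flag unassigned candidate contigs that always co-occur with a
    named virus (candidate genome segments).  Constant columns give NaN.
    """
    mat = pres.presence.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mat.corr()
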