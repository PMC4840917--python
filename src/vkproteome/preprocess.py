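"""Normalization, coverage filtering, and derived outcome variables.

Reporter-ion intensities from one iTRAQ run are only comparable after
log2-transforming and centering each reporter channel (i.e. each child's
sample) on its median across the proteins quantified in that run. After
centering, each channel's log2 median is exactly zero, which removes
sample-loading differences and makes channels comparable across runs.

A per-protein-within-experiment centering mode is also provided for
sensitivity analysis (``by="protein"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DETECTION_LIMIT, CohortDataset


@dataclass
class NormalizationReport:
    """Per-(experiment, channel) medians subtracted during normalization."""

    medians: pd.DataFrame  # columns: experiment_id, child_id, median_log2, n_obs
    n_observations: int

    def to_frame(self) -> pd.DataFrame:
        return self.medians.copy()


def log2_median_normalize(dataset: CohortDataset, by: str = "channel"
                          ) -> tuple[CohortDataset, NormalizationReport]:
    """log2-transform raw intensities and median-center within experiment.

    ``by="channel"`` (default): subtract, from each log2 intensity, the
    median log2 intensity of that child's channel within its experiment.
    ``by="protein"``: subtract the per-protein median within the experiment
    instead (sensitivity mode).

    Raises ``ValueError`` if the dataset is already normalized or any
    intensity is non-positive.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    obs = dataset.observations.copy()
    values = obs["value"].to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        row = obs.iloc[i]
        raise ValueError(
            "non-positive raw intensity for protein "
            f"{row['gi_accession']!r}, child {row['child_id']!r}")
    log2v = np.log2(values)
    obs["value"] = log2v
    if by == "channel":
        keys = ["experiment_id", "child_id"]
    elif by == "protein":
        keys = ["experiment_id", "gi_accession"]
    else:
        raise ValueError(f"unknown centering mode {by!r}")
    med = obs.groupby(keys, sort=False)["value"].transform("median")
    obs["value"] = obs["value"] - med.to_numpy()

    report_frame = (obs.assign(median_log2=med.to_numpy())
                    .groupby(keys, sort=False)
                    .agg(median_log2=("median_log2", "first"),
                         n_obs=("value", "size"))
                    .reset_index())
    report = NormalizationReport(medians=report_frame,
                                 n_observations=len(obs))
    return dataset.replace(observations=obs, normalized=True), report


def filter_proteins_by_coverage(dataset: CohortDataset,
                                min_children: int = 50) -> CohortDataset:
    """Keep proteins quantified in strictly more than ``min_children`` children.

    The study's coverage rule is ">10% of children", i.e. n > 50 of 500 —
    a strict inequality on the count of distinct children.
    """
    if min_children < 0:
        raise ValueError("min_children must be >= 0")
    obs = dataset.observations
    counts = obs.groupby("gi_accession")["child_id"].nunique()
    keep = set(counts.index[counts > min_children])
    filtered = obs[obs["gi_accession"].isin(keep)].reset_index(drop=True)
    return dataset.replace(observations=filtered)


def dichotomize_vk(subjects: pd.DataFrame, cutoff_ugL: float = 2.0
                   ) -> pd.DataFrame:
    """Attach ``vk_status``: "deficient" iff PIVKA-II > cutoff (2 μg/L).

    The cutoff is inclusive on the sufficient side (2.0 → sufficient).
    Below-detection children are classed sufficient; a missing PIVKA-II
    leaves the status missing (excluded downstream).
    """
    subjects = subjects.copy()
    pivka = subjects["pivka2_ugL"]
    status = np.where(pivka > cutoff_ugL, "deficient", "sufficient")
    subjects["vk_status"] = pd.Series(status, index=subjects.index).where(
        pivka.notna(), other=pd.NA)
    return subjects


def continuous_outcome_subset(subjects: pd.DataFrame) -> pd.DataFrame:
    """Drop below-detection children and attach ``log2_pivka``.

    PIVKA-II below the 0.001 μg/L detection limit cannot enter the
    continuous (log2) analysis; in the study this leaves 474 of 500
    children. No pseudo-count is used.
    """
    if "below_detection" in subjects.columns:
        mask = ~subjects["below_detection"].astype(bool)
    else:
        mask = subjects["pivka2_ugL"] >= DETECTION_LIMIT
    kept = subjects[mask & subjects["pivka2_ugL"].notna()].copy()
    kept["log2_pivka"] = np.log2(kept["pivka2_ugL"].to_numpy(dtype=float))
    return kept.reset_index(drop=True)
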