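"""Domain containers and tab-delimited interchange I/O.

The analysis moves between three flat tables, all TSV with a header row:

``subjects.tsv``
    one row per child: ``child_id``, ``experiment_id`` (the iTRAQ run the
    child's plasma was labelled in), ``channel`` (reporter channel 1-8),
    ``pivka2_ugL`` (plasma PIVKA-II, μg/L), plus any number of covariate
    columns (age, sex, lipids, inflammation flags ...) which are carried
    through untouched.

``abundance.tsv``
    one row per (protein, child) quantitation: ``gene_symbol``,
    ``gi_accession``, ``child_id``, ``experiment_id`` and ``value`` — either
    a raw reporter-ion intensity (pre-normalization) or a log2 relative
    abundance (post-normalization).

results tables
    with the field's reporting conventions: percent change / percent
    difference with a 95% CI rendered as ``"137.5 (50.1, 275.8)"``, sorted by
    ascending p.

Protein identity is the (gene_symbol, gi_accession) pair; the GI accession
alone is the primary key because gene symbols are not unique across isoforms.

Exports produced by other tools may use different header names; every
reader accepts a ``column_map`` translating standard names to the names found
in the file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: PIVKA-II concentrations below this (μg/L) are undetectable by the assay.
DETECTION_LIMIT = 0.001

SUBJECT_COLUMNS = ("child_id", "experiment_id", "channel", "pivka2_ugL")
ABUNDANCE_COLUMNS = ("gene_symbol", "gi_accession", "child_id",
                     "experiment_id", "value")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """A uniqueness or referential-integrity invariant is violated."""


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Per-protein PIVKA-II association (outcome = log2 PIVKA-II).

    ``beta`` is the slope of log2 PIVKA-II on log2 protein abundance, so
    ``percent_change = (2**beta - 1) * 100`` is the percent change in
    PIVKA-II per doubling of protein abundance.
    """

    gene_symbol: str
    gi_accession: str
    n_obs: int
    beta: float
    se_beta: float
    percent_change: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None
    r2: float


@dataclass
class GroupDiffResult:
    """Per-protein deficient-vs-sufficient abundance difference.

    ``beta_group`` is the log2 abundance difference (deficient − sufficient;
    deficient coded 1), so ``percent_difference = (2**beta_group - 1) * 100``.
    """

    gene_symbol: str
    gi_accession: str
    n_obs: int
    beta_group: float
    se_beta: float
    percent_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A cohort: subject table + long-format protein abundance table.

    ``normalized`` records whether ``observations.value`` is log2 relative
    abundance (True) or raw reporter-ion intensity (False).
    """

    subjects: pd.DataFrame
    observations: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_experiments(self) -> int:
        return self.subjects["experiment_id"].nunique()

    @property
    def n_children(self) -> int:
        return len(self.subjects)

    @property
    def protein_ids(self) -> pd.DataFrame:
        """Distinct (gene_symbol, gi_accession) pairs present."""
        return (self.observations[["gene_symbol", "gi_accession"]]
                .drop_duplicates().reset_index(drop=True))

    def replace(self, **changes) -> "CohortDataset":
        return replace(self, **changes)

    def validate(self, plex_size: int = 8) -> None:
        subj, obs = self.subjects, self.observations
        for col in SUBJECT_COLUMNS:
            if col not in subj.columns:
                raise SchemaError(f"subject table is missing column {col!r}")
        for col in ABUNDANCE_COLUMNS:
            if col not in obs.columns:
                raise SchemaError(f"abundance table is missing column {col!r}")
        if subj["child_id"].duplicated().any():
            dup = subj.loc[subj["child_id"].duplicated(), "child_id"].iloc[0]
            raise IntegrityError(f"duplicate child_id {dup!r}")
        chan = subj["channel"]
        if ((chan < 1) | (chan > plex_size)).any():
            raise IntegrityError(
                f"channel outside 1..{plex_size} in subject table")
        if (subj["pivka2_ugL"].dropna() < 0).any():
            raise IntegrityError("negative PIVKA-II concentration")
        dup_slot = subj.duplicated(["experiment_id", "channel"])
        if dup_slot.any():
            row = subj.loc[dup_slot, ["experiment_id", "channel"]].iloc[0]
            raise IntegrityError(
                "duplicate (experiment, channel) slot "
                f"({row['experiment_id']!r}, {int(row['channel'])})")
        dup_obs = obs.duplicated(["gi_accession", "child_id"])
        if dup_obs.any():
            row = obs.loc[dup_obs, ["gi_accession", "child_id"]].iloc[0]
            raise IntegrityError(
                "duplicate observation for protein "
                f"{row['gi_accession']!r}, child {row['child_id']!r}")
        if len(obs):
            known = set(subj["child_id"])
            unknown = set(obs["child_id"]) - known
            if unknown:
                raise IntegrityError(
                    f"observations reference unknown child_id {sorted(unknown)[:3]}")
            exp_of = subj.set_index("child_id")["experiment_id"]
            mismatch = obs["experiment_id"].to_numpy() != \
                exp_of.loc[obs["child_id"]].to_numpy()
            if mismatch.any():
                bad = obs.loc[np.flatnonzero(mismatch)[0]]
                raise IntegrityError(
                    f"observation for child {bad['child_id']!r} carries "
                    f"experiment {bad['experiment_id']!r}, which is not the "
                    "child's experiment")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _apply_column_map(df: pd.DataFrame,
                      column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={src: std for std, src in column_map.items()})
    return df


def read_subject_table(path, column_map: Mapping[str, str] | None = None,
                       plex_size: int = 8) -> pd.DataFrame:
    """Read a subject TSV.

    Below-detection PIVKA-II values (< 0.001 μg/L) are kept as measured and
    flagged in a ``below_detection`` column; downstream stages decide whether
    to include them. Unknown columns are preserved as covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"child_id": str,
                                            "experiment_id": str})
    df = _apply_column_map(df, column_map)
    for col in SUBJECT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"subject table {path} is missing column {col!r}")
    df["child_id"] = df["child_id"].astype(str)
    df["experiment_id"] = df["experiment_id"].astype(str)
    df["channel"] = pd.to_numeric(df["channel"], errors="raise").astype(int)
    df["pivka2_ugL"] = pd.to_numeric(df["pivka2_ugL"], errors="raise")
    df["below_detection"] = df["pivka2_ugL"] < DETECTION_LIMIT
    if ((df["channel"] < 1) | (df["channel"] > plex_size)).any():
        raise IntegrityError(f"channel outside 1..{plex_size} in {path}")
    dup = df.duplicated(["experiment_id", "channel"])
    if dup.any():
        row = df.loc[dup, ["experiment_id", "channel"]].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (experiment, channel) slot "
            f"({row['experiment_id']!r}, {int(row['channel'])})")
    return df


def read_abundance_table(path, column_map: Mapping[str, str] | None = None
                         ) -> pd.DataFrame:
    """Read a long-format protein abundance TSV."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"child_id": str, "experiment_id": str,
                            "gi_accession": str, "gene_symbol": str})
    df = _apply_column_map(df, column_map)
    for col in ABUNDANCE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(
                f"abundance table {path} is missing column {col!r}")
    for col in ("gene_symbol", "gi_accession", "child_id", "experiment_id"):
        df[col] = df[col].astype(str)
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        # +2: header line and 1-based numbering
        rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"{path}: non-numeric abundance value at line {rownum}")
    df["value"] = values
    dup = df.duplicated(["gi_accession", "child_id"])
    if dup.any():
        row = df.loc[dup, ["gi_accession", "child_id"]].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate observation for protein "
            f"{row['gi_accession']!r}, child {row['child_id']!r}")
    if df.empty:
        warnings.warn(f"abundance table {path} holds no observations",
                      stacklevel=2)
    return df


def read_cohort(subjects_path, abundance_path, normalized: bool = False,
                subject_column_map: Mapping[str, str] | None = None,
                abundance_column_map: Mapping[str, str] | None = None
                ) -> CohortDataset:
    """Read both tables and assemble a validated :class:`CohortDataset`."""
    subjects = read_subject_table(subjects_path, subject_column_map)
    observations = read_abundance_table(abundance_path, abundance_column_map)
    return CohortDataset(subjects, observations, normalized=normalized)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def write_abundance_table(observations: pd.DataFrame, path) -> None:
    # default float formatting is shortest-round-trip: values survive exactly
    observations.to_csv(path, sep="\t", index=False)


def write_cohort(dataset: CohortDataset, subjects_path, abundance_path) -> None:
    write_subject_table(dataset.subjects, subjects_path)
    write_abundance_table(dataset.observations, abundance_path)


def _format_percent_ci(pc: float, lo: float, hi: float) -> str:
    return f"{pc:.1f} ({lo:.1f}, {hi:.1f})"


def results_to_frame(results: Sequence[AssociationResult | GroupDiffResult],
                     kind: str) -> pd.DataFrame:
    """Tabulate result records, sorted by ascending p."""
    if kind == "association":
        rows = [{"gene_symbol": r.gene_symbol,
                 "gi_accession": r.gi_accession,
                 "n": r.n_obs,
                 "percent_change": _format_percent_ci(
                     r.percent_change, r.ci_low, r.ci_high),
                 "p_value": r.p_value,
                 "q_value": r.q_value,
                 "r2": r.r2} for r in results]
        cols = ["gene_symbol", "gi_accession", "n", "percent_change",
                "p_value", "q_value", "r2"]
    elif kind == "group_diff":
        rows = [{"gene_symbol": r.gene_symbol,
                 "gi_accession": r.gi_accession,
                 "n": r.n_obs,
                 "percent_difference": _format_percent_ci(
                     r.percent_difference, r.ci_low, r.ci_high),
                 "p_value": r.p_value,
                 "q_value": r.q_value} for r in results]
        cols = ["gene_symbol", "gi_accession", "n", "percent_difference",
                "p_value", "q_value"]
    else:
        raise ValueError(f"unknown results kind {kind!r}")
    frame = pd.DataFrame(rows, columns=cols)
    if len(frame):
        frame = frame.sort_values("p_value", kind="mergesort",
                                  ignore_index=True)
    return frame


def write_results_table(results, path, kind: str) -> None:
    """Write an association / group-difference / correlation results TSV.

    Percent values are rounded to 1 decimal with the CI rendered as
    ``"lo, hi"`` inside parentheses; rows are sorted by ascending p. For
    ``kind="correlation"``, ``results`` is an averaged correlation matrix.
    """
    if kind == "correlation":
        write_correlation_matrix(results, path)
        return
    results_to_frame(results, kind).to_csv(path, sep="\t", index=False,
                                           float_format="%.6g")


def write_correlation_matrix(matrix, path) -> None:
    """Write an averaged correlation matrix as a labelled TSV."""
    labels = [f"{g}|{a}" for g, a in matrix.protein_ids]
    frame = pd.DataFrame(matrix.r_matrix, index=labels, columns=labels)
    frame.to_csv(path, sep="\t", float_format="%.6g")
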