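"""Proteome-wide association scans.

Two scans, sharing the random-intercept REML engine but with opposite model
directions (kept explicit so they cannot be swapped):

``AssociationScan``
    per protein, regress log2 PIVKA-II (outcome) on log2 protein abundance
    (predictor) with a per-experiment random intercept, over the children
    with a detectable PIVKA-II; the slope is reported as the percent change
    in PIVKA-II per doubling of protein abundance, (2**beta - 1) * 100.

``GroupDifferenceScan``
    per protein, regress log2 protein abundance (outcome) on the vitamin K
    deficiency indicator (PIVKA-II > 2 μg/L, deficient coded 1), again with
    an experiment random intercept; the coefficient is reported as the
    percent difference in abundance, deficient relative to sufficient.

Both scans apply the coverage rule (protein quantified in > ``min_children``
distinct children), correct each p-value family separately with Storey
q-values, and order results by ascending p. Degenerate per-protein fits are
logged and skipped, never fatal.

``build_cohort_table`` produces the descriptive deficient-vs-sufficient
comparison: t-test for continuous covariates declared normal, Mann-Whitney
for those declared skewed, chi-square (with continuity correction for 2x2)
for categoricals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssociationResult, CohortDataset, GroupDiffResult, \
    results_to_frame
from .lme import DegenerateDesignError, ModelSpec, RandomInterceptLM
from .preprocess import continuous_outcome_subset, dichotomize_vk, \
    filter_proteins_by_coverage
from .qvalue import QValueResult, storey_qvalues, threshold_report

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and conventions shared by the analyses."""

    q_primary: float = 0.10
    q_relaxed: float = 0.20
    vkd_cutoff_ugL: float = 2.0
    min_children: int = 50
    ci_level: float = 0.95
    #: Wald reference for per-protein p-values; "t_groups" (t with
    #: n_groups - 1 df) keeps the far tail calibrated with ~72 experiments,
    #: "normal" is the plain z-test
    p_reference: str = "t_groups"
    pi0_method: str = "smoother"
    r2_include_random: bool = True
    #: group analysis keeps below-detection children (classed sufficient)
    include_below_detection_in_groups: bool = True
    chi2_continuity_correction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.q_primary <= self.q_relaxed < 1.0):
            raise ValueError("need 0 < q_primary <= q_relaxed < 1")
        if self.vkd_cutoff_ugL <= 0:
            raise ValueError("VKD cutoff must be positive")


def percent_change(beta: float) -> float:
    """Percent change per doubling: (2**beta - 1) * 100."""
    return float((2.0 ** beta - 1.0) * 100.0)


def percent_change_interval(beta: float, se: float, level: float = 0.95
                            ) -> tuple[float, float, float]:
    """Percent change with CI transformed monotonically from beta +/- z*SE."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (percent_change(beta),
            percent_change(beta - z * se),
            percent_change(beta + z * se))


# ---------------------------------------------------------------------------
# scan machinery
# ---------------------------------------------------------------------------

def _per_protein_frames(dataset: CohortDataset, subject_cols: pd.DataFrame,
                        min_children: int):
    """Merge observations with per-child columns, yield per-protein frames.

    Coverage is assessed on all children with a quantitation (the study
    counts quantified children, not analysable ones); proteins whose
    analysable subset then falls to ``min_children`` or fewer are skipped by
    the caller.
    """
    filtered = filter_proteins_by_coverage(dataset, min_children)
    merged = filtered.observations.merge(subject_cols, on="child_id",
                                         how="inner")
    for (gi, symbol), frame in merged.groupby(["gi_accession", "gene_symbol"],
                                              sort=True):
        yield gi, symbol, frame


class _ScanResultsBase:
    """Shared surface for scan results: frame/report/summary accessors."""

    kind: str = ""

    def __init__(self, results, qresult: QValueResult, skipped, config):
        self.results = results
        self.qresult = qresult
        self.skipped = skipped
        self.config = config

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results, self.kind)

    def threshold_report(self) -> dict:
        q = np.array([r.q_value for r in self.results])
        ids = [r.gi_accession for r in self.results]
        return threshold_report(q, (self.config.q_primary,
                                    self.config.q_relaxed), ids=ids)

    def summary(self) -> str:
        rep = self.threshold_report()
        pi0 = (f"{self.qresult.pi0_hat:.3f}" if self.qresult is not None
               else "n/a")
        lines = [f"{type(self).__name__}: {len(self.results)} proteins "
                 f"tested, {len(self.skipped)} skipped",
                 f"  pi0_hat = {pi0}"]
        for t, entry in rep.items():
            lines.append(f"  discoveries at q < {t:g}: {entry['count']}")
        return "\n".join(lines)


class AssociationScanResults(_ScanResultsBase):
    kind = "association"


class GroupDifferenceScanResults(_ScanResultsBase):
    kind = "group_diff"


class AssociationScan:
    """Continuous PIVKA-II association scan (outcome = log2 PIVKA-II)."""

    def __init__(self, dataset: CohortDataset,
                 config: AnalysisConfig | None = None):
        if not dataset.normalized:
            raise ValueError("association scan requires a normalized dataset")
        self.dataset = dataset
        self.config = config or AnalysisConfig()

    def fit(self) -> AssociationScanResults:
        cfg = self.config
        subjects = continuous_outcome_subset(self.dataset.subjects)
        cols = subjects[["child_id", "log2_pivka"]]
        rows, skipped = [], []
        for gi, symbol, frame in _per_protein_frames(self.dataset, cols,
                                                     cfg.min_children):
            if len(frame) <= cfg.min_children:
                skipped.append((gi, "analysable children below coverage"))
                continue
            spec = ModelSpec(outcome=frame["log2_pivka"].to_numpy(),
                             predictor=frame["value"].to_numpy(),
                             group=frame["experiment_id"].to_numpy(),
                             direction="nutrient_on_protein")
            try:
                res = RandomInterceptLM.from_spec(spec).fit()
            except (DegenerateDesignError, np.linalg.LinAlgError) as exc:
                logger.warning("skipping protein %s: %s", gi, exc)
                skipped.append((gi, str(exc)))
                continue
            if not res.converged or not res.se_beta1 or res.se_beta1 <= 0:
                logger.warning("skipping protein %s: non-convergent fit", gi)
                skipped.append((gi, "non-convergent fit"))
                continue
            pc, lo, hi = percent_change_interval(res.beta1, res.se_beta1,
                                                 cfg.ci_level)
            rows.append(AssociationResult(
                gene_symbol=symbol, gi_accession=gi,
                n_obs=int(frame["child_id"].nunique()),
                beta=res.beta1, se_beta=res.se_beta1,
                percent_change=pc, ci_low=lo, ci_high=hi,
                p_value=res.wald_pvalue(cfg.p_reference), q_value=None,
                r2=res.r2(include_random=cfg.r2_include_random)))
        qresult = _attach_qvalues(rows, cfg)
        rows.sort(key=lambda r: r.p_value)
        return AssociationScanResults(rows, qresult, skipped, cfg)


class GroupDifferenceScan:
    """Deficient-vs-sufficient differential abundance scan."""

    def __init__(self, dataset: CohortDataset,
                 config: AnalysisConfig | None = None,
                 subjects_with_status: pd.DataFrame | None = None):
        if not dataset.normalized:
            raise ValueError("group scan requires a normalized dataset")
        self.dataset = dataset
        self.config = config or AnalysisConfig()
        if subjects_with_status is None:
            subjects_with_status = dichotomize_vk(
                dataset.subjects, cutoff_ugL=self.config.vkd_cutoff_ugL)
        self.subjects = subjects_with_status

    def fit(self) -> GroupDifferenceScanResults:
        cfg = self.config
        subjects = self.subjects[self.subjects["vk_status"].notna()]
        cols = subjects[["child_id", "vk_status"]].copy()
        cols["deficient"] = (cols["vk_status"] == "deficient").astype(float)
        rows, skipped = [], []
        for gi, symbol, frame in _per_protein_frames(
                self.dataset, cols[["child_id", "deficient"]],
                cfg.min_children):
            n_def = int(frame["deficient"].sum())
            n_suf = len(frame) - n_def
            if n_def < 2 or n_suf < 2:
                logger.warning("skipping protein %s: a group has < 2 children",
                               gi)
                skipped.append((gi, "group with < 2 observed children"))
                continue
            spec = ModelSpec(outcome=frame["value"].to_numpy(),
                             predictor=frame["deficient"].to_numpy(),
                             group=frame["experiment_id"].to_numpy(),
                             direction="protein_on_group")
            try:
                res = RandomInterceptLM.from_spec(spec).fit()
            except (DegenerateDesignError, np.linalg.LinAlgError) as exc:
                logger.warning("skipping protein %s: %s", gi, exc)
                skipped.append((gi, str(exc)))
                continue
            if not res.converged or not res.se_beta1 or res.se_beta1 <= 0:
                skipped.append((gi, "non-convergent fit"))
                continue
            pd_, lo, hi = percent_change_interval(res.beta1, res.se_beta1,
                                                  cfg.ci_level)
            rows.append(GroupDiffResult(
                gene_symbol=symbol, gi_accession=gi,
                n_obs=int(frame["child_id"].nunique()),
                beta_group=res.beta1, se_beta=res.se_beta1,
                percent_difference=pd_, ci_low=lo, ci_high=hi,
                p_value=res.wald_pvalue(cfg.p_reference), q_value=None))
        qresult = _attach_qvalues(rows, cfg)
        rows.sort(key=lambda r: r.p_value)
        return GroupDifferenceScanResults(rows, qresult, skipped, cfg)


def _attach_qvalues(rows, cfg: AnalysisConfig) -> QValueResult | None:
    if not rows:
        return None
    p = np.array([r.p_value for r in rows])
    qresult = storey_qvalues(p, pi0_method=cfg.pi0_method)
    for r, q in zip(rows, qresult.q_values):
        r.q_value = float(q)
    return qresult


# spec-level functional wrappers -------------------------------------------

def associate_all(dataset: CohortDataset,
                  config: AnalysisConfig | None = None
                  ) -> AssociationScanResults:
    """Run the per-protein PIVKA-II association scan."""
    return AssociationScan(dataset, config).fit()


def group_diff_all(dataset: CohortDataset,
                   config: AnalysisConfig | None = None,
                   subjects_with_status: pd.DataFrame | None = None
                   ) -> GroupDifferenceScanResults:
    """Run the per-protein deficiency-group differential abundance scan."""
    return GroupDifferenceScan(dataset, config, subjects_with_status).fit()


# ---------------------------------------------------------------------------
# descriptive cohort comparison
# ---------------------------------------------------------------------------

def build_cohort_table(subjects: pd.DataFrame,
                       covariates: dict[str, str],
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Deficient-vs-sufficient descriptive table.

    ``covariates`` maps column name -> kind: "normal" (mean (SD), t-test),
    "skewed" (median (IQR), Mann-Whitney) or "categorical" (percent,
    chi-square; continuity-corrected for 2x2). Covariates with no data in a
    group get a blank p.
    """
    config = config or AnalysisConfig()
    if "vk_status" not in subjects.columns:
        subjects = dichotomize_vk(subjects, config.vkd_cutoff_ugL)
    subjects = subjects[subjects["vk_status"].notna()]
    grp = {name: g for name, g in subjects.groupby("vk_status")}
    deficient = grp.get("deficient", subjects.iloc[0:0])
    sufficient = grp.get("sufficient", subjects.iloc[0:0])

    rows = []
    for name, kind in covariates.items():
        d = deficient[name].dropna() if name in deficient else pd.Series(dtype=float)
        s = sufficient[name].dropna() if name in sufficient else pd.Series(dtype=float)
        p = np.nan
        test = {"normal": "t-test", "skewed": "Mann-Whitney",
                "categorical": "chi-square"}[kind]
        if kind == "normal":
            d_sum = f"{d.mean():.2f} ({d.std():.2f})" if len(d) else ""
            s_sum = f"{s.mean():.2f} ({s.std():.2f})" if len(s) else ""
            if len(d) > 1 and len(s) > 1:
                p = stats.ttest_ind(d, s, equal_var=False).pvalue
        elif kind == "skewed":
            def iqr_fmt(v):
                return (f"{v.median():.2f} "
                        f"({v.quantile(0.25):.2f}, {v.quantile(0.75):.2f})")
            d_sum = iqr_fmt(d) if len(d) else ""
            s_sum = iqr_fmt(s) if len(s) else ""
            if len(d) and len(s):
                p = stats.mannwhitneyu(d, s, alternative="two-sided").pvalue
        elif kind == "categorical":
            levels = sorted(set(d.unique()) | set(s.unique()))
            def pct(v):
                if not len(v) or not levels:
                    return ""
                return "; ".join(
                    f"{lv}: {100.0 * (v == lv).mean():.1f}%" for lv in levels)
            d_sum, s_sum = pct(d), pct(s)
            if len(d) and len(s) and len(levels) > 1:
                table = np.array([[(d == lv).sum() for lv in levels],
                                  [(s == lv).sum() for lv in levels]])
                correction = (config.chi2_continuity_correction
                              and table.shape == (2, 2))
                p = stats.chi2_contingency(table, correction=correction)[1]
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
        rows.append({"covariate": name, "kind": kind,
                     "deficient": d_sum, "sufficient": s_sum,
                     "p_value": p, "test": test})
    return pd.DataFrame(rows, columns=["covariate", "kind", "deficient",
                                       "sufficient", "p_value", "test"])
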