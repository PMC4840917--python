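"""Within-experiment-averaged protein co-abundance correlation matrix.

Because each iTRAQ experiment carries its own batch offset, correlations
between protein abundances are computed within each experiment (over the
children quantified for both proteins in that run) and the per-experiment
Pearson coefficients are then averaged, unweighted, across experiments.
Pairs with no contributing experiment are left missing. Per-experiment
sample sizes are small (at most the plex size), so n-weighted and
Fisher-z-averaged modes are provided as sensitivity options.

For display, coefficients smaller than ±0.01 in magnitude are set to exactly
zero (strict inequality; the diagonal is untouched).

The proteins entering the matrix are those associated with PIVKA-II or with
vitamin K deficiency at the relaxed threshold q < 0.20, in either scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDataset

__all__ = ["AveragedCorrelationMatrix", "averaged_correlation",
           "display_threshold", "select_network_proteins", "plot_heatmap"]


@dataclass
class AveragedCorrelationMatrix:
    protein_ids: list[tuple[str, str]]  # (gene_symbol, gi_accession)
    r_matrix: np.ndarray
    support_matrix: np.ndarray  # experiments contributing per pair

    def __post_init__(self) -> None:
        r = self.r_matrix
        if r.shape[0] != r.shape[1] or r.shape[0] != len(self.protein_ids):
            raise ValueError("matrix/ids shape mismatch")
        finite = np.isfinite(r)
        if finite.any() and (np.abs(r[finite]) > 1.0 + 1e-12).any():
            raise ValueError("correlation outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{g}|{a}" for g, a in self.protein_ids]
        return pd.DataFrame(self.r_matrix, index=labels, columns=labels)


def averaged_correlation(dataset: CohortDataset, protein_ids,
                         min_pairs_per_experiment: int = 3,
                         method: str = "mean") -> AveragedCorrelationMatrix:
    """Average within-experiment Pearson correlations across experiments.

    ``protein_ids`` is a sequence of GI accessions (order preserved).
    ``method``: "mean" (unweighted, default), "weighted" (by complete pairs
    per experiment) or "fisher" (average on the atanh scale, back-transform).
    Experiments contributing fewer than ``min_pairs_per_experiment`` complete
    pairs for a given pair of proteins are skipped for that pair.
    """
    gis = list(protein_ids)
    if len(gis) < 2:
        raise ValueError("need at least 2 proteins for a correlation matrix")
    if min_pairs_per_experiment < 2:
        raise ValueError("min_pairs_per_experiment must be >= 2")
    obs = dataset.observations
    sub = obs[obs["gi_accession"].isin(set(gis))]
    symbol_of = dict(zip(sub["gi_accession"], sub["gene_symbol"]))
    missing = [g for g in gis if g not in symbol_of]
    if missing:
        raise ValueError(f"proteins not present in dataset: {missing[:5]}")
    P = len(gis)
    idx = {g: k for k, g in enumerate(gis)}

    sums = np.zeros((P, P))
    wsum = np.zeros((P, P))
    support = np.zeros((P, P), dtype=int)
    for _, frame in sub.groupby("experiment_id", sort=False):
        wide = frame.pivot(index="child_id", columns="gi_accession",
                           values="value")
        if wide.shape[0] < min_pairs_per_experiment or wide.shape[1] < 2:
            continue
        cols = [idx[g] for g in wide.columns]
        r = wide.corr(min_periods=min_pairs_per_experiment).to_numpy()
        counts = wide.notna().astype(float).T @ wide.notna().astype(float)
        counts = counts.to_numpy()
        ok = np.isfinite(r)
        ii, jj = np.meshgrid(cols, cols, indexing="ij")
        if method == "fisher":
            with np.errstate(divide="ignore"):
                val = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
            w = np.where(ok, 1.0, 0.0)
        elif method == "weighted":
            val, w = r, np.where(ok, counts, 0.0)
        elif method == "mean":
            val, w = r, np.where(ok, 1.0, 0.0)
        else:
            raise ValueError(f"unknown averaging method {method!r}")
        val = np.where(ok, val, 0.0)
        np.add.at(sums, (ii, jj), w * val)
        np.add.at(wsum, (ii, jj), w)
        np.add.at(support, (ii, jj), ok.astype(int))

    with np.errstate(invalid="ignore"):
        avg = sums / wsum
    if method == "fisher":
        avg = np.tanh(avg)
    avg = np.clip(avg, -1.0, 1.0)
    np.fill_diagonal(avg, 1.0)
    np.fill_diagonal(support, int(support.max(initial=0)))
    symbols = [(symbol_of[g], g) for g in gis]
    return AveragedCorrelationMatrix(protein_ids=symbols, r_matrix=avg,
                                     support_matrix=support)


def display_threshold(matrix: AveragedCorrelationMatrix, eps: float = 0.01
                      ) -> AveragedCorrelationMatrix:
    """Zero out coefficients with |r| strictly below ``eps`` (diagonal kept)."""
    r = matrix.r_matrix.copy()
    mask = np.abs(r) < eps
    np.fill_diagonal(mask, False)
    r[mask] = 0.0
    return AveragedCorrelationMatrix(protein_ids=list(matrix.protein_ids),
                                     r_matrix=r,
                                     support_matrix=matrix.support_matrix.copy())


def select_network_proteins(association_results, group_results,
                            q_relaxed: float = 0.20) -> list[str]:
    """Union of proteins with q < ``q_relaxed`` in either scan.

    Returns GI accessions, de-duplicated, ordered by ascending minimum q
    across the two families (strict inequality at the threshold).
    """
    min_q: dict[str, float] = {}
    for r in list(association_results) + list(group_results):
        q = r.q_value
        if q is None or not (q < q_relaxed):
            continue
        min_q[r.gi_accession] = min(q, min_q.get(r.gi_accession, np.inf))
    if not min_q:
        raise ValueError(
            f"no protein passes q < {q_relaxed}; relax the threshold")
    return sorted(min_q, key=lambda g: (min_q[g], g))


def plot_heatmap(matrix: AveragedCorrelationMatrix, path,
                 eps: float = 0.01) -> None:
    """Render the thresholded matrix (blue positive, red negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    shown = display_threshold(matrix, eps)
    labels = [g for g, _ in shown.protein_ids]
    fig, ax = plt.subplots(figsize=(0.35 * len(labels) + 3,) * 2)
    sns.heatmap(shown.to_frame(), cmap="RdBu", vmin=-1, vmax=1,
                xticklabels=labels, yticklabels=labels, square=True, ax=ax,
                cbar_kws={"label": "averaged Pearson r"})
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
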