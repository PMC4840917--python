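"""Synthetic cohort generator.

Emulates the study design the analysis assumes: 500 children allocated
across 72 iTRAQ 8-plex experiments (576 channel slots, surplus left empty at
random), ~4705 proteins with missing-by-experiment quantitation averaging
589 detected proteins per run, a right-skewed PIVKA-II distribution (median
1.31 μg/L, quartiles 0.83 / 1.87, ~20% above the 2 μg/L deficiency cutoff,
26/500 below the 0.001 μg/L detection limit) partially driven by a handful
of "driver" proteins, experiment-level batch effects on abundance, and one
correlated block of proteins sharing a latent factor (the hemoglobin /
erythrocyte-enzyme cluster analogue).

Generative model
----------------
latent log2 abundance deviation:   x_ip = u_{j(i),p} + b_ip,
    u_{j,p} ~ N(0, sigma2_u), b_ip ~ N(0, sigma2_bio); block proteins share
    a child-level factor so that corr(b_ip, b_iq) = rho within the block.
outcome:   log2 Y_i = sum_k beta_k x_{i,driver_k} + e_i,
    e_i skew-normal with (location, scale, shape) solved numerically so the
    full-sample marginal of Y matches the target median, quartiles and
    deficient fraction (a symmetric residual cannot match the asymmetric
    quartile gaps). A randomly chosen ``frac_below_detection`` of children
    form an assay-floor component: their latent value is shifted far below
    the 0.001 μg/L detection limit (the study's undetectable values sit
    three orders of magnitude under the bulk median), making them exactly
    the lowest-latent fraction, censored to 0. Because the floor indicator
    is independent of protein abundance, dropping these children from the
    continuous analysis does not truncate the outcome distribution of the
    remaining bulk — mirroring the real analysis, where excluding assay
    failures is not selection on the modelled outcome. The bulk calibration
    accounts for the floor mass (full-sample probability p maps to bulk
    probability (p - p0) / (1 - p0)).
detection: protein p is detected in experiment j with probability pi_p drawn
    from a Beta calibrated so that both the mean detected-per-experiment
    count and the expected number of well-covered proteins (> 50 children)
    hit their targets. Driver and block proteins receive the largest drawn
    detection probabilities (the reported drivers were quantified in 200-474
    children).
raw reporter intensity: 2 ** (base + c_i + mu_p + x_ip) with a per-channel
    loading offset c_i and a per-protein baseline mu_p — both removed by
    log2 channel-median normalization downstream.

A single master seed fans out to per-stage substreams, so identical configs
and seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CohortDataset

__all__ = ["PivkaTarget", "BlockConfig", "SimConfig", "SyntheticTruth",
           "generate_cohort", "resample_null", "CalibrationError",
           "DEFAULT_DRIVER_SLOPES"]


class CalibrationError(ValueError):
    """The requested marginal targets cannot be met by the generator."""


#: Default true slopes of log2 PIVKA-II on log2 protein abundance for the
#: driver proteins; log2 of (1 + percent/100) for percent changes of
#: +137.5, -39.8, -46.0, -38.6 and +11.7 per doubling.
DEFAULT_DRIVER_SLOPES = (1.2479, -0.7322, -0.8890, -0.7027, 0.1596)


@dataclass(frozen=True)
class PivkaTarget:
    """Marginal targets for the PIVKA-II distribution (μg/L)."""

    median: float = 1.31
    q1: float = 0.83
    q3: float = 1.87
    frac_deficient: float = 0.20
    frac_below_detection: float = 26 / 500

    def __post_init__(self) -> None:
        if not (0 < self.q1 < self.median < self.q3):
            raise CalibrationError("need 0 < q1 < median < q3")
        if not (0 <= self.frac_below_detection <= 1
                and 0 <= self.frac_deficient <= 1):
            raise CalibrationError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class BlockConfig:
    """A block of proteins sharing one latent factor (within-block rho)."""

    size: int = 6
    rho: float = 0.8


@dataclass(frozen=True)
class SimConfig:
    n_children: int = 500
    n_experiments: int = 72
    plex_size: int = 8
    n_proteins_total: int = 4705
    mean_proteins_per_experiment: float = 589.0
    #: expected number of proteins quantified in > min_children children;
    #: None -> detection Beta uses a fixed concentration instead
    n_covered_target: float | None = 978.0
    min_children: int = 50
    driver_slopes: tuple[float, ...] = DEFAULT_DRIVER_SLOPES
    sigma2_u_protein: float = 0.045
    sigma2_bio: float = 0.06
    sigma2_mu: float = 0.25
    channel_loading_sd: float = 0.3
    log2_intensity_base: float = 14.0
    pivka_target: PivkaTarget = field(default_factory=PivkaTarget)
    correlated_block: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plex_size < 1:
            raise ValueError("plex_size must be >= 1")
        if self.n_children > self.n_experiments * self.plex_size:
            raise ValueError("more children than channel slots")
        if min(self.sigma2_u_protein, self.sigma2_bio, self.sigma2_mu) < 0:
            raise ValueError("variances must be non-negative")
        n_special = len(self.driver_slopes) + self.correlated_block.size
        if n_special > self.n_proteins_total:
            raise ValueError("drivers + block exceed the proteome size")
        if self.mean_proteins_per_experiment > self.n_proteins_total:
            raise CalibrationError(
                "mean detected per experiment exceeds the proteome size")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def reduced(cls, n_proteins_total: int = 300,
                mean_proteins_per_experiment: float = 200.0,
                **kwargs) -> "SimConfig":
        """A runtime-reduced proteome for simulation studies.

        The detected fraction per experiment is kept high (default 200/300)
        rather than scaled down proportionally: channel-median normalization
        relies on hundreds of quantified proteins per run, and the variance
        of the median reference grows as 1/#proteins — scaling detection
        down with the proteome would inject normalization noise the
        full-scale design does not have.
        """
        kwargs.setdefault("n_covered_target", None)
        return cls(n_proteins_total=n_proteins_total,
                   mean_proteins_per_experiment=mean_proteins_per_experiment,
                   **kwargs)


@dataclass
class SyntheticTruth:
    """Everything needed to recompute the generative model from the seed."""

    config: SimConfig
    protein_table: pd.DataFrame  # gene_symbol, gi_accession, mu, is_driver,
    #                              in_block, detection_prob, true_slope
    latent_log2_pivka: np.ndarray
    residual_params: dict  # skew-normal (xi, omega, shape) and d_var
    detection_beta: tuple[float, float]
    detected: np.ndarray  # (n_proteins, n_experiments) bool

    @property
    def drivers(self) -> pd.DataFrame:
        t = self.protein_table
        return t[t["is_driver"]].reset_index(drop=True)

    @property
    def block_members(self) -> list[str]:
        t = self.protein_table
        return list(t.loc[t["in_block"], "gi_accession"])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _children_per_experiment(n_children: int, n_experiments: int) -> np.ndarray:
    base, extra = divmod(n_children, n_experiments)
    sizes = np.full(n_experiments, base, dtype=int)
    sizes[:extra] += 1
    return sizes


def calibrate_detection_beta(config: SimConfig) -> tuple[float, float]:
    """Solve the Beta(a, b) of per-protein detection probabilities.

    Constraints: mean pi = mean_proteins_per_experiment / n_proteins_total,
    and (when ``n_covered_target`` is set) the expected fraction of proteins
    detected in enough experiments to cover > min_children children matches
    n_covered_target / n_proteins_total.
    """
    mu = config.mean_proteins_per_experiment / config.n_proteins_total
    if not (0.0 < mu < 1.0):
        raise CalibrationError("mean detection probability outside (0, 1)")
    if config.n_covered_target is None:
        a = 8.0 * mu
        return a, a * (1.0 - mu) / mu
    children_per_exp = config.n_children / config.n_experiments
    k_min = int(np.floor(config.min_children / children_per_exp)) + 1
    target = config.n_covered_target / config.n_proteins_total
    u = (np.arange(2000) + 0.5) / 2000.0

    def covered_frac(log10_a: float) -> float:
        a = 10.0 ** log10_a
        b = a * (1.0 - mu) / mu
        pi = stats.beta.ppf(u, a, b)
        return float(np.mean(stats.binom.sf(k_min - 1, config.n_experiments,
                                            pi))) - target

    lo, hi = -3.0, 3.0
    f_lo, f_hi = covered_frac(lo), covered_frac(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            "covered-protein target unreachable for the requested mean "
            f"detection (bracket values {f_lo + target:.3f}, "
            f"{f_hi + target:.3f}, target {target:.3f})")
    log10_a = optimize.brentq(covered_frac, lo, hi, xtol=1e-10)
    a = 10.0 ** log10_a
    return a, a * (1.0 - mu) / mu


def _sum_cdf(t: float, xi: float, omega: float, shape: float,
             d_sd: float, nodes: np.ndarray, weights: np.ndarray) -> float:
    """CDF of D + e at t, D ~ N(0, d_sd^2), e ~ skew-normal."""
    if d_sd == 0.0:
        return float(stats.skewnorm.cdf(t, shape, loc=xi, scale=omega))
    vals = stats.skewnorm.cdf(t - d_sd * nodes, shape, loc=xi, scale=omega)
    return float(np.sum(weights * vals))


def calibrate_outcome_residual(d_var: float, target: PivkaTarget,
                               max_misfit: float = 0.03) -> dict:
    """Solve skew-normal residual params so D + e matches the marginal targets.

    Matches, in least squares on the CDF scale, the target median, both
    quartiles and the deficient fraction (P(Y > 2 μg/L)) of the marginal
    distribution of D + e, D ~ N(0, d_var). Four targets, three parameters:
    an exact fit is generally impossible (the driver contribution is
    symmetric while the target quartile gaps are not), but the balanced
    solution stays within ~0.01 on the CDF scale, i.e. ~2% on the quantiles.
    Raises :class:`CalibrationError` when the best CDF misfit exceeds
    ``max_misfit`` (infeasible targets).
    """
    t_q1, t_med, t_q3 = (np.log2(target.q1), np.log2(target.median),
                         np.log2(target.q3))
    t_cut = 1.0  # log2 of the 2 μg/L deficiency cutoff
    # the below-detection floor holds the lowest p0 of the full sample, so a
    # full-sample probability p corresponds to (p - p0)/(1 - p0) in the bulk
    p0 = target.frac_below_detection
    if p0 >= 0.25:
        raise CalibrationError(
            "below-detection fraction must be below the first quartile")
    full = np.array([0.25, 0.50, 0.75, 1.0 - target.frac_deficient])
    bulk = (full - p0) / (1.0 - p0)
    targets = np.column_stack([[t_q1, t_med, t_q3, t_cut], bulk])
    d_sd = float(np.sqrt(max(d_var, 0.0)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    weights = weights / np.sqrt(2.0 * np.pi)

    total_sd = (t_q3 - t_q1) / (2.0 * 0.6744897501960817)
    omega0 = np.sqrt(max(total_sd ** 2 - d_var, 0.05 * total_sd ** 2))

    def residuals(params):
        xi, log_omega, shape = params
        omega = np.exp(log_omega)
        return np.array([
            _sum_cdf(t, xi, omega, shape, d_sd, nodes, weights) - prob
            for t, prob in targets])

    best = None
    for shape0 in (-1.5, 0.0, -4.0, 1.5):
        sol = optimize.least_squares(
            residuals, x0=[t_med, np.log(omega0), shape0],
            bounds=([-5.0, -5.0, -30.0], [5.0, 2.0, 30.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if np.max(np.abs(sol.fun)) < 1e-10:
            break
    misfit = float(np.max(np.abs(best.fun)))
    if misfit > max_misfit:
        raise CalibrationError(
            "could not match the PIVKA-II marginal targets given the driver "
            f"variance contribution (best CDF misfit {misfit:.3f})")
    xi, log_omega, shape = best.x
    return {"xi": float(xi), "omega": float(np.exp(log_omega)),
            "shape": float(shape), "d_var": float(d_var),
            "cdf_misfit": misfit}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[CohortDataset, SyntheticTruth]:
    """Generate a raw-intensity cohort plus its ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_alloc, rng_prot, rng_det, rng_abund, rng_out, rng_chan = \
        [np.random.default_rng(s) for s in ss.spawn(6)]

    nC, nE, nP = (config.n_children, config.n_experiments,
                  config.n_proteins_total)
    child_ids = np.array([f"C{i + 1:04d}" for i in range(nC)])
    exp_ids = np.array([f"E{j + 1:02d}" for j in range(nE)])

    # --- allocation: shuffled children chunked into experiments ------------
    sizes = _children_per_experiment(nC, nE)
    rng_alloc.shuffle(sizes)
    order = rng_alloc.permutation(nC)
    child_exp = np.empty(nC, dtype=int)
    child_channel = np.empty(nC, dtype=int)
    pos = 0
    for j, sz in enumerate(sizes):
        members = order[pos:pos + sz]
        child_exp[members] = j
        child_channel[members] = rng_chan.choice(
            config.plex_size, size=sz, replace=False) + 1
        pos += sz

    # --- proteins -----------------------------------------------------------
    gene = np.array([f"PROT{p + 1:04d}" for p in range(nP)])
    gi = np.array([f"{10_000_000 + p + 1}" for p in range(nP)])
    mu = rng_prot.normal(0.0, np.sqrt(config.sigma2_mu), size=nP)

    n_drivers = len(config.driver_slopes)
    block_size = config.correlated_block.size
    driver_idx = np.arange(n_drivers)
    block_idx = np.arange(n_drivers, n_drivers + block_size)

    # --- detection ----------------------------------------------------------
    a, b = calibrate_detection_beta(config)
    pi = rng_det.beta(a, b, size=nP)
    special = np.concatenate([driver_idx, block_idx]).astype(int)
    if len(special):
        # swap the largest detection probabilities onto driver/block slots so
        # the reported-effect proteins are analysable; a pure permutation of
        # the draws, so the marginal Beta calibration is untouched
        special_set = set(special.tolist())
        top = np.argsort(-pi)[:len(special)]
        free_special = [s for s in special if s not in set(top.tolist())]
        for idx in top:
            if int(idx) in special_set:
                continue
            s = free_special.pop()
            pi[s], pi[idx] = pi[idx], pi[s]
    detected = rng_det.random((nP, nE)) < pi[:, None]

    # --- latent abundance deviations ---------------------------------------
    sd_u = np.sqrt(config.sigma2_u_protein)
    sd_b = np.sqrt(config.sigma2_bio)
    u = rng_abund.normal(0.0, sd_u, size=(nE, nP))
    b_dev = rng_abund.normal(0.0, sd_b, size=(nC, nP))
    rho = config.correlated_block.rho
    if block_size and rho > 0:
        f = rng_abund.normal(0.0, 1.0, size=nC)
        eps = rng_abund.normal(0.0, 1.0, size=(nC, block_size))
        b_dev[:, block_idx] = sd_b * (np.sqrt(rho) * f[:, None]
                                      + np.sqrt(1.0 - rho) * eps)
    x_dev = u[child_exp, :] + b_dev  # (nC, nP)

    # --- outcome ------------------------------------------------------------
    slopes = np.asarray(config.driver_slopes, dtype=float)
    var_x = config.sigma2_u_protein + config.sigma2_bio
    d_var = float(np.sum(slopes ** 2) * var_x)
    resid = calibrate_outcome_residual(d_var, config.pivka_target)
    d = x_dev[:, driver_idx] @ slopes if n_drivers else np.zeros(nC)
    e = stats.skewnorm.rvs(resid["shape"], loc=resid["xi"],
                           scale=resid["omega"], size=nC,
                           random_state=rng_out)
    latent = d + e
    n_censor = int(round(config.pivka_target.frac_below_detection * nC))
    if n_censor:
        # assay-floor component: far below the detection limit, independent
        # of protein abundance (excluding it is not outcome truncation)
        floor = rng_out.choice(nC, size=n_censor, replace=False)
        latent[floor] = latent[floor] - 14.0
    pivka = np.power(2.0, latent)
    below = np.zeros(nC, dtype=bool)
    if n_censor:
        cut = np.argsort(latent)[:n_censor]
        below[cut] = True
        pivka[cut] = 0.0

    subjects = pd.DataFrame({
        "child_id": child_ids,
        "experiment_id": exp_ids[child_exp],
        "channel": child_channel,
        "pivka2_ugL": np.round(pivka, 6),
        "below_detection": below,
    })

    # --- observations -------------------------------------------------------
    c_off = rng_abund.normal(0.0, config.channel_loading_sd, size=nC)
    base = config.log2_intensity_base
    chunks = []
    for j in range(nE):
        prot_j = np.flatnonzero(detected[:, j])
        kids_j = np.flatnonzero(child_exp == j)
        if not len(prot_j) or not len(kids_j):
            continue
        pp = np.repeat(prot_j, len(kids_j))
        kk = np.tile(kids_j, len(prot_j))
        log2_raw = base + c_off[kk] + mu[pp] + x_dev[kk, pp]
        chunks.append(pd.DataFrame({
            "gene_symbol": gene[pp],
            "gi_accession": gi[pp],
            "child_id": child_ids[kk],
            "experiment_id": exp_ids[j],
            "value": np.power(2.0, log2_raw),
        }))
    observations = (pd.concat(chunks, ignore_index=True) if chunks
                    else pd.DataFrame(columns=["gene_symbol", "gi_accession",
                                               "child_id", "experiment_id",
                                               "value"]))

    true_slope = np.zeros(nP)
    true_slope[driver_idx] = slopes
    protein_table = pd.DataFrame({
        "gene_symbol": gene,
        "gi_accession": gi,
        "mu": mu,
        "is_driver": np.isin(np.arange(nP), driver_idx),
        "in_block": np.isin(np.arange(nP), block_idx),
        "detection_prob": pi,
        "true_slope": true_slope,
    })
    truth = SyntheticTruth(config=config, protein_table=protein_table,
                           latent_log2_pivka=latent, residual_params=resid,
                           detection_beta=(a, b), detected=detected)
    dataset = CohortDataset(subjects=subjects, observations=observations,
                            normalized=False)
    return dataset, truth


def resample_null(dataset: CohortDataset, seed: int) -> CohortDataset:
    """Permute PIVKA-II across children within each experiment.

    Severs child-level protein-outcome association while preserving the
    multiset of outcome values and the batch structure.
    """
    rng = np.random.default_rng(seed)
    subjects = dataset.subjects.copy()
    cols = ["pivka2_ugL"]
    if "below_detection" in subjects.columns:
        cols.append("below_detection")
    for _, idx in subjects.groupby("experiment_id").groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        subjects.loc[idx, cols] = subjects.loc[idx[perm], cols].to_numpy()
    return dataset.replace(subjects=subjects)
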