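"""Composite goodness-of-fit test of the standard neutral model.

The observed multi-locus data are reduced to five summaries: the variance
across loci of Tajima's D, plus across-locus means of the segregating-site
count S, the mean pairwise difference pi, Fu & Li's D* and Tajima's D.
Many datasets are then simulated under a constant-size, random-mating
coalescent in which each locus draws its theta from a Gamma and its rho
from a log-normal hyperprior (moment-matched to per-locus rate estimates).
Each summary gets a two-sided empirical p-value against the simulated
distribution, C = sum of their natural logs, and the reported fit p-value
is the proportion of simulated datasets whose own (leave-one-out) C is at
least as extreme.  rho is drawn, so linkage affects the across-locus
variance, but is never itself a summary statistic.

Loci with S = 0 contribute zero to the S and pi means and are excluded
from the D-statistic means and variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .popgen import (fu_li_dstar_from_counts, locus_summary,
                     tajimas_d_from_counts)
from .simulate import CoalescentParams, _simulate_counts

STAT_NAMES = ("var_tajima_d", "mean_S", "mean_pi", "mean_fu_li_dstar",
              "mean_tajima_d")


@dataclass(frozen=True)
class NullModelConfig:
    """Null-model layout: per-locus sample sizes/lengths and the theta /
    rho hyperpriors.  A Gamma shape of +inf encodes a point mass at the
    scale value; a log-normal sdlog of 0 is naturally a point mass."""

    reps: int
    loci: list[tuple[int, int]]
    theta_gamma: tuple[float, float]
    rho_lognormal: tuple[float, float]
    seed: int = 0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not all(s > 0 or math.isinf(s) for s in
                   (self.theta_gamma[0], self.theta_gamma[1] + 1e-300)):
            raise ValueError("gamma parameters must be positive")


@dataclass(frozen=True)
class SummaryVector:
    var_tajima_d: float
    mean_S: float
    mean_pi: float
    mean_fu_li_dstar: float
    mean_tajima_d: float
    n_loci_defined: int = 0  # loci with S >= 1 entering the D statistics

    def as_array(self) -> np.ndarray:
        return np.array([self.var_tajima_d, self.mean_S, self.mean_pi,
                         self.mean_fu_li_dstar, self.mean_tajima_d])


@dataclass(frozen=True)
class FitResult:
    observed: SummaryVector
    per_stat_pvalues: dict[str, float]
    C: float
    fit_pvalue: float
    reps: int
    seed: int


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _locus_stats_from_counts(counts: np.ndarray, n: int):
    """(S, pi_total, D, D*) from derived-allele counts at one locus."""
    S = len(counts)
    if S == 0:
        return 0, 0.0, math.nan, math.nan
    minor = np.minimum(counts, n - counts)
    pi_total = float(np.sum(counts * (n - counts)) / (n * (n - 1) / 2.0))
    d = tajimas_d_from_counts(S, pi_total, n)
    dstar = fu_li_dstar_from_counts(S, int(np.sum(minor == 1)), n)
    return S, pi_total, d, dstar


def summarize_loci(per_locus) -> SummaryVector:
    """Aggregate per-locus (S, pi_total, D, D*) tuples into a SummaryVector."""
    S = np.array([x[0] for x in per_locus], dtype=float)
    pi = np.array([x[1] for x in per_locus], dtype=float)
    d = np.array([x[2] for x in per_locus], dtype=float)
    ds = np.array([x[3] for x in per_locus], dtype=float)
    ok = S >= 1
    ndef = int(ok.sum())
    return SummaryVector(
        var_tajima_d=float(np.var(d[ok], ddof=1)) if ndef >= 2 else math.nan,
        mean_S=float(S.mean()),
        mean_pi=float(pi.mean()),
        mean_fu_li_dstar=float(ds[ok].mean()) if ndef else math.nan,
        mean_tajima_d=float(d[ok].mean()) if ndef else math.nan,
        n_loci_defined=ndef)


def observed_summary(alignments, population: str | None = None) -> SummaryVector:
    """SummaryVector for observed multi-locus haplotype alignments."""
    per_locus = []
    for aln in alignments:
        s = locus_summary(aln, population)
        per_locus.append((s.S, s.pi_total, s.tajima_d, s.fu_li_dstar))
    return summarize_loci(per_locus)


# ---------------------------------------------------------------------------
# null simulation
# ---------------------------------------------------------------------------

def _draw_theta(rng, gamma: tuple[float, float]) -> float:
    shape, scale = gamma
    return scale if math.isinf(shape) else float(rng.gamma(shape, scale))


def _draw_rho(rng, lognorm: tuple[float, float]) -> float:
    meanlog, sdlog = lognorm
    return math.exp(meanlog) if sdlog == 0 else float(
        math.exp(rng.normal(meanlog, sdlog)))


def simulate_null(config: NullModelConfig) -> list[SummaryVector]:
    """One SummaryVector per simulated multi-locus dataset; theta and rho
    are drawn independently for each locus of each replicate."""
    if not config.loci:
        raise ValueError("config.loci must be non-empty")
    rng = np.random.default_rng(config.seed)
    out: list[SummaryVector] = []
    for _ in range(config.reps):
        per_locus = []
        for n, length in config.loci:
            theta = _draw_theta(rng, config.theta_gamma)
            rho = _draw_rho(rng, config.rho_lognormal)
            params = CoalescentParams(n_samples=n, locus_length=length,
                                      theta=theta, rho=rho,
                                      growth_rate=config.growth_rate)
            counts = _simulate_counts(params, rng)
            per_locus.append(_locus_stats_from_counts(counts, n))
        out.append(summarize_loci(per_locus))
    return out


# ---------------------------------------------------------------------------
# empirical p-values and the composite statistic
# ---------------------------------------------------------------------------

def empirical_pvalue(observed: float, null_draws) -> float:
    """Two-sided empirical p-value with add-one smoothing:
    p = min(1, 2 * min[(1 + #{x <= obs}) / (1 + R), (1 + #{x >= obs}) / (1 + R)]).
    """
    x = np.asarray(null_draws, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one null draw")
    if not np.isfinite(observed):
        return 1.0
    R = x.size
    le = int(np.sum(x <= observed))
    ge = int(np.sum(x >= observed))
    return min(1.0, 2.0 * min((1 + le) / (1 + R), (1 + ge) / (1 + R)))


def _loo_pvalues(col: np.ndarray) -> np.ndarray:
    """Leave-one-out two-sided p-values of each draw against the rest."""
    R = col.size
    p = np.ones(R)
    finite = np.isfinite(col)
    x = col[finite]
    if x.size < 2:
        return p
    xs = np.sort(x)
    le = np.searchsorted(xs, x, side="right") - 1   # ties minus self
    ge = (x.size - np.searchsorted(xs, x, side="left")) - 1
    denom = float(x.size)  # 1 + (Rf - 1) comparison draws
    pf = np.minimum(1.0, 2.0 * np.minimum((1 + le) / denom, (1 + ge) / denom))
    p[finite] = pf
    return p


def composite_fit(observed: SummaryVector,
                  null: NullModelConfig | list[SummaryVector],
                  seed: int | None = None) -> FitResult:
    """Composite C-statistic test of the observed summaries against the
    simulated null.  Smaller C (more extreme joint p-values) indicates a
    worse fit; fit_pvalue is the smoothed proportion of simulated datasets
    whose leave-one-out C is <= the observed C."""
    if isinstance(null, NullModelConfig):
        config_seed = null.seed
        reps = null.reps
        draws = simulate_null(null)
    else:
        config_seed = seed if seed is not None else -1
        draws = list(null)
        reps = len(draws)
    if reps < 100:
        warnings.warn("fewer than 100 null replicates: p-values are unstable")

    mat = np.array([d.as_array() for d in draws])  # reps x 5
    obs = observed.as_array()
    p_obs = {name: empirical_pvalue(obs[j], mat[:, j])
             for j, name in enumerate(STAT_NAMES)}
    C_obs = float(sum(math.log(p) for p in p_obs.values()))

    logp_null = np.zeros(reps)
    for j in range(5):
        logp_null += np.log(_loo_pvalues(mat[:, j]))
    fit_p = (1 + int(np.sum(logp_null <= C_obs))) / (1 + reps)
    return FitResult(observed=observed, per_stat_pvalues=p_obs, C=C_obs,
                     fit_pvalue=float(fit_p), reps=reps, seed=config_seed)


# ---------------------------------------------------------------------------
# calibration / power experiments
# ---------------------------------------------------------------------------

def calibration_experiment(config: NullModelConfig, n_repetitions: int = 200,
                           n_blocks: int = 8, alpha: float = 0.05,
                           observed_growth_rate: float = 0.0) -> dict:
    """Repeatedly test data simulated under a known model against the null.

    The repetitions are split over n_blocks independently simulated null
    ensembles (each of config.reps replicates), which keeps the experiment
    tractable while the observed datasets stay fully independent.  With
    observed_growth_rate = 0 this measures the test's type-I error at
    ``alpha``; with growth > 0 it measures power against an expanding
    population.  Returns the fit p-values and the rejection rate.
    """
    if n_repetitions % n_blocks:
        raise ValueError("n_repetitions must divide evenly into n_blocks")
    per_block = n_repetitions // n_blocks
    master = np.random.default_rng(config.seed)
    pvals: list[float] = []
    for _ in range(n_blocks):
        null_cfg = NullModelConfig(
            reps=config.reps, loci=config.loci,
            theta_gamma=config.theta_gamma,
            rho_lognormal=config.rho_lognormal,
            seed=int(master.integers(2 ** 31)))
        null_draws = simulate_null(null_cfg)
        obs_cfg = NullModelConfig(
            reps=per_block, loci=config.loci,
            theta_gamma=config.theta_gamma,
            rho_lognormal=config.rho_lognormal,
            seed=int(master.integers(2 ** 31)),
            growth_rate=observed_growth_rate)
        for obs in simulate_null(obs_cfg):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = composite_fit(obs, null_draws)
            pvals.append(fit.fit_pvalue)
    arr = np.asarray(pvals)
    return {"fit_pvalues": pvals,
            "rejection_rate": float(np.mean(arr <= alpha)),
            "median_pvalue": float(np.median(arr)),
            "alpha": alpha, "n_repetitions": n_repetitions}
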