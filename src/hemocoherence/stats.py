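"""Statistical stage: per-patient velocity distribution fits and comparison,
rank correlations, post-hoc bootstrap, and the Pmca plateau estimator.

Velocity distributions are fitted as log-normals by maximum likelihood (the
sample mean/sd of the log-velocities) with a Kolmogorov-Smirnov goodness-of-fit
check of the logs against the fitted normal. Group comparison is the
Kruskal-Wallis rank test (the standard non-parametric one-way ANOVA).
Correlations are Kendall's tau-b (tie-corrected; velocities and
table-precision pressures contain ties) and Spearman's rho. Because the
clinical analogue has only 20 subjects, correlations are accompanied by a
small-n post-hoc bootstrap (percentile intervals over resampled pairs;
n_resamples = 30 by default, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class LogNormalFit:
    """Log-normal ML fit on the natural-log scale."""

    mu_log: float
    sigma_log: float
    n: int
    ks_stat: float
    ks_p: float

    @property
    def implied_mean(self) -> float:
        """Linear-scale mean, exp(mu + sigma^2/2)."""
        return float(np.exp(self.mu_log + 0.5 * self.sigma_log**2))

    @property
    def implied_sd(self) -> float:
        m = self.implied_mean
        return float(m * np.sqrt(np.expm1(self.sigma_log**2)))


def fit_lognormal(velocities) -> LogNormalFit:
    """ML log-normal fit of positive samples (n >= 3).

    ``mu_log``/``sigma_log`` are the mean and (population) sd of the logs;
    ``ks_stat``/``ks_p`` are the KS test of the logs against N(mu, sigma).
    A degenerate sample (sigma = 0) gets ks_stat 0 / ks_p 1.
    """
    v = np.asarray(velocities, dtype=float)
    if v.size < 3:
        raise StatsError("need at least 3 samples")
    if not np.all(v > 0):
        raise StatsError("velocities must be strictly positive")
    logs = np.log(v)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))
    if sigma == 0.0:
        return LogNormalFit(mu, 0.0, v.size, 0.0, 1.0)
    ks = sps.kstest(logs, "norm", args=(mu, sigma))
    return LogNormalFit(mu, sigma, v.size, float(ks.statistic), float(ks.pvalue))


def compare_velocity_distributions(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across >= 2 groups.

    All-identical data gives H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StatsError("need >= 2 groups with >= 2 samples each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class CorrelationResult:
    method: str           # "kendall" | "spearman"
    coefficient: float    # in [-1, 1]
    p_value: float
    n: int


def rank_correlation(x, y, method: str = "kendall") -> CorrelationResult:
    """Kendall tau-b or Spearman rho with the conventional p-value.

    scipy computes the exact Kendall p for small tie-free samples and the
    normal/t approximation otherwise. Constant inputs are an error (the
    coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise StatsError("x and y must be equal-length with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("correlation undefined for a constant vector")
    if method == "kendall":
        r = sps.kendalltau(x, y)  # tau-b with tie correction
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise StatsError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r.statistic), float(r.pvalue), x.size)


@dataclass
class BootstrapResult:
    method: str
    n_resamples: int
    replicates: np.ndarray
    plug_in: CorrelationResult
    seed: int
    ci_level: float = 0.95

    @property
    def point_estimate(self) -> float:
        """Mean of the replicate coefficients."""
        return float(np.mean(self.replicates))

    @property
    def ci(self) -> tuple[float, float]:
        """Percentile interval (not BCa; documented small-n convention)."""
        a = 100 * (1 - self.ci_level) / 2
        lo, hi = np.percentile(self.replicates, [a, 100 - a])
        return float(lo), float(hi)

    @property
    def p_value(self) -> float:
        """Two-sided sign-crossing p from the replicate distribution (crude
        at small n_resamples; the plug-in asymptotic p is also carried)."""
        r = self.replicates
        frac = (np.sum(r < 0) + 0.5 * np.sum(r == 0) + 0.5) / (r.size + 1)
        return float(2 * min(frac, 1 - frac))


def bootstrap_correlation(
    x, y, method: str = "kendall", n_resamples: int = 30, seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Pairs bootstrap of a rank correlation; deterministic given ``seed``.

    Resamples (x_i, y_i) pairs with replacement and recomputes the
    coefficient per replicate; degenerate replicates (a constant vector) are
    redrawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise StatsError("bootstrap needs n >= 5")
    plug_in = rank_correlation(x, y, method)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_resamples)
    for k in range(n_resamples):
        for _ in range(max_redraws):
            idx = rng.integers(0, x.size, size=x.size)
            xb, yb = x[idx], y[idx]
            if not (np.all(xb == xb[0]) or np.all(yb == yb[0])):
                break
        else:
            raise StatsError("could not draw a non-degenerate replicate")
        reps[k] = rank_correlation(xb, yb, method).coefficient
    return BootstrapResult(method, n_resamples, reps, plug_in, seed)


@dataclass
class PlateauEstimate:
    mean: float | None
    sd: float | None
    n_in_band: int

    @property
    def mean_rounded(self) -> float | None:
        """Table-precision (1 decimal) rendering of the plateau mean."""
        return None if self.mean is None else round(self.mean, 1)


def estimate_plateau(
    pmca, velocities, band: tuple[float, float] = (6.0, 24.0)
) -> PlateauEstimate:
    """Mean/sd of Pmca over patients whose mean velocity lies in the closed
    band (um/s). An empty band yields an explicit empty result, not NaN."""
    pmca = np.asarray(pmca, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if pmca.shape != v.shape:
        raise StatsError("pmca and velocities must align")
    mask = (v >= band[0]) & (v <= band[1])
    if not mask.any():
        return PlateauEstimate(None, None, 0)
    sel = pmca[mask]
    return PlateauEstimate(float(np.mean(sel)), float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0, int(mask.sum()))
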