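"""Bootstrap and error-propagation machinery for correlated series.

Trajectory observables are averaged over non-overlapping time blocks
whose length exceeds twice the autocorrelation time; block averages are
then treated as exchangeable and resampled with a bias-corrected and
accelerated (BCa) bootstrap.  Vector-valued observables (per-residue
profiles) are resampled jointly, block by block, so residue-residue
correlations survive resampling.  Monte-Carlo propagation pushes Gaussian
input uncertainty through arbitrary functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "BlockSpec",
    "BootstrapResult",
    "autocorrelation_time",
    "choose_block_length",
    "block_averages",
    "bca_bootstrap",
    "mc_propagate",
    "chi2_norm",
]


@dataclass(frozen=True)
class BlockSpec:
    """Blocking of a time series: physical length, frames, and the
    autocorrelation first-zero time tau it must exceed (block > 2*tau)."""

    block_length_ns: float
    tau_ns: float
    frames_per_block: int


@dataclass
class BootstrapResult:
    estimate: object
    ci_lower: object
    ci_upper: object
    level: float = 0.95
    n_resamples: int = 10_000
    seed: int | None = None
    flagged: bool = False
    flag_reason: str = ""


def autocorrelation_time(series, dt: float = 1.0) -> float:
    """First zero passage of the empirical autocorrelation function.

    Uses the biased ACF estimator.  Returns the lag (in ``dt`` units) of
    the first non-positive autocorrelation.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for autocorrelation analysis")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has no autocorrelation time")
    n = x.size
    for lag in range(1, n // 2 + 1):
        c = np.dot(x[:-lag], x[lag:]) / var
        if c <= 0:
            return lag * dt
    raise ValueError(
        "autocorrelation does not cross zero within half the series; "
        "use a longer series"
    )


def choose_block_length(series, dt: float = 1.0, safety: float = 2.0) -> BlockSpec:
    """Block length > ``safety`` * tau, rounded up to whole frames."""
    tau = autocorrelation_time(series, dt)
    frames = max(1, int(np.ceil(safety * tau / dt)) + 1)
    return BlockSpec(block_length_ns=frames * dt, tau_ns=tau, frames_per_block=frames)


def block_averages(values, frames_per_block: int) -> np.ndarray:
    """Means of non-overlapping blocks along axis 0 (trailing partial
    block discarded)."""
    v = np.asarray(values, dtype=float)
    n_blocks = v.shape[0] // frames_per_block
    if n_blocks < 1:
        raise ValueError("series shorter than one block")
    trimmed = v[: n_blocks * frames_per_block]
    return trimmed.reshape((n_blocks, frames_per_block) + v.shape[1:]).mean(axis=1)


def _bca_interval(theta_hat, theta_boot, theta_jack, level):
    """BCa interval for one scalar statistic from bootstrap and jackknife
    replicates (standard bias-correction z0 and acceleration a)."""
    alpha = (1.0 - level) / 2.0
    prop = np.mean(theta_boot < theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        # degenerate resampling distribution; fall back to percentiles
        lo, hi = np.quantile(theta_boot, [alpha, 1 - alpha])
        return lo, hi, True
    z0 = norm.ppf(prop)
    jm = theta_jack.mean()
    num = np.sum((jm - theta_jack) ** 3)
    den = 6.0 * np.sum((jm - theta_jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    zs = norm.ppf([alpha, 1 - alpha])
    adj = norm.cdf(z0 + (z0 + zs) / (1 - a * (z0 + zs)))
    lo, hi = np.quantile(theta_boot, adj)
    return lo, hi, False


def bca_bootstrap(
    blocks,
    statistic=None,
    n: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """BCa bootstrap over block averages.

    ``blocks`` has shape (n_blocks,) or (n_blocks, n_residues); whole
    blocks are resampled with replacement so per-residue values stay
    jointly coupled.  ``statistic`` maps a (m, ...) block sample to a
    scalar or per-residue vector (default: mean over blocks).
    Deterministic under a fixed ``seed``.
    """
    blocks = np.asarray(blocks, dtype=float)
    n_blocks = blocks.shape[0]
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks for a bootstrap")
    mean_stat = statistic is None
    if mean_stat:
        statistic = lambda b: b.mean(axis=0)  # noqa: E731
    rng = np.random.default_rng(seed)
    theta_hat = np.atleast_1d(np.asarray(statistic(blocks), dtype=float))
    idx = rng.integers(0, n_blocks, size=(n, n_blocks))
    if mean_stat:
        theta_boot = blocks[idx].mean(axis=1).reshape((n,) + theta_hat.shape)
        total = blocks.sum(axis=0)
        theta_jack = ((total - blocks) / (n_blocks - 1)).reshape(
            (n_blocks,) + theta_hat.shape
        )
    else:
        theta_boot = np.empty((n,) + theta_hat.shape)
        for b in range(n):
            theta_boot[b] = statistic(blocks[idx[b]])
        theta_jack = np.empty((n_blocks,) + theta_hat.shape)
        mask = np.ones(n_blocks, dtype=bool)
        for j in range(n_blocks):
            mask[j] = False
            theta_jack[j] = statistic(blocks[mask])
            mask[j] = True

    if np.allclose(blocks, blocks[0]):
        return BootstrapResult(
            estimate=_maybe_scalar(theta_hat),
            ci_lower=_maybe_scalar(theta_hat),
            ci_upper=_maybe_scalar(theta_hat),
            level=level,
            n_resamples=n,
            seed=seed,
            flagged=True,
            flag_reason="identical blocks: zero-width interval",
        )

    lo = np.empty_like(theta_hat)
    hi = np.empty_like(theta_hat)
    flagged = False
    for k in np.ndindex(theta_hat.shape):
        lo[k], hi[k], f = _bca_interval(
            theta_hat[k], theta_boot[(slice(None),) + k],
            theta_jack[(slice(None),) + k], level,
        )
        flagged |= f
    return BootstrapResult(
        estimate=_maybe_scalar(theta_hat),
        ci_lower=_maybe_scalar(lo),
        ci_upper=_maybe_scalar(hi),
        level=level,
        n_resamples=n,
        seed=seed,
        flagged=flagged,
        flag_reason="degenerate resampling distribution" if flagged else "",
    )


def _maybe_scalar(a):
    a = np.asarray(a)
    return float(a[0]) if a.shape == (1,) else a


def mc_propagate(
    function,
    means,
    standard_errors,
    n: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
    lognormal: bool = False,
) -> BootstrapResult:
    """Monte-Carlo propagation of independent Gaussian input errors.

    Draws inputs from N(mean, se) (or a matched log-normal for strictly
    positive quantities), applies ``function`` and reports percentile
    intervals.  Draws on which ``function`` raises or returns non-finite
    values are rejected and counted; >50% rejection flags the result.
    """
    means = np.asarray(means, dtype=float)
    ses = np.broadcast_to(np.asarray(standard_errors, dtype=float), means.shape)
    rng = np.random.default_rng(seed)
    out = []
    rejected = 0
    for _ in range(n):
        if lognormal:
            with np.errstate(divide="ignore", invalid="ignore"):
                sigma = np.sqrt(np.log1p((ses / means) ** 2))
                mu = np.log(means) - 0.5 * sigma**2
            draw = rng.lognormal(mu, sigma)
        else:
            draw = rng.normal(means, ses)
        try:
            val = function(draw)
        except (ValueError, FloatingPointError, ZeroDivisionError):
            rejected += 1
            continue
        val = np.asarray(val, dtype=float)
        if not np.all(np.isfinite(val)):
            rejected += 1
            continue
        out.append(val)
    if not out:
        raise ValueError("all Monte-Carlo draws rejected")
    samples = np.stack(out)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(samples, [alpha, 1 - alpha], axis=0)
    frac_rej = rejected / n
    point = np.asarray(function(means), dtype=float)
    return BootstrapResult(
        estimate=_maybe_scalar(np.atleast_1d(point)),
        ci_lower=_maybe_scalar(np.atleast_1d(lo)),
        ci_upper=_maybe_scalar(np.atleast_1d(hi)),
        level=level,
        n_resamples=n,
        seed=seed,
        flagged=frac_rej > 0.5,
        flag_reason=(
            f"{frac_rej:.0%} of draws rejected" if frac_rej > 0.5 else ""
        ),
    )


def chi2_norm(model_curve, data_curve) -> float:
    """Normalized mean-squared deviation between model and data.

    Mean over time points of the squared deviation, divided by the
    variance of the data series (so a constant model at the data mean
    scores exactly 1).
    """
    model = np.asarray(model_curve, dtype=float)
    data = np.asarray(data_curve, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data must share a time grid")
    var = data.var()
    if var == 0:
        raise ValueError("constant data: normalized chi^2 undefined")
    return float(np.mean((model - data) ** 2) / var)
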