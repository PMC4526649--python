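"""Adaptive Metropolis sampler with convergence diagnostics.

Random-walk Metropolis whose Gaussian proposal covariance is continually
tuned to the empirical covariance of the chain history (Haario-style):
for the first ``t0`` iterations proposals come from a fixed diagonal
Gaussian; afterwards from ``N(x, s_d * (Cov(history) + eps * I))`` with
``s_d = 2.38^2 / d``.  Adaptation continues for the whole run (vanishing
adaptation); diagnostics — split Gelman-Rubin R-hat and effective sample
size — catch pathologies.  Every stochastic entry point takes an explicit
seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core_types import ValidationError

__all__ = [
    "ChainResult",
    "adaptive_metropolis",
    "gelman_rubin",
    "effective_sample_size",
    "extract_draws",
]

#: Re-factorize the adapted proposal covariance every this many iterations.
_CHOL_REFRESH = 25


@dataclass
class ChainResult:
    """Kept (post burn-in, thinned) samples of one chain plus diagnostics."""

    samples: np.ndarray  # (n_kept, d)
    acceptance_rate: float
    rhat: np.ndarray  # per-parameter split R-hat (within this chain)
    ess: np.ndarray  # per-parameter effective sample size
    log_posts: np.ndarray  # log target at each kept sample

    @property
    def n_kept(self) -> int:
        return self.samples.shape[0]

    @property
    def dim(self) -> int:
        return self.samples.shape[1]


def adaptive_metropolis(
    target: Callable[[np.ndarray], float],
    init: Sequence[float],
    n_iter: int,
    burn_in: int | None = None,
    thin: int = 1,
    seed: int | np.random.SeedSequence = 0,
    initial_sd: float = 0.1,
    t0: int | None = None,
    eps: float = 1e-6,
) -> ChainResult:
    """Run one adaptive-Metropolis chain on an unnormalized log density.

    Parameters
    ----------
    target
        Log of the (unnormalized) target density; must be finite at ``init``.
    init
        Starting position, length ``d``.
    n_iter
        Total iterations (including burn-in).
    burn_in
        Iterations discarded from the front; defaults to ``n_iter // 2``.
    thin
        Keep every ``thin``-th post-burn-in state.
    seed
        Integer or :class:`numpy.random.SeedSequence`; same seed, same chain.
    initial_sd
        Per-coordinate proposal SD for the warm-start phase.
    t0
        Warm-start length before covariance adaptation kicks in;
        defaults to ``max(100, 10 d)``.
    eps
        Ridge added to the empirical covariance so the proposal never
        degenerates, even while the history is rank-deficient.
    """
    x = np.asarray(init, dtype=float).copy()
    d = x.size
    if burn_in is None:
        burn_in = n_iter // 2
    if not 0 <= burn_in < n_iter:
        raise ValidationError(f"need 0 <= burn_in < n_iter, got {burn_in}/{n_iter}")
    if t0 is None:
        t0 = max(100, 10 * d)
    rng = np.random.default_rng(seed)
    lp = float(target(x))
    if not np.isfinite(lp):
        raise ValidationError("target is not finite at the initial position")

    s_d = 2.38**2 / d
    # running moments of the full history (Welford, vector form)
    mean = x.copy()
    m2 = np.zeros((d, d))
    count = 1
    chol: np.ndarray | None = None
    chain = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    accepted = 0

    for t in range(n_iter):
        z = rng.standard_normal(d)
        if t < t0 or count < 2 * d:
            prop = x + initial_sd * z
        else:
            if chol is None or t % _CHOL_REFRESH == 0:
                cov = m2 / (count - 1)
                chol = np.linalg.cholesky(s_d * (cov + eps * np.eye(d)))
            prop = x + chol @ z
        lp_prop = float(target(prop))
        if math.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        chain[t] = x
        lps[t] = lp
        count += 1
        delta = x - mean
        mean += delta / count
        m2 += np.outer(delta, x - mean)

    kept = chain[burn_in::thin]
    kept_lps = lps[burn_in::thin]
    rhat = _split_rhat_single(kept)
    ess = effective_sample_size(kept)
    return ChainResult(
        samples=kept,
        acceptance_rate=accepted / n_iter,
        rhat=rhat,
        ess=ess,
        log_posts=kept_lps,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _rhat_core(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction for an (m, n, d) stack of chains."""
    m, n, _ = chains.shape
    chain_means = chains.mean(axis=1)  # (m, d)
    chain_vars = chains.var(axis=1, ddof=1)  # (m, d)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / w)
    return np.where(w > 0, out, 1.0)


def gelman_rubin(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Split R-hat across chains: each chain is halved, then the between-
    to within-chain variance ratio is formed over all half-chains.

    Values near 1 indicate the chains are sampling the same distribution.
    """
    if len(chains) < 2:
        raise ValidationError(
            "gelman_rubin needs >= 2 chains; for a single chain use its "
            "ChainResult.rhat (split-chain mode)"
        )
    arrs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in chains]
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValidationError("all chains must have identical shape")
    if n < 10:
        raise ValidationError("chains must have length >= 10")
    half = n // 2
    halves = []
    for a in arrs:
        halves.append(a[:half])
        halves.append(a[half : 2 * half])
    return _rhat_core(np.stack(halves))


def _split_rhat_single(samples: np.ndarray) -> np.ndarray:
    samples = np.atleast_2d(samples)
    n = samples.shape[0]
    if n < 4:
        return np.full(samples.shape[1], np.nan)
    half = n // 2
    return _rhat_core(np.stack([samples[:half], samples[half : 2 * half]]))


def effective_sample_size(samples: np.ndarray) -> np.ndarray:
    """Per-parameter effective sample size of one chain.

    Autocorrelation-time estimate with Geyer's initial monotone positive
    sequence: pair successive autocorrelations, keep pairs while their sum
    is positive, enforce monotone non-increase, and sum.  Autocorrelations
    come from one FFT per parameter.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if n < 4:
        return np.full(d, np.nan)
    centered = samples - samples.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:n].real
    acov /= np.arange(n, 0, -1)[:, None]  # unbiased normalization
    ess = np.empty(d)
    for j in range(d):
        if acov[0, j] <= 0:
            ess[j] = float(n)  # constant column
            continue
        rho = acov[:, j] / acov[0, j]
        # Geyer pairs Gamma_k = rho_{2k} + rho_{2k+1}, k = 0, 1, ...
        m = n // 2
        gamma = rho[0 : 2 * m : 2] + rho[1 : 2 * m : 2]
        nonpos = np.nonzero(gamma <= 0)[0]
        cut = nonpos[0] if len(nonpos) else len(gamma)
        if cut == 0:
            ess[j] = float(n)
            continue
        g = np.minimum.accumulate(gamma[:cut])
        tau = max(-1.0 + 2.0 * g.sum(), 1.0 / n)
        ess[j] = min(float(n), n / tau)
    return ess


# ---------------------------------------------------------------------------
# Posterior draws
# ---------------------------------------------------------------------------


def extract_draws(
    result: ChainResult | np.ndarray, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """Draw ``n_draws`` parameter vectors from kept samples.

    When the chain holds at least ``n_draws`` samples, an evenly strided
    subset is taken (the identity when counts match, and deterministic);
    otherwise draws are resampled uniformly with replacement using
    ``seed``.
    """
    samples = result.samples if isinstance(result, ChainResult) else np.asarray(result)
    samples = np.atleast_2d(samples)
    n_kept = samples.shape[0]
    if n_kept < 1:
        raise ValidationError("cannot extract draws from an empty chain")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if n_kept >= n_draws:
        idx = (np.arange(n_draws) * n_kept) // n_draws
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_kept, size=n_draws)
    return samples[idx]
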