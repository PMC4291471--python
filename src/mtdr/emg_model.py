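"""Exponentially modified Gaussian (EMG) model of per-codon NFC distributions.

A codon's normalized footprint counts are modeled as the sum of two
independent components: a Gaussian N(mu, sigma^2) describing the typical,
pause-free decoding time of the codon, and an Exponential(lambda)
describing rare long dwell events (translational pauses, ribosomal
traffic jams). The sum has the exponentially modified Gaussian density

    f(x; mu, sigma, lam) = (lam/2) * exp((lam/2) * (2*mu + lam*sigma^2 - 2*x))
                           * erfc((mu + lam*sigma^2 - x) / (sqrt(2)*sigma))

with lam the exponential *rate* (the mean pause contribution is 1/lam).
Parameters are estimated per codon by maximum likelihood; the fitted mu is
interpreted as the codon's typical decoding time.

Numerical note: the naive density underflows/overflows when lam*sigma is
large (near-Gaussian regime). All likelihood computations therefore go
through ``emg_logpdf``, which uses erfcx (the scaled complementary error
function) for positive arguments of erfc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "EMGParams",
    "EMGFit",
    "FitOptions",
    "emg_pdf",
    "emg_logpdf",
    "emg_loglik",
    "init_moments",
    "fit_emg",
    "fit_codon_table",
]

_SQRT2 = math.sqrt(2.0)
_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)

#: Maximum skewness of an EMG is 2 (pure-exponential limit); moment
#: initialization clamps the sample skewness inside (0, 0.98*2] for stability.
_SKEW_MAX = 2.0


@dataclass(frozen=True)
class EMGParams:
    """EMG parameters: mu (location, NFC units), sigma (>0), lam (rate, >0)."""

    mu: float
    sigma: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError("lam must be positive and finite")

    @property
    def mean(self) -> float:
        """Distribution mean mu + 1/lam."""
        return self.mu + 1.0 / self.lam

    @property
    def variance(self) -> float:
        """Distribution variance sigma^2 + 1/lam^2."""
        return self.sigma**2 + 1.0 / self.lam**2


@dataclass
class EMGFit:
    """Result of one codon's maximum-likelihood EMG fit."""

    params: EMGParams | None
    loglik: float
    n: int
    converged: bool
    init: EMGParams | None = None
    n_iter: int = 0
    status: str = ""

    @property
    def atypical(self) -> bool:
        """True when the fitted typical time is non-positive (rate undefined)."""
        return self.params is not None and self.params.mu <= 0


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls for :func:`fit_emg`."""

    min_samples: int = 200
    maxiter: int = 2000
    ftol: float = 1e-13
    gtol: float = 1e-8
    n_restarts: int = 5
    seed: int = 0


def _emg_logpdf_arrays(
    x: np.ndarray, mu: float, sigma: float, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stable log-density and the erfc argument z (reused by the gradient).

    Uses the identity (exact for all z)
        log f = log(lam/2) - (x-mu)^2 / (2 sigma^2) + log erfcx(z),
    which avoids the catastrophic cancellation between the lam^2*sigma^2/2
    growth of the naive exponent and the -z^2 decay of log erfc when
    lam*sigma is large. Where erfcx overflows (z << 0, deep exponential
    tail) the erfc ~ 2 asymptote is substituted.
    """
    z = (mu + lam * sigma**2 - x) / (_SQRT2 * sigma)
    log_erfcx = np.empty_like(z)
    deep = z < -25.0  # erfcx(z) = e^{z^2} erfc(z) overflows; erfc ~ 2
    log_erfcx[deep] = math.log(2.0) + z[deep] ** 2
    rest = ~deep
    log_erfcx[rest] = np.log(special.erfcx(z[rest]))
    logpdf = math.log(lam / 2.0) - (x - mu) ** 2 / (2.0 * sigma**2) + log_erfcx
    return logpdf, z


def emg_logpdf(x, p: EMGParams) -> np.ndarray | float:
    """Log-density of the EMG, stable for large lam*sigma."""
    arr = np.asarray(x, dtype=float)
    out, _ = _emg_logpdf_arrays(np.atleast_1d(arr), p.mu, p.sigma, p.lam)
    return float(out[0]) if arr.ndim == 0 else out


def emg_pdf(x, p: EMGParams) -> np.ndarray | float:
    """EMG density (exponentiated stable log form; always >= 0)."""
    return np.exp(emg_logpdf(x, p))


def emg_loglik(samples: Sequence[float], p: EMGParams) -> float:
    """Sum of log EMG densities over the samples."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("samples must be non-empty")
    logp, _ = _emg_logpdf_arrays(arr, p.mu, p.sigma, p.lam)
    return float(np.sum(logp))


def _loglik_and_grad(theta: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in (mu, log sigma, log lam)."""
    mu, log_sigma, log_lam = theta
    sigma = math.exp(log_sigma)
    lam = math.exp(log_lam)
    logp, z = _emg_logpdf_arrays(x, mu, sigma, lam)
    # d/dz log erfc(z) = -(2/sqrt(pi)) / erfcx(z)
    g = -_TWO_OVER_SQRT_PI / special.erfcx(z)
    d_mu = lam + g / (_SQRT2 * sigma)
    dz_dsigma = -(mu - x) / (_SQRT2 * sigma**2) + lam / _SQRT2
    d_sigma = lam**2 * sigma + g * dz_dsigma
    d_lam = 1.0 / lam + (mu + lam * sigma**2 - x) + g * (sigma / _SQRT2)
    grad = np.array(
        [np.sum(d_mu), np.sum(d_sigma) * sigma, np.sum(d_lam) * lam]
    )
    return -float(np.sum(logp)), -grad


def init_moments(samples: Sequence[float]) -> EMGParams:
    """Method-of-moments starting point for the EMG fit.

    With sample mean m, variance s^2 and skewness g clamped to
    [0.02, 0.98 * 2]: 1/lam = s * (g/2)^(1/3), mu = m - 1/lam,
    sigma^2 = max(s^2 * (1 - (g/2)^(2/3)), 1e-4 * s^2).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for moment initialization")
    m = float(np.mean(x))
    s2 = float(np.var(x, ddof=1))
    if s2 <= 0:
        raise ValueError("sample variance must be positive")
    s = math.sqrt(s2)
    g = float(np.mean((x - m) ** 3)) / s2**1.5
    g = min(max(g, 0.02), 0.98 * _SKEW_MAX)
    inv_lam = s * (g / 2.0) ** (1.0 / 3.0)
    sigma2 = max(s2 * (1.0 - (g / 2.0) ** (2.0 / 3.0)), 1e-4 * s2)
    return EMGParams(mu=m - inv_lam, sigma=math.sqrt(sigma2), lam=1.0 / inv_lam)


def _pack(p: EMGParams) -> np.ndarray:
    return np.array([p.mu, math.log(p.sigma), math.log(p.lam)])


def _unpack(theta: np.ndarray) -> EMGParams:
    return EMGParams(
        mu=float(theta[0]),
        sigma=math.exp(float(np.clip(theta[1], -20, 20))),
        lam=math.exp(float(np.clip(theta[2], -20, 20))),
    )


def fit_emg(samples: Sequence[float], options: FitOptions | None = None) -> EMGFit:
    """Maximum-likelihood EMG fit of one codon's NFC samples.

    Optimizes in (mu, log sigma, log lam) with L-BFGS-B and an analytic
    gradient, starting from :func:`init_moments`. If the first start does
    not converge, a deterministic sequence of perturbed restarts is tried
    and the best log-likelihood wins (ties broken by smaller lam).
    Fewer than ``options.min_samples`` samples yields an unfit result
    (``converged=False``) rather than an exception.
    """
    opts = options or FitOptions()
    x = np.asarray(samples, dtype=float)
    if x.size < opts.min_samples:
        return EMGFit(
            params=None,
            loglik=float("nan"),
            n=int(x.size),
            converged=False,
            status=f"too few samples ({x.size} < {opts.min_samples})",
        )
    init = init_moments(x)
    span = 5.0 * float(np.max(np.abs(x)))
    bounds = [(-span, span), (-20.0, 20.0), (-20.0, 20.0)]

    def _run(theta0: np.ndarray):
        return optimize.minimize(
            _loglik_and_grad,
            theta0,
            args=(x,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.maxiter,
                "ftol": opts.ftol,
                "gtol": opts.gtol,
            },
        )

    def _converged(r) -> bool:
        gmax = float(np.max(np.abs(r.jac)))
        # optimizer success plus a loose stationarity check, or a line-search
        # stall (ABNORMAL) that nevertheless sits at a tight stationary point
        loose = gmax < max(1.0, x.size) * 1e-5
        return (r.success and loose) or gmax < 1e-2

    result = _run(_pack(init))
    if not _converged(result):
        candidates = [result]
        rng = np.random.default_rng(opts.seed)
        theta0 = _pack(init)
        for _ in range(opts.n_restarts):
            perturbed = theta0 + rng.normal(scale=[0.1 * init.sigma + 0.05, 0.3, 0.3])
            candidates.append(_run(perturbed))
        candidates.sort(key=lambda r: (r.fun, r.x[2]))
        result = candidates[0]

    params = _unpack(result.x)
    loglik = -float(result.fun)
    init_ll = emg_loglik(x, init)
    if loglik < init_ll - 1e-9:  # optimizer regressed; keep the start
        params, loglik = init, init_ll
    return EMGFit(
        params=params,
        loglik=loglik,
        n=int(x.size),
        converged=_converged(result),
        init=init,
        n_iter=int(result.nit),
        status=str(result.message),
    )


def fit_codon_table(
    samples_by_codon: Mapping[str, Sequence[float]],
    options: FitOptions | None = None,
) -> dict[str, EMGFit]:
    """Fit every codon's NFC sample vector; returns codon -> EMGFit."""
    return {
        codon: fit_emg(samples, options)
        for codon, samples in sorted(samples_by_codon.items())
    }
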