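"""Adaptive Metropolis-within-Gibbs machinery shared by the fitting modules.

Each model module implements its own sweep of conditional updates
(vectorised across sites/species where the conditionals are independent,
conjugate Gibbs where available); this module provides the common pieces:
Robbins-Monro step-size adaptation, prior log-densities, chain containers
and convergence diagnostics (rank-normalised split R-hat via arviz).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "half_cauchy_logpdf",
    "normal_logpdf",
    "poisson_logpmf",
    "rhat",
    "summarize_chains",
    "max_rhat",
    "R_HAT_THRESHOLD",
]

R_HAT_THRESHOLD = 1.1

_LOG_2PI = float(np.log(2.0 * np.pi))


def half_cauchy_logpdf(x: np.ndarray, scale: float = 5.0) -> np.ndarray:
    """log density of a half-Cauchy(0, scale), the default SD prior."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        -np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return out  # normalising constant dropped


def normal_logpdf(x, mu, sigma):
    z = (np.asarray(x) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def poisson_logpmf(k, mean):
    """Unnormalised in k! terms cancel in MH ratios, but keep them so the
    value is a true log-pmf (needed by the likelihood oracle tests)."""
    from scipy.special import gammaln

    mean = np.asarray(mean, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(mean) - mean - gammaln(k + 1.0)
    out = np.where(mean > 0, out, np.where(k == 0, 0.0, -np.inf))
    return out


def rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat for an array shaped (chain, draw)."""
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (chain, draw)")
    if np.allclose(chains, chains.flat[0]):
        return 1.0
    return float(
        np.asarray(az.rhat(az.convert_to_dataset(chains[..., None]))["x"].values).ravel()[0]
    )


def summarize_chains(draws: dict[str, np.ndarray]) -> dict[str, dict]:
    """Median / 95% credible interval / R-hat per scalar parameter.

    ``draws`` maps a parameter name to an array shaped (chain, draw) or
    (chain, draw, ...); vector parameters are summarised elementwise with
    ``name[i]`` keys.
    """
    out: dict[str, dict] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            flat = arr.reshape(-1)
            out[name] = {
                "median": float(np.median(flat)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": rhat(arr),
            }
        else:
            tail = arr.shape[2:]
            for idx in np.ndindex(*tail):
                sub = arr[(slice(None), slice(None)) + idx]
                key = name + "[" + ",".join(map(str, idx)) + "]"
                flat = sub.reshape(-1)
                out[key] = {
                    "median": float(np.median(flat)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "rhat": rhat(sub),
                }
    return out


def max_rhat(summary: dict[str, dict]) -> float:
    vals = [v["rhat"] for v in summary.values() if np.isfinite(v["rhat"])]
    return max(vals) if vals else np.nan
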