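"""Sparse multi-species Ricker state-space fit for one site.

Observation: counts ``N_it ~ Poisson(n_it * exp(eps_obs_it) * A_t)``.
Process (interaction-scale Ricker)::

    ln n_{i,t} = ln n_{i,t-1} + r_i - sum_j alpha'_ij n_{j,t-1} + eps_state_it

``alpha'_ij = r_i alpha_ij / K_i`` absorbs the carrying capacity, so the
comparably scaled competition coefficient is the ratio
``alpha_ij = alpha'_ij / alpha'_ii`` (diagonal exactly 1).  Sparsity comes
from spike-and-slab half-normal priors: a Bernoulli indicator ``z_ij``
selects prior variance ``c1 = 1`` (slab, coefficient freely estimated) or
``c0 = 0.01`` (spike, coefficient shrunk to ~0), with separate inclusion
probabilities for intra- and interspecific elements.  Process errors are
correlated across species through ``D`` latent factors with
multiplicative-gamma loadings, giving
``Omega_eps = Delta^T Delta + diag(sigma_pi^2)``.

Conditional structure is exploited heavily: ``r_i`` and ``alpha'_ij`` have
conjugate (truncated-)normal updates, ``z``, the factors, the loadings and
their gamma hyper-priors are exact Gibbs draws; only the latent states,
observation errors and SDs use Metropolis steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._mcmc import (
    R_HAT_THRESHOLD,
    half_cauchy_logpdf,
    max_rhat,
    normal_logpdf,
    summarize_chains,
)

__all__ = [
    "InteractionSpec",
    "InteractionPosterior",
    "select_species",
    "fit_interaction",
    "rescale_alpha",
]


@dataclass
class InteractionSpec:
    """Model and sampler settings for the interaction fit."""

    c1: float = 1.0  # slab prior variance
    c0: float = 0.01  # spike prior variance
    p_intra: float = 0.9
    p_slab_inter: float = 0.5
    D: int = 2
    mga_a: tuple = (2.0, 3.0)  # multiplicative-gamma shape hyperparameters
    min_occurrences: int = 4  # strict ">" rule for species inclusion
    min_years: int = 17  # required observed years per site
    chains: int = 4
    n_warmup: int = 1000
    n_iter: int = 1000
    thin: int = 2
    seed: int = 0
    prior_r_mean: float = 1.0  # weakly informative: Ricker growth rates
    prior_r_sd: float = 1.0    # above ~2.5 are rarely seen in nature
    prior_scale: float = 5.0
    init_state_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.c1 > self.c0 > 0:
            raise ValueError("need c1 > c0 > 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")


@dataclass
class InteractionPosterior:
    """Draws (chain, draw, ...) for one site's interaction model."""

    draws: dict
    species: list
    years: list
    spec: InteractionSpec
    summary: dict = field(default_factory=dict)
    converged: bool = False

    def inclusion_probability(self) -> np.ndarray:
        """Posterior Pr(z_ij = 1)."""
        return self.draws["z"].mean(axis=(0, 1))


# --------------------------------------------------------------------------
# species selection
# --------------------------------------------------------------------------


def select_species(
    site_series: pd.DataFrame, min_occurrences: int = 4
) -> pd.DataFrame:
    """Keep taxa observed (count > 0) in strictly more than
    ``min_occurrences`` years; drop the rest.

    Raises if fewer than two taxa remain (a single-species "community"
    cannot inform interactions).
    """
    obs = site_series.dropna(subset=["count"])
    occ = obs[obs["count"] > 0].groupby("group")["year"].nunique()
    keep = occ[occ > min_occurrences].index
    out = site_series[site_series["group"].isin(keep)].copy()
    if out["group"].nunique() < 2:
        raise ValueError(
            f"fewer than 2 taxa pass the >{min_occurrences}-occurrence rule"
        )
    return out


# --------------------------------------------------------------------------
# sampler pieces
# --------------------------------------------------------------------------


def _half_normal_logpdf(x, var):
    return np.where(
        x >= 0, -0.5 * x**2 / var - 0.5 * np.log(var) + 0.5 * np.log(2 / np.pi), -np.inf
    )


def _sample_trunc_normal(rng, mean, sd, lower=0.0):
    """Draw from Normal(mean, sd) truncated to [lower, inf)."""
    a = (lower - mean) / sd
    lo = ndtr(a)
    u = rng.uniform(lo, 1.0)
    u = np.clip(u, 1e-15, 1 - 1e-16)
    return mean + sd * ndtri(u)


def _prepare_site_arrays(site_series: pd.DataFrame) -> dict:
    species = sorted(site_series["group"].unique())
    years = sorted(site_series["year"].unique())
    S, T = len(species), len(years)
    Y = np.zeros((S, T))
    A = np.ones((S, T))
    M = np.zeros((S, T), dtype=bool)
    si = {s: i for i, s in enumerate(species)}
    yi = {y: j for j, y in enumerate(years)}
    for _, row in site_series.dropna(subset=["count"]).iterrows():
        i, j = si[row["group"]], yi[row["year"]]
        Y[i, j] = row["count"]
        A[i, j] = row["sampling_area"]
        M[i, j] = True
    return {"Y": Y, "A": A, "M": M, "species": species, "years": years}


def _sweep(st, d, spec, rng, sc, adapt):
    Y, A, M = d["Y"], d["A"], d["M"]
    S, T = Y.shape
    D = spec.D
    g = sc["_g"]
    sig_pi = np.exp(st["log_sig_pi"])
    sig_obs = np.exp(st["log_sig_obs"])

    def process_resid(U):
        """pi_{i,t} for transitions t=1..T-1 after removing the factor part."""
        n_prev = np.exp(U[:, :-1])
        pred = U[:, :-1] + st["r"][:, None] - st["ap"] @ n_prev
        res = U[:, 1:] - pred
        if D > 0:
            res = res - st["delta"].T @ st["zeta"].T  # (S, T-1)
        return res

    # ---- latent states: joint species block per year ---------------------
    U = st["U"]
    E = st["E"]

    def cols_lp(u_sub, cols, with_obs):
        """Conditional log-density terms touching each column in ``cols``
        (pairwise distance >= 2, so their conditionals are independent),
        evaluated at candidate values u_sub (S, nc).  Returns (nc,)."""
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            lp = np.zeros(len(cols))
            if with_obs:
                lam = np.exp(u_sub + E[:, cols])
                ol = np.where(
                    M[:, cols],
                    Y[:, cols] * np.log(lam * A[:, cols]) - lam * A[:, cols],
                    0.0,
                )
                ol = np.where(M[:, cols] & ~np.isfinite(ol), -np.inf, ol)
                lp += ol.sum(axis=0)
            first = cols == 0
            if first.any():
                lp[first] += normal_logpdf(
                    u_sub[:, first], 0.0, spec.init_state_sd
                ).sum(axis=0)
            rest = ~first
            if rest.any():
                pc = cols[rest]
                pred = (
                    U[:, pc - 1] + st["r"][:, None] - st["ap"] @ np.exp(U[:, pc - 1])
                )
                if D > 0:
                    pred = pred + st["delta"].T @ st["zeta"][pc - 1].T
                lp[rest] += normal_logpdf(
                    u_sub[:, rest] - pred, 0.0, sig_pi[:, None]
                ).sum(axis=0)
            inner = cols + 1 < T
            if inner.any():
                ic = cols[inner]
                pred = (
                    u_sub[:, inner]
                    + st["r"][:, None]
                    - st["ap"] @ np.exp(u_sub[:, inner])
                )
                if D > 0:
                    pred = pred + st["delta"].T @ st["zeta"][ic].T
                lp[inner] += normal_logpdf(
                    U[:, ic + 1] - pred, 0.0, sig_pi[:, None]
                ).sum(axis=0)
        return lp

    parities = (np.arange(0, T, 2), np.arange(1, T, 2))
    for cols in parities:
        prop = U[:, cols] + sc["U"][:, cols] * rng.normal(size=(S, len(cols)))
        delta_lp = cols_lp(prop, cols, True) - cols_lp(U[:, cols], cols, True)
        acc = np.log(rng.uniform(size=len(cols))) < delta_lp
        U[:, cols[acc]] = prop[:, acc]
        if adapt:
            sc["U"][:, cols] *= np.exp(g * (acc[None, :] - 0.35))

    # ---- compensated shift: (U + d, E - d) leaves the likelihood invariant
    # at observed cells; the process model and E-prior arbitrate the
    # additively confounded U/E split (density scale vs observation error)
    for cols in parities:
        m_sub = M[:, cols]
        du = np.where(m_sub, sc["shift"][:, cols] * rng.normal(size=(S, len(cols))), 0.0)
        delta_lp = cols_lp(U[:, cols] + du, cols, False) - cols_lp(
            U[:, cols], cols, False
        )
        dpr = np.where(
            m_sub,
            normal_logpdf(E[:, cols] - du, 0.0, sig_obs[:, None])
            - normal_logpdf(E[:, cols], 0.0, sig_obs[:, None]),
            0.0,
        )
        delta_lp += dpr.sum(axis=0)
        acc = np.log(rng.uniform(size=len(cols))) < delta_lp
        U[:, cols[acc]] += du[:, acc]
        E[:, cols[acc]] -= np.where(m_sub[:, acc], du[:, acc], 0.0)
        if adapt:
            sc["shift"][:, cols] *= np.exp(g * (acc[None, :] - 0.35))

    # ---- funnel move: rescale each species' observation-error field with
    # its SD (E' = cE, sigma' = c sigma)
    c = np.exp(sc["obs_scale"] * rng.normal(size=S))
    E_new = np.where(M, E * c[:, None], 0.0)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lam_o = np.exp(U + E)
        lam_n = np.exp(U + E_new)
        dll = np.where(M, Y * np.log(lam_n / lam_o) - (lam_n - lam_o) * A, 0.0)
    dll = np.where(np.isfinite(dll), dll, -np.inf)
    delta = (
        dll.sum(axis=1)
        + half_cauchy_logpdf(sig_obs * c, spec.prior_scale)
        - half_cauchy_logpdf(sig_obs, spec.prior_scale)
        + np.log(c)
    )
    acc = np.log(rng.uniform(size=S)) < delta
    E[acc] = E_new[acc]
    st["log_sig_obs"] = np.where(acc, st["log_sig_obs"] + np.log(c), st["log_sig_obs"])
    sig_obs = np.exp(st["log_sig_obs"])
    if adapt:
        sc["obs_scale"] *= np.exp(g * (acc - 0.44))

    # ---- observation errors ----------------------------------------------
    prop = E + sc["E"] * rng.normal(size=(S, T))
    lam_o, lam_n = np.exp(U + E), np.exp(U + prop)
    with np.errstate(divide="ignore", invalid="ignore"):
        dll = Y * np.log(lam_n / lam_o) - (lam_n - lam_o) * A
    dll = np.where(M, dll, 0.0)
    dll += normal_logpdf(prop, 0, sig_obs[:, None]) - normal_logpdf(
        E, 0, sig_obs[:, None]
    )
    acc = (np.log(rng.uniform(size=(S, T))) < dll) & M
    E[acc] = prop[acc]
    if adapt:
        sc["E"][M] *= np.exp(g * (acc[M] - 0.44))

    # ---- growth rates: conjugate normal ----------------------------------
    n_prev = np.exp(U[:, :-1])  # (S, T-1)
    base = U[:, 1:] - U[:, :-1] + st["ap"] @ n_prev  # r + factor + pi
    if D > 0:
        base = base - st["delta"].T @ st["zeta"].T
    prec = (T - 1) / sig_pi**2 + 1.0 / spec.prior_r_sd**2
    mean = (
        base.sum(axis=1) / sig_pi**2 + spec.prior_r_mean / spec.prior_r_sd**2
    ) / prec
    st["r"] = mean + rng.normal(size=S) / np.sqrt(prec)

    # ---- interaction coefficients: truncated-normal Gibbs ----------------
    sig2_slab = np.where(st["z"] == 1, spec.c1, spec.c0)
    res = process_resid(U)  # (S, T-1) with current ap
    for i in range(S):
        for j in range(S):
            x = n_prev[j]  # predictor for ap[i, j]
            # res_i = c + ap_ij * x; c excludes this coefficient's term
            partial = res[i] - st["ap"][i, j] * x
            prec = (x**2).sum() / sig_pi[i] ** 2 + 1.0 / sig2_slab[i, j]
            mean = -(partial * x).sum() / sig_pi[i] ** 2 / prec
            new = _sample_trunc_normal(rng, mean, 1.0 / np.sqrt(prec))
            res[i] = partial + new * x
            st["ap"][i, j] = new

    # ---- inclusion indicators: exact Gibbs --------------------------------
    p_prior = np.where(
        np.eye(S, dtype=bool), spec.p_intra, spec.p_slab_inter
    )
    lp1 = np.log(p_prior) + _half_normal_logpdf(st["ap"], spec.c1)
    lp0 = np.log1p(-p_prior) + _half_normal_logpdf(st["ap"], spec.c0)
    pz = 1.0 / (1.0 + np.exp(lp0 - lp1))
    st["z"] = (rng.uniform(size=(S, S)) < pz).astype(int)

    # ---- latent factors and loadings (Gibbs) ------------------------------
    if D > 0:
        resid_nf = (
            U[:, 1:] - U[:, :-1] - st["r"][:, None] + st["ap"] @ n_prev
        )  # (S, T-1), still contains factor part + pi
        Dl = st["delta"]  # (D, S)
        ivar = 1.0 / sig_pi**2
        prec_z = np.eye(D) + (Dl * ivar) @ Dl.T
        cov_z = np.linalg.inv(prec_z)
        chol_z = np.linalg.cholesky(cov_z)
        mean_z = resid_nf.T @ (Dl * ivar).T @ cov_z.T  # (T-1, D)
        st["zeta"] = mean_z + rng.normal(size=(T - 1, D)) @ chol_z.T

        # loadings per species
        tau_d = np.cumprod(st["mga_theta"])
        Z = st["zeta"]  # (T-1, D)
        ZtZ = Z.T @ Z
        for i in range(S):
            prec_d = np.diag(st["mga_phi"][:, i] * tau_d) + ZtZ * ivar[i]
            cov_d = np.linalg.inv(prec_d)
            mean_d = cov_d @ (Z.T @ resid_nf[i]) * ivar[i]
            st["delta"][:, i] = mean_d + np.linalg.cholesky(cov_d) @ rng.normal(size=D)

        # multiplicative-gamma hyper-priors
        st["mga_phi"] = rng.gamma(
            1.5 + 0.5, 1.0 / (1.5 + 0.5 * tau_d[:, None] * st["delta"] ** 2)
        )
        a1, a2 = spec.mga_a
        for h in range(D):
            tau_wo = np.cumprod(st["mga_theta"])
            # tau_d without the h-th multiplier, for d >= h
            with np.errstate(divide="ignore"):
                tau_ratio = tau_wo[h:] / st["mga_theta"][h]
            shape = (a1 if h == 0 else a2) + 0.5 * S * (D - h)
            rate = 1.0 + 0.5 * np.sum(
                tau_ratio[:, None] * (st["mga_phi"][h:] * st["delta"][h:] ** 2)
            )
            st["mga_theta"][h] = rng.gamma(shape, 1.0 / rate)

    # ---- SDs ----------------------------------------------------------------
    res = process_resid(U)
    for name, terms, counts in (
        ("log_sig_pi", res, np.full(S, T - 1)),
        ("log_sig_obs", np.where(M, E, 0.0), M.sum(axis=1)),
    ):
        cur = st[name]
        prop = cur + sc[name] * rng.normal(size=S)
        ss = (terms**2).sum(axis=1)
        d_lp = (
            -counts * prop
            - 0.5 * ss / np.exp(2 * prop)
            + counts * cur
            + 0.5 * ss / np.exp(2 * cur)
            + half_cauchy_logpdf(np.exp(prop), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
            + (prop - cur)
        )
        acc = np.log(rng.uniform(size=S)) < d_lp
        st[name] = np.where(acc, prop, cur)
        if adapt:
            sc[name] *= np.exp(g * (acc - 0.44))


def fit_interaction(
    site_series: pd.DataFrame, spec: InteractionSpec | None = None
) -> InteractionPosterior:
    """Fit the sparse-interaction Ricker state-space model to one site.

    The series must contain strictly more than ``spec.min_years - 1``
    observed years (the inclusion rule for sites); taxa should already have
    passed :func:`select_species`.  Returns a posterior whose draws include
    ``alpha_prime``, ``z``, ``r``, ``sigma_pi``, ``sigma_obs``,
    ``log_density``, ``Omega_eps`` (reconstructed from the loadings per
    draw) and the derived theory-scale ``alpha``.
    """
    spec = spec or InteractionSpec()
    d = _prepare_site_arrays(site_series)
    S, T = d["Y"].shape
    n_years_obs = int(d["M"].any(axis=0).sum())
    if n_years_obs < spec.min_years:
        raise ValueError(
            f"site has {n_years_obs} observed years; need >= {spec.min_years}"
        )
    D = spec.D
    n_keep = spec.n_iter // spec.thin
    kept = {
        "alpha_prime": np.zeros((spec.chains, n_keep, S, S)),
        "z": np.zeros((spec.chains, n_keep, S, S), dtype=int),
        "r": np.zeros((spec.chains, n_keep, S)),
        "sigma_pi": np.zeros((spec.chains, n_keep, S)),
        "sigma_obs": np.zeros((spec.chains, n_keep, S)),
        "log_density": np.zeros((spec.chains, n_keep, S, T)),
        "Omega_eps": np.zeros((spec.chains, n_keep, S, S)),
        "delta": np.zeros((spec.chains, n_keep, D, S)),
    }

    root = np.random.SeedSequence(spec.seed)
    for c, ss in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(ss)
        with np.errstate(divide="ignore"):
            u0 = np.where(d["M"], np.log((d["Y"] + 0.5) / d["A"]), np.nan)
        u0 = (
            pd.DataFrame(u0).interpolate(axis=1, limit_direction="both").to_numpy()
        )
        u0 = np.nan_to_num(u0, nan=0.0) + rng.normal(0, 0.1, (S, T))
        st = {
            "U": u0,
            "E": np.zeros((S, T)),
            "r": np.full(S, 0.5) + rng.normal(0, 0.1, S),
            "ap": np.full((S, S), 0.1) + rng.uniform(0, 0.1, (S, S)),
            "z": np.ones((S, S), dtype=int),
            "zeta": np.zeros((T - 1, D)),
            "delta": rng.normal(0, 0.1, (D, S)),
            "mga_phi": np.ones((D, S)),
            "mga_theta": np.ones(D),
            "log_sig_pi": np.full(S, np.log(0.3)),
            "log_sig_obs": np.full(S, np.log(0.3)),
        }
        sc = {
            "U": np.full((S, T), 0.3),
            "shift": np.full((S, T), 0.3),
            "obs_scale": np.full(S, 0.3),
            "E": np.full((S, T), 0.5),
            "log_sig_pi": np.full(S, 0.3),
            "log_sig_obs": np.full(S, 0.3),
        }
        k = 0
        for it in range(spec.n_warmup + spec.n_iter):
            sc["_g"] = min(0.25, 4.0 / np.sqrt(it + 8))
            _sweep(st, d, spec, rng, sc, adapt=it < spec.n_warmup)
            if (
                it >= spec.n_warmup
                and (it - spec.n_warmup + 1) % spec.thin == 0
                and k < n_keep
            ):
                kept["alpha_prime"][c, k] = st["ap"]
                kept["z"][c, k] = st["z"]
                kept["r"][c, k] = st["r"]
                kept["sigma_pi"][c, k] = np.exp(st["log_sig_pi"])
                kept["sigma_obs"][c, k] = np.exp(st["log_sig_obs"])
                kept["log_density"][c, k] = st["U"]
                kept["delta"][c, k] = st["delta"]
                kept["Omega_eps"][c, k] = st["delta"].T @ st["delta"] + np.diag(
                    np.exp(2 * st["log_sig_pi"])
                )
                k += 1

    diag = {
        "r": kept["r"],
        "alpha_prime": kept["alpha_prime"],
        "sigma_pi": kept["sigma_pi"],
    }
    summary = summarize_chains(diag)
    converged = max_rhat(summary) < R_HAT_THRESHOLD
    return InteractionPosterior(
        draws=kept,
        species=d["species"],
        years=d["years"],
        spec=spec,
        summary=summary,
        converged=converged,
    )


def rescale_alpha(posterior: InteractionPosterior) -> dict:
    """Theory-scale competition coefficients ``alpha_ij = alpha'_ij / alpha'_ii``.

    Per-draw elementwise ratios; the diagonal is exactly 1.  Draws whose
    intraspecific coefficient is numerically zero are excluded from the
    summaries and counted.
    """
    ap = posterior.draws["alpha_prime"]
    nc, nk, S, _ = ap.shape
    diag = np.einsum("ckii->cki", ap)
    ok = np.all(diag > 1e-10, axis=-1)  # (chain, draw)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = ap / diag[..., :, None]
    flat = alpha[ok]  # (n_ok, S, S)
    return {
        "draws": alpha,
        "valid": ok,
        "n_excluded": int((~ok).sum()),
        "median": np.median(flat, axis=0),
        "q2.5": np.quantile(flat, 0.025, axis=0),
        "q97.5": np.quantile(flat, 0.975, axis=0),
    }
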