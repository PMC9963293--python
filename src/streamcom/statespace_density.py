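"""Bayesian state-space reconstruction of fish density per site.

Observation model (per site ``s`` and year ``t``, observed years only)::

    N_st ~ Poisson(lambda_st * A_st)
    lambda_st = n_st * exp(eps_obs_st) + psi * beta_s * Fry_wt

where ``A`` is the sampled area (m^2), ``Fry`` the spring fry release of the
surrounding watershed (million fish), and ``psi`` is 1 for the enhanced
species group and 0 for the unenhanced group.  ``beta_s`` (the site-level
catch of released fry) is positive with a Normal hyper-distribution.

Process model (all years, missing ones imputed)::

    ln n_st = xi1_s + xi2_s * ln n'_{s,t-1} + eps_state_st
    ln n'_{s,t-1} = sum_q w_q(tau) ln n_{s,t-q}

a Q-order autoregression whose lag weights decay as a normalised geometric
series ``tau**q``, so two parameters (``xi2_s``, ``tau``) describe the whole
lag structure.  ``(xi1_s, xi2_s)`` are exchangeable across sites with a
bivariate-normal hyper-distribution.

Fitting is by adaptive Metropolis-within-Gibbs (conjugate Gibbs for the
site-level AR coefficients, vectorised Metropolis updates for latent states
and variance parameters), run as parallel chains with rank-normalised split
R-hat convergence checks (threshold 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import (
    R_HAT_THRESHOLD,
    half_cauchy_logpdf,
    max_rhat,
    normal_logpdf,
    poisson_logpmf,
    summarize_chains,
)

__all__ = [
    "StateSpaceSpec",
    "StateSpacePosterior",
    "SiteSummary",
    "geometric_lag_weights",
    "log_likelihood",
    "fit_statespace",
    "bayesian_p_value",
    "derive_site_summaries",
]


@dataclass
class StateSpaceSpec:
    """Model and sampler settings for one species-group fit."""

    group: str = "unenhanced"  # "enhanced" switches the fry term on
    Q: int = 3
    chains: int = 4
    n_warmup: int = 1500
    n_iter: int = 1500
    thin: int = 5
    seed: int = 0
    prior_loc_sd: float = 10.0  # Normal(0, sd) on location hyper-parameters
    prior_scale: float = 5.0  # half-Cauchy scale on SD parameters
    init_state_sd: float = 2.0  # diffuse prior on the first Q log-densities
    # (on the log fish-per-m^2 scale +-3 sd spans e-6..e6, far beyond any
    # realistic density, while keeping unobserved lead-in years bounded)

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.group not in ("enhanced", "unenhanced"):
            raise ValueError("group must be 'enhanced' or 'unenhanced'")

    @property
    def psi(self) -> int:
        return 1 if self.group == "enhanced" else 0


@dataclass
class StateSpacePosterior:
    """Posterior draws (chain, draw, ...) plus diagnostics and data echo."""

    draws: dict
    sites: list
    watersheds: list
    years: list
    group: str
    spec: StateSpaceSpec
    data: dict
    summary: dict = field(default_factory=dict)
    converged: bool = False

    @property
    def n_draws(self) -> int:
        tau = self.draws["tau"]
        return tau.shape[0] * tau.shape[1]

    def median_density(self) -> pd.DataFrame:
        """Median latent density per site and year (fish per m^2),
        including imputed years."""
        u = self.draws["log_density"]  # (chain, draw, S, T)
        med = np.exp(np.median(u.reshape(-1, *u.shape[2:]), axis=0))
        return pd.DataFrame(med, index=self.sites, columns=self.years)


# --------------------------------------------------------------------------
# pure functions
# --------------------------------------------------------------------------


def geometric_lag_weights(tau: float, Q: int) -> np.ndarray:
    """Normalised geometric lag weights ``tau**q / sum_q tau**q``.

    ``w[0]`` weights lag 1.  Weights sum to one and are nonincreasing in q.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    if Q < 1:
        raise ValueError("Q must be >= 1")
    w = tau ** np.arange(1, Q + 1)
    return w / w.sum()


def log_likelihood(
    counts: np.ndarray,
    areas: np.ndarray,
    obs_mask: np.ndarray,
    log_density: np.ndarray,
    eps_obs: np.ndarray,
    fry: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    psi: int = 0,
) -> float:
    """Total observation log-likelihood for one parameter draw.

    Sums Poisson log-masses over observed (site, year) cells at mean
    ``lambda * A`` with ``lambda = exp(u + eps_obs) + psi * beta_s * Fry``.
    Missing years contribute nothing.  An invalid draw producing a negative
    lambda returns ``-inf``.
    """
    lam = np.exp(log_density + eps_obs)
    if psi:
        if fry is None or beta is None:
            raise ValueError("enhanced-group likelihood needs fry and beta")
        lam = lam + np.asarray(beta)[:, None] * fry
    if np.any(lam[obs_mask] < 0):
        return -np.inf
    return float(np.sum(poisson_logpmf(counts[obs_mask], (lam * areas)[obs_mask])))


def _bvn_logpdf(x1, x2, m1, m2, s1, s2, rho):
    """Bivariate normal log density, elementwise."""
    z1 = (x1 - m1) / s1
    z2 = (x2 - m2) / s2
    om = 1.0 - rho**2
    return (
        -0.5 * (z1**2 - 2 * rho * z1 * z2 + z2**2) / om
        - np.log(s1 * s2)
        - 0.5 * np.log(om)
        - np.log(2 * np.pi)
    )


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------


def _prepare_group_arrays(dataset, group: str) -> dict:
    """Pivot the long count records of one species group into (S, T) arrays
    on the full calendar-year grid."""
    c = dataset.counts
    sub = c[c["group"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    years = list(range(int(c["year"].min()), int(c["year"].max()) + 1))
    sites = sorted(sub["site"].unique())
    site_ws = sub.groupby("site")["watershed"].first().to_dict()
    S, T = len(sites), len(years)
    Y = np.zeros((S, T))
    A = np.ones((S, T))
    M = np.zeros((S, T), dtype=bool)
    obs = sub.dropna(subset=["count"])
    si = {s: i for i, s in enumerate(sites)}
    yi = {y: j for j, y in enumerate(years)}
    for _, row in obs.iterrows():
        i, j = si[row["site"]], yi[int(row["year"])]
        Y[i, j] = row["count"]
        A[i, j] = row["sampling_area"]
        M[i, j] = True

    fry = np.zeros((S, T))
    rel = dataset.releases
    if rel is not None and len(rel):
        fr = rel[rel["stage"] == "fry"].set_index(["watershed", "year"])["number"]
        for s in sites:
            for y in years:
                key = (site_ws[s], y)
                if key in fr.index:
                    fry[si[s], yi[y]] = fr.loc[key]
    return {
        "Y": Y,
        "A": A,
        "M": M,
        "fry": fry,
        "sites": sites,
        "years": years,
        "watersheds": [site_ws[s] for s in sites],
    }


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def _column_colors(T: int, Q: int) -> list:
    """Group time columns so that members of a group are > Q apart (their
    Metropolis conditionals are then mutually independent and can be
    updated as one vectorised block).  Each entry is (cols, kinfo) where
    kinfo lists, per lag k, the valid source indices and affected
    downstream columns."""
    colors = []
    for c in range(Q + 1):
        cols = np.arange(c, T, Q + 1)
        kinfo = []
        for k in range(1, Q + 1):
            tk = cols + k
            valid = (tk < T) & (tk >= Q)
            kinfo.append((k, valid, tk[valid]))
        colors.append((cols, kinfo))
    return colors


def _init_state(d: dict, spec: StateSpaceSpec, rng) -> dict:
    Y, A, M = d["Y"], d["A"], d["M"]
    S, T = Y.shape
    with np.errstate(divide="ignore"):
        emp = np.where(M, np.log((Y + 0.5) / A), np.nan)
    emp = (
        pd.DataFrame(emp)
        .interpolate(axis=1, limit_direction="both")
        .to_numpy()
    )
    emp = np.nan_to_num(emp, nan=-1.0)
    # start from a smoothed latent path, with the observation-error terms
    # absorbing the residual (the U/E split is then refined by the sampler)
    u0 = (
        pd.DataFrame(emp.T)
        .rolling(3, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T
    )
    u0 = u0 + rng.normal(0, 0.1, u0.shape)
    e0 = np.where(M, emp - u0, 0.0)
    st = {
        "U": u0,
        "E": e0,
        "xi1": 0.7 * u0.mean(axis=1),
        "xi2": np.full(S, 0.3) + rng.normal(0, 0.05, S),
        "log_sig_state": np.full(S, np.log(0.3)),
        "log_sig_obs": np.full(S, np.log(0.3)),
        "beta": np.full(S, 0.5),
        "theta_beta": 0.5 + rng.normal(0, 0.1),
        "log_sig_beta": np.log(0.3),
        "logit_tau": rng.normal(0, 0.5),
        "theta_xi": np.array([u0.mean() * 0.7, 0.3]) + rng.normal(0, 0.05, 2),
        "log_sd_xi": np.log(np.array([0.3, 0.2])),
        "atanh_rho": 0.0,
    }
    return st


def _lag_matrix(U: np.ndarray, w: np.ndarray, Q: int) -> np.ndarray:
    """W[:, t] = sum_q w[q-1] * U[:, t-q] for t >= Q (0 elsewhere)."""
    S, T = U.shape
    W = np.zeros((S, T))
    for q in range(1, Q + 1):
        W[:, Q:] += w[q - 1] * U[:, Q - q : T - q]
    return W


def _obs_ll_matrix(st, d, psi) -> np.ndarray:
    """Elementwise observation log-likelihood (0 where unobserved)."""
    lam = np.exp(st["U"] + st["E"])
    if psi:
        lam = lam + st["beta"][:, None] * d["fry"]
    ll = np.where(d["M"], d["Y"] * np.log(lam * d["A"]) - lam * d["A"], 0.0)
    return ll


def _sweep(st, d, spec, rng, scales, adapt: bool):
    """One full Metropolis-within-Gibbs sweep, in place."""
    Y, A, M, fry = d["Y"], d["A"], d["M"], d["fry"]
    S, T = Y.shape
    Q = spec.Q
    psi = spec.psi
    tau = 1.0 / (1.0 + np.exp(-st["logit_tau"]))
    w = geometric_lag_weights(tau, Q)
    sig_state = np.exp(st["log_sig_state"])
    sig_obs = np.exp(st["log_sig_obs"])

    U = st["U"]
    W = _lag_matrix(U, w, Q)
    resid = np.zeros((S, T))
    resid[:, Q:] = U[:, Q:] - st["xi1"][:, None] - st["xi2"][:, None] * W[:, Q:]

    E = st["E"]

    def obs_ll_cols(u_sub, e_sub, cols):
        lam = np.exp(u_sub + e_sub)
        if psi:
            lam = lam + st["beta"][:, None] * fry[:, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                M[:, cols],
                Y[:, cols] * np.log(lam * A[:, cols]) - lam * A[:, cols],
                0.0,
            )
        return np.where(M[:, cols] & ~np.isfinite(out), -np.inf, out)

    def column_group_gibbs(cols, kinfo):
        """Exact Gaussian Gibbs update of U over a group of mutually
        independent columns (pairwise distance > Q).  At observed cells the
        combination V = U + E (which the Poisson likelihood sees) is held
        fixed, with E absorbing the change; the conditional of U given V
        and the process model is then exactly Gaussian.  Unobserved cells
        reduce to the plain process conditional."""
        nc = len(cols)
        prec = np.zeros((S, nc))
        pm = np.zeros((S, nc))  # precision * mean accumulator
        m_sub = M[:, cols]
        # pseudo-observation V with noise sigma_obs at observed cells
        V = U[:, cols] + E[:, cols]
        prec += np.where(m_sub, 1.0 / sig_obs[:, None] ** 2, 0.0)
        pm += np.where(m_sub, V / sig_obs[:, None] ** 2, 0.0)
        is_proc = cols >= Q
        if np.any(is_proc):
            pc = cols[is_proc]
            mu_t = st["xi1"][:, None] + st["xi2"][:, None] * W[:, pc]
            prec[:, is_proc] += 1.0 / sig_state[:, None] ** 2
            pm[:, is_proc] += mu_t / sig_state[:, None] ** 2
        if np.any(~is_proc):
            prec[:, ~is_proc] += 1.0 / spec.init_state_sd**2
        for k, valid, tk in kinfo:
            a = -st["xi2"][:, None] * w[k - 1]  # d resid_tk / d u_t
            b = resid[:, tk] - a * U[:, cols[valid]]
            prec[:, valid] += a**2 / sig_state[:, None] ** 2
            pm[:, valid] += -a * b / sig_state[:, None] ** 2
        u_new = pm / prec + rng.normal(size=(S, nc)) / np.sqrt(prec)
        du = u_new - U[:, cols]
        U[:, cols] = u_new
        # keep V fixed at observed cells
        E[:, cols] = np.where(m_sub, E[:, cols] - du, 0.0)
        if np.any(is_proc):
            resid[:, cols[is_proc]] = (
                U[:, cols[is_proc]]
                - st["xi1"][:, None]
                - st["xi2"][:, None] * W[:, cols[is_proc]]
            )
        for k, valid, tk in kinfo:
            W[:, tk] += w[k - 1] * du[:, valid]
            resid[:, tk] -= st["xi2"][:, None] * w[k - 1] * du[:, valid]

    for cols, kinfo in d["colors"]:
        column_group_gibbs(cols, kinfo)

    # ---- observation errors --------------------------------------------
    prop = E + scales["E"] * rng.normal(size=(S, T))
    lam_old = np.exp(U + E)
    lam_new = np.exp(U + prop)
    if psi:
        add = st["beta"][:, None] * fry
        lam_old = lam_old + add
        lam_new = lam_new + add
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_old = Y * np.log(lam_old * A) - lam_old * A
        ll_new = Y * np.log(lam_new * A) - lam_new * A
    delta = np.where(M, ll_new - ll_old, 0.0)
    delta += normal_logpdf(prop, 0.0, sig_obs[:, None]) - normal_logpdf(
        E, 0.0, sig_obs[:, None]
    )
    delta = np.where(np.isfinite(delta), delta, -np.inf)
    acc = (np.log(rng.uniform(size=(S, T))) < delta) & M
    E[acc] = prop[acc]
    if adapt:
        scales["E"][M] *= np.exp(scales["_g"] * (acc[M] - 0.44))

    # ---- funnel move: jointly rescale each site's observation-error
    # field and its SD (E' = cE, sigma' = c sigma); leaves the E-prior
    # invariant so only the likelihood, the SD prior and a log c term decide
    c = np.exp(scales["obs_scale"] * rng.normal(size=S))
    E_new = np.where(M, E * c[:, None], 0.0)
    with np.errstate(over="ignore"):
        lam_old = np.exp(U + E)
        lam_new = np.exp(U + E_new)
    if psi:
        add = st["beta"][:, None] * fry
        lam_old = lam_old + add
        lam_new = lam_new + add
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        dll = np.where(M, Y * np.log(lam_new / lam_old) - (lam_new - lam_old) * A, 0.0)
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
        scales["obs_scale"] *= np.exp(scales["_g"] * (acc - 0.44))

    # ---- (xi1, xi2): conjugate bivariate Gibbs per site -----------------
    sd1, sd2 = np.exp(st["log_sd_xi"])
    rho = np.tanh(st["atanh_rho"])
    cov = np.array([[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]])
    prec_prior = np.linalg.inv(cov)
    x = W[:, Q:]
    y = U[:, Q:]
    n_t = T - Q
    s2 = sig_state**2
    # per-site 2x2 posterior precision
    P11 = prec_prior[0, 0] + n_t / s2
    P12 = prec_prior[0, 1] + x.sum(axis=1) / s2
    P22 = prec_prior[1, 1] + (x**2).sum(axis=1) / s2
    b = prec_prior @ np.array(st["theta_xi"])
    b1 = b[0] + y.sum(axis=1) / s2
    b2 = b[1] + (x * y).sum(axis=1) / s2
    det = P11 * P22 - P12**2
    m1 = (P22 * b1 - P12 * b2) / det
    m2 = (P11 * b2 - P12 * b1) / det
    # Cholesky of the 2x2 covariance (inverse precision), per site
    c11 = np.sqrt(P22 / det)
    c21 = -P12 / det / c11
    c22 = np.sqrt(P11 / det - c21**2)
    z1, z2 = rng.normal(size=S), rng.normal(size=S)
    st["xi1"] = m1 + c11 * z1
    st["xi2"] = m2 + c21 * z1 + c22 * z2
    resid[:, Q:] = U[:, Q:] - st["xi1"][:, None] - st["xi2"][:, None] * W[:, Q:]

    # ---- process and observation SDs (log-scale Metropolis) -------------
    for name, terms, axis_count in (
        ("log_sig_state", resid[:, Q:], np.full(S, T - Q)),
        ("log_sig_obs", np.where(M, E, 0.0), M.sum(axis=1)),
    ):
        cur = st[name]
        prop = cur + scales[name] * rng.normal(size=S)
        ss = (terms**2).sum(axis=1)
        def nll(logsig):
            sig = np.exp(logsig)
            return -axis_count * logsig - 0.5 * ss / sig**2
        delta = (
            nll(prop)
            - nll(cur)
            + half_cauchy_logpdf(np.exp(prop), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
            + (prop - cur)  # Jacobian of the log transform
        )
        acc = np.log(rng.uniform(size=S)) < delta
        st[name] = np.where(acc, prop, cur)
        if adapt:
            scales[name] *= np.exp(scales["_g"] * (acc - 0.44))
    sig_state = np.exp(st["log_sig_state"])
    sig_obs = np.exp(st["log_sig_obs"])

    # ---- fry-catch coefficients (enhanced group only) --------------------
    if psi:
        beta = st["beta"]
        prop = beta + scales["beta"] * rng.normal(size=S)
        ok = prop >= 0
        lam_old = np.exp(U + E) + beta[:, None] * fry
        lam_new = np.exp(U + E) + np.where(ok, prop, beta)[:, None] * fry
        with np.errstate(divide="ignore", invalid="ignore"):
            dll = np.where(
                M, Y * np.log(lam_new / lam_old) - (lam_new - lam_old) * A, 0.0
            )
        dll = np.where(np.isfinite(dll), dll, -np.inf)
        sig_b = np.exp(st["log_sig_beta"])
        delta = dll.sum(axis=1) + normal_logpdf(
            prop, st["theta_beta"], sig_b
        ) - normal_logpdf(beta, st["theta_beta"], sig_b)
        acc = ok & (np.log(rng.uniform(size=S)) < delta)
        st["beta"] = np.where(acc, prop, beta)
        if adapt:
            scales["beta"] *= np.exp(scales["_g"] * (acc - 0.44))

        # hyper-parameters of the truncated-normal beta hierarchy
        from scipy.stats import norm as _norm

        def beta_hyper_lp(theta, log_sig):
            sig = np.exp(log_sig)
            return float(
                np.sum(
                    normal_logpdf(st["beta"], theta, sig)
                    - _norm.logsf(-theta / sig)
                )
            )

        cur_lp = beta_hyper_lp(st["theta_beta"], st["log_sig_beta"])
        prop_t = st["theta_beta"] + scales["theta_beta"] * rng.normal()
        delta = (
            beta_hyper_lp(prop_t, st["log_sig_beta"])
            - cur_lp
            + normal_logpdf(prop_t, 0.0, spec.prior_loc_sd)
            - normal_logpdf(st["theta_beta"], 0.0, spec.prior_loc_sd)
        )
        acc = np.log(rng.uniform()) < delta
        if acc:
            st["theta_beta"] = prop_t
            cur_lp = beta_hyper_lp(prop_t, st["log_sig_beta"])
        if adapt:
            scales["theta_beta"] *= np.exp(scales["_g"] * (float(acc) - 0.44))

        prop_s = st["log_sig_beta"] + scales["log_sig_beta"] * rng.normal()
        delta = (
            beta_hyper_lp(st["theta_beta"], prop_s)
            - cur_lp
            + half_cauchy_logpdf(np.exp(prop_s), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(st["log_sig_beta"]), spec.prior_scale)
            + (prop_s - st["log_sig_beta"])
        )
        acc = np.log(rng.uniform()) < delta
        if acc:
            st["log_sig_beta"] = prop_s
        if adapt:
            scales["log_sig_beta"] *= np.exp(scales["_g"] * (float(acc) - 0.44))

    # ---- tau (geometric-lag decay) ---------------------------------------
    cur = st["logit_tau"]
    prop = cur + scales["logit_tau"] * rng.normal()
    tau_new = 1.0 / (1.0 + np.exp(-prop))
    w_new = geometric_lag_weights(tau_new, Q)
    W_new = _lag_matrix(U, w_new, Q)
    r_new = U[:, Q:] - st["xi1"][:, None] - st["xi2"][:, None] * W_new[:, Q:]
    ll_new = normal_logpdf(r_new, 0.0, sig_state[:, None]).sum()
    ll_old = normal_logpdf(resid[:, Q:], 0.0, sig_state[:, None]).sum()
    # Beta(1,1) prior on tau; Jacobian of the logit transform
    jac = np.log(tau_new * (1 - tau_new)) - np.log(tau * (1 - tau))
    delta = ll_new - ll_old + jac
    acc = np.log(rng.uniform()) < delta
    if acc:
        st["logit_tau"] = prop
        tau, w, W = tau_new, w_new, W_new
        resid[:, Q:] = r_new
    if adapt:
        scales["logit_tau"] *= np.exp(scales["_g"] * (float(acc) - 0.44))

    # ---- hyper-distribution of (xi1, xi2) --------------------------------
    def xi_hyper_lp(theta, log_sd, atanh_rho):
        s1, s2 = np.exp(log_sd)
        rr = np.tanh(atanh_rho)
        return float(
            np.sum(
                _bvn_logpdf(st["xi1"], st["xi2"], theta[0], theta[1], s1, s2, rr)
            )
        )

    cur_lp = xi_hyper_lp(st["theta_xi"], st["log_sd_xi"], st["atanh_rho"])
    for idx in (0, 1):
        prop_v = st["theta_xi"].copy()
        prop_v[idx] += scales["theta_xi"][idx] * rng.normal()
        delta = (
            xi_hyper_lp(prop_v, st["log_sd_xi"], st["atanh_rho"])
            - cur_lp
            + normal_logpdf(prop_v[idx], 0.0, spec.prior_loc_sd)
            - normal_logpdf(st["theta_xi"][idx], 0.0, spec.prior_loc_sd)
        )
        acc = np.log(rng.uniform()) < delta
        if acc:
            st["theta_xi"] = prop_v
            cur_lp = xi_hyper_lp(prop_v, st["log_sd_xi"], st["atanh_rho"])
        if adapt:
            scales["theta_xi"][idx] *= np.exp(scales["_g"] * (float(acc) - 0.44))
    for idx in (0, 1):
        prop_v = st["log_sd_xi"].copy()
        prop_v[idx] += scales["log_sd_xi"][idx] * rng.normal()
        delta = (
            xi_hyper_lp(st["theta_xi"], prop_v, st["atanh_rho"])
            - cur_lp
            + half_cauchy_logpdf(np.exp(prop_v[idx]), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(st["log_sd_xi"][idx]), spec.prior_scale)
            + (prop_v[idx] - st["log_sd_xi"][idx])
        )
        acc = np.log(rng.uniform()) < delta
        if acc:
            st["log_sd_xi"] = prop_v
            cur_lp = xi_hyper_lp(st["theta_xi"], prop_v, st["atanh_rho"])
        if adapt:
            scales["log_sd_xi"][idx] *= np.exp(scales["_g"] * (float(acc) - 0.44))
    # ---- funnel move: rescale the (xi1, xi2) deviations about the hyper
    # mean jointly with the hyper SDs; prior ratio and Jacobian cancel up
    # to the SD priors and a 2 log c term, the process likelihood decides
    c = np.exp(scales["xi_scale"] * rng.normal())
    th = st["theta_xi"]
    xi1n = th[0] + c * (st["xi1"] - th[0])
    xi2n = th[1] + c * (st["xi2"] - th[1])
    resid_new = U[:, Q:] - xi1n[:, None] - xi2n[:, None] * W[:, Q:]
    dll = (
        normal_logpdf(resid_new, 0.0, sig_state[:, None])
        - normal_logpdf(resid[:, Q:], 0.0, sig_state[:, None])
    ).sum()
    sd1, sd2 = np.exp(st["log_sd_xi"])
    delta = (
        dll
        + half_cauchy_logpdf(c * sd1, spec.prior_scale)
        - half_cauchy_logpdf(sd1, spec.prior_scale)
        + half_cauchy_logpdf(c * sd2, spec.prior_scale)
        - half_cauchy_logpdf(sd2, spec.prior_scale)
        + 2.0 * np.log(c)
    )
    acc = np.log(rng.uniform()) < delta
    if acc:
        st["xi1"], st["xi2"] = xi1n, xi2n
        st["log_sd_xi"] = st["log_sd_xi"] + np.log(c)
        resid[:, Q:] = resid_new
        cur_lp = xi_hyper_lp(st["theta_xi"], st["log_sd_xi"], st["atanh_rho"])
    if adapt:
        scales["xi_scale"] *= np.exp(scales["_g"] * (float(acc) - 0.44))

    prop_r = st["atanh_rho"] + scales["atanh_rho"] * rng.normal()
    rho_new = np.tanh(prop_r)
    # uniform prior on rho; Jacobian d rho / d atanh_rho = 1 - rho^2
    delta = (
        xi_hyper_lp(st["theta_xi"], st["log_sd_xi"], prop_r)
        - cur_lp
        + np.log1p(-rho_new**2)
        - np.log1p(-np.tanh(st["atanh_rho"]) ** 2)
    )
    acc = np.log(rng.uniform()) < delta
    if acc:
        st["atanh_rho"] = prop_r
    if adapt:
        scales["atanh_rho"] *= np.exp(scales["_g"] * (float(acc) - 0.44))


def fit_statespace(dataset, spec: StateSpaceSpec) -> StateSpacePosterior:
    """Fit the state-space model to one species group by MCMC.

    Runs ``spec.chains`` independent adaptive MWG chains, discards
    ``n_warmup`` adaptation sweeps, keeps every ``thin``-th of ``n_iter``
    sweeps, and attaches per-parameter R-hat diagnostics.  A fit whose
    worst R-hat exceeds 1.1 is returned with ``converged=False``;
    downstream stages should refuse such fits unless forced.
    """
    d = _prepare_group_arrays(dataset, spec.group)
    S, T = d["Y"].shape
    d["colors"] = _column_colors(T, spec.Q)
    n_per_site = d["M"].sum(axis=1)
    if np.any(n_per_site < spec.Q + 2):
        bad = [d["sites"][i] for i in np.where(n_per_site < spec.Q + 2)[0]]
        raise ValueError(f"sites with fewer than Q+2 observed years: {bad}")

    root = np.random.SeedSequence(spec.seed)
    chain_seeds = root.spawn(spec.chains)
    kept = {}
    n_keep = spec.n_iter // spec.thin
    scalar_names = [
        "tau",
        "theta_xi1",
        "theta_xi2",
        "sd_xi1",
        "sd_xi2",
        "rho_xi",
        "theta_beta",
        "sigma_beta",
    ]
    for name in scalar_names:
        kept[name] = np.zeros((spec.chains, n_keep))
    kept["xi1"] = np.zeros((spec.chains, n_keep, S))
    kept["xi2"] = np.zeros((spec.chains, n_keep, S))
    kept["beta"] = np.zeros((spec.chains, n_keep, S))
    kept["sigma_state"] = np.zeros((spec.chains, n_keep, S))
    kept["sigma_obs"] = np.zeros((spec.chains, n_keep, S))
    kept["log_density"] = np.zeros((spec.chains, n_keep, S, T))
    kept["eps_obs"] = np.zeros((spec.chains, n_keep, S, T))

    for c in range(spec.chains):
        rng = np.random.default_rng(chain_seeds[c])
        st = _init_state(d, spec, rng)
        scales = {
            "U": np.full((S, T), 0.5),
            "shift": np.full((S, T), 0.5),
            "E": np.full((S, T), 0.5),
            "obs_scale": np.full(S, 0.3),
            "xi_scale": 0.3,
            "log_sig_state": np.full(S, 0.3),
            "log_sig_obs": np.full(S, 0.3),
            "beta": np.full(S, 0.3),
            "theta_beta": 0.3,
            "log_sig_beta": 0.3,
            "logit_tau": 0.5,
            "theta_xi": np.full(2, 0.3),
            "log_sd_xi": np.full(2, 0.3),
            "atanh_rho": 0.3,
        }
        for i in range(spec.n_warmup):
            scales["_g"] = min(0.25, 4.0 / np.sqrt(i + 8))
            _sweep(st, d, spec, rng, scales, adapt=True)
        k = 0
        for i in range(spec.n_iter):
            _sweep(st, d, spec, rng, scales, adapt=False)
            if (i + 1) % spec.thin == 0 and k < n_keep:
                tau = 1.0 / (1.0 + np.exp(-st["logit_tau"]))
                kept["tau"][c, k] = tau
                kept["theta_xi1"][c, k] = st["theta_xi"][0]
                kept["theta_xi2"][c, k] = st["theta_xi"][1]
                kept["sd_xi1"][c, k], kept["sd_xi2"][c, k] = np.exp(st["log_sd_xi"])
                kept["rho_xi"][c, k] = np.tanh(st["atanh_rho"])
                kept["theta_beta"][c, k] = st["theta_beta"]
                kept["sigma_beta"][c, k] = np.exp(st["log_sig_beta"])
                kept["xi1"][c, k] = st["xi1"]
                kept["xi2"][c, k] = st["xi2"]
                kept["beta"][c, k] = st["beta"]
                kept["sigma_state"][c, k] = np.exp(st["log_sig_state"])
                kept["sigma_obs"][c, k] = np.exp(st["log_sig_obs"])
                kept["log_density"][c, k] = st["U"]
                kept["eps_obs"][c, k] = st["E"]
                k += 1

    diag = {n: kept[n] for n in scalar_names}
    diag["xi1"] = kept["xi1"]
    diag["xi2"] = kept["xi2"]
    diag["sigma_state"] = kept["sigma_state"]
    diag["sigma_obs"] = kept["sigma_obs"]
    if not spec.psi:
        for n in ("theta_beta", "sigma_beta"):
            diag.pop(n)
    summary = summarize_chains(diag)
    converged = max_rhat(summary) < R_HAT_THRESHOLD
    return StateSpacePosterior(
        draws=kept,
        sites=d["sites"],
        watersheds=d["watersheds"],
        years=d["years"],
        group=spec.group,
        spec=spec,
        data=d,
        summary=summary,
        converged=converged,
    )


# --------------------------------------------------------------------------
# posterior-predictive check and summaries
# --------------------------------------------------------------------------


def bayesian_p_value(
    posterior: StateSpacePosterior, seed: int = 0, max_draws: int = 500
) -> float:
    """Posterior-predictive P-value with a chi-squared discrepancy.

    For each kept draw, expected counts ``E = lambda * A`` are formed from
    the draw's latent densities (and observation errors), a replicate count
    matrix is drawn Poisson(E), and the discrepancy
    ``sum (y - E)^2 / (E + eps)`` is compared between replicate and data.
    Values near 0.5 indicate an adequate fit; near 0 or 1, misfit.
    """
    d = posterior.data
    M, Y, A, fry = d["M"], d["Y"], d["A"], d["fry"]
    psi = posterior.spec.psi
    rng = np.random.default_rng(seed)
    U = posterior.draws["log_density"]
    E_obs = posterior.draws["eps_obs"]
    beta = posterior.draws["beta"]
    nc, nk = U.shape[:2]
    flat = [(c, k) for c in range(nc) for k in range(nk)]
    if len(flat) > max_draws:
        idx = rng.choice(len(flat), max_draws, replace=False)
        flat = [flat[i] for i in idx]
    hits = 0
    for c, k in flat:
        lam = np.exp(U[c, k] + E_obs[c, k])
        if psi:
            lam = lam + beta[c, k][:, None] * fry
        mean = lam * A
        yrep = rng.poisson(mean)
        t_obs = np.sum(((Y - mean) ** 2 / (mean + 1e-12))[M])
        t_rep = np.sum(((yrep - mean) ** 2 / (mean + 1e-12))[M])
        hits += t_rep >= t_obs
    return hits / len(flat)


@dataclass
class SiteSummary:
    """Tidy per-site summary table; see :func:`derive_site_summaries`."""

    table: pd.DataFrame


def derive_site_summaries(
    posterior_enh: StateSpacePosterior,
    posterior_unenh: StateSpacePosterior,
    richness: pd.DataFrame | None = None,
    require_converged: bool = True,
) -> pd.DataFrame:
    """Per-site temporal CV / mean / SD from posterior-median densities.

    The median latent-density series (including imputed years) is summarised
    per species group; the whole-community series is the sum of the two
    group medians.  Sites present in only one posterior are dropped with a
    warning.  ``richness`` (columns site, richness) is merged when given.
    """
    import warnings

    for post in (posterior_enh, posterior_unenh):
        if require_converged and not post.converged:
            raise RuntimeError(
                f"{post.group} posterior not converged; pass "
                "require_converged=False to override"
            )
    med_e = posterior_enh.median_density()
    med_u = posterior_unenh.median_density()
    common = [s for s in med_e.index if s in set(med_u.index)]
    dropped = (set(med_e.index) | set(med_u.index)) - set(common)
    if dropped:
        warnings.warn(f"sites missing from one posterior: {sorted(dropped)}")
    ws = dict(zip(posterior_enh.sites, posterior_enh.watersheds))
    n_obs = dict(
        zip(posterior_enh.sites, posterior_enh.data["M"].sum(axis=1).astype(int))
    )
    rows = []
    for s in common:
        series = {
            "enhanced": med_e.loc[s].to_numpy(),
            "unenhanced": med_u.loc[s].to_numpy(),
        }
        series["whole"] = series["enhanced"] + series["unenhanced"]
        row = {"site": s, "watershed": ws[s], "n_obs_years": n_obs[s]}
        for g, arr in series.items():
            mu = float(arr.mean())
            sd = float(arr.std(ddof=1))
            row[f"mu_{g}"] = mu
            row[f"sd_{g}"] = sd
            row[f"cv_{g}"] = sd / mu if mu > 0 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if richness is not None:
        out = out.merge(richness, on="site", how="left")
    return out
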