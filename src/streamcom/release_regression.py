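"""Hierarchical regression of site summaries on latent effective release.

Responses per site are (i) taxonomic richness, modelled Poisson with a
lognormal overdispersion term, and (ii) the temporal mean and SD of
community density, modelled jointly lognormal with covariance ``Omega_y``.
The focal predictor is the *effective release* ``R'_s = eta_{w,s} R_w``:
each watershed's average yearly release total ``R_w`` is split across its
sites (plus one unsurveyed slot) by a latent simplex ``eta_w`` estimated
jointly with the regression by MCMC (flat Dirichlet prior).  Watershed
intercepts follow a second hierarchy driven by ocean productivity and
elevational relief.  Because ``CV = sd / mu``, the release effect on the
log CV is the per-draw difference of the SD- and mean-model coefficients —
derived exactly, never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._mcmc import (
    R_HAT_THRESHOLD,
    half_cauchy_logpdf,
    max_rhat,
    normal_logpdf,
    summarize_chains,
)

__all__ = [
    "RegressionSpec",
    "RegressionPosterior",
    "standardize",
    "effective_release",
    "fit_release_models",
    "derive_cv_coefficients",
    "SITE_PREDICTORS",
    "WATERSHED_PREDICTORS",
]

SITE_PREDICTORS = [
    "log_watershed_area",
    "temperature",
    "precipitation",
    "forest_fraction",
    "n_obs_years",
]
WATERSHED_PREDICTORS = ["ocean_productivity", "sd_elevation"]


@dataclass
class RegressionSpec:
    """Settings for the release regressions."""

    responses: tuple = ("joint", "richness")
    site_predictors: tuple = tuple(SITE_PREDICTORS)
    watershed_predictors: tuple = tuple(WATERSHED_PREDICTORS)
    standardize_release: bool = True  # scale R' by its cross-site SD per draw
    chains: int = 4
    n_warmup: int = 1500
    n_iter: int = 1500
    thin: int = 3
    seed: int = 0
    prior_loc_sd: float = 10.0
    prior_scale: float = 5.0
    eta_kappa: float = 50.0  # Dirichlet proposal concentration


@dataclass
class RegressionPosterior:
    """Draws for both regression models plus derived CV coefficients.

    ``draws`` holds (chain, draw, ...) arrays keyed e.g. ``gamma_mu``
    (release coefficient first, then site predictors), ``gamma0_mu``
    (watershed intercepts), hyper-parameters, and ``eta_<model>`` as a dict
    watershed -> (chain, draw, S_w + 1).  ``coef_names`` orders the
    coefficient axis.
    """

    draws: dict
    coef_names: list
    watersheds: list
    sites: list
    summary: dict = field(default_factory=dict)
    converged: bool = False

    def sign_probability(self, key: str) -> np.ndarray:
        """Fraction of draws > 0 along the coefficient axis."""
        arr = self.draws[key]
        return (arr > 0).mean(axis=(0, 1))


# --------------------------------------------------------------------------
# small pure operations
# --------------------------------------------------------------------------


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale predictor columns to mean 0, SD 1 (sample SD).

    Returns the transformed table and a scaling record (column, mean, sd)
    for back-transformation.  A zero-variance column is rejected by name.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rec = []
    for col in columns:
        x = out[col].astype(float)
        m, s = x.mean(), x.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        out[col] = (x - m) / s
        rec.append({"column": col, "mean": m, "sd": s})
    return out, pd.DataFrame(rec)


def effective_release(eta: np.ndarray, R_w: float) -> np.ndarray:
    """Site-level effective release ``R'_s = eta_s * R_w``.

    ``eta`` lives on the (S_w + 1)-simplex whose last slot is the share
    escaping to unsurveyed areas; only the first S_w entries are returned.
    """
    eta = np.asarray(eta, dtype=float)
    if R_w < 0:
        raise ValueError("R_w must be >= 0")
    if np.any(eta < 0) or abs(eta.sum() - 1.0) > 1e-8:
        raise ValueError("eta must be a simplex (nonnegative, summing to 1)")
    return eta[:-1] * R_w


def derive_cv_coefficients(posterior: RegressionPosterior) -> dict:
    """Per-draw CV coefficients ``gamma_cv = gamma_sd - gamma_mu``.

    Exact draw-by-draw differences (the CV is sd/mu, so its log-scale
    regression coefficients are coefficient differences); returns arrays
    plus median / 95% interval / sign-probability summaries.
    """
    g_sd = posterior.draws["gamma_sd"]
    g_mu = posterior.draws["gamma_mu"]
    if g_sd.shape != g_mu.shape:
        raise ValueError("mean and SD draws are misaligned")
    g_cv = g_sd - g_mu
    flat = g_cv.reshape(-1, g_cv.shape[-1])
    return {
        "draws": g_cv,
        "median": np.median(flat, axis=0),
        "q2.5": np.quantile(flat, 0.025, axis=0),
        "q97.5": np.quantile(flat, 0.975, axis=0),
        "pr_positive": (flat > 0).mean(axis=0),
        "names": list(posterior.coef_names),
    }


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------


def _dirichlet_logpdf(x, a):
    return float(
        gammaln(a.sum()) - gammaln(a).sum() + np.sum((a - 1.0) * np.log(x))
    )


def _propose_eta(eta, kappa, rng):
    a = kappa * eta + 0.5
    prop = rng.dirichlet(a)
    prop = np.clip(prop, 1e-12, None)
    prop = prop / prop.sum()
    a_rev = kappa * prop + 0.5
    log_q_fwd = _dirichlet_logpdf(prop, a)
    log_q_rev = _dirichlet_logpdf(eta, a_rev)
    return prop, log_q_rev - log_q_fwd


class _RegressionData:
    """Aligned numpy views of the regression inputs."""

    def __init__(self, site_table, watershed_table, spec):
        self.sites = list(site_table["site"])
        self.watersheds = list(watershed_table["watershed"])
        widx = {w: i for i, w in enumerate(self.watersheds)}
        self.widx = np.array([widx[w] for w in site_table["watershed"]])
        std, self.scaling = standardize(
            site_table[list(spec.site_predictors)].copy()
        )
        self.X = std.to_numpy()
        wstd, _ = standardize(watershed_table[list(spec.watershed_predictors)].copy())
        self.Xw = wstd.to_numpy()
        self.R_w = watershed_table.set_index("watershed")["R_w"].loc[
            self.watersheds
        ].to_numpy()
        self.n = len(self.sites)
        self.n_w = len(self.watersheds)
        self.slots = np.array(
            [int((self.widx == i).sum()) + 1 for i in range(self.n_w)]
        )
        # site order within each watershed (for eta -> R' scatter)
        self.site_pos = np.zeros(self.n, dtype=int)
        self.members = []
        for i in range(self.n_w):
            members = np.where(self.widx == i)[0]
            self.site_pos[members] = np.arange(len(members))
            self.members.append(members)
        if "richness" in site_table:
            self.richness = site_table["richness"].to_numpy(dtype=float)
        self.has_joint = "mu" in site_table and "sd" in site_table
        if self.has_joint:
            self.ln_y = np.log(
                site_table[["mu", "sd"]].to_numpy(dtype=float)
            )

    def r_prime(self, eta_list):
        rp = np.zeros(self.n)
        for i in range(self.n_w):
            members = self.widx == i
            rp[members] = eta_list[i][self.site_pos[members]] * self.R_w[i]
        return rp


def _release_pred(rp, standardize_release):
    if not standardize_release:
        return rp
    sd = rp.std(ddof=1)
    return rp / sd if sd > 0 else rp


def _fit_joint(data: _RegressionData, spec: RegressionSpec, kept, chain, rng):
    """MWG chain for the joint (ln mu, ln sd) model."""
    n, n_w, K = data.n, data.n_w, data.X.shape[1]
    resp = ("mu", "sd")
    st = {
        "g0": {r: data.ln_y[:, j].mean() + rng.normal(0, 0.2, n_w) for j, r in enumerate(resp)},
        "gam": {r: rng.normal(0, 0.1, K + 1) for r in resp},  # [release, covs]
        "gp0": {r: float(data.ln_y[:, j].mean()) for j, r in enumerate(resp)},
        "gp": {r: np.zeros(2) for r in resp},
        "log_sgam": {r: np.log(0.3) for r in resp},
        "log_sd_y": np.log(np.array([0.3, 0.3])),
        "atanh_rho": 0.0,
        "eta": [np.ones(s) / s for s in data.slots],
    }
    sc = {
        "g0": {r: np.full(n_w, 0.3) for r in resp},
        "gam": {r: np.full(K + 1, 0.1) for r in resp},
        "gp0": {r: 0.3 for r in resp},
        "gp": {r: np.full(2, 0.3) for r in resp},
        "log_sgam": {r: 0.3 for r in resp},
        "log_sd_y": np.full(2, 0.2),
        "atanh_rho": 0.2,
    }

    def theta(st, rp_std):
        out = {}
        for r in resp:
            out[r] = (
                st["g0"][r][data.widx]
                + st["gam"][r][0] * rp_std
                + data.X @ st["gam"][r][1:]
            )
        return out

    def ll_site(st, rp_std):
        th = theta(st, rp_std)
        s1, s2 = np.exp(st["log_sd_y"])
        rho = np.tanh(st["atanh_rho"])
        z1 = (data.ln_y[:, 0] - th["mu"]) / s1
        z2 = (data.ln_y[:, 1] - th["sd"]) / s2
        om = 1 - rho**2
        return (
            -0.5 * (z1**2 - 2 * rho * z1 * z2 + z2**2) / om
            - np.log(s1 * s2)
            - 0.5 * np.log(om)
        )

    n_keep = spec.n_iter // spec.thin
    total = spec.n_warmup + spec.n_iter
    k = 0
    rp = data.r_prime(st["eta"])
    for it in range(total):
        adapt = it < spec.n_warmup
        g = min(0.25, 4.0 / np.sqrt(it + 8))
        rp_std = _release_pred(rp, spec.standardize_release)
        ll = ll_site(st, rp_std)

        # watershed intercepts (vectorised over watersheds)
        for r in resp:
            prop = st["g0"][r] + sc["g0"][r] * rng.normal(size=n_w)
            old = st["g0"][r].copy()
            st["g0"][r] = prop
            ll_new = ll_site(st, rp_std)
            d_site = ll_new - ll
            d_w = np.bincount(data.widx, weights=d_site, minlength=n_w)
            sgam = np.exp(st["log_sgam"][r])
            thg = st["gp0"][r] + data.Xw @ st["gp"][r]
            d_w += normal_logpdf(prop, thg, sgam) - normal_logpdf(old, thg, sgam)
            acc = np.log(rng.uniform(size=n_w)) < d_w
            st["g0"][r] = np.where(acc, prop, old)
            if adapt:
                sc["g0"][r] *= np.exp(g * (acc - 0.44))
            ll = ll_site(st, rp_std)

        # regression coefficients
        for r in resp:
            for j in range(K + 1):
                cur = st["gam"][r][j]
                st["gam"][r][j] = cur + sc["gam"][r][j] * rng.normal()
                ll_new = ll_site(st, rp_std)
                d = (
                    ll_new.sum()
                    - ll.sum()
                    + normal_logpdf(st["gam"][r][j], 0, spec.prior_loc_sd)
                    - normal_logpdf(cur, 0, spec.prior_loc_sd)
                )
                if np.log(rng.uniform()) < d:
                    ll = ll_new
                else:
                    st["gam"][r][j] = cur
                if adapt:
                    sc["gam"][r][j] *= np.exp(
                        g * (float(st["gam"][r][j] != cur) - 0.44)
                    )

        # watershed hierarchy
        for r in resp:
            sgam = np.exp(st["log_sgam"][r])
            thg = st["gp0"][r] + data.Xw @ st["gp"][r]
            lp = normal_logpdf(st["g0"][r], thg, sgam).sum()
            for name, idx in (("gp0", None), ("gp", 0), ("gp", 1)):
                if idx is None:
                    cur = st["gp0"][r]
                    prop = cur + sc["gp0"][r] * rng.normal()
                    th_new = thg + (prop - cur)
                else:
                    cur = st["gp"][r][idx]
                    prop = cur + sc["gp"][r][idx] * rng.normal()
                    th_new = thg + (prop - cur) * data.Xw[:, idx]
                lp_new = normal_logpdf(st["g0"][r], th_new, sgam).sum()
                d = (
                    lp_new
                    - lp
                    + normal_logpdf(prop, 0, spec.prior_loc_sd)
                    - normal_logpdf(cur, 0, spec.prior_loc_sd)
                )
                acc = np.log(rng.uniform()) < d
                if acc:
                    if idx is None:
                        st["gp0"][r] = prop
                    else:
                        st["gp"][r][idx] = prop
                    thg, lp = th_new, lp_new
                if adapt:
                    key = sc["gp0"] if idx is None else None
                    if idx is None:
                        sc["gp0"][r] *= np.exp(g * (float(acc) - 0.44))
                    else:
                        sc["gp"][r][idx] *= np.exp(g * (float(acc) - 0.44))
            cur = st["log_sgam"][r]
            prop = cur + sc["log_sgam"][r] * rng.normal()
            lp_new = normal_logpdf(st["g0"][r], thg, np.exp(prop)).sum()
            d = (
                lp_new
                - lp
                + half_cauchy_logpdf(np.exp(prop), spec.prior_scale)
                - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
                + (prop - cur)
            )
            acc = np.log(rng.uniform()) < d
            if acc:
                st["log_sgam"][r] = prop
            if adapt:
                sc["log_sgam"][r] *= np.exp(g * (float(acc) - 0.44))

        # Omega_y
        for name, idx in (("log_sd_y", 0), ("log_sd_y", 1), ("atanh_rho", None)):
            if idx is None:
                cur = st["atanh_rho"]
                st["atanh_rho"] = cur + sc["atanh_rho"] * rng.normal()
                extra = np.log1p(-np.tanh(st["atanh_rho"]) ** 2) - np.log1p(
                    -np.tanh(cur) ** 2
                )
            else:
                cur = st["log_sd_y"][idx]
                st["log_sd_y"][idx] = cur + sc["log_sd_y"][idx] * rng.normal()
                extra = (
                    half_cauchy_logpdf(np.exp(st["log_sd_y"][idx]), spec.prior_scale)
                    - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
                    + (st["log_sd_y"][idx] - cur)
                )
            ll_new = ll_site(st, rp_std)
            d = ll_new.sum() - ll.sum() + extra
            acc = np.log(rng.uniform()) < d
            if acc:
                ll = ll_new
            else:
                if idx is None:
                    st["atanh_rho"] = cur
                else:
                    st["log_sd_y"][idx] = cur
            if adapt:
                if idx is None:
                    sc["atanh_rho"] *= np.exp(g * (float(acc) - 0.44))
                else:
                    sc["log_sd_y"][idx] *= np.exp(g * (float(acc) - 0.44))

        # latent release simplexes (flat Dirichlet prior)
        for i in range(data.n_w):
            prop, log_h = _propose_eta(st["eta"][i], spec.eta_kappa, rng)
            if data.R_w[i] == 0:
                if np.log(rng.uniform()) < log_h:
                    st["eta"][i] = prop
                continue
            old = st["eta"][i]
            st["eta"][i] = prop
            rp_new = rp.copy()
            rp_new[data.members[i]] = prop[: len(data.members[i])] * data.R_w[i]
            rp_std_new = _release_pred(rp_new, spec.standardize_release)
            ll_new = ll_site(st, rp_std_new)
            d = ll_new.sum() - ll.sum() + log_h
            if np.log(rng.uniform()) < d:
                rp, rp_std, ll = rp_new, rp_std_new, ll_new
            else:
                st["eta"][i] = old

        if not adapt and (it - spec.n_warmup + 1) % spec.thin == 0 and k < n_keep:
            for r in resp:
                kept[f"gamma_{r}"][chain, k] = st["gam"][r]
                kept[f"gamma0_{r}"][chain, k] = st["g0"][r]
                kept[f"gamma_prime_{r}"][chain, k] = np.concatenate(
                    [[st["gp0"][r]], st["gp"][r]]
                )
                kept[f"sigma_gamma_{r}"][chain, k] = np.exp(st["log_sgam"][r])
            kept["omega_sd"][chain, k] = np.exp(st["log_sd_y"])
            kept["omega_rho"][chain, k] = np.tanh(st["atanh_rho"])
            for i, w in enumerate(data.watersheds):
                kept["eta_joint"][w][chain, k] = st["eta"][i]
            k += 1


def _fit_richness(data: _RegressionData, spec: RegressionSpec, kept, chain, rng):
    """MWG chain for the overdispersed-Poisson richness model."""
    n, n_w, K = data.n, data.n_w, data.X.shape[1]
    y = data.richness
    st = {
        "g0": np.log(y.mean() + 0.5) + rng.normal(0, 0.2, n_w),
        "gam": rng.normal(0, 0.1, K + 1),
        "eps": np.zeros(n),
        "log_sig_lam": np.log(0.3),
        "gp0": float(np.log(y.mean() + 0.5)),
        "gp": np.zeros(2),
        "log_sgam": np.log(0.3),
        "eta": [np.ones(s) / s for s in data.slots],
    }
    sc = {
        "g0": np.full(n_w, 0.3),
        "gam": np.full(K + 1, 0.1),
        "eps": np.full(n, 0.5),
        "log_sig_lam": 0.3,
        "gp0": 0.3,
        "gp": np.full(2, 0.3),
        "log_sgam": 0.3,
    }

    def ll_site(st, rp_std):
        lnlam = (
            st["g0"][data.widx]
            + st["gam"][0] * rp_std
            + data.X @ st["gam"][1:]
            + st["eps"]
        )
        return y * lnlam - np.exp(lnlam)

    n_keep = spec.n_iter // spec.thin
    total = spec.n_warmup + spec.n_iter
    k = 0
    rp = data.r_prime(st["eta"])
    for it in range(total):
        adapt = it < spec.n_warmup
        g = min(0.25, 4.0 / np.sqrt(it + 8))
        rp_std = _release_pred(rp, spec.standardize_release)
        ll = ll_site(st, rp_std)

        # overdispersion residuals, vectorised
        sig = np.exp(st["log_sig_lam"])
        prop = st["eps"] + sc["eps"] * rng.normal(size=n)
        old = st["eps"].copy()
        st["eps"] = prop
        ll_new = ll_site(st, rp_std)
        d = ll_new - ll + normal_logpdf(prop, 0, sig) - normal_logpdf(old, 0, sig)
        acc = np.log(rng.uniform(size=n)) < d
        st["eps"] = np.where(acc, prop, old)
        if adapt:
            sc["eps"] *= np.exp(g * (acc - 0.44))
        ll = ll_site(st, rp_std)

        cur = st["log_sig_lam"]
        prop_s = cur + sc["log_sig_lam"] * rng.normal()
        d = (
            normal_logpdf(st["eps"], 0, np.exp(prop_s)).sum()
            - normal_logpdf(st["eps"], 0, np.exp(cur)).sum()
            + half_cauchy_logpdf(np.exp(prop_s), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
            + (prop_s - cur)
        )
        acc_s = np.log(rng.uniform()) < d
        if acc_s:
            st["log_sig_lam"] = prop_s
        if adapt:
            sc["log_sig_lam"] *= np.exp(g * (float(acc_s) - 0.44))

        # intercepts
        prop = st["g0"] + sc["g0"] * rng.normal(size=n_w)
        old = st["g0"].copy()
        st["g0"] = prop
        ll_new = ll_site(st, rp_std)
        d_w = np.bincount(data.widx, weights=ll_new - ll, minlength=n_w)
        sgam = np.exp(st["log_sgam"])
        thg = st["gp0"] + data.Xw @ st["gp"]
        d_w += normal_logpdf(prop, thg, sgam) - normal_logpdf(old, thg, sgam)
        acc = np.log(rng.uniform(size=n_w)) < d_w
        st["g0"] = np.where(acc, prop, old)
        if adapt:
            sc["g0"] *= np.exp(g * (acc - 0.44))
        ll = ll_site(st, rp_std)

        # coefficients
        for j in range(K + 1):
            cur = st["gam"][j]
            st["gam"][j] = cur + sc["gam"][j] * rng.normal()
            ll_new = ll_site(st, rp_std)
            d = (
                ll_new.sum()
                - ll.sum()
                + normal_logpdf(st["gam"][j], 0, spec.prior_loc_sd)
                - normal_logpdf(cur, 0, spec.prior_loc_sd)
            )
            if np.log(rng.uniform()) < d:
                ll = ll_new
            else:
                st["gam"][j] = cur
            if adapt:
                sc["gam"][j] *= np.exp(g * (float(st["gam"][j] != cur) - 0.44))

        # hierarchy
        lp = normal_logpdf(st["g0"], thg, sgam).sum()
        for name, idx in (("gp0", None), ("gp", 0), ("gp", 1)):
            if idx is None:
                cur = st["gp0"]
                prop_v = cur + sc["gp0"] * rng.normal()
                th_new = thg + (prop_v - cur)
            else:
                cur = st["gp"][idx]
                prop_v = cur + sc["gp"][idx] * rng.normal()
                th_new = thg + (prop_v - cur) * data.Xw[:, idx]
            lp_new = normal_logpdf(st["g0"], th_new, sgam).sum()
            d = (
                lp_new
                - lp
                + normal_logpdf(prop_v, 0, spec.prior_loc_sd)
                - normal_logpdf(cur, 0, spec.prior_loc_sd)
            )
            acc_h = np.log(rng.uniform()) < d
            if acc_h:
                if idx is None:
                    st["gp0"] = prop_v
                else:
                    st["gp"][idx] = prop_v
                thg, lp = th_new, lp_new
            if adapt:
                if idx is None:
                    sc["gp0"] *= np.exp(g * (float(acc_h) - 0.44))
                else:
                    sc["gp"][idx] *= np.exp(g * (float(acc_h) - 0.44))
        cur = st["log_sgam"]
        prop_v = cur + sc["log_sgam"] * rng.normal()
        lp_new = normal_logpdf(st["g0"], thg, np.exp(prop_v)).sum()
        d = (
            lp_new
            - lp
            + half_cauchy_logpdf(np.exp(prop_v), spec.prior_scale)
            - half_cauchy_logpdf(np.exp(cur), spec.prior_scale)
            + (prop_v - cur)
        )
        acc_h = np.log(rng.uniform()) < d
        if acc_h:
            st["log_sgam"] = prop_v
        if adapt:
            sc["log_sgam"] *= np.exp(g * (float(acc_h) - 0.44))

        # eta
        for i in range(data.n_w):
            prop_e, log_h = _propose_eta(st["eta"][i], spec.eta_kappa, rng)
            if data.R_w[i] == 0:
                if np.log(rng.uniform()) < log_h:
                    st["eta"][i] = prop_e
                continue
            old_e = st["eta"][i]
            st["eta"][i] = prop_e
            rp_new = rp.copy()
            rp_new[data.members[i]] = prop_e[: len(data.members[i])] * data.R_w[i]
            rp_std_new = _release_pred(rp_new, spec.standardize_release)
            ll_new = ll_site(st, rp_std_new)
            d = ll_new.sum() - ll.sum() + log_h
            if np.log(rng.uniform()) < d:
                rp, rp_std, ll = rp_new, rp_std_new, ll_new
            else:
                st["eta"][i] = old_e

        if not adapt and (it - spec.n_warmup + 1) % spec.thin == 0 and k < n_keep:
            kept["gamma_richness"][chain, k] = st["gam"]
            kept["gamma0_richness"][chain, k] = st["g0"]
            kept["gamma_prime_richness"][chain, k] = np.concatenate(
                [[st["gp0"]], st["gp"]]
            )
            kept["sigma_gamma_richness"][chain, k] = np.exp(st["log_sgam"])
            kept["sigma_lambda"][chain, k] = np.exp(st["log_sig_lam"])
            for i, w in enumerate(data.watersheds):
                kept["eta_richness"][w][chain, k] = st["eta"][i]
            k += 1


def fit_release_models(
    site_summaries: pd.DataFrame,
    watershed_table: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> RegressionPosterior:
    """Fit the requested regressions jointly with the latent release split.

    ``site_summaries`` needs columns site, watershed, the predictors named
    in the ``RegressionSpec``, and the responses (``richness`` and/or
    ``mu``/``sd``);
    ``watershed_table`` needs watershed, ``R_w`` (average yearly release
    total) and the watershed predictors.  Zero-release watersheds keep
    their eta at the flat prior without destabilising the fit.
    """
    spec = spec or RegressionSpec()
    data = _RegressionData(site_summaries, watershed_table, spec)
    K = data.X.shape[1]
    n_keep = spec.n_iter // spec.thin
    coef_names = ["release"] + list(spec.site_predictors)

    kept: dict = {}
    if "joint" in spec.responses:
        if not data.has_joint:
            raise ValueError("site_summaries lacks mu/sd columns")
        for r in ("mu", "sd"):
            kept[f"gamma_{r}"] = np.zeros((spec.chains, n_keep, K + 1))
            kept[f"gamma0_{r}"] = np.zeros((spec.chains, n_keep, data.n_w))
            kept[f"gamma_prime_{r}"] = np.zeros((spec.chains, n_keep, 3))
            kept[f"sigma_gamma_{r}"] = np.zeros((spec.chains, n_keep))
        kept["omega_sd"] = np.zeros((spec.chains, n_keep, 2))
        kept["omega_rho"] = np.zeros((spec.chains, n_keep))
        kept["eta_joint"] = {
            w: np.zeros((spec.chains, n_keep, data.slots[i] ))
            for i, w in enumerate(data.watersheds)
        }
    if "richness" in spec.responses:
        if not hasattr(data, "richness"):
            raise ValueError("site_summaries lacks a richness column")
        kept["gamma_richness"] = np.zeros((spec.chains, n_keep, K + 1))
        kept["gamma0_richness"] = np.zeros((spec.chains, n_keep, data.n_w))
        kept["gamma_prime_richness"] = np.zeros((spec.chains, n_keep, 3))
        kept["sigma_gamma_richness"] = np.zeros((spec.chains, n_keep))
        kept["sigma_lambda"] = np.zeros((spec.chains, n_keep))
        kept["eta_richness"] = {
            w: np.zeros((spec.chains, n_keep, data.slots[i]))
            for i, w in enumerate(data.watersheds)
        }

    root = np.random.SeedSequence(spec.seed)
    for chain, ss in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(ss)
        if "joint" in spec.responses:
            _fit_joint(data, spec, kept, chain, rng)
        if "richness" in spec.responses:
            _fit_richness(data, spec, kept, chain, rng)

    diag = {
        k: v
        for k, v in kept.items()
        if isinstance(v, np.ndarray) and k.startswith(("gamma_", "sigma_", "omega_"))
        and "gamma0" not in k
    }
    summary = summarize_chains(diag)
    converged = max_rhat(summary) < R_HAT_THRESHOLD
    return RegressionPosterior(
        draws=kept,
        coef_names=coef_names,
        watersheds=data.watersheds,
        sites=data.sites,
        summary=summary,
        converged=converged,
    )
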