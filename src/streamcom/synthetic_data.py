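"""Synthetic monitoring datasets with known ground truth.

Emulates the structure of a long-term stream-fish monitoring design:
counts of an enhanced species (hatchery-supplemented) and of the pooled
unenhanced community at sites nested in watersheds, observed at irregular
1-3 year intervals over 1999-2019, with Poisson sampling over a measured
area, watershed-aggregated release records (fry / juvenile / smolt, in
million fish), and site- and watershed-level covariates.  Every fitting
module in the package can be exercised end-to-end on generator output, and
the generating parameters are stored for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .statespace_density import geometric_lag_weights

__all__ = [
    "GeneratorConfig",
    "MonitoringDataset",
    "RegressionDataset",
    "generate_statespace_data",
    "generate_regression_data",
    "generate_interaction_data",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic monitoring-data generator.

    Defaults mirror the study design being emulated: 31 watersheds, ~3
    sites each, years 1999-2019 observed at irregular 1-3 y gaps, sampling
    areas around 175 m^2, and spring fry releases up to 0.24 million fish
    per watershed-year with several release-free watersheds.
    """

    n_watersheds: int = 31
    sites_per_watershed: int = 3
    year_start: int = 1999
    year_end: int = 2019
    gap_probs: tuple = ((1, 0.5), (2, 0.3), (3, 0.2))
    mean_area: float = 175.0
    sd_area: float = 60.0

    # state-space truth (shared by both species groups)
    Q: int = 3
    tau: float = 0.6
    theta_xi: tuple = (-0.8, 0.5)
    sigma_xi: tuple = (0.2, 0.1)
    rho_xi: float = 0.0
    sigma_state: float = 0.3
    sigma_obs: float = 0.2
    theta_beta: float = 1.0
    sigma_beta: float = 0.3

    # release regime
    frac_zero_release: float = 0.25
    release_max: float = 0.24  # million fish (fry), per watershed-year
    release_jitter: float = 0.1
    juvenile_ratio: float = 0.09
    smolt_ratio: float = 0.41

    # regression truth (per response: richness, ln mean, ln SD)
    gamma1: dict = field(
        default_factory=lambda: {"richness": -0.2, "mu": -0.4, "sd": -0.1}
    )
    gamma_cov: dict = field(
        default_factory=lambda: {
            "richness": (0.1, 0.05, -0.05, 0.1, 0.05),
            "mu": (0.15, 0.1, -0.1, 0.1, 0.0),
            "sd": (0.1, 0.05, -0.05, 0.05, 0.0),
        }
    )
    gamma0: dict = field(
        default_factory=lambda: {"richness": 2.3, "mu": -1.6, "sd": -2.6}
    )
    gamma_prime: dict = field(
        default_factory=lambda: {
            "richness": (0.1, 0.05),
            "mu": (0.1, -0.05),
            "sd": (0.05, -0.05),
        }
    )
    sigma_gamma: float = 0.15
    sigma_lambda: float = 0.15
    omega_y_sd: tuple = (0.15, 0.15)
    omega_y_rho: float = 0.3

    # interaction truth (alpha' = r * alpha / K with theory-scale
    # alpha12 = 0.3, alpha21 = 0.6)
    n_species: int = 2
    n_years_interaction: int = 40
    r_interaction: tuple = (1.0, 1.0)
    alpha_interaction: tuple = ((0.5, 0.15), (0.3, 0.5))
    K_interaction: float = 2.0  # fish per m^2; alpha'_ii = r_i / K_i
    n_factors: int = 0
    sigma_pi: float = 0.3
    sigma_obs_interaction: float = 0.1
    area_interaction: float = 150.0

    seed: int = 0


@dataclass
class MonitoringDataset:
    """Long-format monitoring records plus covariates and optional truth."""

    counts: pd.DataFrame
    releases: pd.DataFrame
    site_covariates: pd.DataFrame
    watershed_covariates: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> None:
        c = self.counts
        if (c["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        obs = c.dropna(subset=["count"])
        if not np.allclose(obs["count"], np.round(obs["count"])):
            raise ValueError("counts must be integers")
        if (c["sampling_area"].dropna() <= 0).any():
            raise ValueError("sampling areas must be > 0")
        s2w = c.groupby("site")["watershed"].nunique()
        if (s2w > 1).any():
            bad = s2w[s2w > 1].index.tolist()
            raise ValueError(f"sites map to multiple watersheds: {bad}")
        known = set(self.site_covariates["site"])
        missing = set(c["site"]) - known
        if missing:
            raise ValueError(f"sites missing from site_covariates: {sorted(missing)}")
        wknown = set(self.watershed_covariates["watershed"])
        wmissing = set(c["watershed"]) - wknown
        if wmissing:
            raise ValueError(
                f"watersheds missing from watershed_covariates: {sorted(wmissing)}"
            )


@dataclass
class RegressionDataset:
    """Site-level responses and covariates for the release regression."""

    site_table: pd.DataFrame
    watershed_table: pd.DataFrame
    truth: dict | None = None


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _observation_years(cfg: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    """Irregular observation years: start in the first 1-3 years of the
    window, then gaps drawn from the configured categorical distribution."""
    gaps, probs = zip(*cfg.gap_probs)
    year = cfg.year_start + rng.integers(0, 3)
    years = []
    while year <= cfg.year_end:
        years.append(int(year))
        year += rng.choice(gaps, p=probs)
    return years


def _release_table(
    cfg: GeneratorConfig, rng: np.random.Generator, watersheds: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Constant-with-jitter yearly releases; a configured fraction of
    watersheds receives none (controls)."""
    n_zero = int(round(cfg.frac_zero_release * len(watersheds)))
    zero_ws = set(watersheds[:n_zero])
    base = {
        w: 0.0 if w in zero_ws else float(rng.uniform(0.2, 1.0) * cfg.release_max)
        for w in watersheds
    }
    rows = []
    years = range(cfg.year_start, cfg.year_end + 1)
    for w in watersheds:
        for y in years:
            jit = 1.0 + rng.uniform(-cfg.release_jitter, cfg.release_jitter)
            fry = base[w] * jit
            rows.append({"watershed": w, "year": y, "stage": "fry", "number": fry})
            rows.append(
                {
                    "watershed": w,
                    "year": y,
                    "stage": "juvenile",
                    "number": fry * cfg.juvenile_ratio,
                }
            )
            rows.append(
                {
                    "watershed": w,
                    "year": y,
                    "stage": "smolt",
                    "number": fry * cfg.smolt_ratio,
                }
            )
    return pd.DataFrame(rows), base


def _covariate_tables(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sites: list[str],
    site_ws: dict[str, str],
    n_obs: dict[str, int],
    watersheds: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    site_cov = pd.DataFrame(
        {
            "site": sites,
            "watershed": [site_ws[s] for s in sites],
            "watershed_area": np.exp(rng.normal(3.0, 1.0, len(sites))),
            "temperature": rng.normal(6.0, 1.5, len(sites)),
            "precipitation": rng.normal(1100.0, 200.0, len(sites)),
            "forest_fraction": rng.uniform(0.5, 1.0, len(sites)),
            "n_obs_years": [n_obs[s] for s in sites],
        }
    )
    ws_cov = pd.DataFrame(
        {
            "watershed": watersheds,
            "ocean_productivity": rng.normal(2.0, 0.5, len(watersheds)),
            "sd_elevation": rng.normal(200.0, 50.0, len(watersheds)),
        }
    )
    return site_cov, ws_cov


def _simulate_latent_logdensity(
    cfg: GeneratorConfig, rng: np.random.Generator, T: int, xi1: float, xi2: float
) -> np.ndarray:
    """Forward-simulate the geometric-lag AR log-density process."""
    w = geometric_lag_weights(cfg.tau, cfg.Q)
    m = xi1 / (1.0 - xi2) if xi2 < 1 else xi1
    u = np.empty(T)
    u[: cfg.Q] = m + rng.normal(0.0, cfg.sigma_state, cfg.Q)
    for t in range(cfg.Q, T):
        lagged = u[t - cfg.Q : t][::-1]  # lag 1 first
        u[t] = xi1 + xi2 * float(w @ lagged) + rng.normal(0.0, cfg.sigma_state)
    return u


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def generate_statespace_data(cfg: GeneratorConfig) -> MonitoringDataset:
    """Monitoring dataset drawn from the state-space generative model.

    Latent log-densities follow the geometric-lag AR process per site and
    species group; observed counts are Poisson with lognormal observation
    error, plus the fry term ``beta_s * Fry`` for the enhanced group; years
    between observations are retained as explicit missing records.
    """
    rng = np.random.default_rng(cfg.seed)
    years_all = list(range(cfg.year_start, cfg.year_end + 1))
    T = len(years_all)
    watersheds = [f"w{k:02d}" for k in range(cfg.n_watersheds)]
    releases, base = _release_table(cfg, rng, watersheds)
    fry = (
        releases[releases["stage"] == "fry"]
        .set_index(["watershed", "year"])["number"]
        .to_dict()
    )

    sx1, sx2 = cfg.sigma_xi
    cov = np.array(
        [
            [sx1**2, cfg.rho_xi * sx1 * sx2],
            [cfg.rho_xi * sx1 * sx2, sx2**2],
        ]
    )

    rows = []
    sites, site_ws, n_obs = [], {}, {}
    truth_sites = {}
    for w in watersheds:
        for j in range(cfg.sites_per_watershed):
            s = f"{w}_s{j}"
            sites.append(s)
            site_ws[s] = w
            obs_years = _observation_years(cfg, rng)
            n_obs[s] = len(obs_years)
            area = {
                y: max(20.0, rng.normal(cfg.mean_area, cfg.sd_area))
                for y in obs_years
            }
            site_truth = {}
            for group in ("enhanced", "unenhanced"):
                xi = rng.multivariate_normal(np.array(cfg.theta_xi), cov)
                u = _simulate_latent_logdensity(cfg, rng, T, xi[0], xi[1])
                beta = 0.0
                if group == "enhanced":
                    beta = -1.0
                    while beta < 0:
                        beta = rng.normal(cfg.theta_beta, cfg.sigma_beta)
                site_truth[group] = {
                    "xi1": xi[0],
                    "xi2": xi[1],
                    "beta": beta,
                    "log_density": u,
                }
                for y in years_all:
                    if y not in area:
                        rows.append(
                            {
                                "site": s,
                                "watershed": w,
                                "year": y,
                                "group": group,
                                "count": np.nan,
                                "sampling_area": np.nan,
                            }
                        )
                        continue
                    t = y - cfg.year_start
                    lam = np.exp(u[t] + rng.normal(0.0, cfg.sigma_obs))
                    if group == "enhanced":
                        lam = lam + beta * fry[(w, y)]
                    rows.append(
                        {
                            "site": s,
                            "watershed": w,
                            "year": y,
                            "group": group,
                            "count": float(rng.poisson(lam * area[y])),
                            "sampling_area": area[y],
                        }
                    )
            truth_sites[s] = site_truth

    counts = pd.DataFrame(rows)
    site_cov, ws_cov = _covariate_tables(
        cfg, rng, sites, site_ws, n_obs, watersheds
    )
    truth = {
        "config": asdict(cfg),
        "tau": cfg.tau,
        "theta_xi": list(cfg.theta_xi),
        "theta_beta": cfg.theta_beta,
        "sigma_state": cfg.sigma_state,
        "sigma_obs": cfg.sigma_obs,
        "base_release": base,
        "sites": truth_sites,
    }
    ds = MonitoringDataset(counts, releases, site_cov, ws_cov, truth)
    ds.validate()
    return ds


def generate_regression_data(cfg: GeneratorConfig) -> RegressionDataset:
    """Site-level responses drawn from the hierarchical regression model.

    Watershed intercepts follow the watershed-covariate hierarchy;
    (ln mean, ln SD) are bivariate normal with covariance ``Omega_y``;
    richness is Poisson with lognormal overdispersion.  The effective
    release ``R'_s = eta_{w,s} * R_w`` uses a true Dirichlet simplex per
    watershed (with one unsurveyed slot) and enters the linear predictors
    scaled by its cross-site SD, so the release coefficients are on the
    same standardized footing as the other predictors.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    watersheds = [f"w{k:02d}" for k in range(cfg.n_watersheds)]
    _, base = _release_table(cfg, rng, watersheds)
    R_w = {w: base[w] * (1.0 + cfg.juvenile_ratio + cfg.smolt_ratio) for w in watersheds}

    cov_names = [
        "log_watershed_area",
        "temperature",
        "precipitation",
        "forest_fraction",
        "n_obs_years",
    ]
    sites, site_ws = [], {}
    eta_true = {}
    for w in watersheds:
        for j in range(cfg.sites_per_watershed):
            s = f"{w}_s{j}"
            sites.append(s)
            site_ws[s] = w
        eta_true[w] = rng.dirichlet(np.ones(cfg.sites_per_watershed + 1))
    n = len(sites)

    x = rng.normal(0.0, 1.0, (n, len(cov_names)))  # already standardized
    xw = rng.normal(0.0, 1.0, (cfg.n_watersheds, 2))

    R_prime = np.array(
        [
            eta_true[site_ws[s]][int(s.split("_s")[1])] * R_w[site_ws[s]]
            for s in sites
        ]
    )
    sd_R = R_prime.std(ddof=1)
    R_std = R_prime / sd_R if sd_R > 0 else R_prime

    # watershed intercepts per response
    g0 = {}
    for resp in ("richness", "mu", "sd"):
        gp = cfg.gamma_prime[resp]
        theta_g = cfg.gamma0[resp] + xw @ np.array(gp)
        g0[resp] = theta_g + rng.normal(0.0, cfg.sigma_gamma, cfg.n_watersheds)
    widx = np.array([watersheds.index(site_ws[s]) for s in sites])

    def linpred(resp):
        return (
            g0[resp][widx]
            + cfg.gamma1[resp] * R_std
            + x @ np.array(cfg.gamma_cov[resp])
        )

    # joint (ln mu, ln sd)
    s1, s2 = cfg.omega_y_sd
    omega = np.array(
        [
            [s1**2, cfg.omega_y_rho * s1 * s2],
            [cfg.omega_y_rho * s1 * s2, s2**2],
        ]
    )
    theta = np.column_stack([linpred("mu"), linpred("sd")])
    ln_y = theta + rng.multivariate_normal(np.zeros(2), omega, n)

    lam_r = np.exp(linpred("richness") + rng.normal(0.0, cfg.sigma_lambda, n))
    richness = rng.poisson(lam_r)

    site_table = pd.DataFrame(
        {
            "site": sites,
            "watershed": [site_ws[s] for s in sites],
            "richness": richness,
            "mu": np.exp(ln_y[:, 0]),
            "sd": np.exp(ln_y[:, 1]),
            **{name: x[:, k] for k, name in enumerate(cov_names)},
        }
    )
    site_table["cv"] = site_table["sd"] / site_table["mu"]
    watershed_table = pd.DataFrame(
        {
            "watershed": watersheds,
            "R_w": [R_w[w] for w in watersheds],
            "ocean_productivity": xw[:, 0],
            "sd_elevation": xw[:, 1],
        }
    )
    truth = {
        "gamma1": dict(cfg.gamma1),
        "gamma_cov": {k: list(v) for k, v in cfg.gamma_cov.items()},
        "gamma0": dict(cfg.gamma0),
        "gamma_prime": {k: list(v) for k, v in cfg.gamma_prime.items()},
        "eta": {w: list(map(float, eta_true[w])) for w in watersheds},
        "R_prime": list(map(float, R_prime)),
        "sd_R_prime": float(sd_R),
        "gamma1_cv": cfg.gamma1["sd"] - cfg.gamma1["mu"],
    }
    return RegressionDataset(site_table, watershed_table, truth)


def generate_interaction_data(cfg: GeneratorConfig) -> MonitoringDataset:
    """Multi-species count series from the interaction-scale Ricker model.

    Latent log-densities follow
    ``ln n_{i,t+1} = ln n_{i,t} + r_i - sum_j alpha'_ij n_{j,t} + eps`` with
    factor-structured process noise (D latent factors plus independent
    residuals); counts are Poisson(density x area).  The configured truth
    must give a stable interior equilibrium (checked via the spectral
    radius of the Jacobian at ``n* = alpha'^{-1} r``).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    S = cfg.n_species
    T = cfg.n_years_interaction
    r = np.asarray(cfg.r_interaction, dtype=float)
    ap = np.asarray(cfg.alpha_interaction, dtype=float)
    if r.shape != (S,) or ap.shape != (S, S):
        raise ValueError("r_interaction / alpha_interaction shape mismatch")

    n_star = np.linalg.solve(ap, r)
    if np.any(n_star <= 0):
        raise ValueError("configured truth has no positive equilibrium")
    jac = np.eye(S) - ap * n_star[None, :]
    rho = np.max(np.abs(np.linalg.eigvals(jac)))
    if rho >= 1.0:
        raise ValueError(
            f"configured truth is dynamically unstable (spectral radius {rho:.3f})"
        )

    D = cfg.n_factors
    delta = rng.normal(0.0, 0.2, (D, S)) if D > 0 else np.zeros((0, S))
    u = np.empty((S, T))
    u[:, 0] = np.log(n_star) + rng.normal(0.0, 0.2, S)
    for t in range(1, T):
        eps = rng.normal(0.0, cfg.sigma_pi, S)
        if D > 0:
            eps = eps + rng.normal(0.0, 1.0, D) @ delta
        u[:, t] = u[:, t - 1] + r - ap @ np.exp(u[:, t - 1]) + eps

    years = list(range(cfg.year_start, cfg.year_start + T))
    rows = []
    for i in range(S):
        for t, y in enumerate(years):
            lam = np.exp(u[i, t] + rng.normal(0.0, cfg.sigma_obs_interaction))
            rows.append(
                {
                    "site": "site0",
                    "watershed": "w00",
                    "year": y,
                    "group": f"taxon{i}",
                    "count": float(rng.poisson(lam * cfg.area_interaction)),
                    "sampling_area": cfg.area_interaction,
                }
            )
    counts = pd.DataFrame(rows)
    alpha_theory = ap / np.diag(ap)[:, None]
    truth = {
        "r": list(map(float, r)),
        "alpha_prime": ap.tolist(),
        "alpha": alpha_theory.tolist(),
        "K": list(map(float, r / np.diag(ap))),
        "log_density": u.tolist(),
        "delta": delta.tolist(),
        "sigma_pi": cfg.sigma_pi,
        "sigma_obs": cfg.sigma_obs_interaction,
    }
    site_cov = pd.DataFrame(
        {
            "site": ["site0"],
            "watershed": ["w00"],
            "watershed_area": [20.0],
            "temperature": [6.0],
            "precipitation": [1100.0],
            "forest_fraction": [0.9],
            "n_obs_years": [T],
        }
    )
    ws_cov = pd.DataFrame(
        {"watershed": ["w00"], "ocean_productivity": [2.0], "sd_elevation": [200.0]}
    )
    releases = pd.DataFrame(columns=["watershed", "year", "stage", "number"])
    ds = MonitoringDataset(counts, releases, site_cov, ws_cov, truth)
    ds.validate()
    return ds
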