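"""Multilevel lognormal regression of identification thresholds.

Model
-----
Each retained threshold ``y`` (deg) for participant ``p`` in condition cell
``c`` is lognormal::

    y ~ LogNormal(eta, sigma)
    eta = x(c) @ beta + z(c) @ b_p
    b_p ~ Normal(0, diag(tau**2))

``x(c)`` is the fixed-effect dummy row: four location intercepts (no global
intercept), inward/outward flanker dummies, pre-cued/random design dummies,
and all two- and three-way interaction dummies (36 columns, full rank, so all
36 cell means are reachable).  ``z(c)`` is the observer-level row: intercept
plus the main-effect dummies.  The linear predictor lives on the natural-log
scale.

Priors: location intercepts N(1, 2); flanker main-effect dummies N(1, 0.5)
(flanked thresholds expected larger, inward and outward treated identically a
priori); every design dummy and interaction N(0, 1); each varying-effect SD
half-Cauchy(0, 10); residual SD half-Cauchy(0, 1).

Sampler
-------
Partially collapsed Gibbs.  Per sweep: (1) each scale parameter
(varying-effect SDs, residual SD) is updated by univariate slice sampling
against the *marginal* likelihood with the varying effects integrated out
(Woodbury identities reduce every participant block to 8 x 8 operations,
batched across participants) — this sidesteps the funnel geometry that makes
centred Gibbs mix poorly; (2) the fixed-effect vector is drawn from its
Gaussian conditional, again with varying effects marginalised, which removes
the soft trade-off between fixed intercepts and the mean of the random
intercepts; (3) the varying effects are redrawn from their conjugate Gaussian
conditional.  Chains are independent and seed-derived; R-hat and ESS come
from arviz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design_core import (
    DESIGNS,
    FLANKERS,
    LOCATIONS,
    RANDOM_EFFECTS,
    ConditionCell,
    enumerate_cells,
    random_effect_row,
)

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ModelData",
    "PosteriorDraws",
    "MCMC_PRESETS",
    "fixed_effect_names",
    "fixed_effect_row",
    "build_design_matrix",
    "prior_predictive",
    "fit",
    "bayes_r2",
    "save_draws",
    "load_draws",
]

_NONREF_LOCATIONS = LOCATIONS[1:]
_FLANKER_DUMMIES = FLANKERS[1:]   # inward, outward
_DESIGN_DUMMIES = DESIGNS[1:]     # precued, random


def _build_terms() -> list[tuple[str, float, float]]:
    """(name, prior mean, prior sd) for every fixed-effect column, in order."""
    terms: list[tuple[str, float, float]] = []
    for l in LOCATIONS:
        terms.append((f"loc_{l}", 1.0, 2.0))
    for f in _FLANKER_DUMMIES:
        terms.append((f"fl_{f}", 1.0, 0.5))
    for d in _DESIGN_DUMMIES:
        terms.append((f"des_{d}", 0.0, 1.0))
    for f in _FLANKER_DUMMIES:
        for d in _DESIGN_DUMMIES:
            terms.append((f"fl_{f}:des_{d}", 0.0, 1.0))
    for l in _NONREF_LOCATIONS:
        for f in _FLANKER_DUMMIES:
            terms.append((f"loc_{l}:fl_{f}", 0.0, 1.0))
    for l in _NONREF_LOCATIONS:
        for d in _DESIGN_DUMMIES:
            terms.append((f"loc_{l}:des_{d}", 0.0, 1.0))
    for l in _NONREF_LOCATIONS:
        for f in _FLANKER_DUMMIES:
            for d in _DESIGN_DUMMIES:
                terms.append((f"loc_{l}:fl_{f}:des_{d}", 0.0, 1.0))
    return terms


_TERMS = _build_terms()
N_FIXED = len(_TERMS)  # 36


def fixed_effect_names() -> list[str]:
    return [t[0] for t in _TERMS]


def fixed_effect_row(cell: ConditionCell) -> np.ndarray:
    """Dummy-coded fixed-effect row for one cell (36 columns)."""
    loc = {l: float(cell.location == l) for l in LOCATIONS}
    fl = {f: float(cell.flanker == f) for f in _FLANKER_DUMMIES}
    des = {d: float(cell.design == d) for d in _DESIGN_DUMMIES}
    row = []
    for l in LOCATIONS:
        row.append(loc[l])
    for f in _FLANKER_DUMMIES:
        row.append(fl[f])
    for d in _DESIGN_DUMMIES:
        row.append(des[d])
    for f in _FLANKER_DUMMIES:
        for d in _DESIGN_DUMMIES:
            row.append(fl[f] * des[d])
    for l in _NONREF_LOCATIONS:
        for f in _FLANKER_DUMMIES:
            row.append(loc[l] * fl[f])
    for l in _NONREF_LOCATIONS:
        for d in _DESIGN_DUMMIES:
            row.append(loc[l] * des[d])
    for l in _NONREF_LOCATIONS:
        for f in _FLANKER_DUMMIES:
            for d in _DESIGN_DUMMIES:
                row.append(loc[l] * fl[f] * des[d])
    return np.array(row)


_CELL_ROWS = {c: fixed_effect_row(c) for c in enumerate_cells()}


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; defaults are the analysis's stated priors."""

    location_mean: float = 1.0
    location_sd: float = 2.0
    flanker_mean: float = 1.0
    flanker_sd: float = 0.5
    other_mean: float = 0.0
    other_sd: float = 1.0
    random_effect_scale: float = 10.0   # half-Cauchy scale for varying-effect SDs
    residual_scale: float = 1.0         # half-Cauchy scale for residual SD

    def __post_init__(self) -> None:
        for name in ("location_sd", "flanker_sd", "other_sd",
                     "random_effect_scale", "residual_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def fixed_means(self) -> np.ndarray:
        out = []
        for name, _, _ in _TERMS:
            if name.startswith("loc_") and ":" not in name:
                out.append(self.location_mean)
            elif name.startswith("fl_") and ":" not in name:
                out.append(self.flanker_mean)
            else:
                out.append(self.other_mean)
        return np.array(out)

    def fixed_sds(self) -> np.ndarray:
        out = []
        for name, _, _ in _TERMS:
            if name.startswith("loc_") and ":" not in name:
                out.append(self.location_sd)
            elif name.startswith("fl_") and ":" not in name:
                out.append(self.flanker_sd)
            else:
                out.append(self.other_sd)
        return np.array(out)


@dataclass(frozen=True)
class ModelSpec:
    priors: PriorSpec = field(default_factory=PriorSpec)


@dataclass
class ModelData:
    """Model-ready dataset: one row per retained threshold."""

    y: np.ndarray                 # natural-log thresholds
    X: np.ndarray                 # (n, 36) fixed-effect dummies
    Z: np.ndarray                 # (n, 8) varying-effect dummies
    participant_index: np.ndarray
    participants: list[str]
    cells: list[ConditionCell]

    @property
    def n_rows(self) -> int:
        return len(self.y)


def build_design_matrix(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> ModelData:
    """Turn a (flag-filtered) threshold table into the model-ready dataset.

    Rows flagged ``excluded`` are dropped here; factor levels are validated
    against the canonical orderings.
    """
    del spec  # coding is fixed; spec reserved for future variants
    frame = table.copy()
    if "excluded" in frame.columns:
        frame = frame[~frame["excluded"].astype(bool)]
    if frame.empty:
        raise ValueError("no retained thresholds to model")
    cells = []
    for r in frame.itertuples(index=False):
        cells.append(ConditionCell(r.design, r.location, r.flanker))
    participants = sorted(frame["participant"].astype(str).unique())
    pmap = {p: i for i, p in enumerate(participants)}
    pidx = np.array([pmap[str(p)] for p in frame["participant"]])
    thr = frame["threshold_deg"].to_numpy(dtype=float)
    if np.any(thr <= 0):
        raise ValueError("thresholds must be strictly positive")
    X = np.stack([_CELL_ROWS[c] for c in cells])
    Z = np.stack([random_effect_row(c) for c in cells])
    return ModelData(
        y=np.log(thr),
        X=X,
        Z=Z,
        participant_index=pidx,
        participants=participants,
        cells=cells,
    )


# ---------------------------------------------------------------------------
# Prior predictive


def prior_predictive(
    spec: ModelSpec | None = None,
    n_draws: int = 50_000,
    rng: np.random.Generator | int | None = None,
    include_random: bool = False,
    hdi_mass: float = 0.75,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Simulate thresholds from the priors through the likelihood.

    Each draw picks a cell uniformly, draws the fixed effects and residual SD
    from their priors and one lognormal observation from the implied
    distribution.  Varying effects are excluded by default: their
    half-Cauchy(0, 10) scales make the unconditional prior predictive
    extremely heavy-tailed.  Returns (draws, HDI at ``hdi_mass``).
    """
    from .posterior_analysis import hdi  # local import avoids a module cycle

    spec = spec or ModelSpec()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pri = spec.priors
    cells = enumerate_cells()
    X36 = np.stack([_CELL_ROWS[c] for c in cells])
    which = rng.integers(0, len(cells), size=n_draws)
    beta = pri.fixed_means() + rng.standard_normal((n_draws, N_FIXED)) * pri.fixed_sds()
    eta = np.einsum("ij,ij->i", X36[which], beta)
    if include_random:
        Z36 = np.stack([random_effect_row(c) for c in cells])
        tau = np.abs(pri.random_effect_scale * rng.standard_cauchy((n_draws, len(RANDOM_EFFECTS))))
        b = rng.standard_normal((n_draws, len(RANDOM_EFFECTS))) * tau
        eta = eta + np.einsum("ij,ij->i", Z36[which], b)
    sigma = np.abs(pri.residual_scale * rng.standard_cauchy(n_draws))
    # the half-Cauchy scales give genuinely heavy tails; clip the log draws
    # to the finite float range so interval summaries stay well defined
    draws = np.exp(np.clip(eta + sigma * rng.standard_normal(n_draws), -700.0, 700.0))
    return draws, hdi(draws, hdi_mass)


# ---------------------------------------------------------------------------
# Gibbs sampler

MCMC_PRESETS: dict[str, dict] = {
    "smoke": {"chains": 2, "warmup": 500, "draws": 500},
    "paper": {"chains": 4, "warmup": 1000, "draws": 2000},
}


def _slice_sample(
    logf, x0: float, rng: np.random.Generator, w: float = 1.0, max_steps: int = 100
) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    logy = logf(x0) - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logf(right) > logy:
        right += w
        k -= 1
    for _ in range(1000):
        x1 = left + (right - left) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pragma: no cover - shrinkage failed to move; keep current point


@dataclass
class PosteriorDraws:
    """MCMC draws (chain x draw x ...) plus diagnostics and metadata."""

    beta: np.ndarray          # (chains, draws, 36)
    b: np.ndarray             # (chains, draws, participants, 8)
    tau: np.ndarray           # (chains, draws, 8)
    sigma: np.ndarray         # (chains, draws)
    fixed_names: list[str]
    random_names: list[str]
    participants: list[str]
    seed: int
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def flat_tau(self) -> np.ndarray:
        return self.tau.reshape(-1, self.tau.shape[-1])

    def flat_sigma(self) -> np.ndarray:
        return self.sigma.reshape(-1)

    def flat_b(self) -> np.ndarray:
        return self.b.reshape(-1, *self.b.shape[2:])

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior={
                "beta": self.beta,
                "tau": self.tau,
                "sigma": self.sigma,
            },
            coords={"fixed": self.fixed_names, "varying": self.random_names},
            dims={"beta": ["fixed"], "tau": ["varying"]},
        )


def _resolve_mcmc(mcmc) -> dict:
    if isinstance(mcmc, str):
        try:
            return dict(MCMC_PRESETS[mcmc])
        except KeyError:
            raise ValueError(
                f"unknown MCMC preset {mcmc!r}; choose from {sorted(MCMC_PRESETS)}"
            ) from None
    return dict(mcmc)


def fit(
    data: ModelData,
    spec: ModelSpec | None = None,
    mcmc: str | dict = "smoke",
    seed: int = 0,
    rhat_threshold: float = 1.01,
) -> PosteriorDraws:
    """Fit the multilevel lognormal model by blocked Gibbs sampling.

    ``mcmc`` is a preset name ("smoke": 2 chains x 500 post-warmup draws,
    "paper": 4 x 2000) or a dict with keys chains/warmup/draws.  Convergence
    is summarised by split R-hat over the fixed effects, varying-effect SDs
    and residual SD; values above ``rhat_threshold`` raise a warning, never a
    silent pass.  Deterministic given (data, seed, settings).
    """
    spec = spec or ModelSpec()
    settings = _resolve_mcmc(mcmc)
    chains, warmup, draws = settings["chains"], settings["warmup"], settings["draws"]
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")

    pri = spec.priors
    y, X, Z, pidx = data.y, data.X, data.Z, data.participant_index
    n, K = X.shape
    R = Z.shape[1]
    P = len(data.participants)

    prior_mean = pri.fixed_means()
    prior_prec = 1.0 / pri.fixed_sds() ** 2
    XtX = X.T @ X
    Xty = X.T @ y
    rows_of = [np.flatnonzero(pidx == p) for p in range(P)]
    Zp_list = [Z[rows] for rows in rows_of]
    n_p = np.array([len(rows) for rows in rows_of], dtype=float)
    ZtZ = np.stack([zp.T @ zp for zp in Zp_list])          # (P, R, R)
    XtZ = np.stack([X[rows].T @ zp for rows, zp in zip(rows_of, Zp_list)])  # (P, K, R)
    Zty = np.stack([zp.T @ y[rows] for rows, zp in zip(rows_of, Zp_list)])  # (P, R)
    eyeR = np.eye(R)

    def marginal_loglik(tau: np.ndarray, sigma: float, u: np.ndarray, s: np.ndarray) -> float:
        """Log p(y | beta, tau, sigma) with varying effects integrated out.

        ``u[p] = Z_p' r_p`` and ``s[p] = r_p' r_p`` for residuals
        ``r = y - X beta``.  Woodbury per participant:
        B_p = I + diag(tau) Z_p'Z_p diag(tau) / sigma^2, and
        r'Sigma^-1 r = s/sigma^2 - v' B^-1 v / sigma^4 with v = tau * u.
        """
        s2 = sigma * sigma
        tt = np.outer(tau, tau)
        B = eyeR + ZtZ * tt / s2                            # (P, R, R)
        sign, logdet = np.linalg.slogdet(B)
        if np.any(sign <= 0):  # pragma: no cover - B is PD by construction
            return -np.inf
        v = u * tau                                         # (P, R)
        Binv_v = np.linalg.solve(B, v[..., None])[..., 0]
        quad = s / s2 - np.einsum("pr,pr->p", v, Binv_v) / (s2 * s2)
        return float(-0.5 * np.sum(n_p * np.log(2.0 * np.pi * s2) + logdet + quad))

    beta_out = np.empty((chains, draws, K))
    b_out = np.empty((chains, draws, P, R))
    tau_out = np.empty((chains, draws, R))
    sigma_out = np.empty((chains, draws))

    re_scale2 = pri.random_effect_scale**2
    res_scale2 = pri.residual_scale**2

    for chain in range(chains):
        rng = np.random.default_rng([seed, chain])
        # Initialise at a ridge-regularised least-squares solution.
        beta = np.linalg.solve(XtX + np.eye(K) * 1e-6, Xty)
        tau = np.full(R, 0.2)
        sigma = float(max((y - X @ beta).std(), 0.05))
        b = np.zeros((P, R))

        for it in range(warmup + draws):
            # --- scales | beta, with varying effects marginalised ---
            r_all = y - X @ beta
            u = np.stack([zp.T @ r_all[rows] for zp, rows in zip(Zp_list, rows_of)])
            s = np.array([r_all[rows] @ r_all[rows] for rows in rows_of])

            for k in range(R):
                def logf_tau(theta, k=k):
                    t = tau.copy()
                    t[k] = np.exp(theta)
                    return (
                        marginal_loglik(t, sigma, u, s)
                        - np.log1p(t[k] ** 2 / re_scale2)
                        + theta
                    )

                theta = _slice_sample(logf_tau, np.log(max(tau[k], 1e-8)), rng)
                tau[k] = float(np.exp(theta))

            def logf_sigma(theta):
                sg = np.exp(theta)
                return (
                    marginal_loglik(tau, sg, u, s)
                    - np.log1p(sg**2 / res_scale2)
                    + theta
                )

            sigma = float(np.exp(_slice_sample(logf_sigma, np.log(sigma), rng, w=0.5)))

            # --- fixed effects | scales, varying effects marginalised ---
            # X' Sigma^-1 X = [X'X - sum_p G_p B_p^-1 G_p'] / sigma^2 with
            # G_p = X_p'Z_p diag(tau) / sigma, via the same Woodbury factors.
            s2 = sigma * sigma
            tt = np.outer(tau, tau)
            B = eyeR + ZtZ * tt / s2
            G = XtZ * tau[None, None, :]                    # (P, K, R)
            BinvGt = np.linalg.solve(B, np.swapaxes(G, 1, 2))  # (P, R, K)
            correction = np.einsum("pkr,prj->kj", G, BinvGt) / s2
            prec = (XtX - correction) / s2 + np.diag(prior_prec)
            vty = Zty * tau[None, :]
            Binv_vty = np.linalg.solve(B, vty[..., None])[..., 0]
            xsy = (Xty - np.einsum("pkr,pr->k", G, Binv_vty) / s2) / s2
            rhs = xsy + prior_mean * prior_prec
            cf = cho_factor(prec, lower=True)
            mean = cho_solve(cf, rhs)
            beta = mean + solve_triangular(cf[0].T, rng.standard_normal(K), lower=False)

            # --- varying effects | everything (conjugate) ---
            r_all = y - X @ beta
            tau_prec = 1.0 / np.maximum(tau, 1e-10) ** 2
            for p in range(P):
                Ap = ZtZ[p] / s2 + np.diag(tau_prec)
                rhsp = Zp_list[p].T @ r_all[rows_of[p]] / s2
                cfp = cho_factor(Ap, lower=True)
                meanp = cho_solve(cfp, rhsp)
                b[p] = meanp + solve_triangular(
                    cfp[0].T, rng.standard_normal(R), lower=False
                )

            if it >= warmup:
                d = it - warmup
                beta_out[chain, d] = beta
                b_out[chain, d] = b
                tau_out[chain, d] = tau
                sigma_out[chain, d] = sigma

    result = PosteriorDraws(
        beta=beta_out,
        b=b_out,
        tau=tau_out,
        sigma=sigma_out,
        fixed_names=fixed_effect_names(),
        random_names=list(RANDOM_EFFECTS),
        participants=list(data.participants),
        seed=seed,
    )
    idata = result.to_inference_data()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    for i, name in enumerate(result.fixed_names):
        result.rhat[f"beta[{name}]"] = float(rhat_ds["beta"].values[i])
        result.ess[f"beta[{name}]"] = float(ess_ds["beta"].values[i])
    for i, name in enumerate(result.random_names):
        result.rhat[f"tau[{name}]"] = float(rhat_ds["tau"].values[i])
        result.ess[f"tau[{name}]"] = float(ess_ds["tau"].values[i])
    result.rhat["sigma"] = float(rhat_ds["sigma"].values)
    result.ess["sigma"] = float(ess_ds["sigma"].values)
    worst = result.max_rhat()
    if np.isnan(worst) or worst > rhat_threshold:
        warnings.warn(
            f"convergence diagnostics exceed threshold: max R-hat = {worst:.4f} "
            f"(threshold {rhat_threshold}); consider more iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return result


def bayes_r2(draws: PosteriorDraws, data: ModelData) -> np.ndarray:
    """Per-draw Bayesian R-squared on the log scale.

    R2 = Var(linear predictor over rows) / (Var + sigma**2), with the
    varying effects included in the predictor.
    """
    beta = draws.flat_beta()
    b = draws.flat_b()
    sigma = draws.flat_sigma()
    eta_fixed = data.X @ beta.T                       # (n, ndraws)
    # row-wise varying-effect contribution per draw
    eta_rand = np.einsum("nr,dnr->nd", data.Z, b[:, data.participant_index, :])
    eta = eta_fixed + eta_rand
    var_eta = eta.var(axis=0)
    return var_eta / (var_eta + sigma**2)


# ---------------------------------------------------------------------------
# Persistence: npz of arrays + JSON sidecar of names


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        beta=draws.beta,
        b=draws.b,
        tau=draws.tau,
        sigma=draws.sigma,
    )
    meta = {
        "fixed_names": draws.fixed_names,
        "random_names": draws.random_names,
        "participants": draws.participants,
        "seed": draws.seed,
        "rhat": draws.rhat,
        "ess": draws.ess,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_draws(path: str | Path) -> PosteriorDraws:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return PosteriorDraws(
        beta=arrays["beta"],
        b=arrays["b"],
        tau=arrays["tau"],
        sigma=arrays["sigma"],
        fixed_names=meta["fixed_names"],
        random_names=meta["random_names"],
        participants=meta["participants"],
        seed=meta["seed"],
        rhat=meta["rhat"],
        ess=meta["ess"],
    )
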