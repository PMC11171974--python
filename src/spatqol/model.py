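"""Bayesian spatio-temporal multilevel logistic model with BYM area effects.

The outcome is a patient-level binary indicator (poor QoL); the linear
predictor is

    eta_i = alpha + x_i' beta + delta1 * t_i + delta2 * t_i^2
            + u_{j(i)} + v_{j(i)}

where x_i one-hot encodes categorical covariates against declared
reference levels, t_i is the centred calendar-year index, and the area
effects follow the Besag-York-Mollie decomposition: u is intrinsic CAR
(precision tau_u, sum-to-zero constrained) over the spatial weight
matrix, v is iid Normal(0, 1/tau_v). Fixed effects get Normal(0,
precision 0.725) priors — the precision giving the odds ratio a 95%
central prior range of (0.1, 10) — and the precisions get Gamma
hyperpriors.

Fitting is by an adaptive Metropolis-within-Gibbs sampler: Gaussian
random-walk updates for each fixed effect (Robbins-Monro step-size
adaptation during burn-in only, targeting ~20-50% acceptance), single-site
random-walk updates for each u_j and v_j (u updates are performed by graph
colour class, which is equivalent to sequential single-site updating
because areas in a colour class are conditionally independent), a
recentring of u to sum zero each sweep with the mean absorbed into alpha,
and conjugate Gibbs draws for tau_u and tau_v.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import norm

from spatqol import datasets
from spatqol.diagnostics import WaicAccumulator
from spatqol.weights import WeightMatrix


# ---------------------------------------------------------------------------
# Specifications


def _default_covariates() -> dict:
    """Final-model covariate set with reference levels."""
    return {
        "age_group": {"levels": list(datasets.COVARIATE_LEVELS["age_group"]), "ref": "<=55"},
        "nccn": {"levels": list(datasets.COVARIATE_LEVELS["nccn"]), "ref": "Low risk"},
        "psa": {"levels": list(datasets.COVARIATE_LEVELS["psa"]), "ref": "<=10"},
        "institution": {"levels": list(datasets.COVARIATE_LEVELS["institution"]), "ref": "Private"},
        "accessibility": {
            "levels": list(datasets.COVARIATE_LEVELS["accessibility"]),
            "ref": "Accessible",
        },
    }


@dataclass
class ModelSpec:
    covariates: dict = field(default_factory=_default_covariates)
    include_time: bool = True
    area_field: str = "area_id"
    year_field: str = "year"
    outcome_field: str = "poor_qol"
    years: tuple = (2015, 2021)

    def coefficient_names(self) -> list:
        names = []
        for cov, info in self.covariates.items():
            for level in info["levels"]:
                if level != info["ref"]:
                    names.append(f"{cov}[{level}]")
        return names


@dataclass
class PriorSpec:
    coef_mean: float = 0.0
    coef_precision: float = 0.725
    tau_u_prior: tuple = (0.5, 0.0005)  # Gamma(shape, rate)
    tau_v_prior: tuple = (0.5, 0.0005)

    def __post_init__(self):
        if self.coef_precision <= 0:
            raise ValueError("coef_precision must be positive")
        if min(self.tau_u_prior) <= 0 or min(self.tau_v_prior) <= 0:
            raise ValueError("Gamma hyperparameters must be positive")


@dataclass
class MCMCConfig:
    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 2
    n_chains: int = 2
    seeds: list | None = None
    adapt_until: int | None = None  # default: burn_in
    likelihood_weight: float = 1.0  # 0 -> prior-only sampling
    allow_isolated: bool = False
    tau_u_fixed: float | None = None
    tau_v_fixed: float | None = None
    store_loglik: str | bool = "auto"  # full matrix kept iff draws*n small
    accept_target: float = 0.35
    # debugging/validation hooks: hold the area effects at fixed values so
    # the tau Gibbs draws can be checked against their full conditionals
    freeze_u: object = None
    freeze_v: object = None

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seeds is not None and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("chain seeds must be distinct")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


def prior_precision_for_or_interval(low: float = 0.1, high: float = 10.0, mass: float = 0.95) -> float:
    """Normal precision on the log-odds scale giving the odds ratio a
    central prior interval (low, high) with the stated mass.

    For the symmetric default this is (z_{0.975}/ln 10)^2 ~= 0.7246, the
    0.725 used by PriorSpec.
    """
    from scipy.optimize import brentq

    lo, hi = np.log(low), np.log(high)

    def mass_at(sd):
        return norm.cdf(hi, scale=sd) - norm.cdf(lo, scale=sd) - mass

    sd = brentq(mass_at, 1e-6, 100.0)
    return 1.0 / sd**2


# ---------------------------------------------------------------------------
# Design and likelihood


@dataclass
class DesignData:
    y: np.ndarray
    X: np.ndarray  # n x p dummy design (no intercept, no time)
    colnames: list
    area_index: np.ndarray  # patient -> area position in W
    t: np.ndarray  # centred year index
    n_areas: int


def build_design(records: pd.DataFrame, spec: ModelSpec, W: WeightMatrix) -> DesignData:
    """One-hot design against reference levels + centred time + area index.

    Unknown covariate levels and areas missing from the weight matrix are
    reported by name rather than silently encoded.
    """
    y = records[spec.outcome_field].to_numpy()
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    y = y.astype(float)
    n = len(records)
    cols, names = [], []
    for cov, info in spec.covariates.items():
        vals = records[cov].astype(str).to_numpy()
        unknown = set(vals) - set(map(str, info["levels"]))
        if unknown:
            raise ValueError(f"covariate {cov!r}: unseen level(s) {sorted(unknown)}")
        for level in info["levels"]:
            if level == info["ref"]:
                continue
            cols.append((vals == str(level)).astype(float))
            names.append(f"{cov}[{level}]")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    try:
        area_index = np.array([W.index_of(a) for a in records[spec.area_field]], dtype=int)
    except KeyError as e:
        raise ValueError(f"area {e} not present in the weight matrix") from e
    if spec.include_time:
        mid = (spec.years[0] + spec.years[1]) / 2.0
        t = records[spec.year_field].to_numpy(dtype=float) - mid
    else:
        t = np.zeros(n)
    return DesignData(y=y, X=X, colnames=names, area_index=area_index, t=t, n_areas=W.n)


def log_likelihood(y, eta):
    """Bernoulli log-likelihood under the logit link.

    Returns (total, pointwise) with the numerically stable form
    y*eta - log(1 + exp(eta)) evaluated via logaddexp.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    pointwise = y * eta - np.logaddexp(0.0, eta)
    return float(pointwise.sum()), pointwise


def car_log_kernel(u, W: WeightMatrix, tau_u: float) -> float:
    """Log kernel of the intrinsic CAR prior (improper, rank-deficient):

        ((n - c)/2) log tau_u - (tau_u/2) * sum_{j<k} w_jk (u_j - u_k)^2

    with c the number of connected components. The pairwise sum equals the
    Laplacian quadratic form u'(D - W)u.
    """
    u = np.asarray(u, dtype=float)
    A = W.to_sparse()
    if (A != A.T).nnz != 0:
        raise ValueError("CAR kernel requires a symmetric weight matrix")
    ncomp, _ = W.components()
    quad = float(u @ (W.neighbour_counts() * u) - u @ (A @ u))
    return 0.5 * (W.n - ncomp) * np.log(tau_u) - 0.5 * tau_u * quad


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class ChainDraws:
    params: dict  # name -> (n_retained,) array; "u","v" -> (n_retained, J)
    acceptance: dict
    seed_entropy: object
    loglik_matrix: np.ndarray | None
    waic_acc: WaicAccumulator


@dataclass
class PosteriorDraws:
    chains: list
    colnames: list
    config: MCMCConfig
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def parameter_names(self) -> list:
        return [k for k in self.chains[0].params if k not in ("u", "v")]

    def stacked(self, name) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return np.concatenate([c.params[name] for c in self.chains], axis=0)

    def per_chain(self, name) -> list:
        return [c.params[name] for c in self.chains]

    def loglik_matrix(self) -> np.ndarray:
        mats = [c.loglik_matrix for c in self.chains]
        if any(m is None for m in mats):
            raise ValueError("full pointwise log-likelihood matrix was not stored")
        return np.concatenate(mats, axis=0)

    def waic_accumulator(self) -> WaicAccumulator:
        acc = self.chains[0].waic_acc
        for c in self.chains[1:]:
            acc = acc.merged(c.waic_acc)
        return acc


def posterior_summaries(draws: PosteriorDraws, include_reference: bool = True) -> pd.DataFrame:
    """Odds-ratio table: OR = exp(posterior median), 95% CrI = exp of the
    2.5/97.5 empirical quantiles, per coefficient; reference levels are
    reported with OR 1 when the model spec is attached."""
    rows = []
    if include_reference and draws.spec is not None:
        ref_of = {cov: info["ref"] for cov, info in draws.spec.covariates.items()}
    else:
        ref_of = {}
    seen_cov = set()
    for name in draws.colnames:
        cov = name.split("[")[0]
        if cov not in seen_cov and cov in ref_of:
            rows.append(
                {"coefficient": f"{cov}[{ref_of[cov]}]", "mean_logodds": 0.0,
                 "or": 1.0, "or_lo": 1.0, "or_hi": 1.0, "reference": True}
            )
            seen_cov.add(cov)
        b = draws.stacked(name)
        lo, med, hi = np.quantile(b, [0.025, 0.5, 0.975])
        rows.append(
            {"coefficient": name, "mean_logodds": float(b.mean()),
             "or": float(np.exp(med)), "or_lo": float(np.exp(lo)),
             "or_hi": float(np.exp(hi)), "reference": False}
        )
    for extra in ("alpha", "delta1", "delta2"):
        if extra in draws.chains[0].params:
            b = draws.stacked(extra)
            lo, med, hi = np.quantile(b, [0.025, 0.5, 0.975])
            rows.append(
                {"coefficient": extra, "mean_logodds": float(b.mean()),
                 "or": float(np.exp(med)), "or_lo": float(np.exp(lo)),
                 "or_hi": float(np.exp(hi)), "reference": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sampler internals


def _greedy_colouring(W: WeightMatrix) -> list:
    """Greedy vertex colouring; returns a list of index arrays (colour
    classes). Areas within a class share no edge, so their single-site
    conditionals are mutually independent."""
    n = W.n
    colour = np.full(n, -1, dtype=int)
    order = np.argsort(-W.neighbour_counts(), kind="stable")
    for j in order:
        used = {colour[k] for k in W.neighbours[j] if colour[k] >= 0}
        c = 0
        while c in used:
            c += 1
        colour[j] = c
    return [np.flatnonzero(colour == c) for c in range(colour.max() + 1)]


def _softplus(x):
    return np.logaddexp(0.0, x)


class _AreaLayout:
    """Patients regrouped by area for fast per-area likelihood deltas."""

    def __init__(self, area_index: np.ndarray, n_areas: int):
        self.order = np.argsort(area_index, kind="stable")
        sorted_areas = area_index[self.order]
        self.starts = np.searchsorted(sorted_areas, np.arange(n_areas + 1))

    def class_view(self, areas: np.ndarray):
        """(patient indices, reduceat boundaries, per-patient segment map)
        for a set of areas."""
        counts = self.starts[areas + 1] - self.starts[areas]
        idx = np.concatenate(
            [self.order[self.starts[j]:self.starts[j + 1]] for j in areas]
        ) if len(areas) else np.empty(0, dtype=int)
        bounds = np.concatenate([[0], np.cumsum(counts)[:-1]])
        seg = np.repeat(np.arange(len(areas)), counts)
        return idx, bounds, seg, counts


class _RWBlock:
    """Scalar random-walk Metropolis block with Robbins-Monro adaptation."""

    def __init__(self, support, xvals, prior_prec, step=0.1, target=0.35):
        self.support = support
        self.x = xvals
        self.prior_prec = prior_prec
        self.log_step = np.log(step)
        self.target = target
        self.n_prop = 0
        self.n_acc = 0

    def step_size(self):
        return np.exp(self.log_step)

    def adapt(self, accepted: bool, it: int):
        gamma = (it + 1) ** -0.6
        self.log_step += gamma * ((1.0 if accepted else 0.0) - self.target)


def run_mcmc(
    data: DesignData,
    W: WeightMatrix,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    spec: ModelSpec | None = None,
    base_seed: int = 0,
) -> PosteriorDraws:
    """Fit the BYM spatio-temporal logistic model by Metropolis-within-Gibbs.

    Deterministic given the chain seeds (``config.seeds`` or seeds derived
    from ``base_seed``). Refuses weight matrices with isolated areas
    unless ``config.allow_isolated`` — an island has no CAR neighbours and
    its u_j is unidentified beyond the prior.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if W.isolated() and not config.allow_isolated:
        raise ValueError(
            f"weight matrix has isolated areas {W.isolated()}; pass "
            "allow_isolated=True to fit anyway"
        )
    seeds = config.seeds
    if seeds is None:
        seeds = list(np.random.SeedSequence(base_seed).spawn(config.n_chains))
    elif len(seeds) != config.n_chains:
        raise ValueError("need one seed per chain")

    chains = [
        _run_single_chain(data, W, priors, config, seed, chain_id=c)
        for c, seed in enumerate(seeds)
    ]
    return PosteriorDraws(chains=chains, colnames=list(data.colnames), config=config, spec=spec)


def _run_single_chain(data, W, priors, config, seed, chain_id) -> ChainDraws:
    rng = np.random.default_rng(seed)
    y, X, t = data.y, data.X, data.t
    n, p = X.shape
    J = data.n_areas
    area_index = data.area_index
    lw = config.likelihood_weight
    kappa = priors.coef_precision
    adapt_until = config.adapt_until if config.adapt_until is not None else config.burn_in

    # --- initial state: chain 0 at crude estimates, later chains perturbed
    ybar = min(max(y.mean(), 1e-3), 1 - 1e-3)
    alpha = float(logit(ybar))
    beta = np.zeros(p)
    d1 = d2 = 0.0
    u = np.zeros(J) if config.freeze_u is None else np.asarray(config.freeze_u, dtype=float).copy()
    v = np.zeros(J) if config.freeze_v is None else np.asarray(config.freeze_v, dtype=float).copy()
    tau_u = config.tau_u_fixed if config.tau_u_fixed is not None else 1.0
    tau_v = config.tau_v_fixed if config.tau_v_fixed is not None else 1.0
    if chain_id > 0:
        alpha += 0.5 * chain_id
        beta = beta + 0.5 * chain_id
        if config.tau_u_fixed is None:
            tau_u = 10.0
        if config.tau_v_fixed is None:
            tau_v = 10.0

    # --- fixed-effect blocks
    all_idx = np.arange(n)
    blocks = {"alpha": _RWBlock(all_idx, np.ones(n), kappa, target=config.accept_target)}
    for k, name in enumerate(data.colnames):
        supp = np.flatnonzero(X[:, k] != 0)
        blocks[name] = _RWBlock(supp, X[supp, k], kappa, target=config.accept_target)
    include_time = np.any(t != 0)
    if include_time:
        s1 = np.flatnonzero(t != 0)
        blocks["delta1"] = _RWBlock(s1, t[s1], kappa, target=config.accept_target)
        blocks["delta2"] = _RWBlock(s1, t[s1] ** 2, kappa, target=config.accept_target)
    for b in blocks.values():
        b.yx = float(y[b.support] @ b.x)

    # Blocks whose design column is constant within areas (area-level
    # covariates, and the intercept) are confounded with v: a change in the
    # coefficient can be absorbed by the v_j of the affected areas. For
    # those, an additional eta-invariant "shift" move proposes
    # beta -> beta + delta, v_j -> v_j - delta on the affected areas; the
    # likelihood cancels so acceptance depends on the priors alone. This
    # move is what keeps area-level coefficients mixing.
    patients_per_area = np.bincount(area_index, minlength=J)
    shift_blocks = {}
    for name, blk in blocks.items():
        if name in ("delta1", "delta2"):
            continue
        if name == "alpha":
            shift_blocks[name] = np.arange(J)
            continue
        col = np.zeros(n)
        col[blk.support] = blk.x
        if not np.isin(col, [0.0, 1.0]).all():
            continue
        on = np.bincount(area_index, weights=col, minlength=J)
        frac = np.divide(on, patients_per_area, out=np.zeros(J), where=patients_per_area > 0)
        if np.isin(frac[patients_per_area > 0], [0.0, 1.0]).all():
            shift_blocks[name] = np.flatnonzero((frac == 1.0) & (patients_per_area > 0))
    shift_steps = dict.fromkeys(shift_blocks, np.log(0.25))
    shift_acc = dict.fromkeys(shift_blocks, 0)

    # --- area machinery
    layout = _AreaLayout(area_index, J)
    colour_classes = _greedy_colouring(W)
    class_views = [layout.class_view(c) for c in colour_classes]
    all_areas = np.arange(J)
    full_view = layout.class_view(all_areas)
    A = W.to_sparse()
    deg = W.neighbour_counts().astype(float)
    ncomp, _ = W.components()
    a_u, b_u = priors.tau_u_prior
    a_v, b_v = priors.tau_v_prior

    log_step_u = np.full(J, np.log(0.5))
    log_step_v = np.full(J, np.log(0.5))
    acc_u = np.zeros(J)
    acc_v = np.zeros(J)
    n_sweeps = 0

    beta_state = {"alpha": alpha, "delta1": d1, "delta2": d2}
    coef = dict.fromkeys(data.colnames, 0.0)
    if chain_id > 0:
        coef = dict.fromkeys(data.colnames, 0.5 * chain_id)
    beta_state.update(coef)

    def current_eta():
        eta = np.full(n, beta_state["alpha"])
        for k, name in enumerate(data.colnames):
            if beta_state[name] != 0.0:
                eta += beta_state[name] * X[:, k]
        if include_time:
            eta += beta_state["delta1"] * t + beta_state["delta2"] * t**2
        return eta + u[area_index] + v[area_index]

    eta = current_eta()
    if not np.isfinite(eta).all():
        raise FloatingPointError(
            "non-finite posterior at initialization; use weaker starting values"
        )

    # --- retention
    n_ret = config.n_retained
    store = {name: np.empty(n_ret) for name in blocks}
    store["tau_u"] = np.empty(n_ret)
    store["tau_v"] = np.empty(n_ret)
    store_u = np.empty((n_ret, J))
    store_v = np.empty((n_ret, J))
    if config.store_loglik == "auto":
        keep_full = n_ret * n <= 2_000_000
    else:
        keep_full = bool(config.store_loglik)
    llmat = np.empty((n_ret, n)) if keep_full else None
    waic_acc = WaicAccumulator(n)
    ret = 0

    for it in range(config.n_iter):
        adapting = it < adapt_until
        # ---- fixed effects, sequential scalar RW Metropolis
        for name, blk in blocks.items():
            theta = beta_state[name]
            prop = theta + blk.step_size() * rng.standard_normal()
            diff = prop - theta
            s = blk.support
            if lw != 0.0:
                d_eta = diff * blk.x
                eta_s = eta[s]
                d_ll = diff * blk.yx - float(
                    (_softplus(eta_s + d_eta) - _softplus(eta_s)).sum()
                )
            else:
                d_ll = 0.0
            d_lp = -0.5 * kappa * (prop**2 - theta**2)
            accept = np.log(rng.random()) < lw * d_ll + d_lp
            blk.n_prop += 1
            if accept:
                beta_state[name] = prop
                if lw != 0.0:
                    eta[s] = eta_s + d_eta
                else:
                    eta[s] += diff * blk.x
                blk.n_acc += 1
            if adapting:
                blk.adapt(accept, it)

        # ---- structured effects u, by colour class
        u_classes = [] if config.freeze_u is not None else list(zip(colour_classes, class_views))
        for areas_c, (pidx, bounds, seg, counts) in u_classes:
            z = rng.standard_normal(len(areas_c))
            unif = rng.random(len(areas_c))
            delta = np.exp(log_step_u[areas_c]) * z
            Wu = A @ u
            uj = u[areas_c]
            upj = uj + delta
            d_prior = -0.5 * tau_u * (
                deg[areas_c] * (upj**2 - uj**2) - 2.0 * delta * Wu[areas_c]
            )
            if lw != 0.0 and len(pidx):
                d_eta = delta[seg]
                eta_p = eta[pidx]
                d_ll_p = y[pidx] * d_eta - (_softplus(eta_p + d_eta) - _softplus(eta_p))
                d_ll = np.add.reduceat(d_ll_p, bounds)
                d_ll[counts == 0] = 0.0
            else:
                d_ll = np.zeros(len(areas_c))
            acc = np.log(unif) < lw * d_ll + d_prior
            u[areas_c[acc]] = upj[acc]
            if lw != 0.0 and len(pidx):
                acc_p = acc[seg]
                eta[pidx[acc_p]] += d_eta[acc_p]
            if adapting:
                gamma = (it + 1) ** -0.6
                log_step_u[areas_c] += gamma * (acc.astype(float) - config.accept_target)
            acc_u[areas_c] += acc

        if config.freeze_u is None:
            # recentre u to sum zero; absorb the mean into alpha (eta unchanged)
            m = u.mean()
            u -= m
            beta_state["alpha"] += m

        # ---- unstructured effects v, all areas at once (iid prior)
        if config.freeze_v is None:
            pidx, bounds, seg, counts = full_view
            z = rng.standard_normal(J)
            unif = rng.random(J)
            delta = np.exp(log_step_v) * z
            vp = v + delta
            d_prior = -0.5 * tau_v * (vp**2 - v**2)
            if lw != 0.0:
                d_eta = delta[seg]
                eta_p = eta[pidx]
                d_ll_p = y[pidx] * d_eta - (_softplus(eta_p + d_eta) - _softplus(eta_p))
                d_ll = np.add.reduceat(d_ll_p, bounds)
                d_ll[counts == 0] = 0.0
            else:
                d_ll = np.zeros(J)
            acc = np.log(unif) < lw * d_ll + d_prior
            v[acc] = vp[acc]
            if lw != 0.0:
                acc_p = acc[seg]
                eta[pidx[acc_p]] += d_eta[acc_p]
            if adapting:
                gamma = (it + 1) ** -0.6
                log_step_v += gamma * (acc.astype(float) - config.accept_target)
            acc_v += acc
        n_sweeps += 1

        # ---- eta-invariant shift moves for area-level coefficients
        if config.freeze_v is None:
            for name, g in shift_blocks.items():
                delta = np.exp(shift_steps[name]) * rng.standard_normal()
                theta = beta_state[name]
                vg = v[g]
                d_lp = -0.5 * kappa * ((theta + delta) ** 2 - theta**2)
                d_lp += -0.5 * tau_v * float(((vg - delta) ** 2 - vg**2).sum())
                accept = np.log(rng.random()) < d_lp
                if accept:
                    beta_state[name] = theta + delta
                    v[g] = vg - delta
                    shift_acc[name] += 1
                if adapting:
                    shift_steps[name] += (it + 1) ** -0.6 * (
                        (1.0 if accept else 0.0) - config.accept_target
                    )

        # ---- precisions, conjugate Gibbs
        quad_u = float(u @ (deg * u) - u @ (A @ u))
        if config.tau_u_fixed is None:
            tau_u = rng.gamma(a_u + 0.5 * (J - ncomp), 1.0 / (b_u + 0.5 * quad_u))
        if config.tau_v_fixed is None:
            tau_v = rng.gamma(a_v + 0.5 * J, 1.0 / (b_v + 0.5 * float(v @ v)))

        # ---- retain
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for name in blocks:
                store[name][ret] = beta_state[name]
            store["tau_u"][ret] = tau_u
            store["tau_v"][ret] = tau_v
            store_u[ret] = u
            store_v[ret] = v
            pointwise = y * eta - _softplus(eta)
            if llmat is not None:
                llmat[ret] = pointwise
            waic_acc.update(pointwise)
            ret += 1

    params = {name: arr for name, arr in store.items()}
    params["u"] = store_u
    params["v"] = store_v
    acceptance = {name: blk.n_acc / max(blk.n_prop, 1) for name, blk in blocks.items()}
    acceptance["u"] = float(acc_u.mean() / max(n_sweeps, 1))
    acceptance["v"] = float(acc_v.mean() / max(n_sweeps, 1))
    for name, cnt in shift_acc.items():
        acceptance[f"shift:{name}"] = cnt / max(n_sweeps, 1)
    return ChainDraws(
        params=params,
        acceptance=acceptance,
        seed_entropy=getattr(seed, "entropy", seed),
        loglik_matrix=llmat,
        waic_acc=waic_acc,
    )


def fit_model(
    records: pd.DataFrame,
    W: WeightMatrix,
    spec: ModelSpec | None = None,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    base_seed: int = 0,
) -> PosteriorDraws:
    """Convenience wrapper: build the design from a patient table and run
    the sampler."""
    spec = spec or ModelSpec()
    data = build_design(records, spec, W)
    return run_mcmc(data, W, priors=priors, config=config, spec=spec, base_seed=base_seed)
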