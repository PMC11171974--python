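"""MCMC convergence assessment and model comparison.

Convergence uses the Gelman-Rubin potential scale reduction factor (the
classic R-hat: pooled-vs-within chain variance, without the
Brooks-Gelman degrees-of-freedom correction); values near 1 indicate that
multiple chains agree. Model comparison uses WAIC,
-2(lppd - p_waic), computed from the pointwise log-likelihood over
patients; lower is better. Because a full draws-by-patients matrix is
large at production MCMC sizes, WAIC can also be accumulated streaming
(running log-sum-exp for lppd, Welford variance for p_waic) as draws are
retained; both routes give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PSRFResult:
    psrf: float
    between: float  # B: n_ret * variance of chain means
    within: float  # W: mean within-chain sample variance
    n_ret: int


@dataclass
class WAICReport:
    lppd: float
    p_waic: float
    waic: float
    pointwise: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {"lppd": self.lppd, "p_waic": self.p_waic, "waic": self.waic}


def gelman_rubin(chains) -> PSRFResult:
    """Potential scale reduction factor for one parameter.

    ``chains``: >= 2 equal-length draw vectors. W is the mean within-chain
    sample variance, B = n * var(chain means), and

        PSRF = sqrt( ((n-1)/n * W + B/n) / W ).
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n = len(arrs[0])
    if n < 2 or any(len(a) != n for a in arrs):
        raise ValueError("chains must have equal length >= 2")
    within = float(np.mean([a.var(ddof=1) for a in arrs]))
    means = np.array([a.mean() for a in arrs])
    between = n * float(means.var(ddof=1))
    if within == 0.0:
        # degenerate constant chains: pooled variance equals within
        return PSRFResult(psrf=1.0, between=between, within=within, n_ret=n)
    var_plus = (n - 1) / n * within + between / n
    return PSRFResult(psrf=float(np.sqrt(var_plus / within)), between=between, within=within, n_ret=n)


def psrf_report(draws, parameters=None) -> pd.DataFrame:
    """PSRF table for (by default) all scalar parameters of a fit."""
    if parameters is None:
        parameters = draws.parameter_names()
    rows = []
    for name in parameters:
        res = gelman_rubin(draws.per_chain(name))
        rows.append(
            {"parameter": name, "psrf": res.psrf, "between": res.between,
             "within": res.within, "n_ret": res.n_ret}
        )
    return pd.DataFrame(rows)


class WaicAccumulator:
    """Streaming per-patient accumulator for WAIC.

    Tracks, for each patient, a running log-sum-exp of the pointwise
    log-likelihood across draws (for lppd) and a Welford mean/M2 (for the
    sample variance giving p_waic).
    """

    def __init__(self, n_points: int):
        self.n_points = n_points
        self.count = 0
        self._max = np.full(n_points, -np.inf)
        self._sumexp = np.zeros(n_points)
        self._mean = np.zeros(n_points)
        self._m2 = np.zeros(n_points)

    def update(self, pointwise_loglik):
        ll = np.asarray(pointwise_loglik, dtype=float)
        if ll.shape != (self.n_points,):
            raise ValueError("pointwise log-likelihood has wrong length")
        new_max = np.maximum(self._max, ll)
        with np.errstate(invalid="ignore"):
            scale = np.where(np.isfinite(self._max), np.exp(self._max - new_max), 0.0)
        self._sumexp = self._sumexp * scale + np.exp(ll - new_max)
        self._max = new_max
        self.count += 1
        delta = ll - self._mean
        self._mean += delta / self.count
        self._m2 += delta * (ll - self._mean)

    def merged(self, other: "WaicAccumulator") -> "WaicAccumulator":
        if other.n_points != self.n_points:
            raise ValueError("accumulators cover different numbers of patients")
        out = WaicAccumulator(self.n_points)
        out.count = self.count + other.count
        out._max = np.maximum(self._max, other._max)
        out._sumexp = self._sumexp * np.exp(self._max - out._max) + other._sumexp * np.exp(
            other._max - out._max
        )
        # Chan et al. parallel variance combination
        delta = other._mean - self._mean
        out._mean = self._mean + delta * other.count / out.count
        out._m2 = self._m2 + other._m2 + delta**2 * self.count * other.count / out.count
        return out

    def report(self) -> WAICReport:
        if self.count < 1:
            raise ValueError("no draws accumulated")
        if not np.isfinite(self._max).all():
            bad = int(np.flatnonzero(~np.isfinite(self._max))[0])
            raise ValueError(f"patient {bad}: log-likelihood is -inf in every draw")
        lppd_i = self._max + np.log(self._sumexp) - np.log(self.count)
        var_i = self._m2 / (self.count - 1) if self.count > 1 else np.zeros(self.n_points)
        lppd = float(lppd_i.sum())
        p_waic = float(var_i.sum())
        pw = pd.DataFrame({"lppd_i": lppd_i, "p_waic_i": var_i})
        return WAICReport(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic), pointwise=pw)


def waic(pointwise_loglik) -> WAICReport:
    """WAIC from a draws x patients pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(ll_si) (log-sum-exp stabilised); p_waic_i is
    the (s-1)-denominator sample variance of ll_si over draws.
    """
    ll = np.atleast_2d(np.asarray(pointwise_loglik, dtype=float))
    if ll.size == 0:
        raise ValueError("empty log-likelihood matrix")
    allneg = np.isneginf(ll).all(axis=0)
    if allneg.any():
        raise ValueError(
            f"patient {int(np.flatnonzero(allneg)[0])}: log-likelihood is -inf in every draw"
        )
    if not np.isfinite(ll[~np.isneginf(ll)]).all():
        raise ValueError("non-finite entries in the log-likelihood matrix")
    s = ll.shape[0]
    m = ll.max(axis=0)
    lppd_i = m + np.log(np.exp(ll - m).sum(axis=0)) - np.log(s)
    var_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    lppd = float(lppd_i.sum())
    p_waic = float(var_i.sum())
    pw = pd.DataFrame({"lppd_i": lppd_i, "p_waic_i": var_i})
    return WAICReport(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic), pointwise=pw)


def compare_models(reports) -> pd.DataFrame:
    """Rank (label, WAICReport) pairs by ascending WAIC with deltas
    against the best; ties keep the input label order."""
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    for label, rep in reports:
        if hasattr(rep, "waic"):
            rows.append({"label": label, "waic": rep.waic, "lppd": rep.lppd, "p_waic": rep.p_waic})
        else:  # bare WAIC value
            rows.append({"label": label, "waic": float(rep), "lppd": np.nan, "p_waic": np.nan})
    df = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    return df
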