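"""Post-model outputs: spatial fraction, relative-risk tables,
weight-matrix sensitivity, and descriptive prevalence crosstabs.

The spatial fraction phi = var(u) / (var(u) + var(v)) measures the share
of the area-level variation attributable to spatially structured (rather
than unstructured) heterogeneity. Relative risks are raw observed /
expected poor-QoL counts per area and year, with the expectation
standardised to the pooled cohort prevalence so the table is calibrated
(sum of observed equals sum of expected) and temporal variation stays
visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass
class SpatialFraction:
    var_u: float
    var_v: float

    def __post_init__(self):
        if self.var_u < 0 or self.var_v < 0:
            raise ValueError("variance components must be nonnegative")
        if self.var_u + self.var_v == 0:
            raise ValueError("zero total area-level variance; phi undefined")

    @property
    def phi(self) -> float:
        return self.var_u / (self.var_u + self.var_v)


def phi_statistic(u_draws, v_draws=None) -> SpatialFraction:
    """Spatial fraction phi = var(u)/(var(u)+var(v)).

    Called either with posterior draw matrices (draws x areas) for u and
    v — var(u), var(v) are then posterior means of the per-draw
    across-area empirical variances ((J-1) denominator) — or with two
    scalar variance components directly.
    """
    if np.isscalar(u_draws):
        return SpatialFraction(var_u=float(u_draws), var_v=float(v_draws))
    u = np.atleast_2d(np.asarray(u_draws, dtype=float))
    v = np.atleast_2d(np.asarray(v_draws, dtype=float))
    if u.shape != v.shape:
        raise ValueError("u and v draw matrices must be aligned (same draws, same areas)")
    var_u = float(u.var(axis=1, ddof=1).mean())
    var_v = float(v.var(axis=1, ddof=1).mean())
    return SpatialFraction(var_u=var_u, var_v=var_v)


def rr_table(
    records: pd.DataFrame,
    area_field: str = "area_id",
    year_field: str = "year",
    outcome_field: str = "poor_qol",
) -> pd.DataFrame:
    """Observed/expected relative risk of poor QoL per area and year.

    E_jt = n_jt * pooled prevalence, so sum(observed) == sum(expected)
    exactly; cells with no patients are omitted.
    """
    y = records[outcome_field].to_numpy()
    prevalence = y.mean()
    if prevalence == 0:
        raise ValueError("no poor-QoL outcomes in the cohort; RR undefined")
    grp = records.groupby([area_field, year_field], sort=True)[outcome_field].agg(
        n_patients="size", observed="sum"
    )
    out = grp.reset_index()
    out["expected"] = out["n_patients"] * prevalence
    out["rr"] = out["observed"] / out["expected"]
    return out


def coefficient_percent_change(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, label_a: str = "adjacency", label_b: str = "distance"
) -> pd.DataFrame:
    """Sensitivity of coefficients to the weight matrix: per coefficient,
    100 * |m_b - m_a| / |m_a| on the posterior-mean log-odds scale.

    Coefficients with |m_a| below 1e-12 are flagged undefined rather than
    erroring; sign flips (change > 100%) raise a warning.
    """
    a = summary_a.set_index("coefficient")["mean_logodds"]
    b = summary_b.set_index("coefficient")["mean_logodds"]
    if set(a.index) != set(b.index):
        raise ValueError("summaries cover different coefficient sets")
    b = b.reindex(a.index)
    rows = []
    for name in a.index:
        ma, mb = float(a[name]), float(b[name])
        if abs(ma) < 1e-12:
            rows.append({"coefficient": name, f"logodds_{label_a}": ma,
                         f"logodds_{label_b}": mb, "pct_change": np.nan, "undefined": True})
            continue
        pct = 100.0 * abs(mb - ma) / abs(ma)
        if np.sign(mb) != np.sign(ma) and mb != 0.0:
            warnings.warn(
                f"coefficient {name!r} changes sign between weight matrices "
                f"({ma:.4f} -> {mb:.4f})",
                stacklevel=2,
            )
        rows.append({"coefficient": name, f"logodds_{label_a}": ma,
                     f"logodds_{label_b}": mb, "pct_change": pct, "undefined": False})
    out = pd.DataFrame(rows)
    out[f"or_{label_a}"] = np.exp(out[f"logodds_{label_a}"])
    out[f"or_{label_b}"] = np.exp(out[f"logodds_{label_b}"])
    return out


@dataclass
class CrosstabResult:
    table: pd.DataFrame
    chi2: float
    df: int


def crosstab_prevalence(
    records: pd.DataFrame, covariate: str, outcome_field: str = "poor_qol"
) -> CrosstabResult:
    """Poor/good counts and row percentages by covariate level, with the
    Pearson chi-square statistic (no continuity correction) and df."""
    y = records[outcome_field].to_numpy()
    levels = records[covariate]
    tab = pd.crosstab(levels, y).rename(columns={0: "good", 1: "poor"})
    for col in ("poor", "good"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["poor", "good"]]
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("crosstab has a zero margin; chi-square undefined")
    tab["total"] = tab["poor"] + tab["good"]
    tab["poor_pct"] = 100.0 * tab["poor"] / tab["total"]
    tab["good_pct"] = 100.0 * tab["good"] / tab["total"]
    if len(tab) == 1:  # single level: no association to test
        chi2, dof = 0.0, 0
    else:
        chi2, _, dof, _ = chi2_contingency(tab[["poor", "good"]].to_numpy(), correction=False)
    return CrosstabResult(table=tab.reset_index(), chi2=float(chi2), df=int(dof))
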