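"""Derivation of the binary poor-QoL outcome from EPIC-26 domain scores.

EPIC-26 reports five domain scores (urinary incontinence, urinary
irritative/obstructive, bowel, sexual, hormonal), each on a 0-100 scale
with higher = better function. Because the domain scores are heavily
skewed, each domain is categorised into cohort-empirical quartiles, coded
1 (worst) to 4 (best); the five quartile codes are summed into a composite
score on 5-20; and patients whose composite falls strictly below the
cohort median are labelled as having poor quality of life (the median
itself counts as good).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = (
    "urinary_incontinence",
    "urinary_irritative",
    "bowel",
    "sexual",
    "hormonal",
)


@dataclass
class QolThresholds:
    """Frozen scoring thresholds: per-domain quartile cut points and the
    composite median. Lets a sub-cohort be scored against reference-cohort
    thresholds instead of its own."""

    quartile_cuts: dict  # domain -> (q25, q50, q75)
    composite_median: float


@dataclass
class ScoredCohort:
    table: pd.DataFrame  # patient_id, <domain>_q x5, composite, poor_qol
    thresholds: QolThresholds
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def exclusion_report(self) -> dict:
        return {
            "n_input": int(len(self.table) + len(self.exclusions)),
            "n_scored": int(len(self.table)),
            "n_excluded": int(len(self.exclusions)),
            "excluded_patient_ids": [str(p) for p in self.exclusions.get("patient_id", [])],
            "reason": "missing or out-of-range domain score",
        }


def quartile_bin(scores, cuts=None):
    """Map raw domain scores to quartile categories 1-4.

    Cut points are the empirical 25th/50th/75th percentiles (linear
    interpolation of order statistics) unless ``cuts`` is given. Ties at a
    cut point go to the lower bin: value <= Q1 -> 1, <= Q2 -> 2,
    <= Q3 -> 3, else 4.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot quartile-bin an empty score vector")
    bad = ~((scores >= 0) & (scores <= 100))
    if bad.any():
        idx = np.flatnonzero(bad)
        raise ValueError(
            f"domain scores outside [0, 100] at positions {idx.tolist()[:10]}"
        )
    if cuts is None:
        cuts = np.percentile(scores, [25, 50, 75])
    cuts = np.asarray(cuts, dtype=float)
    # value <= q increments nothing; value > q pushes it one bin up
    bins = 1 + (scores[:, None] > cuts[None, :]).sum(axis=1)
    return bins.astype(int), tuple(cuts)


def composite_score(domain_quartiles) -> int:
    """Sum of the five domain quartile codes; ranges 5 (worst) to 20 (best)."""
    q = np.asarray(domain_quartiles)
    if q.shape != (5,):
        raise ValueError(f"expected exactly 5 domain quartiles, got shape {q.shape}")
    if not np.isin(q, [1, 2, 3, 4]).all():
        raise ValueError(f"quartile values must be in {{1,2,3,4}}, got {q.tolist()}")
    return int(q.sum())


def median_split(composites, median=None):
    """Binary poor-QoL outcome: 1 where composite < cohort median, else 0.

    Returns ``(outcomes, median_used)``. Patients exactly at the median are
    good (0).
    """
    c = np.asarray(composites, dtype=float)
    if c.size == 0:
        raise ValueError("cannot median-split an empty composite vector")
    if median is None:
        median = float(np.median(c))
    return (c < median).astype(int), float(median)


def derive_outcomes(
    patients: pd.DataFrame,
    domain_columns=DOMAINS,
    id_column: str = "patient_id",
    thresholds: QolThresholds | None = None,
) -> ScoredCohort:
    """Run the full outcome pipeline on a patient table.

    Patients with any missing or out-of-range domain score are excluded
    from scoring and listed in the exclusion report (never silently
    dropped). If ``thresholds`` is given, its quartile cuts and composite
    median are applied instead of being re-estimated, which is how a
    sub-cohort is scored consistently against a reference cohort.
    """
    domain_columns = list(domain_columns)
    missing_cols = [c for c in domain_columns if c not in patients.columns]
    if missing_cols:
        raise ValueError(f"patient table lacks domain columns {missing_cols}")

    dom = patients[domain_columns].apply(pd.to_numeric, errors="coerce")
    ok = dom.notna().all(axis=1) & ((dom >= 0) & (dom <= 100)).all(axis=1)
    scored = patients.loc[ok].reset_index(drop=True)
    excluded = patients.loc[~ok].reset_index(drop=True)
    if len(scored) == 0:
        raise ValueError("no patient has a complete set of valid domain scores")

    out = pd.DataFrame({id_column: scored[id_column]})
    cuts = {}
    for d in domain_columns:
        given = thresholds.quartile_cuts[d] if thresholds is not None else None
        out[f"{d}_q"], cuts[d] = quartile_bin(scored[d].to_numpy(), cuts=given)
    qcols = [f"{d}_q" for d in domain_columns]
    out["composite"] = out[qcols].sum(axis=1).astype(int)
    med = thresholds.composite_median if thresholds is not None else None
    out["poor_qol"], med = median_split(out["composite"].to_numpy(), median=med)
    return ScoredCohort(
        table=out,
        thresholds=QolThresholds(quartile_cuts=cuts, composite_median=med),
        exclusions=excluded,
    )
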