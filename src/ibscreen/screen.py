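"""Replicate-level statistics and dual-criterion hit calling for the screen.

A mutant is a hit when (1) its replicate Class-3 percentages differ from the
wild-type reference by Student's t-test at p <= alpha (inclusive, default
0.05) and (2) the difference of means is at least ``min_abs_delta_points``
percentage points (default 20) in the configured direction.  No
multiple-testing correction is applied: the effect-size gate, not the p-value,
is what controls false positives at genome scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutantMeasurement",
    "HitCriteria",
    "HitCall",
    "student_t_two_sample",
    "evaluate_mutant",
    "call_hits",
    "call_hits_from_table",
]


@dataclass(frozen=True)
class MutantMeasurement:
    """Replicate Class-3 percentages for one strain."""

    mutant_id: str
    values: tuple[float, ...]
    collection: str = "deletion"  # or "ts"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(vals) < 2:
            raise ValueError("need at least two replicates")
        if not np.all(np.isfinite(vals)):
            raise ValueError("replicate values must be finite")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))


@dataclass(frozen=True)
class HitCriteria:
    alpha: float = 0.05
    min_abs_delta_points: float = 20.0
    direction: str = "increase"  # "increase" | "decrease" | "both"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_delta_points < 0:
            raise ValueError("min_abs_delta_points must be >= 0")
        if self.direction not in ("increase", "decrease", "both"):
            raise ValueError("direction must be increase, decrease or both")


@dataclass(frozen=True)
class HitCall:
    mutant_id: str
    delta_points: float  # mutant mean - WT mean
    t_statistic: float
    p_two_sided: float
    passes_significance: bool
    passes_effect: bool
    is_hit: bool
    direction_label: str


def student_t_two_sample(a, b) -> tuple[float, int, float]:
    """Pooled-variance (Student's) two-sample t-test.

    Returns (t, df, two-sided p) for mean(a) - mean(b); df = n_a + n_b - 2.
    Degenerate limits: zero pooled variance with equal means gives t = 0,
    p = 1; with unequal means p = 0 (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0",
                      stacklevel=2)
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def evaluate_mutant(m: MutantMeasurement, wt: MutantMeasurement,
                    criteria: HitCriteria = HitCriteria()) -> HitCall:
    """Apply both hit criteria to one mutant against the wild-type reference."""
    t, _, p = student_t_two_sample(np.asarray(m.values), np.asarray(wt.values))
    delta = float(np.mean(m.values) - np.mean(wt.values))
    passes_sig = p <= criteria.alpha  # inclusive by definition
    if criteria.direction == "increase":
        passes_eff = delta >= criteria.min_abs_delta_points
    elif criteria.direction == "decrease":
        passes_eff = -delta >= criteria.min_abs_delta_points
    else:
        passes_eff = abs(delta) >= criteria.min_abs_delta_points
    direction_label = "increase" if delta > 0 else ("decrease" if delta < 0 else "none")
    return HitCall(
        mutant_id=m.mutant_id, delta_points=delta, t_statistic=t,
        p_two_sided=p, passes_significance=bool(passes_sig),
        passes_effect=bool(passes_eff),
        is_hit=bool(passes_sig and passes_eff),
        direction_label=direction_label)


def call_hits(table: list[MutantMeasurement], wt: MutantMeasurement,
              criteria: HitCriteria = HitCriteria(),
              ) -> tuple[pd.DataFrame, dict]:
    """Evaluate every mutant; returns the HitCall table and a screen summary."""
    if not table:
        raise ValueError("empty mutant table")
    calls = [evaluate_mutant(m, wt, criteria) for m in table]
    df = pd.DataFrame([c.__dict__ for c in calls])
    hits = df[df.is_hit]
    summary = {
        "n_mutants": len(df),
        "n_hits": int(df.is_hit.sum()),
        "n_hits_increase": int((hits.direction_label == "increase").sum()),
        "n_hits_decrease": int((hits.direction_label == "decrease").sum()),
        "criteria": {"alpha": criteria.alpha,
                     "min_abs_delta_points": criteria.min_abs_delta_points,
                     "direction": criteria.direction},
    }
    return df, summary


def call_hits_from_table(df: pd.DataFrame,
                         criteria: HitCriteria = HitCriteria(),
                         wt_id: str = "WT") -> tuple[pd.DataFrame, dict]:
    """Hit calling on a tidy table with columns mutant_id, replicate,
    class3_percent (wild-type rows identified by ``wt_id``)."""
    required = {"mutant_id", "replicate", "class3_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    wt_rows = df[df.mutant_id == wt_id]
    if len(wt_rows) == 0:
        raise ValueError(f"wild-type reference {wt_id!r} not present")
    wt = MutantMeasurement(wt_id, tuple(wt_rows.class3_percent))
    mutants = [
        MutantMeasurement(mid, tuple(grp.class3_percent))
        for mid, grp in df[df.mutant_id != wt_id].groupby("mutant_id", sort=True)
    ]
    return call_hits(mutants, wt, criteria)
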