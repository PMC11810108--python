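"""Phenotype classification and population / time-course / cohort summaries.

A cell's phenotype class is a pure function of its inclusion count: one
inclusion is Class 1, two is Class 2, three or more is Class 3 (cells without
inclusions are a fourth, unclassified category).  Class shares are reported
over inclusion-bearing cells, while prevalence (the fraction of cells with at
least one inclusion) is reported over all counted cells; both conventions are
emitted so either denominator can be reconstructed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import screen as screen_stats

__all__ = [
    "CLASS_LABELS",
    "classify_cell",
    "build_cell_records",
    "PopulationSummary",
    "summarize_population",
    "summarize_timecourse",
    "CohortComparison",
    "compare_cohorts",
]

CLASS_LABELS = ("NO_IB", "CLASS1", "CLASS2", "CLASS3")


def classify_cell(ib_count: int) -> str:
    """Inclusion count -> phenotype class label."""
    if isinstance(ib_count, (bool, float)) and not float(ib_count).is_integer():
        raise ValueError(f"ib_count must be an integer, got {ib_count!r}")
    c = int(ib_count)
    if c != ib_count or c < 0:
        raise ValueError(f"ib_count must be a non-negative integer, got {ib_count!r}")
    if c == 0:
        return "NO_IB"
    if c == 1:
        return "CLASS1"
    if c == 2:
        return "CLASS2"
    return "CLASS3"


def build_cell_records(cell_counts: pd.DataFrame, cell_mask=None,
                       areas: dict[int, int] | None = None) -> pd.DataFrame:
    """Attach class labels and the border flag to a per-cell count table.

    ``cell_counts`` needs columns field_id, cell_label, ib_count.  When the
    cell mask is provided, cells touching the field border are flagged (their
    inclusion complement may be truncated) and areas are filled in.
    """
    df = cell_counts.copy()
    df["class_label"] = [classify_cell(c) for c in df.ib_count]
    border = set()
    if cell_mask is not None:
        border = set(int(v) for v in cell_mask.border_labels())
        if areas is None:
            counts = np.bincount(cell_mask.labels.ravel())
            areas = {lab: int(counts[lab]) for lab in range(1, len(counts))}
    df["border_flag"] = [lab in border for lab in df.cell_label]
    df["area_px"] = [areas.get(int(lab), np.nan) if areas else np.nan
                     for lab in df.cell_label]
    return df


@dataclass
class PopulationSummary:
    n_cells: int
    n_ib_bearing: int
    fraction_with_ibs: float
    class1_share: float
    class2_share: float
    class3_share: float
    mean_count: float  # over inclusion-bearing cells
    sd_count: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_population(records: pd.DataFrame) -> PopulationSummary:
    """Population summary over non-border cell records.

    Class shares use inclusion-bearing cells as the denominator; prevalence
    uses all counted cells.
    """
    df = records
    if "border_flag" in df.columns:
        df = df[~df.border_flag]
    if len(df) == 0:
        raise ValueError("no non-border cells to summarize")
    counts = df.ib_count.to_numpy()
    bearing = counts[counts >= 1]
    nb = len(bearing)
    if nb:
        shares = [float(np.mean(bearing == 1)), float(np.mean(bearing == 2)),
                  float(np.mean(bearing >= 3))]
        mean_c, sd_c = float(bearing.mean()), float(bearing.std(ddof=1)) if nb > 1 else 0.0
    else:
        shares = [float("nan")] * 3
        mean_c = sd_c = float("nan")
    return PopulationSummary(
        n_cells=len(df), n_ib_bearing=nb,
        fraction_with_ibs=nb / len(df),
        class1_share=shares[0], class2_share=shares[1], class3_share=shares[2],
        mean_count=mean_c, sd_count=sd_c)


def summarize_timecourse(points: list[tuple[float | str, pd.DataFrame]],
                         ) -> pd.DataFrame:
    """One summary row per time point, ordered by time.

    ``points`` is a list of (time label in hours, cell-record table).
    Duplicate time labels raise.
    """
    if len(points) < 2:
        raise ValueError("a time course needs at least two points")
    times = [float(t) for t, _ in points]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time labels in time course")
    rows = []
    for t, recs in sorted(zip(times, (r for _, r in points)), key=lambda x: x[0]):
        row = {"time_h": t}
        row.update(summarize_population(recs).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortComparison:
    delta_fraction_with_ibs: float
    delta_mean_count: float
    t_fraction: float
    p_fraction: float
    t_mean_count: float
    p_mean_count: float
    summary_a: PopulationSummary
    summary_b: PopulationSummary


def _per_field_values(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    fracs, means = [], []
    for _, grp in records.groupby("field_id", sort=True):
        s = summarize_population(grp)
        fracs.append(s.fraction_with_ibs)
        means.append(s.mean_count)
    return np.array(fracs), np.array(means)


def compare_cohorts(a: pd.DataFrame, b: pd.DataFrame) -> CohortComparison:
    """Compare two cohorts of cell records (e.g. young vs old).

    Deltas are b minus a.  Significance uses Student's t on per-field summary
    values (the field is the biological replicate); with fewer than two fields
    per arm the t statistics are reported as NaN.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both cohorts must be non-empty")
    sa, sb = summarize_population(a), summarize_population(b)
    fa, ma = _per_field_values(a)
    fb, mb = _per_field_values(b)
    if len(fa) >= 2 and len(fb) >= 2:
        t_f, _, p_f = screen_stats.student_t_two_sample(fb, fa)
        ok_a, ok_b = ~np.isnan(ma), ~np.isnan(mb)
        if ok_a.sum() >= 2 and ok_b.sum() >= 2:
            t_m, _, p_m = screen_stats.student_t_two_sample(mb[ok_b], ma[ok_a])
        else:
            t_m = p_m = float("nan")
    else:
        t_f = p_f = t_m = p_m = float("nan")
    return CohortComparison(
        delta_fraction_with_ibs=sb.fraction_with_ibs - sa.fraction_with_ibs,
        delta_mean_count=sb.mean_count - sa.mean_count,
        t_fraction=t_f, p_fraction=p_f, t_mean_count=t_m, p_mean_count=p_m,
        summary_a=sa, summary_b=sb)
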