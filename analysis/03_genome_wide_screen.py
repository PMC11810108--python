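#!/usr/bin/env python
"""Genome-wide screen simulation and dual-criterion hit calling.

Simulates ten independent 5500-mutant screens, each with 84 planted
maturation-defective mutants (Class-3 percentage shifted +30 points over a
50% wild-type baseline; replicate SD 5 points, triplicate measurements), and
calls hits with the dual criterion: Student's t-test p <= 0.05 against the
wild-type reference AND an effect of at least 20 percentage points.

Output: results/screen_recovery.csv, results/screen_hits_seed1.csv
"""

from pathlib import Path

from ibscreen.screen import call_hits_from_table
from ibscreen.simulate import ScreenSpec, generate_screen_dataset
from ibscreen.studies import run_screen_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

res = run_screen_study(list(range(1, 11)))
res.to_csv(OUT / "screen_recovery.csv", index=False)
print(res.to_string(index=False))

# keep the full hit table of the first replicate screen for inspection
df = generate_screen_dataset(ScreenSpec(seed=1))
calls, summary = call_hits_from_table(df)
calls[calls.is_hit].to_csv(OUT / "screen_hits_seed1.csv", index=False)

n_exact = int(res.exact_recovery.sum())
print(f"\nFinding: the planted 84-mutant hit set was recovered exactly in "
      f"{n_exact}/10 screens with {int(res.false_positives.sum())} false "
      "positives overall; the 20-point effect gate, not the p-value, is what "
      "suppresses false discoveries at genome scale without any multiple-"
      "testing correction.")
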