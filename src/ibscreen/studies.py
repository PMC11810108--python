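"""Reusable study runners: the canonical end-to-end experiments.

Each function generates synthetic data under a named study condition, runs
the full measurement pipeline (pixels -> masks -> counts -> summaries), and
returns both the measured and the planted quantities so recovery can be
scored.  The analysis drivers and the acceptance checks are thin wrappers
around these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .associate import summarize_association
from .classify import summarize_population
from .counts import CategoricalCounts
from .pipeline import AssociationParams, quantify_field
from .screen import HitCriteria, call_hits_from_table
from .simulate import (FieldSpec, ScreenSpec, _child_seeds, generate_field,
                       generate_screen_dataset, get_preset)

__all__ = [
    "quantify_preset_fields",
    "run_class_structure_study",
    "run_cohort_study",
    "run_screen_study",
    "association_field_spec",
    "run_association_study",
]


def quantify_preset_fields(preset_name: str, seeds: list[int],
                           n_cells: int = 150, **spec_overrides,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one field per seed with the given preset and quantify it.

    Returns (cell_records, planted_cells) pooled over fields.
    """
    preset = get_preset(preset_name)
    all_records, all_truth = [], []
    for s in seeds:
        spec = preset.field_spec(seed=int(s), n_cells=n_cells, **spec_overrides)
        fld, gt = generate_field(spec, field_id=f"{preset_name}_s{s}")
        q = quantify_field(fld)
        all_records.append(q.cell_records)
        truth = gt.cells.assign(field_id=gt.field_id)
        all_truth.append(truth)
    return (pd.concat(all_records, ignore_index=True),
            pd.concat(all_truth, ignore_index=True))


def run_class_structure_study(preset_name: str, seeds: list[int],
                              n_cells: int = 150) -> dict:
    """Pooled measured vs planted class structure for one phase preset."""
    records, truth = quantify_preset_fields(preset_name, seeds, n_cells)
    measured = summarize_population(records)
    bearing = truth[truth.planted_count >= 1]
    planted = {
        "class1_share": float((bearing.planted_class == "CLASS1").mean()),
        "class2_share": float((bearing.planted_class == "CLASS2").mean()),
        "class3_share": float((bearing.planted_class == "CLASS3").mean()),
        "fraction_with_ibs": float((truth.planted_count >= 1).mean()),
        "mean_count": float(bearing.planted_count.mean()),
    }
    return {"preset": preset_name, "n_fields": len(seeds),
            "measured": measured.as_dict(), "planted": planted}


def run_cohort_study(preset_name: str, n_cells_total: int, seed: int,
                     cells_per_field: int = 125) -> dict:
    """One aging-cohort arm: ~n_cells_total cells split over several fields."""
    n_fields = max(1, int(np.ceil(n_cells_total / cells_per_field)))
    seeds = _child_seeds(seed, n_fields)
    preset = get_preset(preset_name)
    records, truths = [], []
    remaining = n_cells_total
    for j, s in enumerate(seeds):
        n = min(cells_per_field, remaining)
        remaining -= n
        fld, gt = generate_field(preset.field_spec(seed=s, n_cells=n),
                                 field_id=f"{preset_name}_f{j}")
        q = quantify_field(fld)
        records.append(q.cell_records)
        truths.append(gt.cells)
    records = pd.concat(records, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    measured = summarize_population(records)
    bearing = truth[truth.planted_count >= 1]
    return {
        "preset": preset_name,
        "records": records,
        "measured": measured.as_dict(),
        "planted": {
            "fraction_with_ibs": float((truth.planted_count >= 1).mean()),
            "mean_count": float(bearing.planted_count.mean()) if len(bearing)
            else float("nan"),
        },
    }


def run_screen_study(seeds: list[int],
                     criteria: HitCriteria = HitCriteria(),
                     **spec_overrides) -> pd.DataFrame:
    """Simulate and call one screen per seed; score against planted hits.

    Returns one row per seed: n_hits, false positives, false negatives,
    and whether the planted hit set was recovered exactly.
    """
    rows = []
    for s in seeds:
        spec = ScreenSpec(seed=int(s), **spec_overrides)
        df = generate_screen_dataset(spec)
        calls, summary = call_hits_from_table(df, criteria)
        planted = set(df[df.planted_hit].mutant_id)
        called = set(calls[calls.is_hit].mutant_id)
        rows.append({
            "seed": int(s),
            "n_hits": summary["n_hits"],
            "n_planted": len(planted),
            "false_positives": len(called - planted),
            "false_negatives": len(planted - called),
            "exact_recovery": called == planted,
        })
    return pd.DataFrame(rows)


def association_field_spec(seed: int, shell_probability: float = 0.8,
                           ) -> FieldSpec:
    """Two-channel field for encirclement studies.

    Mature-culture count structure (all three classes present) with cells
    large enough that inclusions sit far apart: a shell-less inclusion must
    not pick up encirclement from a neighbour's shell, so the planted
    surrounded fraction stays a clean oracle.
    """
    return FieldSpec(
        n_cells=110, cell_radius_px=(15.0, 1.2),
        count_law=CategoricalCounts({1: 0.5, 2: 0.3, 3: 0.2}),
        prevalence=0.95, shell_probability=shell_probability,
        ib_min_separation_px=12.0, seed=seed)


def run_association_study(seeds: list[int], shell_probability: float = 0.8,
                          probe_distance_px: float = 3.0,
                          threshold: float = 0.5) -> dict:
    """Measured vs planted organelle-association fractions over fields."""
    assoc_params = AssociationParams(enabled=True,
                                     probe_distance_px=probe_distance_px,
                                     surrounded_threshold=threshold)
    all_recs, planted_shell, planted_n = [], 0, 0
    for s in seeds:
        spec = association_field_spec(int(s), shell_probability)
        fld, gt = generate_field(spec, field_id=f"assoc_s{s}")
        q = quantify_field(fld, assoc_params=assoc_params)
        all_recs.append(q.association)
        planted_shell += int(gt.inclusions.shell.sum())
        planted_n += len(gt.inclusions)
    records = pd.concat([r for r in all_recs if len(r)], ignore_index=True)
    summary = summarize_association(records)
    summary["planted_shell_fraction"] = planted_shell / planted_n
    summary["records"] = records
    return summary
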