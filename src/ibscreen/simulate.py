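"""Synthetic two-channel microscopy fields and screen tables with planted truth.

The generator emulates wide-field fluorescence images of yeast-like cells
expressing a fluorescently tagged aggregation-prone protein: cells are bright
elliptical regions on a dim background, inclusion bodies (IBs) are much
brighter Gaussian puncta inside cells, and an optional second channel renders
organelle "shells" (partial annuli) around a configurable fraction of
inclusions.  Fields carry multiplicative illumination shading (a quadratic
bowl) and additive Gaussian read noise quantized to 16 bits.

Phase presets pin the per-cell count law and prevalence to population
summaries observed for this system: in early (lag-phase) cultures essentially
all inclusion-bearing cells hold three or more small aggregates (~96% Class
3); by stationary phase roughly half retain a single mature inclusion; young
cells (<=1 generation) show inclusions in ~27% of cells with 2.64+/-1.29
inclusions each, versus 61% and 4.91+/-3.32 in aged cells (>=5 generations).

Everything planted is returned as exact ground truth so that the measurement
pipeline can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import CategoricalCounts, CountLaw, ShiftedNegBinomCounts
from .field import CHANNEL_AGGREGATE, CHANNEL_ORGANELLE, ImageField

__all__ = [
    "FieldSpec",
    "PhasePreset",
    "GroundTruth",
    "ScreenSpec",
    "PRESETS",
    "get_preset",
    "generate_field",
    "generate_timecourse",
    "generate_aging_cohort",
    "generate_screen_dataset",
    "classify_count",
]


def classify_count(count: int) -> str:
    """Count -> phenotype class (duplicated here so planted labels never
    depend on the measurement code they are meant to test)."""
    if count == 0:
        return "NO_IB"
    if count == 1:
        return "CLASS1"
    if count == 2:
        return "CLASS2"
    return "CLASS3"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FieldSpec:
    """Full description of one synthetic field; identical spec + seed gives a
    bit-identical field."""

    width_px: int = 1024
    height_px: int = 1024
    n_cells: int = 150
    cell_radius_px: tuple[float, float] = (12.0, 1.2)  # mean, SD
    cell_intensity: float = 3000.0
    ib_intensity: float = 18000.0
    background_level: float = 500.0
    ib_radius_px: tuple[float, float] = (1.8, 0.2)  # mean, SD
    count_law: CountLaw = field(default_factory=lambda: CategoricalCounts({1: 1.0}))
    prevalence: float = 1.0
    shell_probability: float = 0.0
    shell_gap_px: float = 2.0
    shell_thickness_px: float = 2.0
    shell_intensity: float = 15000.0
    ib_min_separation_px: float | None = None  # default: 2 x mean IB radius
    shading_amplitude: float = 0.3
    noise_sd: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("width_px", "height_px", "cell_intensity", "ib_intensity",
                     "background_level", "shell_gap_px", "shell_thickness_px",
                     "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"FieldSpec.{name} must be finite and >= 0, got {v}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.shell_probability <= 1.0):
            raise ValueError("shell_probability must be in [0, 1]")
        if not (0.0 <= self.shading_amplitude < 1.0):
            raise ValueError("shading_amplitude must be in [0, 1)")
        if not (self.ib_intensity > self.cell_intensity > self.background_level):
            raise ValueError(
                "planted contrast ordering requires "
                "ib_intensity > cell_intensity > background_level")
        for name in ("cell_radius_px", "ib_radius_px"):
            m, s = getattr(self, name)
            if m <= 0 or s < 0:
                raise ValueError(f"FieldSpec.{name} needs mean > 0 and SD >= 0")

    @property
    def ib_separation(self) -> float:
        if self.ib_min_separation_px is not None:
            return float(self.ib_min_separation_px)
        return 2.0 * self.ib_radius_px[0]


@dataclass(frozen=True)
class PhasePreset:
    """A named culture condition: conditional count law + prevalence plus the
    cell geometry typical of that condition."""

    name: str
    count_law: CountLaw
    prevalence: float
    cell_radius_px: tuple[float, float] = (12.0, 1.2)

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")

    def class_shares(self) -> dict[str, float]:
        """Planted class shares among inclusion-bearing cells, closed form."""
        return self.count_law.class_shares()

    def field_spec(self, seed: int, **overrides) -> FieldSpec:
        base = FieldSpec(count_law=self.count_law, prevalence=self.prevalence,
                         cell_radius_px=self.cell_radius_px, seed=seed)
        return replace(base, **overrides)


# Presets are calibrated so the planted population summaries equal the printed
# summaries of the system being emulated (see module docstring); recovery of
# these numbers from pixels is what the pipeline is tested on.
PRESETS: dict[str, PhasePreset] = {
    # 4 h culture: nearly all bearing cells carry >=3 small aggregates (96%).
    "lag": PhasePreset(
        "lag",
        CategoricalCounts({1: 0.02, 2: 0.02, 3: 0.24, 4: 0.24, 5: 0.24, 6: 0.24}),
        prevalence=0.90),
    # 16-20 h culture: Class 3 has fallen to ~50%.
    "exponential": PhasePreset(
        "exponential",
        CategoricalCounts({1: 0.25, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10, 6: 0.05}),
        prevalence=0.90),
    # 48 h culture: about half of bearing cells retain a single inclusion.
    "stationary": PhasePreset(
        "stationary",
        CategoricalCounts({1: 0.50, 2: 0.28, 3: 0.12, 4: 0.07, 5: 0.03}),
        prevalence=0.85),
    # young (<=1 generation) / old (>=5 generations) cohorts: prevalence and
    # count moments pinned to 27% / 61% and 2.64+/-1.29 / 4.91+/-3.32.
    "young": PhasePreset(
        "young", ShiftedNegBinomCounts(2.64, 1.29), prevalence=0.27,
        cell_radius_px=(11.0, 1.0)),
    "old": PhasePreset(
        "old", ShiftedNegBinomCounts(4.91, 3.32), prevalence=0.61,
        cell_radius_px=(15.0, 1.2)),
    # screen baseline: wild type at the screening time point (Class 3 ~ 50%).
    "wildtype": PhasePreset(
        "wildtype",
        CategoricalCounts({1: 0.25, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10, 6: 0.05}),
        prevalence=0.90),
    # a maturation-defective mutant: Class 3 strongly increased.
    "mutant": PhasePreset(
        "mutant",
        CategoricalCounts({1: 0.05, 2: 0.10, 3: 0.25, 4: 0.25, 5: 0.20, 6: 0.15}),
        prevalence=0.95),
}


def get_preset(name: str) -> PhasePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Exact record of everything planted in one field."""

    cells: pd.DataFrame        # cell_id, center_row, center_col, radius_px, count, class
    inclusions: pd.DataFrame   # ib_id, cell_id, center_row, center_col, radius_px, shell
    field_id: str = "field_0"

    CELL_COLUMNS = ("cell_id", "center_row", "center_col", "radius_px",
                    "axis_ratio", "orientation_rad", "planted_count",
                    "planted_class")
    IB_COLUMNS = ("ib_id", "cell_id", "center_row", "center_col", "radius_px",
                  "shell", "shell_arc_deg", "shell_start_deg")

    def summary(self) -> dict[str, float]:
        """Field-level planted summaries, aggregated from the per-cell records."""
        n = len(self.cells)
        bearing = self.cells[self.cells.planted_count >= 1]
        nb = len(bearing)
        out = {
            "n_cells": n,
            "n_ib_bearing": nb,
            "n_inclusions": int(self.cells.planted_count.sum()),
            "fraction_with_ibs": nb / n if n else float("nan"),
            "mean_count_bearing": float(bearing.planted_count.mean()) if nb else float("nan"),
        }
        for cls in ("CLASS1", "CLASS2", "CLASS3"):
            out[f"share_{cls.lower()}"] = (
                float((bearing.planted_class == cls).mean()) if nb else float("nan"))
        if len(self.inclusions):
            out["shell_fraction"] = float(self.inclusions.shell.mean())
        else:
            out["shell_fraction"] = float("nan")
        return out


# ---------------------------------------------------------------------------
# field rendering


def _place_cells(spec: FieldSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample non-overlapping elliptical cells fully inside the field."""
    rows, cols, radii, ratios, angles = [], [], [], [], []
    max_retries = 100
    for i in range(spec.n_cells):
        r_mean, r_sd = spec.cell_radius_px
        placed = False
        for _ in range(max_retries):
            r = max(3.0, rng.normal(r_mean, r_sd))
            q = rng.uniform(1.0, 1.4)
            a = r * np.sqrt(q)  # semi-major axis
            margin = a + 3.0
            if (spec.height_px - 2 * margin <= 0) or (spec.width_px - 2 * margin <= 0):
                continue
            cy = rng.uniform(margin, spec.height_px - margin)
            cx = rng.uniform(margin, spec.width_px - margin)
            ok = True
            for j in range(len(rows)):
                aj = radii[j] * np.sqrt(ratios[j])
                if np.hypot(cy - rows[j], cx - cols[j]) < a + aj + 2.0:
                    ok = False
                    break
            if ok:
                rows.append(cy); cols.append(cx); radii.append(r)
                ratios.append(q); angles.append(rng.uniform(0.0, np.pi))
                placed = True
                break
        if not placed:
            density = len(rows) / (spec.width_px * spec.height_px / 1e6)
            raise RuntimeError(
                f"could not place cell {i + 1}/{spec.n_cells} after "
                f"{max_retries} retries; achievable density at this geometry is "
                f"about {density:.0f} cells/Mpx")
    return pd.DataFrame({
        "cell_id": np.arange(1, len(rows) + 1, dtype=int),
        "center_row": rows, "center_col": cols, "radius_px": radii,
        "axis_ratio": ratios, "orientation_rad": angles,
    })


def _ellipse_patch(cy, cx, a, b, theta, shape):
    """Boolean patch and its slices for an ellipse (row-major, 0-based)."""
    r0 = max(0, int(np.floor(cy - a - 1)))
    r1 = min(shape[0], int(np.ceil(cy + a + 2)))
    c0 = max(0, int(np.floor(cx - a - 1)))
    c1 = min(shape[1], int(np.ceil(cx + a + 2)))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (slice(r0, r1), slice(c0, c1))


def _sample_ib_centers(cell, counts_needed, separation, rng):
    """Uniform centers inside a shrunk copy of the cell ellipse, pairwise
    separated; returns the centers actually placed (may be fewer)."""
    a = cell.radius_px * np.sqrt(cell.axis_ratio) * 0.72
    b = cell.radius_px / np.sqrt(cell.axis_ratio) * 0.72
    th = cell.orientation_rad
    centers: list[tuple[float, float]] = []
    for _ in range(counts_needed):
        placed = False
        for _ in range(300):
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform())
            u, v = a * rad * np.cos(ang), b * rad * np.sin(ang)
            dx = u * np.cos(th) - v * np.sin(th)
            dy = u * np.sin(th) + v * np.cos(th)
            cy, cx = cell.center_row + dy, cell.center_col + dx
            if all(np.hypot(cy - py, cx - px) >= separation for py, px in centers):
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            break
    return centers


def generate_field(spec: FieldSpec, field_id: str = "field_0",
                   ) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its exact ground truth.

    Deterministic: the same spec (including its seed) reproduces the field
    bit-for-bit.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shape = (spec.height_px, spec.width_px)

    cells = _place_cells(spec, rng)

    # per-cell planted counts
    n = len(cells)
    bearing = rng.uniform(size=n) < spec.prevalence
    wanted = np.zeros(n, dtype=int)
    if bearing.any():
        wanted[bearing] = spec.count_law.sample(rng, int(bearing.sum()))

    red = np.full(shape, spec.background_level, dtype=float)
    cell_mask_patches = []
    for cell in cells.itertuples():
        a = cell.radius_px * np.sqrt(cell.axis_ratio)
        b = cell.radius_px / np.sqrt(cell.axis_ratio)
        mask, sl = _ellipse_patch(cell.center_row, cell.center_col, a, b,
                                  cell.orientation_rad, shape)
        red[sl][mask] = spec.cell_intensity
        cell_mask_patches.append((mask, sl))

    # inclusions
    ib_rows = []
    placed_counts = np.zeros(n, dtype=int)
    truncated = 0
    for idx, cell in enumerate(cells.itertuples()):
        k = int(wanted[idx])
        if k == 0:
            continue
        centers = _sample_ib_centers(cell, k, spec.ib_separation, rng)
        placed_counts[idx] = len(centers)
        truncated += k - len(centers)
        mask, sl = cell_mask_patches[idx]
        for (cy, cx) in centers:
            r_ib = max(0.6, rng.normal(*spec.ib_radius_px))
            sigma = r_ib / 2.0
            yy, xx = np.mgrid[sl[0], sl[1]]
            spot = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            # clipped to the owner cell so planted counts stay resolvable
            red[sl] += (spec.ib_intensity - spec.cell_intensity) * spot * mask
            shell = bool(rng.uniform() < spec.shell_probability)
            arc = rng.uniform(270.0, 360.0)
            start = rng.uniform(0.0, 360.0)
            ib_rows.append((cell.cell_id, cy, cx, r_ib, shell, arc, start))
    if truncated:
        warnings.warn(f"{truncated} inclusions could not be placed at the "
                      "requested separation; planted counts were reduced",
                      stacklevel=2)

    channels = {CHANNEL_AGGREGATE: red}
    if spec.shell_probability > 0:
        green = np.full(shape, spec.background_level, dtype=float)
        for (cid, cy, cx, r_ib, shell, arc, start) in ib_rows:
            if not shell:
                continue
            inner = r_ib + spec.shell_gap_px
            outer = inner + spec.shell_thickness_px
            r0 = max(0, int(np.floor(cy - outer - 1)))
            r1 = min(shape[0], int(np.ceil(cy + outer + 2)))
            c0 = max(0, int(np.floor(cx - outer - 1)))
            c1 = min(shape[1], int(np.ceil(cx + outer + 2)))
            yy, xx = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(yy - cy, xx - cx)
            ang = (np.degrees(np.arctan2(yy - cy, xx - cx)) - start) % 360.0
            ring = (d >= inner) & (d <= outer) & (ang <= arc)
            green[r0:r1, c0:c1][ring] = spec.shell_intensity
        channels[CHANNEL_ORGANELLE] = green

    # shading bowl: 1 at center, (1 - amplitude) at the corners, separable
    yy = np.linspace(-1.0, 1.0, shape[0])[:, None]
    xx = np.linspace(-1.0, 1.0, shape[1])[None, :]
    bowl = 1.0 - spec.shading_amplitude * (yy**2 + xx**2) / 2.0

    out_channels = {}
    for name in channels:
        img = channels[name] * bowl
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        out_channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    cells = cells.assign(
        planted_count=placed_counts,
        planted_class=[classify_count(c) for c in placed_counts])
    inclusions = pd.DataFrame(
        ib_rows, columns=["cell_id", "center_row", "center_col", "radius_px",
                          "shell", "shell_arc_deg", "shell_start_deg"])
    inclusions.insert(0, "ib_id", np.arange(1, len(inclusions) + 1, dtype=int))

    fld = ImageField(out_channels, provenance=f"synthetic:seed={spec.seed}",
                     field_id=field_id)
    return fld, GroundTruth(cells=cells, inclusions=inclusions, field_id=field_id)


# ---------------------------------------------------------------------------
# higher-level generators


def _child_seeds(seed: int, n: int) -> list[int]:
    """Hierarchical per-field integer seeds derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def generate_timecourse(presets: list[tuple[str, PhasePreset]],
                        fields_per_point: int, seed: int,
                        **spec_overrides,
                        ) -> list[tuple[str, list[ImageField], list[GroundTruth]]]:
    """One entry per time point: (time label, fields, ground truths).

    ``presets`` is an ordered list of (time label, preset); each field gets its
    own child seed so the whole course is reproducible from the single seed.
    """
    if not presets:
        raise ValueError("need at least one preset")
    seeds = _child_seeds(seed, len(presets) * fields_per_point)
    out = []
    for i, (label, preset) in enumerate(presets):
        fields, gts = [], []
        for j in range(fields_per_point):
            s = seeds[i * fields_per_point + j]
            fid = f"t{label}_f{j}"
            fld, gt = generate_field(preset.field_spec(seed=s, **spec_overrides),
                                     field_id=fid)
            fields.append(fld)
            gts.append(gt)
        out.append((label, fields, gts))
    return out


def interpolated_course(n_points: int) -> list[tuple[str, PhasePreset]]:
    """A lag -> exponential -> stationary course with count-law mixtures
    linearly interpolated between the three anchor presets (time labels in
    hours, every 4 h starting at 4 h)."""
    anchors = [PRESETS["lag"], PRESETS["exponential"], PRESETS["stationary"]]
    anchor_pos = [0.0, 0.5, 1.0]
    support = range(1, 7)
    out = []
    for i in range(n_points):
        x = i / max(1, n_points - 1)
        j = 0 if x <= 0.5 else 1
        w = (x - anchor_pos[j]) / 0.5
        pa, pb = anchors[j], anchors[j + 1]
        probs = {}
        for k in support:
            p = (1 - w) * float(pa.count_law.pmf(k)) + w * float(pb.count_law.pmf(k))
            if p > 0:
                probs[k] = p
        total = sum(probs.values())
        probs = {k: v / total for k, v in probs.items()}
        prev = (1 - x) * anchors[0].prevalence + x * anchors[2].prevalence
        out.append((str(4 + 4 * i),
                    PhasePreset(f"course_{i}", CategoricalCounts(probs), prev)))
    return out


def generate_aging_cohort(young: PhasePreset, old: PhasePreset,
                          cells_per_arm: int, seed: int,
                          cells_per_field: int = 125, **spec_overrides,
                          ) -> dict[str, tuple[list[ImageField], list[GroundTruth]]]:
    """Two field sets (young / old arms) totalling ~cells_per_arm cells each."""
    n_fields = max(1, int(np.ceil(cells_per_arm / cells_per_field)))
    seeds = _child_seeds(seed, 2 * n_fields)
    out: dict[str, tuple[list[ImageField], list[GroundTruth]]] = {}
    for arm_idx, (arm, preset) in enumerate((("young", young), ("old", old))):
        fields, gts = [], []
        remaining = cells_per_arm
        for j in range(n_fields):
            n_cells = min(cells_per_field, remaining)
            remaining -= n_cells
            s = seeds[arm_idx * n_fields + j]
            fld, gt = generate_field(
                preset.field_spec(seed=s, n_cells=n_cells, **spec_overrides),
                field_id=f"{arm}_f{j}")
            fields.append(fld)
            gts.append(gt)
        out[arm] = (fields, gts)
    return out


# ---------------------------------------------------------------------------
# screen tables


@dataclass(frozen=True)
class ScreenSpec:
    """Simulated genome-wide screen: per-mutant, per-replicate Class-3
    percentages with a planted set of true hits.

    The wild-type reference is measured once per plate in every screen round
    (``n_wt_replicates`` control wells in total), so its mean is much better
    determined than any single mutant's triplicate.
    """

    n_mutants: int = 5500
    n_hits_planted: int = 84
    baseline_class3_fraction: float = 50.0  # percent
    hit_shift: float = 30.0                 # percentage points
    replicate_sd: float = 5.0               # percentage points
    n_replicates: int = 3
    n_wt_replicates: int = 48
    seed: int = 0

    def validate(self) -> None:
        if self.n_mutants <= 0:
            raise ValueError("n_mutants must be positive")
        if not (0 <= self.n_hits_planted <= self.n_mutants):
            raise ValueError("n_hits_planted must be in [0, n_mutants]")
        if self.n_replicates < 2 or self.n_wt_replicates < 2:
            raise ValueError("need >= 2 replicates (t-test undefined otherwise)")
        if not (0.0 <= self.baseline_class3_fraction <= 100.0):
            raise ValueError("baseline must be a percentage in [0, 100]")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


def generate_screen_dataset(spec: ScreenSpec) -> pd.DataFrame:
    """Tidy table: mutant_id, replicate, class3_percent, planted_hit.

    Wild-type control rows use mutant_id ``"WT"``.  Hit mutants are drawn
    around baseline + hit_shift, the rest around baseline; replicate noise is
    i.i.d. normal with SD ``replicate_sd``, clipped to [0, 100] with a warning
    if clipping occurs.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    hit_ids = rng.choice(spec.n_mutants, size=spec.n_hits_planted, replace=False)
    is_hit = np.zeros(spec.n_mutants, dtype=bool)
    is_hit[hit_ids] = True

    means = np.full(spec.n_mutants, spec.baseline_class3_fraction)
    means[is_hit] += spec.hit_shift

    vals = rng.normal(means[:, None], spec.replicate_sd,
                      size=(spec.n_mutants, spec.n_replicates))
    wt_vals = rng.normal(spec.baseline_class3_fraction, spec.replicate_sd,
                         size=spec.n_wt_replicates)
    if np.any(vals < 0) or np.any(vals > 100) or np.any(wt_vals < 0) or np.any(wt_vals > 100):
        warnings.warn("simulated percentages clipped to [0, 100]", stacklevel=2)
        vals = np.clip(vals, 0.0, 100.0)
        wt_vals = np.clip(wt_vals, 0.0, 100.0)

    mutant_ids = np.array([f"mut{i:05d}" for i in range(spec.n_mutants)])
    rows = {
        "mutant_id": np.repeat(mutant_ids, spec.n_replicates),
        "replicate": np.tile(np.arange(1, spec.n_replicates + 1), spec.n_mutants),
        "class3_percent": vals.ravel(),
        "planted_hit": np.repeat(is_hit, spec.n_replicates),
    }
    df = pd.DataFrame(rows)
    wt = pd.DataFrame({
        "mutant_id": "WT",
        "replicate": np.arange(1, spec.n_wt_replicates + 1),
        "class3_percent": wt_vals,
        "planted_hit": False,
    })
    return pd.concat([wt, df], ignore_index=True)
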