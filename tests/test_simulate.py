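"""Generator contracts: determinism, conservation, planted-summary math."""

import numpy as np
import pandas as pd
import pytest

from ibscreen.counts import CategoricalCounts, TruncatedPoissonCounts
from ibscreen.field import CHANNEL_AGGREGATE, CHANNEL_ORGANELLE
from ibscreen.simulate import (PRESETS, FieldSpec, ScreenSpec,
                               generate_aging_cohort, generate_field,
                               generate_screen_dataset, generate_timecourse,
                               get_preset, interpolated_course)

from conftest import small_spec


class TestGenerateField:
    def test_deterministic_bit_for_bit(self):
        spec = small_spec(seed=99, shell_probability=0.5)
        f1, g1 = generate_field(spec)
        f2, g2 = generate_field(spec)
        for name in f1.channels:
            assert np.array_equal(f1.channels[name], f2.channels[name])
        pd.testing.assert_frame_equal(g1.cells, g2.cells)
        pd.testing.assert_frame_equal(g1.inclusions, g2.inclusions)

    def test_different_seeds_differ(self):
        f1, _ = generate_field(small_spec(seed=1))
        f2, _ = generate_field(small_spec(seed=2))
        assert not np.array_equal(f1.channels[CHANNEL_AGGREGATE],
                                  f2.channels[CHANNEL_AGGREGATE])

    def test_empty_field_is_background_plus_noise(self):
        spec = small_spec(n_cells=0, shading_amplitude=0.0)
        fld, gt = generate_field(spec)
        img = fld.channels[CHANNEL_AGGREGATE].astype(float)
        assert len(gt.cells) == 0 and len(gt.inclusions) == 0
        # mean ~ background, spread ~ noise (clipping at 0 is negligible here)
        assert abs(img.mean() - spec.background_level) < 5 * spec.noise_sd
        assert img.std() == pytest.approx(spec.noise_sd, rel=0.1)

    def test_conservation_planted_ibs(self, small_field):
        _, gt = small_field
        assert gt.cells.planted_count.sum() == len(gt.inclusions)
        assert set(gt.inclusions.cell_id) <= set(gt.cells.cell_id)

    def test_planted_class_consistent_with_rule(self, small_field):
        _, gt = small_field
        for rec in gt.cells.itertuples():
            expected = ("NO_IB" if rec.planted_count == 0 else
                        "CLASS1" if rec.planted_count == 1 else
                        "CLASS2" if rec.planted_count == 2 else "CLASS3")
            assert rec.planted_class == expected

    def test_summary_equals_aggregation(self, small_field):
        _, gt = small_field
        s = gt.summary()
        bearing = gt.cells[gt.cells.planted_count >= 1]
        assert s["fraction_with_ibs"] == pytest.approx(
            len(bearing) / len(gt.cells))
        assert s["share_class3"] == pytest.approx(
            (bearing.planted_class == "CLASS3").mean())

    def test_truncated_poisson_counts_recover_closed_form_mean(self):
        """500 planted cells, Poisson(2.5) truncated at zero: empirical mean
        within 3 SE of the closed-form truncated mean."""
        law = TruncatedPoissonCounts(2.5)
        spec = FieldSpec(width_px=2100, height_px=2100, n_cells=500,
                         count_law=law, prevalence=1.0, seed=7)
        _, gt = generate_field(spec)
        counts = gt.cells.planted_count.to_numpy()
        se = law.sd() / np.sqrt(len(counts))
        assert abs(counts.mean() - law.mean()) < 3 * se

    def test_overcrowding_raises_with_density_message(self):
        spec = small_spec(n_cells=400)  # cannot fit in 360x360
        with pytest.raises(RuntimeError, match="density"):
            generate_field(spec)

    @pytest.mark.parametrize("bad", [
        dict(shading_amplitude=1.5),
        dict(prevalence=-0.1),
        dict(cell_intensity=20000.0),  # breaks contrast ordering vs IBs
        dict(noise_sd=float("nan")),
        dict(width_px=-5),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_field(small_spec(**bad))

    def test_shell_fraction_monotone_in_probability(self):
        fracs = []
        for p in (0.2, 0.5, 0.9):
            _, gt = generate_field(small_spec(shell_probability=p, seed=3))
            fracs.append(gt.inclusions.shell.mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_organelle_channel_only_when_shells_requested(self):
        f0, _ = generate_field(small_spec(shell_probability=0.0))
        f1, _ = generate_field(small_spec(shell_probability=0.5))
        assert CHANNEL_ORGANELLE not in f0.channels
        assert CHANNEL_ORGANELLE in f1.channels


class TestPresets:
    def test_lag_class3_conditional_share(self):
        """Support of the lag law forces Class 3 for counts >= 3; the small
        {1,2} tail leaves a planted conditional share of 96%."""
        shares = get_preset("lag").class_shares()
        assert shares["CLASS3"] == pytest.approx(0.96)

    def test_stationary_class1_share(self):
        assert get_preset("stationary").class_shares()["CLASS1"] == pytest.approx(0.50)

    def test_aging_presets_match_printed_summaries(self):
        young, old = get_preset("young"), get_preset("old")
        assert young.prevalence == pytest.approx(0.27)
        assert old.prevalence == pytest.approx(0.61)
        assert young.count_law.mean() == pytest.approx(2.64, abs=0.02)
        assert old.count_law.mean() == pytest.approx(4.91, abs=0.02)

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            get_preset("diauxic")


class TestTimecourse:
    def test_single_preset_delegates(self):
        pts = generate_timecourse([("4", PRESETS["lag"])], fields_per_point=1,
                                  seed=5, width_px=360, height_px=360,
                                  n_cells=15)
        assert len(pts) == 1
        label, fields, gts = pts[0]
        assert label == "4" and len(fields) == 1 and len(gts) == 1

    def test_empty_preset_list_raises(self):
        with pytest.raises(ValueError):
            generate_timecourse([], 1, 0)

    def test_planted_class3_monotone_and_reproducible(self):
        course = interpolated_course(5)
        shares = [p.class_shares()["CLASS3"] for _, p in course]
        assert all(a >= b - 1e-12 for a, b in zip(shares, shares[1:]))
        kw = dict(fields_per_point=2, seed=11, width_px=360, height_px=360,
                  n_cells=15)
        a = generate_timecourse(course, **kw)
        b = generate_timecourse(course, **kw)
        assert len(a) == 5
        for (la, fa, _), (lb, fb, _) in zip(a, b):
            assert la == lb
            for x, y in zip(fa, fb):
                assert np.array_equal(x.channels[CHANNEL_AGGREGATE],
                                      y.channels[CHANNEL_AGGREGATE])
        # distinct fields within a run
        imgs = [f.channels[CHANNEL_AGGREGATE] for _, fs, _ in a for f in fs]
        assert len({arr.tobytes() for arr in imgs}) == len(imgs)


class TestAgingCohort:
    def test_planted_prevalences_within_3se(self):
        out = generate_aging_cohort(PRESETS["young"], PRESETS["old"],
                                    cells_per_arm=500, seed=13)
        for arm, p0 in (("young", 0.27), ("old", 0.61)):
            cells = pd.concat([gt.cells for gt in out[arm][1]])
            prev = (cells.planted_count >= 1).mean()
            se = np.sqrt(p0 * (1 - p0) / len(cells))
            assert abs(prev - p0) < 3 * se, arm

    def test_planted_old_mean_within_3se(self):
        out = generate_aging_cohort(PRESETS["young"], PRESETS["old"],
                                    cells_per_arm=500, seed=13)
        cells = pd.concat([gt.cells for gt in out["old"][1]])
        bearing = cells[cells.planted_count >= 1]
        law = PRESETS["old"].count_law
        se = law.sd() / np.sqrt(len(bearing))
        assert abs(bearing.planted_count.mean() - law.mean()) < 3 * se


class TestScreenDataset:
    def test_no_hits_all_baseline(self):
        df = generate_screen_dataset(ScreenSpec(n_mutants=50, n_hits_planted=0,
                                                seed=1))
        assert not df.planted_hit.any()
        mut = df[df.mutant_id != "WT"]
        assert abs(mut.class3_percent.mean() - 50.0) < 3 * 5.0 / np.sqrt(len(mut))

    def test_nonhit_grand_mean_within_3se(self):
        spec = ScreenSpec(n_mutants=100, n_hits_planted=10, hit_shift=30.0,
                          replicate_sd=5.0, n_replicates=3, seed=1)
        df = generate_screen_dataset(spec)
        nonhit = df[(~df.planted_hit) & (df.mutant_id != "WT")].class3_percent
        se = spec.replicate_sd / np.sqrt(len(nonhit))
        assert abs(nonhit.mean() - spec.baseline_class3_fraction) < 3 * se

    def test_hit_shift_zero_identical_laws(self):
        spec = ScreenSpec(n_mutants=200, n_hits_planted=100, hit_shift=0.0,
                          seed=2)
        df = generate_screen_dataset(spec)
        mut = df[df.mutant_id != "WT"]
        hit = mut[mut.planted_hit].class3_percent
        non = mut[~mut.planted_hit].class3_percent
        pooled_se = 5.0 * np.sqrt(1 / len(hit) + 1 / len(non))
        assert abs(hit.mean() - non.mean()) < 3 * pooled_se

    def test_replicate_structure_and_wt_present(self):
        spec = ScreenSpec(n_mutants=10, n_hits_planted=2, seed=3)
        df = generate_screen_dataset(spec)
        assert (df[df.mutant_id != "WT"].groupby("mutant_id").size()
                == spec.n_replicates).all()
        assert (df.mutant_id == "WT").sum() == spec.n_wt_replicates

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            generate_screen_dataset(ScreenSpec(n_replicates=1))
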