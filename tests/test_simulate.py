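"""Ground-truth generator, dye model and renderer contracts."""

import math

import numpy as np
import pandas as pd
import pytest

import chromaccess as ca
from chromaccess.simulate import ConditionSpec


class TestSamplePopulation:
    def test_empty_population(self):
        assert ca.sample_population(ca.PopulationParams(n_cells=0)) == []

    def test_degenerate_pure_g1(self):
        p = ca.PopulationParams(
            n_cells=25, phase_fractions=(1, 0, 0), accessible_cv=0.0,
            accessible_fraction=0.3, seed=1,
        )
        for c in ca.sample_population(p):
            assert c.phase == "G1"
            assert c.dna_content == 1.0
            assert c.accessible_fraction == pytest.approx(0.3)

    def test_phase_fractions_within_binomial_bound(self):
        n = 10_000
        p = ca.PopulationParams(n_cells=n, seed=11)
        cells = ca.sample_population(p)
        for frac, phase in zip(p.phase_fractions, ca.simulate.PHASES):
            observed = sum(c.phase == phase for c in cells) / n
            bound = 3 * math.sqrt(frac * (1 - frac) / n)
            assert abs(observed - frac) <= bound

    def test_dna_content_by_phase(self):
        cells = ca.sample_population(ca.PopulationParams(n_cells=2000, seed=5))
        for c in cells:
            if c.phase == "G1":
                assert c.dna_content == 1.0
            elif c.phase == "G2M":
                assert c.dna_content == 2.0
            else:
                assert 1.0 < c.dna_content < 2.0

    def test_edu_only_in_s_phase(self):
        cells = ca.sample_population(
            ca.PopulationParams(n_cells=2000, seed=6, edu_label_s_phase=True)
        )
        for c in cells:
            assert c.edu_positive == (c.phase == "S")

    def test_area_scales_with_dna_content(self):
        p = ca.PopulationParams(n_cells=4000, seed=7, area_cv=0.0)
        cells = ca.sample_population(p)
        for c in cells:
            assert c.area_px == pytest.approx(p.g1_mean_area_px * c.dna_content, rel=1e-9)

    def test_reproducible_from_seed(self):
        a = ca.sample_population(ca.PopulationParams(n_cells=100, seed=3))
        b = ca.sample_population(ca.PopulationParams(n_cells=100, seed=3))
        assert a == b

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_cells=-1),
            dict(phase_fractions=(0.5, 0.5, 0.5)),
            dict(phase_fractions=(1.2, -0.1, -0.1)),
            dict(accessible_fraction=0.0),
            dict(accessible_fraction=1.5),
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            ca.sample_population(ca.PopulationParams(**bad))


class TestDyeResponse:
    def test_bell_maximum_at_d_opt(self):
        dye = ca.DyeModel(response_shape="bell", d_opt=50)
        assert ca.dye_response(50, dye) == pytest.approx(1.0)

    def test_bell_at_twice_d_opt(self):
        dye = ca.DyeModel(response_shape="bell", d_opt=50)
        assert ca.dye_response(100, dye) == pytest.approx(2 * math.exp(-1))

    def test_zero_dose_gives_zero(self):
        assert ca.dye_response(0, ca.DyeModel(response_shape="linear")) == 0.0
        assert ca.dye_response(0, ca.DyeModel(response_shape="bell")) == 0.0

    def test_linear_saturates_at_d_ref(self):
        dye = ca.DyeModel(response_shape="linear", d_ref=2.0)
        assert ca.dye_response(1.0, dye) == pytest.approx(0.5)
        assert ca.dye_response(5.0, dye) == 1.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ca.dye_response(-1, ca.DyeModel())


class TestCellSignal:
    def _cell(self, dna=1.0, af=0.5, area=100.0):
        r = math.sqrt(area / math.pi)
        return ca.CellGroundTruth(0, "G1", dna, af, axes=(r, r))

    def test_direct_formula(self):
        dye = ca.DyeModel(brightness=200, response_shape="linear", staining_dose=1, d_ref=1)
        ppm, total = ca.cell_signal(self._cell(), dye)
        assert total == pytest.approx(100.0)
        assert ppm == pytest.approx(1.0)

    def test_zero_accessibility_gives_zero(self):
        cell = self._cell(af=1e-6)
        _, total = ca.cell_signal(cell, ca.DyeModel())
        assert total == pytest.approx(0.0, abs=1e-6 * ca.DyeModel().brightness * 2)

    def test_doubling_dna_doubles_total_not_mean(self):
        dye = ca.DyeModel()
        p1, t1 = ca.cell_signal(self._cell(dna=1, area=100), dye)
        p2, t2 = ca.cell_signal(self._cell(dna=2, area=200), dye)
        assert t2 == pytest.approx(2 * t1)
        assert p2 == pytest.approx(p1)


class TestRenderWell:
    def test_zero_cells_background_only(self):
        rp = ca.RenderParams(seed=1)
        img, labels, truth = ca.render_well([], ca.DyeModel(), rp)
        assert (img == rp.background_level).all()
        assert labels.max() == 0 and len(truth) == 0
        assert ca.segment_nuclei(img).max() == 0

    def test_rendered_integral_matches_analytic_total(self, noise_free_well):
        img, labels, truth = noise_free_well
        bg = 200.0
        for _, t in truth.iterrows():
            mask = labels == (t.cell_id + 1)
            rendered = (img[mask].astype(float) - bg).sum()
            assert abs(rendered - t.total) <= 0.5 * t.pixel_count  # quantisation
            assert rendered == pytest.approx(t.total, rel=0.01)

    def test_separated_nuclei_give_expected_component_count(self, noise_free_well):
        from scipy import ndimage

        img, labels, truth = noise_free_well
        n, _ = ndimage.label(img > 200, structure=np.ones((3, 3)))[1], None
        _, count = ndimage.label(img > 200, structure=np.ones((3, 3)))
        assert count == len(truth) == 50

    def test_out_of_frame_cell_rejected(self):
        cell = ca.CellGroundTruth(0, "G1", 1.0, 0.3, axes=(9.0, 9.0), center_xy=(4.0, 50.0))
        with pytest.raises(ValueError, match="fit"):
            ca.render_well([cell], ca.DyeModel(), ca.RenderParams(seed=0))

    def test_rnase_property(self):
        """Without RNase the area outside nuclei carries extra signal; with it, none."""
        p = ca.PopulationParams(n_cells=20, seed=9, cytoplasm_signal=300.0)
        rp = ca.RenderParams(seed=10)
        for rnase, extra in [(True, False), (False, True)]:
            cells = ca.sample_population(p)
            dye = ca.DyeModel(rnase_applied=rnase)
            img, labels, _ = ca.render_well(cells, dye, rp)
            outside = img[labels == 0].astype(float)
            excess = outside.mean() - rp.background_level
            if extra:
                assert excess > 10.0
            else:
                assert abs(excess) <= 1.0


class TestSaturationProperty:
    def test_fold_change_non_increasing_with_brightness(self):
        """Detector clipping shrinks the measured effect of opening chromatin."""

        def pop_median(af, brightness, seed):
            dye = ca.DyeModel(brightness=brightness)
            cells = ca.sample_population(
                ca.PopulationParams(n_cells=2000, accessible_fraction=af, seed=seed)
            )
            sig = ca.population_signals(cells, dye)
            clipped = np.minimum(sig["mean"], dye.detector_max)
            return float(np.median(clipped))

        folds = [
            pop_median(0.45, b, 5) / pop_median(0.30, b, 4)
            for b in [1e7, 3e7, 6e7, 1.2e8, 2.4e8]
        ]
        assert all(folds[i + 1] <= folds[i] + 1e-9 for i in range(len(folds) - 1))
        assert folds[0] == pytest.approx(1.5, rel=0.05)
        assert folds[-1] == pytest.approx(1.0, rel=0.01)


class TestGeneratePlate:
    def test_layout_and_file_counts(self, demo_plate):
        out, layout, truth = demo_plate
        assert len(layout) == 8
        assert sorted(layout["condition"].unique()) == ["control", "treated"]
        for _, row in layout.iterrows():
            assert (out / f"plate1_{row['well']}_dna.tif").exists()
            assert (out / f"plate1_{row['well']}_edu.tif").exists()

    def test_truth_tables_identical_for_same_seed(self, tmp_path):
        conds = [ConditionSpec("c", ca.PopulationParams(n_cells=10), n_wells=2)]
        rp = ca.RenderParams(seed=0)
        _, t1 = ca.generate_plate(conds, rp, tmp_path / "a", seed=5)
        _, t2 = ca.generate_plate(conds, rp, tmp_path / "b", seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert (tmp_path / "a" / "plate1_truth.csv").read_bytes() == (
            tmp_path / "b" / "plate1_truth.csv"
        ).read_bytes()

    def test_duplicate_condition_names_rejected(self, tmp_path):
        conds = [
            ConditionSpec("c", ca.PopulationParams(n_cells=5)),
            ConditionSpec("c", ca.PopulationParams(n_cells=5)),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            ca.generate_plate(conds, ca.RenderParams(), tmp_path, seed=0)

    def test_edu_foreground_only_inside_s_phase_nuclei(self, demo_plate):
        import tifffile

        out, layout, truth = demo_plate
        well = layout.iloc[0]["well"]
        edu = tifffile.imread(out / f"plate1_{well}_edu.tif").astype(float)
        sub = truth[truth["well"] == well]
        # EdU-positive nuclei are bright, negative nuclei near background
        for _, t in sub.iterrows():
            r, c = int(round(t.center_row)), int(round(t.center_col))
            val = edu[r, c] - 200.0
            if t.edu_positive:
                assert val > 1000
            else:
                assert val < 200
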