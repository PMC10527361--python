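"""Quantification recipe: background subtraction, exposure integration,
ATP correction, log2, plate normalization, replicate averaging, the >30%
increase filter, and strip-paired LFCs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinaprof import preprocess as pp
from kinaprof import simulate as sim
from kinaprof.errors import InvalidArgumentError, MissingControlError, PairingError

from conftest import array_meta, make_spot_table


class TestNetSignal:
    @pytest.mark.parametrize(
        "intensity,background,expected", [(150, 50, 100.0), (40, 90, 1.0), (0, 0, 1.0)]
    )
    def test_subtraction_with_floor(self, intensity, background, expected):
        assert pp.net_signal(intensity, background) == expected

    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_matches_direct_formula(self, i, b):
        assert pp.net_signal(i, b) == max(i - b, 1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.net_signal(-1.0, 0.0)


class TestIntegrateExposures:
    def test_exact_for_linear_series(self):
        assert pp.integrate_exposures([(10, 100), (20, 200), (50, 500)]) == pytest.approx(1000.0)

    def test_zero_signal_integrates_to_zero(self):
        assert pp.integrate_exposures([(10, 0), (20, 0)]) == 0.0

    def test_single_exposure_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.integrate_exposures([(10, 100), (10, 120)])

    @given(st.lists(st.floats(0, 1e4), min_size=3, max_size=8))
    def test_matches_closed_form_slope(self, ys):
        times = np.arange(1.0, len(ys) + 1) * 10.0
        expected = (times @ np.array(ys)) / (times @ times) * 100.0
        got = pp.integrate_exposures(list(zip(times, ys)))
        assert got == pytest.approx(expected, abs=1e-10)


class TestAtpCorrectAndLog:
    def _plate(self, arrays):
        return make_spot_table(arrays)

    def test_basic_correction(self):
        spot = self._plate(
            [
                (array_meta(array="P1:A01", atp=True), {"pep_001": 33.0}),
                (array_meta(array="P1:A02", atp=True), {"pep_001": 33.0}),
                (array_meta(array="P1:A03", atp=False), {"pep_001": 1.0}),
            ]
        )
        out = pp.atp_correct_and_log(spot)
        assert out.iloc[0, 0] == pytest.approx(np.log2(32.0))

    def test_no_atp_dominating_floors_to_zero(self):
        spot = self._plate(
            [
                (array_meta(array="P1:A01", atp=True), {"pep_001": 5.0}),
                (array_meta(array="P1:A02", atp=True), {"pep_001": 5.0}),
                (array_meta(array="P1:A03", atp=False), {"pep_001": 9.0}),
            ]
        )
        out = pp.atp_correct_and_log(spot)
        assert out.iloc[0, 0] == 0.0

    def test_duplicates_averaged_after_correction(self):
        spot = self._plate(
            [
                (array_meta(array="P1:A01", atp=True), {"pep_001": 19.0}),
                (array_meta(array="P1:A02", atp=True), {"pep_001": 49.0}),
                (array_meta(array="P1:A03", atp=False), {"pep_001": 2.0}),
            ]
        )
        out = pp.atp_correct_and_log(spot)
        # corrected duplicates (17, 47) average to 32 before the log
        assert out.iloc[0, 0] == pytest.approx(5.0)

    def test_missing_control_names_the_sample(self):
        spot = self._plate(
            [
                (array_meta(array="P1:A01", atp=True), {"pep_001": 19.0}),
                (array_meta(array="P1:A02", atp=True, sample="S02"), {"pep_001": 19.0}),
                (array_meta(array="P1:A03", atp=False, sample="S02"), {"pep_001": 2.0}),
            ]
        )
        with pytest.raises(MissingControlError, match="S01"):
            pp.atp_correct_and_log(spot)


class TestNormalizePlates:
    def test_constant_offset_between_plates_removed(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(8, 1, size=(4, 6)))
        values = pd.concat([a, a + 1.0], ignore_index=True)
        plates = pd.Series(["A"] * 4 + ["B"] * 4)
        out = pp.normalize_plates(values, plates)
        assert np.allclose(out.iloc[:4].to_numpy(), out.iloc[4:].to_numpy())

    def test_single_plate_is_identity(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(5, 7)))
        out = pp.normalize_plates(values, pd.Series(["A"] * 5))
        assert np.allclose(out.to_numpy(), values.to_numpy())

    def test_per_plate_medians_equal_grand_median(self):
        rng = np.random.default_rng(2)
        frames, plates = [], []
        for i, offset in enumerate(rng.normal(0, 2, size=3)):
            frames.append(pd.DataFrame(rng.normal(8 + offset, 1, size=(4, 9))))
            plates.extend([f"P{i}"] * 4)
        values = pd.concat(frames, ignore_index=True)
        out = pp.normalize_plates(values, pd.Series(plates))
        grand = np.median(out.to_numpy())
        for p in set(plates):
            rows = [i for i, q in enumerate(plates) if q == p]
            assert np.median(out.iloc[rows].to_numpy()) == pytest.approx(grand)

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.normalize_plates(pd.DataFrame(), pd.Series(dtype=str))


class TestAverageReplicates:
    def test_two_replicates_average(self):
        values = pd.DataFrame(
            [[4.0], [6.0]],
            index=pd.MultiIndex.from_tuples(
                [("S01", 1), ("S01", 2)], names=["sample_id", "replicate_id"]
            ),
        )
        out = pp.average_replicates(values)
        assert out.loc["S01"].iloc[0] == 5.0

    def test_single_replicate_unchanged(self):
        values = pd.DataFrame(
            [[3.5, 2.0]],
            index=pd.MultiIndex.from_tuples([("S01", 1)], names=["sample_id", "replicate_id"]),
        )
        out = pp.average_replicates(values)
        assert np.allclose(out.to_numpy(), values.to_numpy())

    def test_matches_per_cell_mean_oracle(self):
        rng = np.random.default_rng(3)
        idx = pd.MultiIndex.from_product(
            [[f"S{i}" for i in range(5)], [1, 2]], names=["sample_id", "replicate_id"]
        )
        values = pd.DataFrame(rng.normal(size=(10, 4)), index=idx)
        out = pp.average_replicates(values)
        for s in values.index.get_level_values(0).unique():
            expected = values.xs(s, level="sample_id").mean(axis=0)
            assert np.allclose(out.loc[s], expected)

    def test_missing_replicates_ignored_not_imputed(self):
        idx = pd.MultiIndex.from_tuples(
            [("S01", 1), ("S01", 2)], names=["sample_id", "replicate_id"]
        )
        values = pd.DataFrame([[4.0], [np.nan]], index=idx)
        assert pp.average_replicates(values).loc["S01"].iloc[0] == 4.0


class TestFilterPeptides:
    def _arrays(self, fractions, n_arrays=10):
        cols = {}
        for i, f in enumerate(fractions):
            n_up = round(f * n_arrays)
            cols[f"pep_{i:03d}"] = [1.0] * n_up + [-1.0] * (n_arrays - n_up)
        return pd.DataFrame(cols)

    def test_strictly_greater_than_threshold(self):
        kept, report = pp.filter_peptides(self._arrays([0.0, 0.3, 0.4, 1.0]))
        assert kept == ["pep_002", "pep_003"]  # 0.40 and 1.00 pass; 0.30 is strict
        r = report.set_index("peptide_id")
        assert not r.loc["pep_001", "kept"] and r.loc["pep_001", "fraction_increasing"] == 0.3
        assert not r.loc["pep_000", "atp_dependent"]

    def test_kept_implies_atp_dependent(self):
        rng = np.random.default_rng(4)
        arrays = pd.DataFrame(rng.normal(size=(20, 30)))
        _, report = pp.filter_peptides(arrays)
        assert (report.loc[report["kept"], "atp_dependent"]).all()
        assert (report.loc[report["kept"], "fraction_increasing"] > 0.30).all()

    def test_no_arrays_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pp.filter_peptides(pd.DataFrame(columns=["pep_001"]))


class TestComputeLfc:
    def _pair(self, control, inhibitor, strip="P1:S01", sample="T01", replicate=1):
        return [
            (
                array_meta(
                    strip=strip, array=f"{strip}:A1", sample=sample,
                    treatment="none", replicate=replicate,
                ),
                control,
            ),
            (
                array_meta(
                    strip=strip, array=f"{strip}:A2", sample=sample,
                    treatment="dab", replicate=replicate,
                ),
                inhibitor,
            ),
        ]

    def test_no_change_gives_zero(self):
        spot = make_spot_table(self._pair({"pep_001": 64.0}, {"pep_001": 64.0}))
        lfc = pp.compute_lfc(spot)
        assert lfc.values.iloc[0, 0] == 0.0

    def test_halving_gives_minus_one(self):
        spot = make_spot_table(self._pair({"pep_001": 64.0}, {"pep_001": 32.0}))
        assert pp.compute_lfc(spot).values.iloc[0, 0] == pytest.approx(-1.0)

    def test_replicate_strips_averaged(self):
        arrays = self._pair({"pep_001": 64.0}, {"pep_001": 32.0}, strip="P1:S01", replicate=1)
        arrays += self._pair(
            {"pep_001": 64.0}, {"pep_001": 64.0 * 2**-0.5}, strip="P1:S02", replicate=2
        )
        lfc = pp.compute_lfc(make_spot_table(arrays))
        assert lfc.values.iloc[0, 0] == pytest.approx(-0.75)

    def test_antisymmetric_under_condition_swap(self):
        fwd = make_spot_table(self._pair({"pep_001": 80.0}, {"pep_001": 20.0}))
        rev = make_spot_table(self._pair({"pep_001": 20.0}, {"pep_001": 80.0}))
        a = pp.compute_lfc(fwd).values.iloc[0, 0]
        b = pp.compute_lfc(rev).values.iloc[0, 0]
        assert a == pytest.approx(-b)

    def test_unpaired_strip_names_the_strip(self):
        solo = make_spot_table(
            [
                (
                    array_meta(strip="P1:S09", array="P1:S09:A1", treatment="none"),
                    {"pep_001": 64.0},
                ),
                *self._pair({"pep_001": 64.0}, {"pep_001": 32.0}),
            ]
        )
        with pytest.raises(PairingError, match="S09"):
            pp.compute_lfc(solo)


class TestEndToEnd:
    def test_zero_noise_recovery_matches_planted_rates(self, small_config, small_map):
        cfg = small_config.with_(noise_sd=0.0, plate_effect_sd=0.0, nonspecific_fraction=0.0)
        spot, _, truth = sim.simulate_cohort(cfg, small_map)
        matrix, _ = pp.process_cohort(spot, apply_filter=False)
        t = np.asarray(cfg.exposure_times_ms)
        floored_zero = 100.0 * t.sum() / (t @ t)  # a zero-rate ladder integrates to this
        expected = np.log2(np.maximum(truth.peptide_rates * 100.0 - floored_zero, 1.0))
        assert np.allclose(
            matrix.values.to_numpy(), expected.loc[matrix.values.index].to_numpy(), atol=1e-12
        )

    def test_planted_class_effect_recovered(self, small_map):
        cfg = sim.SimulationConfig(
            n_benign=10, n_malignant=10, n_peptides=40, n_kinases=4,
            substrates_per_kinase=5, n_plates=1, noise_sd=0.1,
            class_effect_size=1.0, n_active_kinases=1, seed=21,
        )
        spot, sheet, truth = sim.simulate_cohort(cfg, small_map)
        matrix, _ = pp.process_cohort(spot)
        subs = small_map.loc[
            small_map["kinase_id"].isin(truth.active_kinases), "peptide_id"
        ]
        subs = [s for s in subs if s in matrix.values.columns]
        lab = sheet.set_index("sample_id").loc[matrix.values.index, "class_label"]
        diff = (
            matrix.values.loc[(lab == "malignant").to_numpy(), subs].mean().mean()
            - matrix.values.loc[(lab == "benign").to_numpy(), subs].mean().mean()
        )
        assert diff == pytest.approx(1.0, abs=0.15)

    def test_plate_scale_injection_only_shifts_by_a_constant(self, small_config, small_map):
        # keep every corrected value well above the unit floors: floored
        # cells are scale-invariant and would break the clean shift
        cfg = small_config.with_(
            nonspecific_fraction=0.4,
            inactive_peptide_fraction=0.0,
            basal_rate_range=(0.5, 1.0),
            noise_sd=0.1,
        )
        spot, _, _ = sim.simulate_cohort(cfg, small_map)
        base, _ = pp.process_cohort(spot, apply_filter=False)
        plate = spot["plate_id"].iloc[-1]
        scaled = spot.copy()
        on = scaled["plate_id"] == plate
        scaled.loc[on, "intensity"] *= 3.0
        scaled.loc[on, "local_background"] *= 3.0
        out, _ = pp.process_cohort(scaled, apply_filter=False)
        delta = out.values.to_numpy() - base.values.to_numpy()
        assert np.ptp(delta) == pytest.approx(0.0, abs=1e-9)

    def test_sample_permutation_equivariance(self, small_cohort):
        spot, _, _ = small_cohort
        base, _ = pp.process_cohort(spot)
        shuffled = spot.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out, _ = pp.process_cohort(shuffled)
        pd.testing.assert_frame_equal(
            base.values.sort_index(), out.values.sort_index()[base.values.columns]
        )
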