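"""DVH construction, Dx%/Dvcc interpolation, conformity and renormalization."""

import numpy as np
import pytest

from pctqa import (
    DVHCurve,
    compute_dvh,
    conformity_indices,
    dose_at_absolute_volume,
    dose_at_volume,
    dvh_metric_table,
    dvh_metrics,
    normalize_to_d95,
    structure_volume_cc,
    volume_fraction_at_dose,
)

from conftest import make_mask, make_volume


def uniform_dose(value, shape=(5, 5, 5)):
    return make_volume(np.full(shape, float(value)), modality="dose")


FULL = np.ones((5, 5, 5), dtype=bool)


class TestCompute:
    def test_uniform_structure_is_step_function(self):
        dvh = compute_dvh(uniform_dose(20.0), make_mask(FULL))
        assert volume_fraction_at_dose(dvh, 10.0) == 1.0
        assert volume_fraction_at_dose(dvh, 25.0) == 0.0

    def test_two_voxel_enumeration(self):
        vals = np.zeros((2, 1, 1))
        vals[0], vals[1] = 10.0, 20.0
        dvh = compute_dvh(make_volume(vals, modality="dose"), make_mask(np.ones((2, 1, 1), bool)))
        assert volume_fraction_at_dose(dvh, 5.0) == 1.0
        assert volume_fraction_at_dose(dvh, 15.0) == 0.5
        assert volume_fraction_at_dose(dvh, 25.0) == 0.0

    def test_differential_bins_conserve_volume(self, default_case):
        ptv = default_case.ptv_masks[0]
        dvh = compute_dvh(default_case.dose_ct, ptv)
        assert dvh.differential_cc.sum() == pytest.approx(
            structure_volume_cc(ptv), abs=1e-9
        )

    def test_cumulative_monotone_nonincreasing(self, default_case):
        dvh = compute_dvh(default_case.dose_ct, default_case.structures["brain"])
        assert (np.diff(dvh.cumulative_fraction) <= 1e-12).all()
        assert dvh.cumulative_fraction[0] == 1.0


class TestDoseAtVolume:
    def test_uniform_dose_all_percentiles_equal(self):
        dvh = compute_dvh(uniform_dose(20.0), make_mask(FULL))
        for x in (50.0, 95.0):
            assert dose_at_volume(dvh, x) == pytest.approx(20.0, abs=dvh.bin_width)

    def test_linear_cumulative_curve_inverse(self):
        # cumulative falling linearly from (0 Gy, 1) to (30 Gy, 0): D50% = 15
        edges = np.linspace(0.0, 30.0, 301)
        diff = np.full(300, 1.0 / 300)
        cum = 1.0 - edges / 30.0
        dvh = DVHCurve(edges, diff, cum, "PTV", 1.0)
        assert dose_at_volume(dvh, 50.0) == pytest.approx(15.0, abs=1e-9)
        assert dose_at_volume(dvh, 95.0) == pytest.approx(1.5, abs=1e-9)

    def test_dx_nonincreasing_in_x(self, default_case):
        dvh = compute_dvh(default_case.dose_ct, default_case.ptv_masks[0])
        doses = [dose_at_volume(dvh, x) for x in (5, 25, 50, 75, 95, 100)]
        assert all(a >= b - 1e-12 for a, b in zip(doses, doses[1:]))

    def test_out_of_range_rejected(self):
        dvh = compute_dvh(uniform_dose(10.0), make_mask(FULL))
        for bad in (0.0, 101.0):
            with pytest.raises(ValueError):
                dose_at_volume(dvh, bad)


class TestDoseAtAbsoluteVolume:
    def test_uniform(self):
        # 125 voxels at 1 mm = 0.125 cc
        dvh = compute_dvh(uniform_dose(20.0), make_mask(FULL))
        assert dose_at_absolute_volume(dvh, 0.1) == pytest.approx(20.0, abs=dvh.bin_width)

    def test_half_and_half_enumeration(self):
        # 1 cc structure: half at 10 Gy, half at 30 Gy -> dose at 0.4 cc = 30
        vals = np.full((10, 10, 10), 10.0)
        vals[:5] = 30.0
        dvh = compute_dvh(
            make_volume(vals, modality="dose"), make_mask(np.ones((10, 10, 10), bool))
        )
        assert dvh.total_volume_cc == pytest.approx(1.0)
        assert dose_at_absolute_volume(dvh, 0.4) == pytest.approx(30.0, abs=2 * dvh.bin_width)

    def test_d01cc_bounded_by_dmax(self, default_case):
        m = dvh_metrics(default_case.dose_ct, default_case.ptv_masks[0])
        assert m.D0_1cc <= m.Dmax + 1e-9

    def test_volume_beyond_structure_rejected(self):
        dvh = compute_dvh(uniform_dose(10.0), make_mask(FULL))
        with pytest.raises(ValueError):
            dose_at_absolute_volume(dvh, 1.0)


class TestConformity:
    def test_exact_prescription_box(self):
        dose = np.zeros((10, 10, 10))
        dose[3:6, 3:6, 3:6] = 20.0
        ptv = np.zeros((10, 10, 10), dtype=bool)
        ptv[3:6, 3:6, 3:6] = True
        vol = make_volume(dose, modality="dose")
        r100, r50 = conformity_indices(
            vol, make_mask(ptv), make_mask(np.ones((10, 10, 10), bool), role="body"), 20.0
        )
        assert (r100, r50) == (1.0, 1.0)

    def test_half_dose_shell_bookkeeping(self):
        # shell of twice the PTV volume at >= PD/2 around the PTV: R50 = 3
        dose = np.zeros((12, 12, 12))
        ptv = np.zeros((12, 12, 12), dtype=bool)
        ptv[5:7, 5:7, 5:7] = True  # 8 voxels
        dose[ptv] = 20.0
        shell = np.zeros_like(ptv)
        shell.ravel()[:24] = True  # 16 extra voxels anywhere in the body
        shell[5:7, 5:7, 5:7] = False
        shell_idx = np.argwhere(shell)[:16]
        shell = np.zeros_like(ptv)
        shell[tuple(shell_idx.T)] = True
        dose[shell] = 10.0
        vol = make_volume(dose, modality="dose")
        r100, r50 = conformity_indices(
            vol, make_mask(ptv), make_mask(np.ones((12, 12, 12), bool), role="body"), 20.0
        )
        assert r100 == pytest.approx(1.0)
        assert r50 == pytest.approx(3.0)

    def test_single_lesion_r50_low_single_digits(self, default_case):
        r100, r50 = conformity_indices(
            default_case.dose_ct,
            default_case.ptv_masks[0],
            default_case.structures["body"],
            21.0,
        )
        assert r50 >= r100 >= 0
        assert 1.0 <= r50 <= 10.0  # same order as clinical gradient indices


class TestNormalizeToD95:
    def test_fixed_point(self):
        vol = uniform_dose(20.0)
        mask = make_mask(FULL)
        dvh = compute_dvh(vol, mask)
        d95 = dose_at_volume(dvh, 95.0)
        out, factor = normalize_to_d95(vol, mask, d95)
        assert factor == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.values, vol.values)

    def test_scalar_proportionality(self):
        out, factor = normalize_to_d95(uniform_dose(10.0), make_mask(FULL), 20.0)
        # uniform 10 Gy: D95 sits within a bin of 10, doubling all doses
        assert factor == pytest.approx(2.0, rel=1e-3)
        np.testing.assert_allclose(out.values, 10.0 * factor)

    def test_v100_equals_95pct_after_renormalization(self, default_case):
        ptv = default_case.ptv_masks[0]
        out, _ = normalize_to_d95(default_case.dose_ct, ptv, 21.0)
        dvh = compute_dvh(out, ptv)
        assert 100.0 * volume_fraction_at_dose(dvh, 21.0) == pytest.approx(95.0, abs=1.0)


class TestMetricTable:
    def test_identical_dose_pair_zero_deviation(self, default_case):
        case = default_case
        case2 = type(case)(
            case.ct, case.pct, case.dose_ct, case.dose_ct, case.structures,
            dict(case.manifest),
        )
        df = dvh_metric_table(case2)
        ok = df[~df["missing"]]
        assert (ok["deviation"].abs() < 1e-12).all()

    def test_global_scale_shifts_gy_metrics_linearly(self, default_case):
        from pctqa import perturb_dose

        case = default_case
        scaled = perturb_dose(case.dose_ct, scale=1.01)
        case2 = type(case)(
            case.ct, case.pct, case.dose_ct, scaled, case.structures, dict(case.manifest)
        )
        df = dvh_metric_table(case2, renormalize=False)
        gy = df[~df["missing"] & ~df["metric"].isin(["R100%", "R50%"])]
        # voxel metrics are exactly linear; curve-interpolated ones to a bin
        np.testing.assert_allclose(
            gy["value_pCT"], gy["value_CT"] * 1.01, rtol=1e-6, atol=2 * 0.01
        )
        ptv = df[(df["structure"] == "PTV") & df["metric"].str.endswith("/PD")]
        np.testing.assert_allclose(ptv["value_pCT"], ptv["value_CT"] * 1.01, rtol=1e-9)

    def test_ptv_dmax_ratio_near_inverse_isodose(self, default_case):
        df = dvh_metric_table(default_case, renormalize=False)
        dmax = df[(df["structure"] == "PTV") & (df["metric"] == "Dmax/PD")]
        assert dmax["value_CT"].iloc[0] == pytest.approx(1.25, rel=0.03)

    def test_missing_structure_flagged_not_fatal(self, default_case):
        case = default_case
        structures = {
            k: v for k, v in case.structures.items() if k != "spinal_cord"
        }
        case2 = type(case)(
            case.ct, case.pct, case.dose_ct, case.dose_pct, structures, dict(case.manifest)
        )
        df = dvh_metric_table(case2)
        assert df[(df["structure"] == "spinal_cord")]["missing"].all()


class TestSortingOracle:
    def test_histogram_metrics_match_direct_sorting(self):
        """For small structures, Dx% from the binned cumulative curve agrees
        with direct quantiles of the sorted voxel doses within one bin."""
        rng = np.random.default_rng(12)
        vals = rng.gamma(4.0, 2.0, (12, 12, 12))
        vol = make_volume(vals, modality="dose")
        mask = make_mask(np.ones((12, 12, 12), bool))
        dvh = compute_dvh(vol, mask)
        sv = np.sort(vals.ravel())[::-1]  # hottest first
        n = sv.size
        for x in (10.0, 50.0, 90.0):
            direct = sv[min(int(np.ceil(x / 100 * n)) - 1, n - 1)]
            assert dose_at_volume(dvh, x) == pytest.approx(direct, abs=2 * dvh.bin_width)


class TestProperties:
    """Seeded hypothesis property checks on the DVH primitives."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(0.0, 40.0), min_size=8, max_size=64),
        st.floats(1.0, 99.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dose_at_volume_inverts_volume_at_dose(self, doses, x):
        import numpy as np

        n = len(doses)
        vals = np.array(doses).reshape(n, 1, 1)
        dvh = compute_dvh(
            make_volume(vals, modality="dose"), make_mask(np.ones((n, 1, 1), bool))
        )
        d = dose_at_volume(dvh, x)
        frac = volume_fraction_at_dose(dvh, d)
        # inverse within one bin width along the dose axis
        d_back = dose_at_volume(dvh, max(min(100.0 * frac, 100.0), 1e-9))
        assert abs(d_back - d) <= dvh.bin_width + 1e-9

    @given(st.lists(st.floats(0.1, 40.0), min_size=4, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metrics_invariant_under_voxel_permutation(self, doses):
        import numpy as np

        n = len(doses)
        rng = np.random.default_rng(0)
        a = np.array(doses)
        b = a[rng.permutation(n)]
        mask = make_mask(np.ones((n, 1, 1), bool))
        d1 = compute_dvh(make_volume(a.reshape(n, 1, 1), modality="dose"), mask)
        d2 = compute_dvh(make_volume(b.reshape(n, 1, 1), modality="dose"), mask)
        np.testing.assert_allclose(d1.differential_cc, d2.differential_cc)
        assert dose_at_volume(d1, 50.0) == dose_at_volume(d2, 50.0)
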