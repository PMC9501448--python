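"""SNR, calibration, relaxation weighting, partial volume and the aTSC chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natendon.datamodel import (
    LabelMap,
    Nucleus,
    PHANTOM_RELAXATION,
    RelaxationParams,
    Role,
    StudyConfig,
    TENDON_RELAXATION,
    VIAL_ROLES,
    Volume3D,
)
from natendon.phantom import CompartmentSpec, Phantom, PhantomSpec
from natendon.quantify import (
    compute_atsc,
    compute_snr,
    fit_calibration,
    partial_volume_fraction,
    relaxation_weighting_factor,
)
from natendon.roi import transfer_mask

from conftest import small_spec, tube_mask


class TestSNR:
    def _setup(self, roi_values, noise_values):
        n = len(roi_values) + len(noise_values)
        side = int(np.ceil(n ** (1 / 3))) + 1
        data = np.zeros((side, side, side))
        labels = np.zeros((side, side, side), np.int32)
        flat_idx = np.unravel_index(np.arange(n), data.shape)
        values = np.concatenate([roi_values, noise_values])
        data[flat_idx] = values
        labels[tuple(i[: len(roi_values)] for i in flat_idx)] = 1
        labels[tuple(i[len(roi_values):] for i in flat_idx)] = 99
        vol = Volume3D(data, (2, 2, 2))
        lm = LabelMap(labels, (2, 2, 2), legend={1: "INS", 99: "NOISE"})
        return vol, lm

    def test_snr_is_mean_over_noise_sd(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 10, 500)
        vol, lm = self._setup(np.full(50, 117.0), noise)
        stats = compute_snr(vol, lm, 1, lm, 99)
        assert stats.mean == pytest.approx(117.0 / noise.std(ddof=1), rel=1e-12)
        assert stats.n_voxels == 50

    def test_tiny_noise_roi_rejected(self):
        vol, lm = self._setup(np.full(10, 1.0), np.array([1.0]))
        with pytest.raises(ValueError, match="noise ROI"):
            compute_snr(vol, lm, 1, lm, 99, min_noise_voxels=1)

    def test_zero_noise_sd_rejected(self):
        vol, lm = self._setup(np.full(10, 1.0), np.full(200, 3.0))
        with pytest.raises(ValueError, match="zero standard deviation"):
            compute_snr(vol, lm, 1, lm, 99)

    def test_estimator_tracks_generator_truth(self, snr_phantom):
        """SNR estimate within 2 % of the requested generator SNR (20 seeds)."""
        ph = snr_phantom
        estimates = []
        for seed in range(20):
            vol = ph.render(rng=np.random.default_rng(seed))
            stats = compute_snr(vol, ph.coarse_mask, int(Role.TENDON),
                                ph.coarse_mask, int(Role.NOISE))
            estimates.append(stats.mean)
        assert np.mean(estimates) == pytest.approx(11.7, rel=0.02)


class TestCalibration:
    def test_exact_line(self):
        line = fit_calibration([100, 150, 200, 250], [50, 75, 100, 125])
        assert line.slope == pytest.approx(2.0, rel=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-9)
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_affine_equivariance(self):
        base = fit_calibration([100, 150, 200, 250], [50, 75, 100, 125])
        shifted = fit_calibration([107, 157, 207, 257], [50, 75, 100, 125])
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 7.0, rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = np.array([50.0, 75.0, 100.0, 125.0])
        y = 1.7 * x + 4.0 + rng.normal(0, 2.0, 4)
        line = fit_calibration(y, x)
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_calibration([1.0], [50.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration([1.0, 2.0], [50.0, 50.0])
        line = fit_calibration([250, 200, 150, 100], [50, 75, 100, 125])
        with pytest.raises(ValueError, match="slope"):
            line.invert(10.0)


class TestRelaxationWeighting:
    def test_limits(self):
        r = TENDON_RELAXATION["Total"]
        assert relaxation_weighting_factor(r, 1e9 * r.t1_ms, 0.0) == pytest.approx(1.0)
        rp = RelaxationParams(20.0, 5.0, 5.0, 0.999999)
        f = relaxation_weighting_factor(rp, 15.0, 3.0)
        assert f == pytest.approx((1 - math.exp(-15 / 20)) * math.exp(-3 / 5), rel=1e-5)

    def test_hand_oracle_tendon_vs_phantom(self):
        """Scalar hand evaluation; tissue factor exceeds the vial factor."""
        t = TENDON_RELAXATION["Total"]
        p = PHANTOM_RELAXATION
        f_t = relaxation_weighting_factor(t, 15.0, 0.1)
        f_p = relaxation_weighting_factor(p, 15.0, 0.1)
        oracle_t = (1 - math.exp(-15 / 20.4)) * (
            0.316 * math.exp(-0.1 / 1.4) + 0.684 * math.exp(-0.1 / 13.9)
        )
        oracle_p = (1 - math.exp(-15 / 38.5)) * (
            0.602 * math.exp(-0.1 / 6.0) + 0.398 * math.exp(-0.1 / 13.0)
        )
        assert f_t == pytest.approx(oracle_t, rel=1e-12)
        assert f_p == pytest.approx(oracle_p, rel=1e-12)
        assert f_t > f_p  # shorter tendon T1 recovers more signal per TR

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        t1=st.floats(1.0, 100.0),
        t2s=st.floats(0.1, 10.0),
        dt2=st.floats(0.0, 20.0),
        ps=st.floats(0.01, 0.99),
        tr=st.floats(1.0, 100.0),
        te=st.floats(0.0, 20.0),
    )
    def test_bounds_and_monotonicity(self, t1, t2s, dt2, ps, tr, te):
        r = RelaxationParams(t1, t2s, t2s + dt2, ps)
        f = relaxation_weighting_factor(r, tr, te)
        assert 0.0 < f <= 1.0
        f_longer_tr = relaxation_weighting_factor(r, tr * 1.5, te)
        # strictly increasing in TR until 1 - exp(-TR/T1) saturates in float64
        if math.exp(-tr / t1) > 1e-14:
            assert f_longer_tr > f
        else:
            assert f_longer_tr >= f
        assert relaxation_weighting_factor(r, tr, te + 1.0) < f


class TestPartialVolume:
    def test_exact_tiling_gives_fraction_one(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[0:4, 0:4, 0:8] = 1
        fine = LabelMap(labels, (1, 1, 1), legend={1: "INS"})
        pv = partial_volume_fraction(fine, 1, 2.0)
        assert pv.mean_fraction == 1.0
        assert pv.fractions.max() == 1.0

    def test_half_covered_voxel(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[:, :, 0] = 1  # 4 of 8 fine voxels
        fine = LabelMap(labels, (1, 1, 1), legend={1: "INS"})
        pv = partial_volume_fraction(fine, 1, 2.0, inclusion_threshold=0.5)
        assert pv.fractions[0, 0, 0] == 0.5
        assert pv.mean_fraction == 0.5

    def test_matches_counting_oracle(self):
        mask = tube_mask(center=(9.1, 10.8), radius=5.9)
        pv = partial_volume_fraction(mask, int(Role.TENDON), 2.0)
        oracle = np.zeros_like(pv.fractions)
        m = mask.labels > 0
        for i in range(oracle.shape[0]):
            for j in range(oracle.shape[1]):
                for k in range(oracle.shape[2]):
                    oracle[i, j, k] = m[2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2].sum() / 8.0
        np.testing.assert_array_equal(pv.fractions, oracle)
        assert 0.0 < pv.mean_fraction <= 1.0

    def test_mean_fraction_one_iff_fully_covered(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0:2, 0:2, 0:2] = 1
        fine = LabelMap(labels, (1, 1, 1), legend={1: "INS"})
        assert partial_volume_fraction(fine, 1, 2.0).mean_fraction == 1.0
        labels[0, 0, 0] = 0  # chip one fine voxel off
        fine2 = LabelMap(labels, (1, 1, 1), legend={1: "INS"})
        assert partial_volume_fraction(fine2, 1, 2.0).mean_fraction < 1.0

    def test_empty_roi_rejected(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[0, 0, 0] = 1
        fine = LabelMap(labels, (1, 1, 1), legend={1: "INS"})
        with pytest.raises(ValueError, match="empty"):
            partial_volume_fraction(fine, 1, 2.0, inclusion_threshold=0.5)


def _quantify_phantom(ph: Phantom, concentration: float, relax: RelaxationParams):
    """The noise-free quantification chain used by the inversion property."""
    vol = ph.render(Nucleus.NA23, 15.0, 0.1)
    coarse = transfer_mask(ph.fine_mask, ph.spec.coarse_voxel_mm, 0.5)
    strict = transfer_mask(ph.fine_mask, ph.spec.coarse_voxel_mm, 1.0)
    vial_means = [
        float(vol.data[strict.labels == int(role)].mean()) for role in VIAL_ROLES
    ]
    line = fit_calibration(vial_means, (50, 75, 100, 125))
    pv = partial_volume_fraction(ph.fine_mask, int(Role.TENDON),
                                 ph.spec.coarse_voxel_mm, 0.5)
    result = compute_atsc(
        vol, coarse, line,
        {"TENDON": relax, "Total": relax}, PHANTOM_RELAXATION,
        {"TENDON": pv, "Total": pv}, regions=("TENDON",),
    )
    return result


class TestAtscChain:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        cx=st.floats(20.0, 28.0),
        cy=st.floats(12.0, 20.0),
        radius=st.floats(3.0, 6.0),
        conc=st.floats(20.0, 150.0),
        t1=st.floats(10.0, 60.0),
        ps=st.floats(0.1, 0.9),
    )
    def test_exact_inversion_for_arbitrary_tubes(self, cx, cy, radius, conc, t1, ps):
        """Calibration -> relaxation -> partial-volume chain is exactly invertible.

        Noise-free, uniform sensitivity, block-average downsampling and empty
        surroundings: the recovered tendon aTSC equals the generating
        concentration for any tube placement and relaxation quadruple.
        """
        relax = RelaxationParams(t1, 1.2, 14.0, ps)
        comps = [
            CompartmentSpec(role=Role.TENDON, center_mm=(cx, cy, 57.5),
                            size_mm=(radius, radius, 95.0), concentration_mM=conc,
                            relaxation=relax, h1_amplitude=100.0),
        ]
        for role, c, x in zip(VIAL_ROLES, (50, 75, 100, 125), (8, 21, 34, 47)):
            comps.append(CompartmentSpec(role=role, center_mm=(float(x), 50.0, 60.0),
                                         size_mm=(5.0, 5.0, 36.0), concentration_mM=float(c)))
        spec = PhantomSpec(fov_mm=(64, 64, 120), compartments=tuple(comps))
        ph = Phantom(spec, StudyConfig())
        result = _quantify_phantom(ph, conc, relax)
        assert result.atsc["Total"].mean == pytest.approx(conc, rel=1e-9)
        assert result.atsc["TENDON"].mean == pytest.approx(conc, rel=1e-9)

    def test_zero_concentration_gives_zero(self):
        ph = Phantom(small_spec(tendon_concentration_mM=0.0), StudyConfig())
        result = _quantify_phantom(ph, 0.0, TENDON_RELAXATION["Total"])
        assert result.atsc["Total"].mean == pytest.approx(0.0, abs=1e-9)

    def test_falloff_corrected_recovery_within_2pct(self):
        """Sensitivity falloff + estimated-map correction recovers aTSC to 2 %."""
        from natendon.pipeline import AnalysisOptions, analyze_study
        from natendon.phantom import generate_study

        spec = small_spec(sensitivity_model="exp_falloff", sensitivity_depth_mm=80.0)
        bundle = generate_study(spec, StudyConfig(), seed=None)
        result = analyze_study(bundle, AnalysisOptions(fit_h1_map=False,
                                                       register_series=False))
        assert result.quant.atsc["Total"].mean == pytest.approx(82.2, rel=0.02)

    def test_negative_voxels_flagged_in_qc(self):
        from natendon.pipeline import AnalysisOptions, analyze_study
        from natendon.phantom import generate_study

        bundle = generate_study(small_spec(target_snr=11.7), StudyConfig(), seed=3)
        result = analyze_study(bundle, AnalysisOptions(fit_h1_map=False,
                                                       register_series=False))
        counts = result.quant.qc["negative_voxels"]
        assert set(counts) == {"INS", "MID", "MTJ", "Total"}
        assert all(v >= 0 for v in counts.values())

    def test_missing_region_relaxation_rejected(self, noise_free_phantom):
        ph = noise_free_phantom
        with pytest.raises(ValueError, match="missing tissue relaxation"):
            _ = compute_atsc(
                ph.render(Nucleus.NA23, 15.0, 0.1),
                transfer_mask(ph.fine_mask, 2.0, 0.5),
                fit_calibration([100, 150, 200, 250], [50, 75, 100, 125]),
                {"TENDON": TENDON_RELAXATION["Total"]},  # no "Total" entry
                PHANTOM_RELAXATION,
                {},
                regions=("TENDON",),
            )
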