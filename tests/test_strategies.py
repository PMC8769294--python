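"""Background and scattering corrections and the three strategy variants."""
import numpy as np
import pytest

from viatrace import (
    AbsorbanceImage,
    PixelDoseModel,
    SegmentationParams,
    background_level,
    run_strategy,
    scattering_offset,
    subtract_background,
    to_absorbance,
)
from viatrace.errors import InvalidInputError
from viatrace.phantom import (
    PhantomSpec,
    generate_experiment,
    random_cells,
    generate_field,
    treatment_to_dataset,
)
from viatrace.strategies import TreatmentDataset

PARAMS = SegmentationParams(sensitivity=0.45)
MODEL = PixelDoseModel(epsilon=2555.0, pixel_size=0.65)


def _field(role, seed, medium=0.3, n_cells=40, moles_fmol=0.0, ring_fmol=3.3):
    spec = PhantomSpec(seed=seed, medium_absorbance=medium)
    rng = np.random.default_rng(seed)
    cells = random_cells(
        rng,
        spec,
        moles=np.full(n_cells, moles_fmol * 1e-15),
        ring_moles=np.full(n_cells, ring_fmol * 1e-15),
    )
    spec = PhantomSpec(seed=seed, medium_absorbance=medium, cells=cells)
    trip = generate_field(spec)
    return to_absorbance(trip.I, trip.Imax, trip.Imin)


class TestBackgroundLevel:
    def test_stained_medium_recovered(self):
        A = _field("LT", seed=1, medium=0.30)
        assert background_level(A) == pytest.approx(0.30, abs=0.01)

    def test_unstained_medium_near_zero(self):
        A = _field("LD", seed=2, medium=0.0)
        assert background_level(A) == pytest.approx(0.0, abs=0.005)

    def test_constant_image_degenerate_fallback(self):
        A = AbsorbanceImage(np.full((128, 128), 0.42), pixel_size=0.65)
        assert background_level(A) == pytest.approx(0.42)

    def test_too_few_pixels_rejected(self):
        A = AbsorbanceImage(np.zeros((20, 20)), pixel_size=0.65)
        with pytest.raises(InvalidInputError):
            background_level(A)


class TestSubtractBackground:
    def test_zero_subtraction_is_identity(self):
        A = _field("LT", seed=3)
        out = subtract_background(A, 0.0)
        np.testing.assert_array_equal(out.pixels, A.pixels)

    def test_linearity_of_mean(self):
        A = _field("LT", seed=3)
        out = subtract_background(A, 0.1)
        assert out.pixels.mean() == pytest.approx(A.pixels.mean() - 0.1, rel=1e-12)

    def test_refit_after_subtraction_recenters_background(self):
        A = _field("LT", seed=4, medium=0.30)
        level = background_level(A)
        assert background_level(subtract_background(A, level)) == pytest.approx(
            0.0, abs=0.005
        )


class TestScatteringOffset:
    def test_gaussian_sample_peak_recovered(self):
        rng = np.random.default_rng(9)
        mu, sigma = scattering_offset(rng.normal(3.3e-15, 1.0e-15, 1000))
        assert mu == pytest.approx(3.3e-15, abs=0.1e-15)
        assert sigma == pytest.approx(1.0e-15, abs=0.15e-15)

    def test_identical_values_handled(self):
        mu, sigma = scattering_offset(np.full(100, 2.2e-15))
        assert mu == pytest.approx(2.2e-15)
        assert sigma == 0.0

    def test_self_consistency_after_subtraction(self):
        rng = np.random.default_rng(10)
        v = rng.normal(3.3e-15, 1.0e-15, 1000)
        mu, _ = scattering_offset(v)
        mu2, _ = scattering_offset(v - mu)
        assert mu2 == pytest.approx(0.0, abs=0.1e-15)

    def test_too_few_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            scattering_offset(np.ones(10))


@pytest.fixture(scope="module")
def small_experiment():
    """LT + DT, two fields each, noisy study conditions."""
    exp = generate_experiment(["LT", "DT"], seed=17, n_fields=2, cells_per_field=60)
    lt = treatment_to_dataset(exp["LT"], PARAMS, MODEL)
    dt = treatment_to_dataset(exp["DT"], PARAMS, MODEL)
    return exp, lt, dt


class TestRunStrategy:
    def test_strategy_ordering_on_dead_stained_cells(self, small_experiment):
        """Raw >= background-subtracted >= scattering-subtracted mean dye content."""
        _, lt, dt = small_experiment
        s1 = run_strategy(dt, 1)
        s2 = run_strategy(dt, 2)
        s3 = run_strategy(dt, 3, lt_reference=lt)
        assert s1.moles.mean() >= s2.moles.mean() >= s3.moles.mean()

    def test_strategy3_is_pure_shift_of_strategy2(self, small_experiment):
        _, lt, dt = small_experiment
        s2 = run_strategy(dt, 2)
        s3 = run_strategy(dt, 3, lt_reference=lt)
        assert len(s2.records) == len(s3.records)
        shifts = s2.moles - s3.moles
        np.testing.assert_allclose(shifts, s3.scattering_mu, rtol=1e-9)
        # molarity recomputed from corrected moles
        vols = np.array([r.volume_L for r in s3.records])
        np.testing.assert_allclose(s3.molarities, s3.moles / vols, rtol=1e-12)

    def test_strategy2_matches_strategy1_without_medium_dye(self):
        exp = generate_experiment(["LD"], seed=23, n_fields=2, cells_per_field=50)
        ld = treatment_to_dataset(exp["LD"], PARAMS, MODEL)
        s1 = run_strategy(ld, 1)
        s2 = run_strategy(ld, 2)
        # fitted background is ~0, so the two means agree to sub-fmol level
        assert abs(s1.moles.mean() - s2.moles.mean()) < 0.3e-15
        assert max(abs(l) for l in s2.background_levels) < 0.005

    def test_live_stained_cells_near_zero_after_full_correction(self):
        """Strategy 3 on LT (scattering ring only) returns ~0 fmol/cell."""
        tpl = PhantomSpec().noise_free()
        exp = generate_experiment(
            ["LT"], seed=31, template=tpl, n_fields=2, cells_per_field=60,
            ring_moles_sd=0.0,
        )
        lt = treatment_to_dataset(exp["LT"], PARAMS, MODEL)
        s3 = run_strategy(lt, 3, lt_reference=lt)
        assert abs(s3.moles.mean()) < 0.2e-15

    def test_missing_lt_reference_rejected(self, small_experiment):
        _, _, dt = small_experiment
        with pytest.raises(InvalidInputError):
            run_strategy(dt, 3)

    def test_unknown_strategy_rejected(self, small_experiment):
        _, _, dt = small_experiment
        with pytest.raises(InvalidInputError):
            run_strategy(dt, 4)

    def test_dead_cell_recovery_unbiased_across_seeds(self):
        """Recovered DT mean is unbiased within Monte-Carlo error over seeds."""
        from viatrace.experiments import dt_recovery_experiment

        errs = [
            dt_recovery_experiment(seed, n_fields=1, cells_per_field=80)[
                "recovered_fmol"
            ]
            - 20.0
            for seed in range(5)
        ]
        bias = np.mean(errs)
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        # small systematic deficit from sub-threshold ring tails is tolerated
        assert abs(bias) < max(2 * se, 0.05 * 20.0)
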