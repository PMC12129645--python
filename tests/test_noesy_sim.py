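import numpy as np
import pytest

from nusquant.errors import ParameterError
from nusquant.evaluate import quantify_fids
from nusquant.noesy_sim import (
    SpinSystem,
    make_default_spin_system,
    simulate_fids,
    simulate_integrals,
    subsample,
)
from nusquant.quantify import build_distance_table
from nusquant.schedules import generate_poisson_gap, generate_uniform


class TestSpinSystem:
    def test_default_system_shape(self, sys12):
        assert len(sys12.labels) == 12
        assert sys12.distance("H1", "H2") == 1.78
        d = sys12.distances[~np.eye(12, dtype=bool)]
        assert d.min() == 1.78
        assert d.max() <= 4.5
        assert (d > 3.5).sum() > 10  # several fragile long distances

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.78], [2.0, 0.0]])
        with pytest.raises(ParameterError):
            SpinSystem(("a", "b"), d, ("a", "b"))

    def test_reference_distance_mismatch_rejected(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        with pytest.raises(ParameterError):
            SpinSystem(("a", "b"), d, ("a", "b"))

    def test_pairs_enumeration(self, sys2):
        assert sys2.pairs() == [("H1", "H2")]


class TestSimulateIntegrals:
    def test_sixth_power_law(self, sys2):
        # a pair at twice the reference distance builds up 64x slower
        d = np.array(
            [
                [0.00, 1.78, 3.56],
                [1.78, 0.00, 3.00],
                [3.56, 3.00, 0.00],
            ]
        )
        system = SpinSystem(("H1", "H2", "H3"), d, ("H1", "H2"))
        series = simulate_integrals(system)
        tab = series.tables[0]
        ratio = tab.cross[("H1", "H3")] / tab.cross[("H1", "H2")]
        assert ratio == pytest.approx(1 / 64, rel=1e-12)

    def test_seeded_determinism(self, sys12):
        a = simulate_integrals(sys12, noise_sd=0.05, seed=42)
        b = simulate_integrals(sys12, noise_sd=0.05, seed=42)
        assert a.tables[0].cross == b.tables[0].cross

    def test_reference_pair_self_consistency(self, sys2):
        # noiseless initial-rate data returns the reference distance exactly
        series = simulate_integrals(sys2)
        table = build_distance_table(series)
        entry = table.entries[("H1", "H2")]
        assert entry.r_ab == pytest.approx(1.78, abs=1e-12)

    def test_models_agree_at_short_mixing_time(self):
        # matrix-exponential oracle vs initial-rate on a 3-spin chain;
        # second-order (spin-diffusion) terms are quadratic in sigma, so a
        # small sigma_ref keeps them below 5% at t=0.1 s
        d = np.array(
            [
                [0.00, 1.78, 3.56],
                [1.78, 0.00, 1.78],
                [3.56, 1.78, 0.00],
            ]
        )
        system = SpinSystem(("H1", "H2", "H3"), d, ("H1", "H2"))
        kw = dict(mixing_times=[0.1, 0.7], sigma_ref=0.01)
        a = simulate_integrals(system, model="initial_rate", **kw)
        b = simulate_integrals(system, model="relaxation_matrix", **kw)

        def rel(i, pair):
            return abs(
                a.tables[i].cross[pair] - b.tables[i].cross[pair]
            ) / abs(b.tables[i].cross[pair])

        for pair in [("H1", "H2"), ("H2", "H3"), ("H1", "H3")]:
            assert rel(0, pair) < 0.05
            assert rel(1, pair) > rel(0, pair)  # divergence grows with t

    def test_negative_noise_rejected(self, sys2):
        with pytest.raises(ParameterError):
            simulate_integrals(sys2, noise_sd=-0.1)


class TestSimulateFids:
    def test_seeded_determinism(self, sys2):
        a = simulate_fids(sys2, noise_sd=0.01, seed=5)
        b = simulate_fids(sys2, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.data[0], b.data[0])

    def test_single_pair_peak_count(self, sys2):
        # zero noise: exactly 4 peaks (2 diagonal + 2 cross) above threshold
        from nusquant.evaluate import process_2d

        fids = simulate_fids(sys2, grid_size=64, n_direct=64)
        spec = process_2d(fids.data[-1])
        thr = 0.05 * spec.max()
        hot = spec > thr
        # count connected regions via simple labelling
        from scipy.ndimage import label

        n_regions = label(hot)[1]
        assert n_regions == 4

    def test_amplitude_round_trip(self, sys2):
        # integrals of the processed uniform spectrum recover the input
        # amplitudes within 2% once the common lineshape factor is divided
        fids = simulate_fids(
            sys2, grid_size=128, n_direct=512, t1_decay=1.0, t2_decay=1.5
        )
        got = quantify_fids(fids)
        truth = simulate_integrals(sys2)
        ratios = []
        for i in range(len(got.mixing_times)):
            for lab in sys2.labels:
                ratios.append(
                    got.tables[i].diagonal[lab] / truth.tables[i].diagonal[lab]
                )
            for pair in [("H1", "H2"), ("H2", "H1")]:
                ratios.append(
                    got.tables[i].cross[pair] / truth.tables[i].cross[pair]
                )
        ratios = np.asarray(ratios) / np.median(ratios)
        assert np.all(np.abs(ratios - 1) < 0.02)


class TestSubsample:
    def test_uniform_is_identity(self, sys2):
        fids = simulate_fids(sys2, grid_size=64, n_direct=32)
        out = subsample(fids, generate_uniform(64))
        np.testing.assert_array_equal(out.data[0], fids.data[0])

    def test_half_coverage_zeroes_half_the_rows(self, sys2):
        fids = simulate_fids(sys2, grid_size=512, n_direct=16)
        sched = generate_poisson_gap(512, 0.5, 0)
        out = subsample(fids.data[0], sched)
        nonzero_rows = np.abs(out).sum(axis=1) > 0
        assert nonzero_rows.sum() == 256
        idx = np.asarray(sched.indices)
        np.testing.assert_array_equal(out[idx], fids.data[0][idx])

    def test_idempotent(self, sys2):
        fids = simulate_fids(sys2, grid_size=64, n_direct=16)
        sched = generate_poisson_gap(64, 0.5, 1)
        once = subsample(fids.data[0], sched)
        twice = subsample(once, sched)
        np.testing.assert_array_equal(once, twice)

    def test_grid_mismatch_rejected(self, sys2):
        fids = simulate_fids(sys2, grid_size=64, n_direct=16)
        with pytest.raises(ParameterError):
            subsample(fids.data[0], generate_poisson_gap(128, 0.5, 0))


class TestRoundTripProperties:
    def test_noiseless_integral_level_exact(self, sys12):
        series = simulate_integrals(sys12)
        table = build_distance_table(series)
        for pair, entry in table.entries.items():
            truth = sys12.distance(*pair)
            assert entry.valid
            assert abs(entry.r_ab - truth) / truth < 1e-3

    def test_fid_level_uniform_within_two_percent(self, sys5):
        fids = simulate_fids(
            sys5, grid_size=128, n_direct=512, t1_decay=1.0, t2_decay=1.5
        )
        table = build_distance_table(quantify_fids(fids))
        for pair, entry in table.entries.items():
            truth = sys5.distance(*pair)
            assert entry.valid, pair
            assert abs(entry.r_ab - truth) / truth < 0.02, pair

    def test_noise_injection_unbiased(self, sys2):
        # over many seeds the mean recovered distance hits ground truth
        recovered = []
        d = np.array(
            [[0.00, 1.78, 2.80], [1.78, 0.00, 3.20], [2.80, 3.20, 0.00]]
        )
        system = SpinSystem(("H1", "H2", "H3"), d, ("H1", "H2"))
        for seed in range(200):
            series = simulate_integrals(system, noise_sd=0.01, seed=seed)
            table = build_distance_table(series)
            entry = table.entries[("H1", "H3")]
            if entry.valid:
                recovered.append(entry.r_ab)
        recovered = np.asarray(recovered)
        assert len(recovered) > 190
        se = recovered.std() / np.sqrt(len(recovered))
        assert abs(recovered.mean() - 2.80) < max(4 * se, 0.005)


def test_series_frame_round_trip(sys2):
    series = simulate_integrals(sys2, noise_sd=0.02, seed=9)
    frame = series.to_frame()
    from nusquant.noesy_sim import NoesySeries

    back = NoesySeries.from_frame(frame, sys2)
    assert back.mixing_times == series.mixing_times
    assert back.tables[3].cross == series.tables[3].cross
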