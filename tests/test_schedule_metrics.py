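import math

import numpy as np
import pytest

from nusquant.errors import ParameterError
from nusquant.reconstruct import ist_reconstruct
from nusquant.schedule_metrics import (
    EnvelopeModel,
    ToySignal,
    compute_psf,
    forward_fraction,
    peak_to_sidelobe,
    relative_sensitivity,
    saar,
    score_schedule,
)
from nusquant.schedules import (
    generate_hybrid,
    generate_poisson_gap,
    generate_random_shuffle,
    generate_uniform,
)


def brute_force_psf(schedule, zerofill_factor):
    """O(N*M) term-by-term discrete transform of the sampling mask."""
    n = schedule.grid_size
    m = zerofill_factor * n
    amps = np.zeros(m, dtype=complex)
    for j in range(m):
        for i in schedule.indices:
            amps[j] += np.exp(-2j * np.pi * i * j / m)
    return amps / n


class TestComputePsf:
    def test_matches_brute_force_small_grids(self):
        for grid, cov, seed in [(16, 0.5, 0), (32, 0.25, 1), (64, 0.5, 2)]:
            sched = generate_poisson_gap(grid, cov, seed)
            psf = compute_psf(sched, 4)
            oracle = brute_force_psf(sched, 4)
            np.testing.assert_allclose(psf.amplitudes, oracle, atol=1e-12)

    def test_main_lobe_is_maximal(self):
        sched = generate_random_shuffle(128, 0.5, 3)
        psf = compute_psf(sched, 4)
        assert np.abs(psf.amplitudes).argmax() == 0

    def test_main_lobe_normalization(self):
        sched = generate_poisson_gap(128, 0.5, 3)
        psf = compute_psf(sched, 4)
        assert psf.amplitudes[0].real == pytest.approx(
            sched.n_sampled / sched.grid_size
        )

    def test_parseval(self):
        sched = generate_random_shuffle(64, 0.5, 5)
        psf = compute_psf(sched, 4)
        m = psf.amplitudes.size
        power = np.sum(np.abs(psf.amplitudes) ** 2)
        assert power == pytest.approx(sched.n_sampled * m / sched.grid_size**2)

    def test_zerofill_below_one_rejected(self):
        with pytest.raises(ParameterError):
            compute_psf(generate_uniform(16), 0)


class TestPeakToSidelobe:
    def test_uniform_full_gives_sentinel(self):
        psf = compute_psf(generate_uniform(64), 4)
        assert peak_to_sidelobe(psf) == math.inf

    def test_truncation_matches_dirichlet_kernel(self):
        # closed form: |sin(pi*L*k/N) / sin(pi*k/N)| / N at grid bins k,
        # L = N/2; tallest off-main value at k = 3
        n = 64
        sched = generate_uniform(n, 0.5)
        ratio = peak_to_sidelobe(compute_psf(sched, 8))
        main = 0.5
        first_sidelobe = abs(
            math.sin(math.pi * (n // 2) * 3 / n) / math.sin(math.pi * 3 / n)
        ) / n
        assert ratio == pytest.approx(main / first_sidelobe, rel=1e-12)
        # and it approximates the continuous Dirichlet first-sidelobe ratio
        assert ratio == pytest.approx(1.0 / 0.21723, rel=0.05)

    def test_ranking_matches_brute_force_oracle(self):
        scheds = [generate_poisson_gap(64, 0.5, s) for s in range(4)] + [
            generate_random_shuffle(64, 0.5, s) for s in range(4)
        ]
        fast = [peak_to_sidelobe(compute_psf(s, 4)) for s in scheds]
        slow = []
        for sched in scheds:
            amps = brute_force_psf(sched, 4)
            m = amps.size
            zf = 4
            bins = np.arange(0, m, zf)
            dist = np.minimum(bins, m - bins)
            side = np.abs(amps[bins[dist > zf]]).max()
            slow.append(np.abs(amps[0]) / side)
        np.testing.assert_allclose(fast, slow, rtol=1e-9)
        assert np.argsort(fast).tolist() == np.argsort(slow).tolist()


class TestRelativeSensitivity:
    def test_flat_envelope_equals_coverage(self):
        for sched in (
            generate_poisson_gap(512, 0.5, 1),
            generate_random_shuffle(512, 0.5, 1),
            generate_hybrid(512, 0.5, 0.3, 1),
        ):
            assert relative_sensitivity(sched, EnvelopeModel(0.0)) == 50.0

    def test_truncated_uniform_strong_decay_closed_form(self):
        # geometric-sum oracle: sum of exp(-3 i/N) over first half vs all
        n = 512
        sched = generate_uniform(n, 0.5)
        got = relative_sensitivity(sched, EnvelopeModel(3.0))
        q = math.exp(-3.0 / n)
        expected = 100.0 * (1 - q ** (n // 2)) / (1 - q**n)
        assert got == pytest.approx(expected, rel=1e-12)
        # continuum approximation quoted for this case
        assert got == pytest.approx(
            100 * (1 - math.exp(-1.5)) / (1 - math.exp(-3.0)), rel=1e-3
        )

    def test_random_shuffle_mean_near_half_coverage(self):
        vals = [
            relative_sensitivity(generate_random_shuffle(512, 0.5, s))
            for s in range(1, 16)
        ]
        assert np.mean(vals) == pytest.approx(50.1, abs=0.3)

    def test_monotone_in_us_fraction(self):
        vals = [
            relative_sensitivity(generate_hybrid(512, 0.5, us, 3))
            for us in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_envelope_validation(self):
        with pytest.raises(ParameterError):
            EnvelopeModel(-1.0)


class TestForwardFraction:
    def test_uniform_full(self):
        assert forward_fraction(generate_uniform(64)) == 0.5

    def test_truncated_uniform(self):
        assert forward_fraction(generate_uniform(64, 0.5)) == 1.0

    def test_larger_prefix_more_forward(self):
        hi = generate_hybrid(512, 0.5, 0.45, 3)
        lo = generate_hybrid(512, 0.5, 0.25, 3)
        assert forward_fraction(hi) > forward_fraction(lo)


class TestSaar:
    def test_uniform_full_sentinel(self):
        assert saar(generate_uniform(256)) == math.inf

    def test_deterministic(self):
        sched = generate_poisson_gap(256, 0.5, 4)
        assert saar(sched) == saar(sched)

    def test_poisson_gap_beats_random_shuffle(self):
        pg = [saar(generate_poisson_gap(256, 0.5, s)) for s in range(20)]
        rs = [saar(generate_random_shuffle(256, 0.5, s)) for s in range(20)]
        assert np.median(pg) > np.median(rs)

    def test_poisson_gap_beats_random_shuffle_with_ist(self):
        recon = lambda v, s: ist_reconstruct(v, s, n_iterations=100)  # noqa: E731
        pg = [
            saar(generate_poisson_gap(256, 0.5, s), reconstructor=recon)
            for s in range(8)
        ]
        rs = [
            saar(generate_random_shuffle(256, 0.5, s), reconstructor=recon)
            for s in range(8)
        ]
        assert np.median(pg) > np.median(rs)

    def test_matches_psr_on_flat_single_tone(self):
        # zero-fill reconstructor + single on-bin non-decaying tone reduces
        # SAAR to PSF sidelobe structure exactly
        toy = ToySignal(frequencies=(32 / 256,), amplitudes=(1.0,), decay=0.0)
        scheds = [generate_poisson_gap(256, 0.5, s) for s in range(5)] + [
            generate_random_shuffle(256, 0.5, s) for s in range(5)
        ]
        sa = [
            saar(s, toy, apodize=False, peak_halfwidth=4) for s in scheds
        ]
        ps = [peak_to_sidelobe(compute_psf(s, 4)) for s in scheds]
        np.testing.assert_allclose(sa, ps, rtol=1e-9)

    def test_peak_region_covering_everything_rejected(self):
        sched = generate_poisson_gap(64, 0.5, 0)
        with pytest.raises(ParameterError):
            saar(sched, peak_halfwidth=10_000)


def test_score_schedule_bundles_all_metrics():
    m = score_schedule(generate_hybrid(128, 0.5, 0.25, 0))
    assert m.label == "128-50-25-0"
    assert m.peak_to_sidelobe > 1
    assert 0 < m.relative_sensitivity <= 100
    assert m.saar > 0
    assert 0 <= m.forward_fraction <= 1
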