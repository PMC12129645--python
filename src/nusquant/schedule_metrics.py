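"""Reference-free schedule scoring.

Metrics computed directly from the sampling mask:

* point-spread function (PSF) and its peak-to-sidelobe ratio — the spectrum
  of the 0/1 mask with unsampled points as zeros; its sidelobes predict
  aliasing artefacts;
* relative sensitivity — percentage of a decaying signal envelope captured
  by the sampled points;
* SAAR (signal apex-to-artefact ratio) — apex of a known toy peak divided by
  the tallest artefact after subsampling and reconstruction;
* forward-weighting fraction — a descriptive surrogate for unpublished
  forward-weighting scores: the fraction of samples in the first half grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ParameterError
from .schedules import SamplingSchedule

__all__ = [
    "PointSpreadFunction",
    "EnvelopeModel",
    "ToySignal",
    "ScheduleMetrics",
    "compute_psf",
    "peak_to_sidelobe",
    "relative_sensitivity",
    "forward_fraction",
    "saar",
    "zero_fill_reconstructor",
    "score_schedule",
]

#: Ratio below which the tallest sidelobe counts as numerically zero and the
#: +inf sentinel is returned instead of a ratio.
_ZERO_SIDELOBE_RTOL = 1e-9


@dataclass(frozen=True)
class PointSpreadFunction:
    """Spectrum of a sampling mask (missing points zero-filled).

    ``amplitudes`` has length ``zerofill_factor * grid_size`` and is
    normalized so the main-lobe (zero-frequency) amplitude equals
    ``n_sampled / grid_size``; total power is then
    ``n_sampled * M / grid_size**2`` (Parseval under this convention).
    """

    amplitudes: np.ndarray
    grid_size: int
    n_sampled: int
    zerofill_factor: int
    main_lobe_index: int = 0

    @property
    def main_lobe_width(self) -> int:
        """Half-width (bins) of the main lobe excluded from sidelobe search."""
        return self.zerofill_factor


@dataclass(frozen=True)
class EnvelopeModel:
    """Exponential signal envelope exp(-c * i / grid) over the grid.

    ``decay_constant`` is the grid length divided by the effective T2 in
    increment units; 0 means a flat (constant-time-like) envelope.
    """

    decay_constant: float = 0.2

    def __post_init__(self) -> None:
        if self.decay_constant < 0:
            raise ParameterError("decay_constant must be >= 0")

    def __call__(self, grid_size: int) -> np.ndarray:
        i = np.arange(grid_size)
        return np.exp(-self.decay_constant * i / grid_size)


@dataclass(frozen=True)
class ToySignal:
    """Noiseless sum of decaying complex cosinusoids for SAAR scoring.

    Defaults: three incommensurate frequencies with 1 : 0.1 : 0.01
    amplitudes, mimicking a high-dynamic-range spectrum.
    """

    frequencies: tuple[float, ...] = (0.1234, 0.3171, 0.4118)  # cycles/point
    amplitudes: tuple[float, ...] = (1.0, 0.1, 0.01)
    decay: float = 2.0  # e-folding exponent across the grid

    def synthesize(self, grid_size: int) -> np.ndarray:
        t = np.arange(grid_size)
        y = np.zeros(grid_size, dtype=complex)
        for f, a in zip(self.frequencies, self.amplitudes):
            y += a * np.exp(2j * np.pi * f * t) * np.exp(-self.decay * t / grid_size)
        return y


@dataclass(frozen=True)
class ScheduleMetrics:
    label: str
    peak_to_sidelobe: float
    relative_sensitivity: float
    saar: float
    forward_fraction: float


def compute_psf(
    schedule: SamplingSchedule, zerofill_factor: int = 4
) -> PointSpreadFunction:
    """Discrete transform of the sampling mask, zero-filled by the factor."""
    if zerofill_factor < 1:
        raise ParameterError("zerofill_factor must be >= 1")
    if schedule.n_sampled == 0:
        raise ParameterError("empty schedule has no PSF")
    n = schedule.grid_size
    m = zerofill_factor * n
    amplitudes = np.fft.fft(schedule.mask(), m) / n
    return PointSpreadFunction(amplitudes, n, schedule.n_sampled, zerofill_factor)


def peak_to_sidelobe(psf: PointSpreadFunction) -> float:
    """|main lobe| / max |amplitude| outside the main-lobe width.

    Returns ``inf`` when the sidelobes are numerically zero (complete
    sampling gives a delta response).
    """
    if psf.zerofill_factor < 2:
        raise ParameterError("peak_to_sidelobe needs zerofill_factor >= 2")
    mag = np.abs(psf.amplitudes)
    m = mag.size
    main = mag[psf.main_lobe_index]
    # Sidelobes are read at the grid-commensurate frequencies (every
    # zerofill_factor-th bin = the N-point transform of the mask): complete
    # sampling is then a true delta response, and interpolation wiggles of
    # the zero-fill itself are not mistaken for schedule artefacts.
    bins = np.arange(0, m, psf.zerofill_factor)
    dist = np.minimum(bins, m - bins)  # circular distance from bin 0
    side = mag[bins[dist > psf.main_lobe_width]]
    tallest = side.max()
    if tallest <= _ZERO_SIDELOBE_RTOL * main:
        return float("inf")
    return float(main / tallest)


def relative_sensitivity(
    schedule: SamplingSchedule, envelope: EnvelopeModel = EnvelopeModel()
) -> float:
    """Percent of the signal envelope captured by the sampled points."""
    env = envelope(schedule.grid_size)
    idx = np.asarray(schedule.indices)
    return float(100.0 * env[idx].sum() / env.sum())


def forward_fraction(schedule: SamplingSchedule) -> float:
    """Fraction of sampled points in the first half of the grid."""
    idx = np.asarray(schedule.indices)
    return float(np.mean(idx < schedule.grid_size / 2.0))


def zero_fill_reconstructor(
    values: np.ndarray, schedule: SamplingSchedule
) -> np.ndarray:
    """The identity 'reconstructor': keep unsampled points at zero."""
    return np.asarray(values)


def saar(
    schedule: SamplingSchedule,
    toy_signal: ToySignal = ToySignal(),
    reconstructor: Callable[[np.ndarray, SamplingSchedule], np.ndarray]
    | None = None,
    zerofill_factor: int = 4,
    peak_halfwidth: int | None = None,
    apodize: bool = True,
) -> float:
    """Signal apex-to-artefact ratio via toy-signal reconstruction.

    Synthesizes the toy interferogram on the full grid, subsamples by the
    schedule, reconstructs (zero-fill identity by default) and transforms.
    The apex is the tallest reconstructed amplitude inside the declared
    peak regions; the artefact is the tallest deviation from the
    identically-processed fully-sampled reference spectrum, read at the
    grid-commensurate frequencies outside the peak regions (the same
    convention as :func:`peak_to_sidelobe`, so the toy signal's own
    spectral tails are not miscounted as schedule artefacts).
    Deterministic; higher is better; ``inf`` when the artefact floor is
    numerically zero — in particular for complete sampling, where the
    whole chain is the identity.
    """
    if reconstructor is None:
        reconstructor = zero_fill_reconstructor
    n = schedule.grid_size
    m = zerofill_factor * n
    if peak_halfwidth is None:
        peak_halfwidth = 2 * zerofill_factor
    y = toy_signal.synthesize(n)
    sub = y * schedule.mask()
    recon = reconstructor(sub, schedule)
    spec = np.fft.fft(_apodized_zerofill(recon, m, apodize))
    reference = np.fft.fft(_apodized_zerofill(y, m, apodize))
    in_peak = np.zeros(m, dtype=bool)
    bins = np.arange(m)
    for f in toy_signal.frequencies:
        center = (f * m) % m
        dist = np.minimum(np.abs(bins - center), m - np.abs(bins - center))
        in_peak |= dist <= peak_halfwidth
    if in_peak.all():
        raise ParameterError("peak regions cover the whole spectrum")
    commensurate = np.zeros(m, dtype=bool)
    commensurate[::zerofill_factor] = True
    apex = float(np.abs(spec[in_peak]).max())
    artefact = float(np.abs(spec - reference)[~in_peak & commensurate].max())
    if artefact <= _ZERO_SIDELOBE_RTOL * apex:
        return float("inf")
    return apex / artefact


def _apodized_zerofill(values: np.ndarray, m: int, apodize: bool = True) -> np.ndarray:
    # Same apodization recipe as reconstruct.process_spectrum, but the
    # complex vector is kept (saar() works on complex spectra).
    n = len(values)
    out = np.zeros(m, dtype=complex)
    if apodize:
        w = np.cos(np.pi * np.arange(n) / (2.0 * n)) ** 2
        out[:n] = values * w
        out[0] *= 0.5
    else:
        out[:n] = values
    return out


def score_schedule(
    schedule: SamplingSchedule,
    envelope: EnvelopeModel = EnvelopeModel(),
    zerofill_factor: int = 4,
    toy_signal: ToySignal = ToySignal(),
    reconstructor=None,
) -> ScheduleMetrics:
    """All four metrics for one schedule."""
    psf = compute_psf(schedule, zerofill_factor)
    return ScheduleMetrics(
        label=schedule.label,
        peak_to_sidelobe=peak_to_sidelobe(psf),
        relative_sensitivity=relative_sensitivity(schedule, envelope),
        saar=saar(schedule, toy_signal, reconstructor, zerofill_factor),
        forward_fraction=forward_fraction(schedule),
    )
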