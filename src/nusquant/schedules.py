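"""Sampling-schedule generation, validation and nuslist serialization.

A schedule records which indirect-dimension (t1) increments of a 2D NMR
experiment are acquired on an ``grid_size``-point Nyquist grid. One index is
one hypercomplex increment; quadrature components are never modelled
separately.

Four kinds are supported:

``uniform``
    every increment (or, truncated, the first ``k``) is acquired;
``poisson_gap``
    gaps between consecutive samples drawn from a Poisson law whose rate is
    modulated sinusoidally along the grid, biasing samples toward early
    increments (forward weighting);
``random_shuffle``
    a uniform draw without replacement;
``hybrid``
    an unbroken uniformly sampled prefix followed by a Poisson-gap tail,
    labelled with the ``N-cov-us-seed`` convention (e.g. ``512-50-30-0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .errors import FormatError, ParameterError

__all__ = [
    "SamplingSchedule",
    "generate_uniform",
    "generate_poisson_gap",
    "generate_random_shuffle",
    "generate_hybrid",
    "read_nuslist",
    "write_nuslist",
    "n_points",
]

KINDS = ("uniform", "poisson_gap", "random_shuffle", "hybrid")

#: Hard cap on redraw trials of the Poisson-gap rate-adjustment loop.
_MAX_TRIALS = 20_000


def n_points(grid_size: int, fraction: float) -> int:
    """Number of sampled points implied by a coverage (or prefix) fraction.

    Symmetric half-up rounding, centralized so the prefix-length convention
    (e.g. 154 = round(0.30 x 512)) can be changed in exactly one place.
    """
    return int(math.floor(fraction * grid_size + 0.5))


@dataclass(frozen=True)
class SamplingSchedule:
    """An immutable, validated set of sampled indirect-dimension increments."""

    grid_size: int
    indices: tuple[int, ...]
    kind: str
    coverage: float
    us_fraction: float = 0.0
    seed: int | None = None
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown schedule kind {self.kind!r}")
        if self.grid_size < 1:
            raise ParameterError("grid_size must be positive")
        if not 0.0 < self.coverage <= 1.0:
            raise ParameterError("coverage must lie in (0, 1]")
        if not 0.0 <= self.us_fraction <= self.coverage:
            raise ParameterError("us_fraction must lie in [0, coverage]")
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size == 0:
            raise ParameterError("schedule has no sampled points")
        if idx.min() < 0 or idx.max() >= self.grid_size:
            raise ParameterError("indices out of [0, grid_size)")
        if np.any(np.diff(idx) <= 0):
            raise ParameterError("indices must be strictly increasing")
        expected = n_points(self.grid_size, self.coverage)
        if idx.size != expected:
            raise ParameterError(
                f"{idx.size} indices but coverage {self.coverage} on a "
                f"{self.grid_size} grid requires exactly {expected}"
            )
        if self.kind == "hybrid":
            k = n_points(self.grid_size, self.us_fraction)
            if tuple(self.indices[:k]) != tuple(range(k)):
                raise ParameterError("hybrid prefix {0..k-1} incomplete")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        cov = f"{100 * self.coverage:g}"
        if self.kind == "uniform":
            return f"{self.grid_size}-{cov}-uniform"
        tag = {"poisson_gap": "pg", "random_shuffle": "rs"}.get(self.kind)
        if tag is not None:
            if self.seed is None:  # e.g. parsed from a nuslist file
                return f"{self.grid_size}-{cov}-{tag}"
            return f"{self.grid_size}-{cov}-{tag}-{self.seed}"
        us = f"{100 * self.us_fraction:g}"
        return f"{self.grid_size}-{cov}-{us}-{self.seed}"

    @property
    def n_sampled(self) -> int:
        return len(self.indices)

    def mask(self) -> np.ndarray:
        """0/1 float mask on the full grid (1 where sampled)."""
        m = np.zeros(self.grid_size)
        m[np.asarray(self.indices)] = 1.0
        return m


def generate_uniform(grid_size: int, coverage: float = 1.0) -> SamplingSchedule:
    """Uniform sampling; ``coverage < 1`` means truncation to the first points."""
    _check_common(grid_size, coverage)
    n = n_points(grid_size, coverage)
    return SamplingSchedule(grid_size, tuple(range(n)), "uniform", coverage)


def generate_random_shuffle(
    grid_size: int, coverage: float, seed: int
) -> SamplingSchedule:
    """Uniform draw of round(coverage x grid_size) points without replacement."""
    _check_common(grid_size, coverage)
    n = n_points(grid_size, coverage)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(grid_size, size=n, replace=False))
    return SamplingSchedule(
        grid_size, tuple(int(i) for i in idx), "random_shuffle", coverage, seed=seed
    )


def generate_poisson_gap(
    grid_size: int,
    coverage: float,
    seed: int,
    sinusoidal_weight: bool = True,
    sample_last: bool = False,
) -> SamplingSchedule:
    """Poisson-gap schedule with (default) sinusoidal forward weighting.

    Gaps between consecutive sampled points are Poisson draws whose rate
    grows as sin(theta) with theta sweeping 0 -> pi/2 across the grid, so
    gaps are small early and large late. An outer adjustment loop rescales
    the rate and redraws until the sampled count is hit exactly. Index 0 is
    always sampled; ``sample_last`` additionally pins the final grid point.
    """
    _check_common(grid_size, coverage)
    n = n_points(grid_size, coverage)
    idx = _poisson_gap_indices(
        grid_size, n, seed, sinusoidal_weight, sample_last=sample_last
    )
    return SamplingSchedule(
        grid_size, idx, "poisson_gap", coverage, seed=seed
    )


def generate_hybrid(
    grid_size: int,
    coverage: float,
    us_fraction: float,
    seed: int,
    sample_last: bool = False,
) -> SamplingSchedule:
    """Uniform prefix {0..k-1} plus a forward-weighted Poisson-gap tail.

    ``k = round(us_fraction x grid_size)``; the tail draw places the
    remaining points on {k..grid_size-1} with the sinusoidal weighting swept
    over the tail region only. ``us_fraction == coverage`` degenerates to a
    truncated-uniform schedule, ``us_fraction == 0`` to plain Poisson-gap
    with the same seed.
    """
    _check_common(grid_size, coverage)
    if not 0.0 <= us_fraction <= coverage:
        raise ParameterError("us_fraction must lie in [0, coverage]")
    n = n_points(grid_size, coverage)
    k = n_points(grid_size, us_fraction)
    m = n - k
    if m < 0:
        raise ParameterError("uniform prefix longer than total point budget")
    if m == 0:
        idx: tuple[int, ...] = tuple(range(k))
    else:
        tail = _poisson_gap_indices(
            grid_size - k, m, seed, True, sample_last=sample_last
        )
        idx = tuple(range(k)) + tuple(k + i for i in tail)
    if k == 0:  # degenerate: pure Poisson-gap
        return SamplingSchedule(
            grid_size, idx, "poisson_gap", coverage, seed=seed
        )
    return SamplingSchedule(
        grid_size, idx, "hybrid", coverage, us_fraction=us_fraction, seed=seed
    )


def _check_common(grid_size: int, coverage: float) -> None:
    if grid_size < 2:
        raise ParameterError("grid_size must be at least 2")
    if not 0.0 < coverage <= 1.0:
        raise ParameterError("coverage must lie in (0, 1]")
    if n_points(grid_size, coverage) < 1:
        raise ParameterError("coverage places zero points on this grid")


def _poisson_gap_indices(
    region_len: int,
    n: int,
    seed: int,
    sinusoidal: bool,
    sample_last: bool = False,
) -> tuple[int, ...]:
    """Draw exactly ``n`` Poisson-gap indices on {0..region_len-1}.

    The Poisson rate lambda is rescaled between redraws until the count is
    exact; each trial uses an independent, deterministically derived
    substream so regeneration from the same seed is bit-identical.
    """
    if n > region_len:
        raise ParameterError("more points requested than grid positions")
    if n == region_len:
        return tuple(range(n))
    if sample_last:
        if n == 1:
            return (region_len - 1,)
        inner = _poisson_gap_indices(region_len - 1, n - 1, seed, sinusoidal)
        return inner + (region_len - 1,)

    # Mean gap needed is region_len/n - 1; with sin weighting the average
    # modulation over [0, pi/2) is 2/pi, hence the pi/2 boost.
    target_gap = region_len / n - 1.0
    lam = target_gap * (math.pi / 2.0 if sinusoidal else 1.0)
    for trial in range(_MAX_TRIALS):
        rng = np.random.default_rng([seed, trial])
        idx = _poisson_gap_draw(rng, region_len, lam, sinusoidal)
        got = len(idx)
        if got == n:
            return tuple(idx)
        achieved_gap = region_len / got - 1.0
        lam *= (target_gap + 0.05) / (achieved_gap + 0.05)
    raise ParameterError(
        f"Poisson-gap rate adjustment failed to converge for "
        f"n={n}, region={region_len}, seed={seed}"
    )


def _poisson_gap_draw(
    rng: np.random.Generator, region_len: int, lam: float, sinusoidal: bool
) -> list[int]:
    idx: list[int] = []
    x = 0
    while x < region_len:
        idx.append(x)
        if sinusoidal:
            rate = lam * math.sin((x + 0.5) / region_len * math.pi / 2.0)
        else:
            rate = lam
        x += 1 + int(rng.poisson(rate))
    return idx


def write_nuslist(
    schedule: SamplingSchedule, destination: Union[str, Path, IO[str]]
) -> None:
    """Write one ascending 0-based index per line (Bruker-style nuslist)."""
    text = "\n".join(str(i) for i in schedule.indices) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)  # type: ignore[union-attr]
    else:
        Path(destination).write_text(text)


def read_nuslist(
    source: Union[str, Path, IO[str], Iterable[str]], grid_size: int
) -> SamplingSchedule:
    """Parse a nuslist file back into a validated schedule.

    The kind is unrecoverable from the file and is reported as ``uniform``
    when the indices are exactly {0..n-1}, else ``random_shuffle``.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    elif isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    idx: list[int] = []
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s:
            continue
        try:
            v = int(s)
        except ValueError as exc:
            raise FormatError(f"line {ln}: not an integer: {s!r}") from exc
        if v < 0 or v >= grid_size:
            raise FormatError(f"line {ln}: index {v} outside [0, {grid_size})")
        idx.append(v)
    if not idx:
        raise FormatError("empty nuslist")
    if len(set(idx)) != len(idx):
        raise FormatError("duplicate index in nuslist")
    if sorted(idx) != idx:
        raise FormatError("nuslist indices must be ascending")
    coverage = len(idx) / grid_size
    kind = "uniform" if idx == list(range(len(idx))) else "random_shuffle"
    return SamplingSchedule(grid_size, tuple(idx), kind, coverage)
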