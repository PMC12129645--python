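"""US-vs-NUS fidelity comparison and the schedule-evaluation experiment.

``compare_distance_tables`` turns two distance tables (uniform reference vs
non-uniform test) into a :class:`FidelityReport`: retained fraction,
deviation-cutoff table, signed/absolute mean deviations and the L2 norm.
``run_experiment`` orchestrates the full synthetic pipeline — simulate a
uniform 2D reference, loop over schedules, subsample, reconstruct,
quantify, compare — and emits one row per schedule plus schedule metrics,
so metric-vs-fidelity correlations can be computed exactly as a ranking
study would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ReferenceError_
from . import schedules as sched_mod
from .noesy_sim import (
    Fid2DSeries,
    NoesySeries,
    SpinSystem,
    integrate_peaks,
    make_default_spin_system,
    simulate_fids,
    subsample,
)
from .quantify import DistanceTable, build_distance_table
from .reconstruct import ist_reconstruct, process_spectrum
from .schedule_metrics import (
    EnvelopeModel,
    compute_psf,
    forward_fraction,
    peak_to_sidelobe,
    relative_sensitivity,
)
from .schedules import SamplingSchedule

__all__ = [
    "FidelityReport",
    "ExperimentConfig",
    "compare_distance_tables",
    "artefact_intensity",
    "pearson_r2",
    "process_2d",
    "quantify_fids",
    "run_experiment",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = tuple(range(1, 10))  # percent


@dataclass(frozen=True)
class FidelityReport:
    """How well a test distance table reproduces the reference table."""

    n_reference_valid: int
    n_test_valid: int
    n_common_valid: int
    retained_percent: float
    deviation_table: dict[float, float]  # cutoff % -> % of common pairs beyond
    mean_signed_deviation: float  # percent
    mean_abs_deviation: float  # percent
    l2_norm: float  # Angstrom
    detail: pd.DataFrame = dc_field(repr=False, default=None)
    extra_pairs: tuple[tuple[str, str], ...] = ()  # valid in test only


def compare_distance_tables(
    reference: DistanceTable,
    test: DistanceTable,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> FidelityReport:
    """Per-pair percentage deviations of test vs reference distances.

    Only pairs valid in *both* tables enter the deviation statistics;
    pairs valid in the test but not the reference are listed separately in
    ``extra_pairs`` and excluded. Cutoff classification uses |deviation|.
    """
    if not reference.entries:
        raise ParameterError("empty reference table")
    if not cutoffs:
        raise ParameterError("at least one cutoff required")
    if reference.reference_pair != test.reference_pair:
        raise ParameterError("tables use different reference pairs")
    ref_valid = reference.valid_pairs()
    test_valid = test.valid_pairs()
    common = sorted(ref_valid & test_valid)
    extra = tuple(sorted(test_valid - ref_valid))

    rows = []
    for pair in common:
        r_ref = reference.entries[pair].r_ab
        r_test = test.entries[pair].r_ab
        dev = 100.0 * (r_test - r_ref) / r_ref
        rows.append(
            {"pair": f"{pair[0]}-{pair[1]}", "r_ref_A": r_ref,
             "r_test_A": r_test, "deviation_percent": dev}
        )
    detail = pd.DataFrame(
        rows, columns=["pair", "r_ref_A", "r_test_A", "deviation_percent"]
    )
    devs = detail["deviation_percent"].to_numpy()
    n_common = len(common)
    dev_table = {
        float(c): (
            float(100.0 * np.mean(np.abs(devs) > c)) if n_common else float("nan")
        )
        for c in cutoffs
    }
    retained = 100.0 * n_common / len(ref_valid) if ref_valid else float("nan")
    diffs = detail["r_test_A"].to_numpy() - detail["r_ref_A"].to_numpy()
    return FidelityReport(
        n_reference_valid=len(ref_valid),
        n_test_valid=len(test_valid),
        n_common_valid=n_common,
        retained_percent=float(retained),
        deviation_table=dev_table,
        mean_signed_deviation=float(devs.mean()) if n_common else float("nan"),
        mean_abs_deviation=(
            float(np.abs(devs).mean()) if n_common else float("nan")
        ),
        l2_norm=float(np.sqrt(np.sum(diffs**2))),
        detail=detail,
        extra_pairs=extra,
    )


def artefact_intensity(
    us_spectrum: np.ndarray,
    nus_spectrum: np.ndarray,
    regions: Sequence[tuple[tuple[int, int], tuple[int, int]]],
) -> float:
    """Integral of the magnitude-mode difference spectrum over given regions.

    Each region is ((f1_lo, f1_hi), (f2_lo, f2_hi)) with half-open bounds.
    Regions must not overlap.
    """
    us = np.asarray(us_spectrum)
    nus = np.asarray(nus_spectrum)
    if us.shape != nus.shape:
        raise ParameterError("spectra must share a grid")
    covered = np.zeros(us.shape, dtype=bool)
    diff = np.abs(us - nus)
    total = 0.0
    for (lo1, hi1), (lo2, hi2) in regions:
        if covered[lo1:hi1, lo2:hi2].any():
            raise ParameterError("regions overlap")
        covered[lo1:hi1, lo2:hi2] = True
        total += float(diff[lo1:hi1, lo2:hi2].sum())
    return total


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Squared Pearson correlation; ``None`` for constant columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def process_2d(
    plane: np.ndarray,
    schedule: SamplingSchedule | None = None,
    zf1: int = 2,
    zf2: int = 2,
    reconstruct: bool = True,
    n_iterations: int = 100,
    columns: np.ndarray | None = None,
) -> np.ndarray:
    """Process one 2D plane (t1 x t2) to a real 2D spectrum.

    Direct dimension first (apodize, zero-fill, transform, kept complex),
    then the indirect dimension: optional IST completion of subsampled t1
    vectors, then the same apodize/zero-fill/transform with the real part
    returned. ``columns`` restricts the indirect-dimension work to selected
    f2 columns (an optimization for peak-region integration); the returned
    array then has ``len(columns)`` columns.
    """
    n1, n2 = plane.shape
    # t2: apodized complex transform (no real-part projection yet)
    w2 = np.cos(np.pi * np.arange(n2) / (2.0 * n2)) ** 2
    w2[0] *= 0.5
    f2 = np.fft.fft(plane * w2[None, :], zf2 * n2, axis=1)
    if columns is not None:
        f2 = f2[:, columns]
    if schedule is not None and reconstruct and schedule.n_sampled < n1:
        f2 = ist_reconstruct(f2, schedule, n_iterations=n_iterations)
    return process_spectrum(f2, zerofill_to=zf1 * n1)


def quantify_fids(
    fids: Fid2DSeries,
    schedule: SamplingSchedule | None = None,
    zf1: int = 2,
    zf2: int = 2,
    n_iterations: int = 100,
    halfwidth: int = 3,
    baseline_ring: int = 2,
) -> NoesySeries:
    """Subsample (optional), reconstruct, process and integrate a FID series."""
    labels = fids.system.labels
    # only the f2 columns inside integration boxes (plus the baseline
    # ring) are ever needed
    cols: set[int] = set()
    m2 = zf2 * fids.n_direct
    reach = halfwidth + baseline_ring
    for b in labels:
        p2 = int(round(fids.freqs[b] * m2)) % m2
        cols.update(range(max(p2 - reach, 0), min(p2 + reach + 1, m2)))
    col_idx = np.array(sorted(cols))

    tables = []
    for plane in fids.data:
        if schedule is not None:
            plane = subsample(plane, schedule)
        spec_cols = process_2d(
            plane, schedule, zf1, zf2, n_iterations=n_iterations,
            columns=col_idx,
        )
        # scatter back into a sparse full-width spectrum for integration
        full = np.zeros((spec_cols.shape[0], m2))
        full[:, col_idx] = spec_cols
        tables.append(
            integrate_peaks(
                full, fids, zf1, zf2, halfwidth, halfwidth, baseline_ring
            )
        )
    provenance = (
        f"fid_level/{schedule.label}" if schedule is not None else "fid_level/us"
    )
    return NoesySeries(
        fids.mixing_times, tuple(tables), fids.system,
        provenance=provenance,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed for a deterministic schedule-evaluation run."""

    grid_size: int = 256
    n_direct: int = 256
    mixing_times: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    noise_sd: float = 3e-5
    sim_seed: int = 0
    sigma_ref: float = 0.05
    leakage: float = 1.0
    model: str = "initial_rate"
    n_protons: int = 12
    schedules: tuple[dict, ...] = (
        {"kind": "uniform"},
        {"kind": "hybrid", "us_fraction": 0.30, "seed": 0},
        {"kind": "poisson_gap", "seed": 0},
        {"kind": "random_shuffle", "seed": 0},
    )
    coverage: float = 0.5
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    zf1: int = 2
    zf2: int = 2
    n_iterations: int = 100
    envelope_decay: float = 0.2

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        kwargs = dict(raw)
        for key in ("mixing_times", "cutoffs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "schedules" in kwargs:
            kwargs["schedules"] = tuple(dict(s) for s in kwargs["schedules"])
        return cls(**kwargs)


def _build_schedule(recipe: Mapping, config: ExperimentConfig) -> SamplingSchedule:
    kind = recipe["kind"]
    grid = int(recipe.get("grid_size", config.grid_size))
    cov = float(recipe.get("coverage", config.coverage))
    seed = int(recipe.get("seed", 0))
    if kind == "uniform":
        return sched_mod.generate_uniform(grid, float(recipe.get("coverage", 1.0)))
    if kind == "poisson_gap":
        return sched_mod.generate_poisson_gap(grid, cov, seed)
    if kind == "random_shuffle":
        return sched_mod.generate_random_shuffle(grid, cov, seed)
    if kind == "hybrid":
        return sched_mod.generate_hybrid(
            grid, cov, float(recipe.get("us_fraction", 0.3)), seed
        )
    if kind == "nuslist":
        return sched_mod.read_nuslist(recipe["path"], grid)
    raise ParameterError(f"unknown schedule recipe kind {kind!r}")


def run_experiment(
    config: ExperimentConfig | Mapping,
) -> tuple[pd.DataFrame, dict[str, FidelityReport]]:
    """Simulate a US reference, evaluate every schedule against it.

    Returns a one-row-per-schedule DataFrame (label, kind, metrics,
    fidelity columns) and the per-schedule :class:`FidelityReport` objects.
    Deterministic given the config seeds; individual schedule failures are
    logged and the run continues.
    """
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_dict(config)
    system = make_default_spin_system(config.n_protons)
    fids = simulate_fids(
        system,
        config.mixing_times,
        grid_size=config.grid_size,
        n_direct=config.n_direct,
        noise_sd=config.noise_sd,
        seed=config.sim_seed,
        model=config.model,
        sigma_ref=config.sigma_ref,
        leakage=config.leakage,
    )
    us_series = quantify_fids(
        fids, None, config.zf1, config.zf2, config.n_iterations
    )
    reference = build_distance_table(us_series)
    envelope = EnvelopeModel(config.envelope_decay)

    rows = []
    reports: dict[str, FidelityReport] = {}
    n_ref_valid = len(reference.valid_pairs())
    for recipe in config.schedules:
        try:
            schedule = _build_schedule(recipe, config)
        except Exception:  # noqa: BLE001 — per-schedule failures must not abort
            logger.exception("schedule recipe %r failed; continuing", recipe)
            continue
        psf = compute_psf(schedule, zerofill_factor=4)
        row = {
            "label": schedule.label,
            "kind": schedule.kind,
            "seed": schedule.seed,
            "us_fraction": schedule.us_fraction,
            "peak_to_sidelobe": peak_to_sidelobe(psf),
            "relative_sensitivity": relative_sensitivity(schedule, envelope),
            "forward_fraction": forward_fraction(schedule),
            "n_reference_valid": n_ref_valid,
        }
        try:
            test_series = quantify_fids(
                fids, schedule, config.zf1, config.zf2, config.n_iterations
            )
            test_table = build_distance_table(test_series)
            report = compare_distance_tables(reference, test_table, config.cutoffs)
        except ReferenceError_ as exc:
            # schedule so poor its own reference curve is unusable: no
            # distance can be extracted at all
            logger.warning("schedule %s: %s", schedule.label, exc)
            row.update(
                n_test_valid=0, retained_percent=0.0,
                mean_signed_deviation=float("nan"),
                mean_abs_deviation=float("nan"), l2_norm=float("nan"),
            )
            rows.append(row)
            continue
        except Exception:  # noqa: BLE001
            logger.exception("schedule %s failed; continuing", schedule.label)
            continue
        row.update(
            n_test_valid=report.n_test_valid,
            retained_percent=report.retained_percent,
            mean_signed_deviation=report.mean_signed_deviation,
            mean_abs_deviation=report.mean_abs_deviation,
            l2_norm=report.l2_norm,
        )
        for c, v in report.deviation_table.items():
            row[f"beyond_{c:g}pct"] = v
        rows.append(row)
        reports[schedule.label] = report
    return pd.DataFrame(rows), reports
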