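"""NOE quantitation chain: PANIC normalization, outlier-trimmed linear
build-up fits, validity filtering, and sixth-root distance extraction.

The normalized intensity of a proton pair AB at one mixing time is

    I_norm = sqrt(cross_AB * cross_BA) / sqrt(diag_A * diag_B)

which cancels any scale factor common to a whole spectrum. Build-up curves
(I_norm vs mixing time) are fitted by ordinary least squares with a free
intercept; a curve is *valid* iff r_squared > 0.90 and more than 4 points
survive trimming. Distances follow the inverse-sixth-power law

    r_AB = r_ref * (sigma_ref / sigma_AB) ** (1/6)

referenced to a geminal pair at 1.78 Angstrom by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError, ReferenceError_
from .noesy_sim import NoesySeries

__all__ = [
    "BuildUpCurve",
    "DistanceEntry",
    "DistanceTable",
    "panic_normalize",
    "fit_buildup",
    "distance_from_slopes",
    "build_distance_table",
    "R_SQUARED_THRESHOLD",
    "MIN_VALID_POINTS",
]

logger = logging.getLogger(__name__)

R_SQUARED_THRESHOLD = 0.90
MIN_VALID_POINTS = 4  # validity requires n_used > 4
MAX_OUTLIER_REMOVALS = 2
MIN_FIT_POINTS = 5


def panic_normalize(
    cross_ab: float, cross_ba: float, diag_a: float, diag_b: float
) -> float:
    """Geometric-mean cross intensity over geometric-mean diagonal.

    The magnitude of the cross product is used; the sign is carried from
    the mean of the two cross peaks (noise can make one of them dip below
    zero without the pair being unphysical).
    """
    if diag_a <= 0 or diag_b <= 0:
        raise NormalizationError("diagonal integrals must be positive")
    mag = np.sqrt(abs(cross_ab * cross_ba)) / np.sqrt(diag_a * diag_b)
    sign = 1.0 if (cross_ab + cross_ba) >= 0 else -1.0
    return float(sign * mag)


@dataclass(frozen=True)
class BuildUpCurve:
    pair: tuple[str, str]
    points: tuple[tuple[float, float], ...]  # (mixing time s, I_norm)
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    outliers_removed: tuple[float, ...] = ()
    valid: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.n_used + len(self.outliers_removed) != len(self.points):
            raise ParameterError("n_used + outliers must equal input points")


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Least-squares line; returns slope, intercept, r^2 and residuals."""
    n = t.size
    tm, ym = t.mean(), y.mean()
    stt = np.sum((t - tm) ** 2)
    slope = float(np.sum((t - tm) * (y - ym)) / stt)
    intercept = float(ym - slope * tm)
    fitted = slope * t + intercept
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2, resid


def _studentized(t: np.ndarray, resid: np.ndarray) -> np.ndarray:
    n = t.size
    tm = t.mean()
    stt = np.sum((t - tm) ** 2)
    leverage = 1.0 / n + (t - tm) ** 2 / stt
    dof = max(n - 2, 1)
    s2 = np.sum(resid**2) / dof
    denom = np.sqrt(np.maximum(s2 * (1.0 - leverage), np.finfo(float).tiny))
    return np.abs(resid) / denom


def fit_buildup(
    pair: tuple[str, str],
    points: list[tuple[float, float]],
    r2_threshold: float = R_SQUARED_THRESHOLD,
    max_removals: int = MAX_OUTLIER_REMOVALS,
    min_points: int = MIN_FIT_POINTS,
) -> BuildUpCurve:
    """OLS build-up fit with iterative max-studentized-residual trimming.

    Points are removed one at a time — largest absolute studentized
    residual first — but only while the fit still fails the r^2 criterion,
    while more than ``min_points`` points remain, and never more than
    ``max_removals`` times. Validity: r^2 > threshold and n_used > 4.
    """
    pts = tuple((float(t), float(v)) for t, v in points)
    if len(pts) < MIN_FIT_POINTS:
        return BuildUpCurve(
            pair, pts, float("nan"), float("nan"), 0.0, len(pts),
            valid=False, reason=f"only {len(pts)} points (< {MIN_FIT_POINTS})",
        )
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    keep = np.ones(t.size, dtype=bool)
    removed: list[float] = []
    while True:
        slope, intercept, r2, resid = _ols(t[keep], y[keep])
        if (
            r2 > r2_threshold
            or len(removed) >= max_removals
            or keep.sum() <= min_points
        ):
            break
        stud = _studentized(t[keep], resid)
        worst_local = int(np.argmax(stud))
        worst_global = np.flatnonzero(keep)[worst_local]
        keep[worst_global] = False
        removed.append(float(t[worst_global]))
    n_used = int(keep.sum())
    valid = r2 > r2_threshold and n_used > MIN_VALID_POINTS
    reason = "" if valid else f"r2={r2:.3f}, n={n_used}"
    return BuildUpCurve(
        pair, pts, slope, intercept, r2, n_used,
        tuple(removed), valid, reason,
    )


def distance_from_slopes(
    sigma_ab: float, sigma_ref: float, r_ref: float = 1.78
) -> float:
    """r_AB = r_ref * (sigma_ref / sigma_AB)^(1/6)."""
    if sigma_ref <= 0:
        raise ParameterError("reference slope must be positive")
    if sigma_ab <= 0:
        raise ParameterError("pair slope must be positive")
    return float(r_ref * (sigma_ref / sigma_ab) ** (1.0 / 6.0))


@dataclass(frozen=True)
class DistanceEntry:
    pair: tuple[str, str]
    r_ab: float  # Angstrom; nan when invalid
    valid: bool
    curve: BuildUpCurve


@dataclass(frozen=True)
class DistanceTable:
    entries: dict[tuple[str, str], DistanceEntry]
    reference_pair: tuple[str, str]
    reference_distance: float
    sigma_ref: float

    def valid_pairs(self) -> set[tuple[str, str]]:
        return {p for p, e in self.entries.items() if e.valid}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair": f"{a}-{b}",
                "r_A": e.r_ab,
                "valid": e.valid,
                "r_squared": e.curve.r_squared,
                "n_used": e.curve.n_used,
                "outliers_removed": ";".join(
                    f"{t:g}" for t in e.curve.outliers_removed
                ),
            }
            for (a, b), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def extract_buildup_points(
    series: NoesySeries, pair: tuple[str, str]
) -> list[tuple[float, float]]:
    """PANIC-normalized points for one unordered pair across mixing times.

    Points with missing or non-positive cross integrals, or non-positive
    diagonals, are excluded (logged) rather than imputed.
    """
    a, b = pair
    points = []
    for t, tab in zip(series.mixing_times, series.tables):
        if (a, b) not in tab.cross or (b, a) not in tab.cross:
            continue
        xab, xba = tab.cross[(a, b)], tab.cross[(b, a)]
        if xab <= 0 or xba <= 0:
            logger.debug("pair %s-%s at %gs: non-positive cross, dropped", a, b, t)
            continue
        da, db = tab.diagonal.get(a, 0.0), tab.diagonal.get(b, 0.0)
        try:
            points.append((t, panic_normalize(xab, xba, da, db)))
        except NormalizationError:
            logger.debug("pair %s-%s at %gs: bad diagonal, dropped", a, b, t)
    return points


def build_distance_table(
    series: NoesySeries,
    reference_pair: tuple[str, str] | None = None,
    r_ref: float | None = None,
    r2_threshold: float = R_SQUARED_THRESHOLD,
) -> DistanceTable:
    """Full chain for every pair with cross intensity: PANIC -> fit -> distance.

    The reference pair's curve must be valid, otherwise nothing can be
    referenced and a hard error is raised. Pairs whose curves fail the
    validity filter appear in the table flagged invalid (these are the
    schedule-comparison "missing" distances).
    """
    if reference_pair is None:
        reference_pair = series.system.reference_pair
    if r_ref is None:
        r_ref = series.system.reference_distance
    ref_key = _canonical(*reference_pair)

    pairs: set[tuple[str, str]] = set()
    for tab in series.tables:
        for (a, b) in tab.cross:
            pairs.add(_canonical(a, b))
    if ref_key not in pairs:
        raise ReferenceError_("reference pair has no cross intensity")

    curves: dict[tuple[str, str], BuildUpCurve] = {}
    for pair in sorted(pairs):
        pts = extract_buildup_points(series, pair)
        curves[pair] = fit_buildup(pair, pts, r2_threshold)

    ref_curve = curves[ref_key]
    if not ref_curve.valid:
        raise ReferenceError_(
            f"reference build-up curve invalid ({ref_curve.reason})"
        )
    sigma_ref = ref_curve.slope

    entries = {}
    for pair, curve in curves.items():
        if curve.valid and curve.slope > 0:
            r = distance_from_slopes(curve.slope, sigma_ref, r_ref)
            entries[pair] = DistanceEntry(pair, r, True, curve)
        else:
            entries[pair] = DistanceEntry(pair, float("nan"), False, curve)
    return DistanceTable(entries, ref_key, r_ref, sigma_ref)
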