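"""From raw well fluorescence to calibrated initial velocities.

Pipeline: fit the NADH calibration line from standard wells, subtract the
time-matched mean background, pick a linear window at the start of each
progress curve, convert its least-squares slope to uM/s via the calibration
slope, then average technical replicates. Derived summaries (specific
activity per enzyme, acceptor-independent hydrolysis rate) live here too.

The linear-window policy is a prefix rule: the longest initial stretch of
the curve whose straight-line fit keeps r^2 at or above a threshold
(default 0.98, minimum 4 points) is used. On curves that bend because the
donor pool depletes, this keeps the slope close to the true initial
velocity where a full-window fit would underestimate it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rate_models import AssayCondition, InvalidInputError
from .synthetic_assay import Calibration, PlateDataset

__all__ = [
    "ProgressCurve",
    "VelocityPoint",
    "WindowPolicy",
    "fit_calibration",
    "subtract_background",
    "initial_velocity",
    "average_replicates",
    "specific_activity",
    "hydrolysis_rate",
    "extract_velocities",
]

logger = logging.getLogger(__name__)

VELOCITY_TABLE_COLUMNS = [
    "substrate_id", "conc_xcoa_uM", "conc_acp_uM", "conc_E0_uM",
    "v_uM_per_s", "se_v", "n", "r2", "window_s",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Timestamped fluorescence for one well."""

    well: str
    times: np.ndarray
    signal: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.size < 4 or t.size != y.size:
            raise InvalidInputError(
                f"well {self.well}: need >= 4 matched (time, signal) points"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(f"well {self.well}: times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class VelocityPoint:
    """An initial velocity tied to one assay condition."""

    condition: AssayCondition
    v: float
    se_v: float
    n_replicates: int = 1
    window: tuple[float, float] = (0.0, 0.0)
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.se_v < 0:
            raise InvalidInputError("se_v must be >= 0")


@dataclass(frozen=True)
class WindowPolicy:
    """Prefix-window selection rule for the linear range of a progress curve."""

    r2_min: float = 0.98
    min_points: int = 4


def fit_calibration(nadh_uM, rfu) -> Calibration:
    """Least-squares NADH calibration line from standard measurements.

    Requires at least three standards spanning a nonzero concentration
    range. The standards' span is stored as the calibration's valid range;
    converting signals outside it triggers an extrapolation warning
    downstream.
    """
    c = np.asarray(nadh_uM, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if c.size < 3 or c.size != y.size:
        raise InvalidInputError("need >= 3 (nadh_uM, rfu) standard pairs")
    if np.ptp(c) == 0:
        raise InvalidInputError("calibration standards span a zero concentration range")
    res = stats.linregress(c, y)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(c.min()), float(c.max())),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def subtract_background(curve: ProgressCurve, background_curves) -> ProgressCurve:
    """Subtract the time-matched mean background signal from a well.

    Per-timepoint (not per-well-mean) subtraction, so slow common drift in
    the background wells is absorbed. All background wells must share the
    sample well's read schedule.
    """
    bg = list(background_curves)
    if not bg:
        raise InvalidInputError("no background wells supplied")
    for b in bg:
        if b.times.shape != curve.times.shape or not np.allclose(b.times, curve.times):
            raise InvalidInputError(
                f"background well {b.well} schedule does not match well {curve.well}"
            )
    mean_bg = np.mean([b.signal for b in bg], axis=0)
    return ProgressCurve(
        well=curve.well, times=curve.times, signal=curve.signal - mean_bg, role=curve.role
    )


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope-se and r^2 of a straight-line fit; exact-fit degeneracies -> r2=1."""
    n = t.size
    tm = t - t.mean()
    ym = y - y.mean()
    stt = float(tm @ tm)
    slope = float(tm @ ym) / stt
    resid = ym - slope * tm
    sse = float(resid @ resid)
    sst = float(ym @ ym)
    # flat or perfectly linear signal: call it a perfect fit
    scale = max(sst, (abs(y).max() + 1.0) ** 2 * 1e-24)
    r2 = 1.0 if sse <= 1e-12 * scale else 1.0 - sse / sst
    se = np.sqrt(sse / (n - 2) / stt) if n > 2 else np.inf
    return slope, float(se), r2


def initial_velocity(
    curve: ProgressCurve,
    calibration: Calibration,
    policy: WindowPolicy = WindowPolicy(),
) -> tuple[float, float, float, tuple[float, float]]:
    """Initial velocity of a background-corrected curve, uM/s.

    Returns (v, se_v, r_squared, window). The window is the longest prefix
    of the curve whose linear fit reaches the policy's r^2 threshold; if no
    prefix qualifies the full curve is used and the (sub-threshold) r^2 is
    reported so the caller can judge the well.
    """
    if calibration is None:
        raise InvalidInputError("calibration required")
    t, y = curve.times, curve.signal
    if t.size < policy.min_points:
        raise InvalidInputError(f"well {curve.well}: fewer than {policy.min_points} points")

    chosen = None
    for n in range(t.size, policy.min_points - 1, -1):
        slope, se, r2 = _linfit(t[:n], y[:n])
        if chosen is None:
            full = (slope, se, r2, n)
        if r2 >= policy.r2_min:
            chosen = (slope, se, r2, n)
            break
    if chosen is None:
        chosen = full
    slope, se, r2, n = chosen

    conc_span = (y[:n].min() - calibration.intercept) / calibration.slope, (
        y[:n].max() - calibration.intercept
    ) / calibration.slope
    lo, hi = calibration.valid_range
    # read noise routinely pushes the implied concentration slightly past the
    # standards' span; only warn for genuine extrapolation (>2% of the range)
    tol = 0.02 * (hi - lo) if np.isfinite(hi - lo) else 0.0
    if min(conc_span) < lo - tol or max(conc_span) > hi + tol:
        warnings.warn(
            f"well {curve.well}: signal implies NADH outside the calibration range "
            f"[{lo:g}, {hi:g}] uM",
            stacklevel=2,
        )
    v = slope / calibration.slope
    se_v = se / calibration.slope if np.isfinite(se) else 0.0
    return float(v), float(se_v), float(r2), (float(t[0]), float(t[n - 1]))


def _same_condition(a: AssayCondition, b: AssayCondition) -> bool:
    return (
        a.substrate_id == b.substrate_id
        and np.isclose(a.conc_XCoA, b.conc_XCoA)
        and np.isclose(a.conc_ACP, b.conc_ACP)
        and np.isclose(a.conc_E0, b.conc_E0)
    )


def average_replicates(points) -> VelocityPoint:
    """Mean velocity over technical replicates, se = sd/sqrt(n).

    All points must share one assay condition. A single point passes
    through with its own slope-based standard error.
    """
    pts = list(points)
    if not pts:
        raise InvalidInputError("no velocity points supplied")
    ref = pts[0].condition
    for p in pts[1:]:
        if not _same_condition(ref, p.condition):
            raise InvalidInputError("replicates mix different assay conditions")
    if len(pts) == 1:
        return pts[0]
    vs = np.array([p.v for p in pts])
    se = float(np.std(vs, ddof=1) / np.sqrt(len(vs)))
    return VelocityPoint(
        condition=ref,
        v=float(vs.mean()),
        se_v=se,
        n_replicates=len(pts),
        window=pts[0].window,
        r_squared=float(np.mean([p.r_squared for p in pts])),
    )


def specific_activity(point: VelocityPoint, E0: float, control: VelocityPoint | None = None) -> float:
    """Enzyme-normalized turnover (v - v_control)/E0, 1/s.

    The control is typically a catalytically dead knockout variant; without
    one the uncorrected v/E0 is returned with a logged warning. Negative
    results are reported as-is.
    """
    if E0 <= 0:
        raise InvalidInputError("E0 must be positive")
    if control is None:
        logger.warning("no knockout control supplied; returning uncorrected v/E0")
        return point.v / E0
    return (point.v - control.v) / E0


def hydrolysis_rate(no_acp_points, E0: float) -> tuple[float, float]:
    """Acceptor-independent hydrolysis turnover from no-ACP control wells, 1/s.

    Returns (mean v/E0, propagated se). The standard error is reported
    honestly even when the interval spans zero.
    """
    pts = list(no_acp_points)
    if not pts:
        raise InvalidInputError("no no-ACP control wells supplied")
    if E0 <= 0:
        raise InvalidInputError("E0 must be positive")
    vs = np.array([p.v for p in pts])
    rate = float(vs.mean() / E0)
    if len(pts) > 1:
        se = float(np.std(vs, ddof=1) / np.sqrt(len(vs)) / E0)
    else:
        se = float(pts[0].se_v / E0)
    return rate, se


def _curves_by_role(dataset: PlateDataset) -> dict[str, list[ProgressCurve]]:
    out: dict[str, list[ProgressCurve]] = {}
    layout = dataset.layout.set_index("well")
    for well, grp in dataset.signals.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        role = str(layout.loc[well, "role"])
        out.setdefault(role, []).append(
            ProgressCurve(well=well, times=grp["time_s"].to_numpy(),
                          signal=grp["rfu"].to_numpy(), role=role)
        )
    return out


def extract_velocities(
    dataset: PlateDataset,
    policy: WindowPolicy = WindowPolicy(),
    subtract_hydrolysis: bool = False,
) -> pd.DataFrame:
    """Full extraction pipeline for one plate.

    Fits the calibration from standard wells, subtracts the mean background,
    estimates each sample well's initial velocity, and averages technical
    replicates. With ``subtract_hydrolysis`` the mean no-ACP control
    velocity is subtracted from every sample velocity (off by default; both
    conventions are defensible and the hydrolysis rate is small).

    Returns the velocities table (one row per condition) with columns
    substrate_id, conc_xcoa_uM, conc_acp_uM, conc_E0_uM, v_uM_per_s, se_v,
    n, r2, window_s.
    """
    dataset.validate()
    by_role = _curves_by_role(dataset)
    if "standard" not in by_role or dataset.standards.empty:
        raise InvalidInputError("no calibration standard wells in dataset")
    if "background" not in by_role:
        raise InvalidInputError("no background wells in dataset")

    backgrounds = by_role["background"]
    std_level = {r["well"]: float(r["nadh_uM"]) for _, r in dataset.standards.iterrows()}
    std_c, std_rfu = [], []
    for c in by_role["standard"]:
        if c.well not in std_level:
            raise InvalidInputError(f"standard well {c.well} missing from standards table")
        corrected = subtract_background(c, backgrounds)
        std_c.append(std_level[c.well])
        std_rfu.append(float(corrected.signal.mean()))
    calibration = fit_calibration(std_c, std_rfu)
    logger.info(
        "calibration: slope %.4g RFU/uM, intercept %.4g RFU", calibration.slope, calibration.intercept
    )

    layout = dataset.layout.set_index("well")

    def well_velocity(curve: ProgressCurve) -> VelocityPoint:
        corrected = subtract_background(curve, backgrounds)
        v, se_v, r2, window = initial_velocity(corrected, calibration, policy)
        row = layout.loc[curve.well]
        cond = AssayCondition(
            substrate_id=str(row["substrate_id"]),
            conc_XCoA=float(row["conc_xcoa_uM"]),
            conc_ACP=float(row["conc_acp_uM"]),
            conc_E0=float(row["conc_E0_uM"]),
        )
        logger.debug("well %s: v=%.4g uM/s window=%s r2=%.4f", curve.well, v, window, r2)
        return VelocityPoint(cond, v, se_v, 1, window, r2)

    hyd_correction = 0.0
    if subtract_hydrolysis:
        hyd_pts = [well_velocity(c) for c in by_role.get("no_acp_control", [])]
        if not hyd_pts:
            raise InvalidInputError("subtract_hydrolysis requested but no no-ACP control wells")
        hyd_correction = float(np.mean([p.v for p in hyd_pts]))

    rows = []
    groups: dict[tuple, list[VelocityPoint]] = {}
    for curve in by_role.get("sample", []):
        p = well_velocity(curve)
        key = (p.condition.substrate_id, round(p.condition.conc_XCoA, 9),
               round(p.condition.conc_ACP, 9), round(p.condition.conc_E0, 9))
        groups.setdefault(key, []).append(p)
    for key in sorted(groups):
        avg = average_replicates(groups[key])
        c = avg.condition
        rows.append(
            {
                "substrate_id": c.substrate_id,
                "conc_xcoa_uM": c.conc_XCoA,
                "conc_acp_uM": c.conc_ACP,
                "conc_E0_uM": c.conc_E0,
                "v_uM_per_s": avg.v - hyd_correction,
                "se_v": avg.se_v,
                "n": avg.n_replicates,
                "r2": avg.r_squared,
                "window_s": avg.window[1] - avg.window[0],
            }
        )
    return pd.DataFrame(rows, columns=VELOCITY_TABLE_COLUMNS)
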