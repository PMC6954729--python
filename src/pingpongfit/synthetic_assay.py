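"""Synthetic plate-reader datasets for the coupled transacylation assay.

The alpha-ketoglutarate-dehydrogenase-coupled assay reports transacylation
turnover as rising NADH fluorescence: every CoA released by transfer of an
acyl group to holo-ACP (or by enzyme-catalyzed hydrolysis in acceptor-free
wells) yields one NADH. This module generates the full measurement stack the
analysis code consumes: two-substrate titration designs, true velocities
from a chosen rate law, and realistic plates (sample, background, standard
and control wells on a shared read schedule) with multiplicative velocity
noise and additive read noise. Everything is seeded and reproducible: the
same seed yields a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rate_models import (
    InvalidInputError,
    RateParamsHill,
    RateParamsPingPong,
    hill_velocity,
    pingpong_velocity,
)

__all__ = [
    "TitrationDesign",
    "NoiseModel",
    "Calibration",
    "PlateDataset",
    "KNOWN_SUBSTRATES",
    "MM_DESIGN_MULTIPLES",
    "design_default_grid",
    "design_mm_series",
    "simulate_velocities",
    "simulate_progress_curves",
    "write_plate_files",
    "read_plate_files",
]

#: Number of fixed acceptor (ACP) series per donor substrate in the default
#: titration design: six for octanoyl-CoA, five for myristoyl-CoA.
KNOWN_SUBSTRATES: dict[str, int] = {"C8-CoA": 6, "C14-CoA": 5}

#: The eight-point single-substrate design, as multiples of the Km estimate.
MM_DESIGN_MULTIPLES = np.array([0.2, 0.3, 0.5, 0.75, 1.25, 2.0, 3.0, 5.0])

_ROLES = ("sample", "background", "standard", "no_acp_control", "knockout_control")

LAYOUT_COLUMNS = [
    "well", "role", "substrate_id", "conc_xcoa_uM", "conc_acp_uM", "conc_E0_uM", "replicate",
]


@dataclass(frozen=True)
class TitrationDesign:
    """A two-substrate titration grid: donor levels crossed with fixed acceptor levels."""

    substrate_id: str
    xcoa_levels: tuple[float, ...]
    acp_levels: tuple[float, ...]
    conc_E0: float
    replicates: int = 1

    def __post_init__(self) -> None:
        for name, levels in (("xcoa_levels", self.xcoa_levels), ("acp_levels", self.acp_levels)):
            arr = np.asarray(levels, dtype=float)
            if arr.size == 0 or np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing and positive")
        if self.conc_E0 <= 0:
            raise InvalidInputError("conc_E0 must be positive")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.xcoa_levels) * len(self.acp_levels)


@dataclass(frozen=True)
class NoiseModel:
    """Statistical noise of the simulated assay.

    velocity_cv : multiplicative Gaussian coefficient of variation on the
        true velocity (condition-to-condition scatter).
    read_sd : additive Gaussian standard deviation on each fluorescence
        read, RFU (instrument noise).
    background_level : constant plate background, RFU.
    seed : root seed; identical seeds give bit-identical datasets.
    """

    velocity_cv: float = 0.03
    read_sd: float = 2.0
    background_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_cv < 0 or self.read_sd < 0:
            raise InvalidInputError("velocity_cv and read_sd must be >= 0")


@dataclass(frozen=True)
class Calibration:
    """Linear NADH fluorescence calibration: rfu = slope * [NADH] + intercept.

    slope in RFU per uM NADH (must be positive), intercept in RFU;
    valid_range is the NADH span (uM) covered by the standards. slope_se /
    intercept_se carry the uncertainty of a fitted calibration and are zero
    for an exactly specified one.
    """

    slope: float
    intercept: float = 0.0
    valid_range: tuple[float, float] = (0.0, np.inf)
    slope_se: float = 0.0
    intercept_se: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError("calibration slope must be positive")


@dataclass
class PlateDataset:
    """One simulated (or loaded) plate: layout, signal time series, standards.

    layout : DataFrame with columns well, role, substrate_id, conc_xcoa_uM,
        conc_acp_uM, conc_E0_uM, replicate.
    signals : DataFrame with columns well, time_s, rfu; all wells share the
        same read schedule.
    standards : DataFrame with columns well, nadh_uM for calibration wells.
    """

    layout: pd.DataFrame
    signals: pd.DataFrame
    standards: pd.DataFrame

    def times(self) -> np.ndarray:
        """The shared read schedule, s."""
        return np.sort(self.signals["time_s"].unique())

    def curve(self, well: str) -> pd.DataFrame:
        sub = self.signals[self.signals["well"] == well]
        return sub.sort_values("time_s").reset_index(drop=True)

    def wells_by_role(self, role: str) -> list[str]:
        return list(self.layout.loc[self.layout["role"] == role, "well"])

    def validate(self) -> None:
        missing = set(self.signals["well"]) - set(self.layout["well"])
        if missing:
            raise InvalidInputError(
                f"signal wells missing from layout: {sorted(missing)[:5]}"
            )
        bad = set(self.layout["role"]) - set(_ROLES)
        if bad:
            raise InvalidInputError(f"unknown well roles: {sorted(bad)}")


def design_default_grid(substrate_id: str, conc_E0: float = 0.2, replicates: int = 1) -> TitrationDesign:
    """The default two-substrate titration grid for a donor substrate.

    Twelve log-spaced donor levels spanning 0.1-700 uM crossed with six
    (octanoyl-CoA) or five (myristoyl-CoA) log-spaced acceptor levels
    spanning 5-160 uM, at 0.2 uM enzyme. The log spacing concentrates
    points at the low-concentration end where saturating curves bend.
    """
    if substrate_id not in KNOWN_SUBSTRATES:
        raise InvalidInputError(
            f"unknown substrate {substrate_id!r}; known: {sorted(KNOWN_SUBSTRATES)}"
        )
    n_acp = KNOWN_SUBSTRATES[substrate_id]
    xcoa = np.geomspace(0.1, 700.0, 12)
    acp = np.geomspace(5.0, 160.0, n_acp)
    return TitrationDesign(
        substrate_id=substrate_id,
        xcoa_levels=tuple(xcoa),
        acp_levels=tuple(acp),
        conc_E0=conc_E0,
        replicates=replicates,
    )


def design_mm_series(Km_guess: float) -> np.ndarray:
    """Eight donor concentrations bracketing a Km estimate.

    Returns Km_guess x {0.2, 0.3, 0.5, 0.75, 1.25, 2, 3, 5}, ascending --
    the iterative single-substrate design used for apparent Michaelis-Menten
    constants.
    """
    if not np.isfinite(Km_guess) or Km_guess <= 0:
        raise InvalidInputError(f"Km_guess must be positive, got {Km_guess!r}")
    return Km_guess * MM_DESIGN_MULTIPLES


def _true_velocities(params, design: TitrationDesign, model: str | None):
    if model is None:
        model = "hill" if isinstance(params, RateParamsHill) else "pingpong"
    if model == "hill":
        if not isinstance(params, RateParamsHill):
            raise InvalidInputError("model 'hill' requires RateParamsHill")
        fn = lambda a, b, e0: hill_velocity(
            a, b, e0, params.kcat, params.Kp_XCoA, params.Kp_ACP, params.h_XCoA, params.h_ACP
        )
    elif model == "pingpong":
        if not isinstance(params, RateParamsPingPong):
            raise InvalidInputError("model 'pingpong' requires RateParamsPingPong")
        fn = lambda a, b, e0: pingpong_velocity(
            a, b, e0, params.kcat, params.Km_XCoA, params.Km_ACP
        )
    else:
        raise InvalidInputError(f"unknown model {model!r}; expected 'pingpong' or 'hill'")
    return fn


def simulate_velocities(
    params,
    design: TitrationDesign,
    noise: NoiseModel,
    model: str | None = None,
) -> pd.DataFrame:
    """Draw observed initial velocities for every condition of a design.

    Observed velocity v_obs = v_true * (1 + eps), eps ~ N(0, velocity_cv^2),
    independent across conditions and replicates. Returns a tidy DataFrame
    with one row per (donor level, acceptor level, replicate):
    substrate_id, conc_xcoa_uM, conc_acp_uM, conc_E0_uM, replicate,
    v_true_uM_per_s, v_uM_per_s.
    """
    fn = _true_velocities(params, design, model)
    rng = np.random.default_rng(noise.seed)
    a_grid, b_grid = np.meshgrid(design.xcoa_levels, design.acp_levels, indexing="ij")
    a = np.repeat(a_grid.ravel(), design.replicates)
    b = np.repeat(b_grid.ravel(), design.replicates)
    rep = np.tile(np.arange(1, design.replicates + 1), design.n_conditions)
    v_true = np.asarray(fn(a, b, design.conc_E0), dtype=float)
    eps = rng.normal(0.0, noise.velocity_cv, size=v_true.shape) if noise.velocity_cv > 0 else 0.0
    v_obs = v_true * (1.0 + eps)
    return pd.DataFrame(
        {
            "substrate_id": design.substrate_id,
            "conc_xcoa_uM": a,
            "conc_acp_uM": b,
            "conc_E0_uM": design.conc_E0,
            "replicate": rep,
            "v_true_uM_per_s": v_true,
            "v_uM_per_s": v_obs,
        }
    )


DEFAULT_STANDARDS_UM = tuple(np.linspace(0.0, 8.0, 5))


def _nadh_produced(v_obs: float, a0: float, t: np.ndarray, depletion: bool) -> np.ndarray:
    """NADH concentration produced by time t at observed initial velocity v_obs.

    Linear mode: v_obs * t. Depletion mode: the donor pool a0 is consumed
    first-order, P(t) = a0 * (1 - exp(-v_obs*t/a0)), which has initial slope
    v_obs and saturates at a0.
    """
    if not depletion or v_obs <= 0 or a0 <= 0:
        return v_obs * t
    k = v_obs / a0
    return a0 * (1.0 - np.exp(-k * t))


def simulate_progress_curves(
    velocities: pd.DataFrame,
    calibration: Calibration,
    schedule: tuple[float, float] = (10.0, 300.0),
    noise: NoiseModel = NoiseModel(),
    depletion: bool = False,
    n_background: int = 3,
    standards_uM: tuple[float, ...] = DEFAULT_STANDARDS_UM,
    hydrolysis_rate: float | None = None,
    n_no_acp: int = 3,
    n_knockout: int = 0,
) -> PlateDataset:
    """Convert observed velocities into a full plate of progress curves.

    Each sample well reads background + intercept + slope * NADH(t) + read
    noise; background wells read background + read noise only; standard
    wells hold a fixed NADH concentration; no-ACP control wells (generated
    when ``hydrolysis_rate`` in 1/s is given) progress at the
    acceptor-independent hydrolysis velocity. ``schedule`` is (interval,
    duration) in seconds; intervals follow the instrument's 5-22 s range.
    """
    if calibration is None:
        raise InvalidInputError("a Calibration is required to build progress curves")
    interval, duration = schedule
    if not (5.0 <= interval <= 22.0):
        raise InvalidInputError(f"read interval must be within [5, 22] s, got {interval!r}")
    t = np.arange(0.0, duration + interval / 2, interval)
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 1]))

    layout_rows: list[dict] = []
    signal_frames: list[pd.DataFrame] = []
    standards_rows: list[dict] = []

    def add_well(well: str, role: str, ideal: np.ndarray, cond: dict | None = None) -> None:
        read_noise = rng.normal(0.0, noise.read_sd, size=t.shape) if noise.read_sd > 0 else 0.0
        signal_frames.append(pd.DataFrame({"well": well, "time_s": t, "rfu": ideal + read_noise}))
        row = {
            "well": well,
            "role": role,
            "substrate_id": "",
            "conc_xcoa_uM": 0.0,
            "conc_acp_uM": 0.0,
            "conc_E0_uM": 0.0,
            "replicate": 1,
        }
        if cond:
            row.update(cond)
        layout_rows.append(row)

    base = noise.background_level
    for i, (_, r) in enumerate(velocities.iterrows(), start=1):
        nadh = _nadh_produced(float(r["v_uM_per_s"]), float(r["conc_xcoa_uM"]), t, depletion)
        ideal = base + calibration.intercept + calibration.slope * nadh
        add_well(
            f"S{i:03d}",
            "sample",
            ideal,
            {
                "substrate_id": r["substrate_id"],
                "conc_xcoa_uM": float(r["conc_xcoa_uM"]),
                "conc_acp_uM": float(r["conc_acp_uM"]),
                "conc_E0_uM": float(r["conc_E0_uM"]),
                "replicate": int(r["replicate"]),
            },
        )

    for i in range(1, n_background + 1):
        add_well(f"B{i:02d}", "background", np.full_like(t, base))

    for i, c in enumerate(standards_uM, start=1):
        well = f"N{i:02d}"
        ideal = np.full_like(t, base + calibration.intercept + calibration.slope * float(c))
        add_well(well, "standard", ideal)
        standards_rows.append({"well": well, "nadh_uM": float(c)})

    if hydrolysis_rate is not None and n_no_acp > 0:
        e0 = float(velocities["conc_E0_uM"].iloc[0]) if len(velocities) else 0.2
        sub = str(velocities["substrate_id"].iloc[0]) if len(velocities) else ""
        a_hyd = float(velocities["conc_xcoa_uM"].max()) if len(velocities) else 500.0
        v_hyd = hydrolysis_rate * e0
        for i in range(1, n_no_acp + 1):
            eps = rng.normal(0.0, noise.velocity_cv) if noise.velocity_cv > 0 else 0.0
            v_obs = v_hyd * (1.0 + eps)
            ideal = base + calibration.intercept + calibration.slope * v_obs * t
            add_well(
                f"H{i:02d}",
                "no_acp_control",
                ideal,
                {
                    "substrate_id": sub,
                    "conc_xcoa_uM": a_hyd,
                    "conc_acp_uM": 0.0,
                    "conc_E0_uM": e0,
                    "replicate": i,
                },
            )

    for i in range(1, n_knockout + 1):
        # catalytically dead double-knockout control: no signal above background
        ideal = np.full_like(t, base + calibration.intercept)
        add_well(f"K{i:02d}", "knockout_control", ideal, {"replicate": i})

    dataset = PlateDataset(
        layout=pd.DataFrame(layout_rows, columns=LAYOUT_COLUMNS),
        signals=(
            pd.concat(signal_frames, ignore_index=True)
            if signal_frames
            else pd.DataFrame(columns=["well", "time_s", "rfu"])
        ),
        standards=pd.DataFrame(standards_rows, columns=["well", "nadh_uM"]),
    )
    dataset.validate()
    return dataset


def write_plate_files(dataset: PlateDataset, path) -> None:
    """Write a plate as three CSV files (signals, layout, standards) under path."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.signals.to_csv(path / "signals.csv", index=False)
    dataset.layout.to_csv(path / "layout.csv", index=False)
    dataset.standards.to_csv(path / "standards.csv", index=False)


def read_plate_files(path) -> PlateDataset:
    """Read a plate written by :func:`write_plate_files`; validates layout coverage."""
    from pathlib import Path

    path = Path(path)
    try:
        signals = pd.read_csv(path / "signals.csv", float_precision="round_trip")
        layout = pd.read_csv(path / "layout.csv", keep_default_na=False,
                             float_precision="round_trip")
        standards = pd.read_csv(path / "standards.csv", float_precision="round_trip")
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise InvalidInputError(f"cannot parse plate files under {path}: {exc}") from exc
    for df, cols, name in (
        (signals, ["well", "time_s", "rfu"], "signals.csv"),
        (layout, LAYOUT_COLUMNS, "layout.csv"),
        (standards, ["well", "nadh_uM"], "standards.csv"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise InvalidInputError(f"{name} is missing columns {missing}")
    dataset = PlateDataset(layout=layout, signals=signals, standards=standards)
    dataset.validate()
    return dataset
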