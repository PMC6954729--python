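"""Steady-state rate laws for two-substrate transacylation kinetics.

The transacylation of an acyl group from an acyl-CoA donor (A, "X-CoA") to a
holo-ACP acceptor (B) by an acyltransferase proceeds through a covalent
acyl-enzyme intermediate and therefore follows ping-pong bi-bi kinetics:

    v = kcat * E0 * A * B / (A*Km_ACP + B*Km_XCoA + A*B)

For a dimeric enzyme whose two active sites communicate, the saturation
curves become sigmoidal; this is captured by raising each substrate
concentration to a Hill exponent h:

    v = kcat * E0 * A^hA * B^hB / (A^hA*Kp_ACP + B^hB*Kp_XCoA + A^hA*B^hB)

where the half-saturation constants K' carry units of concentration^h.
All concentrations are in uM, time in s, velocities in uM/s; specificity
constants kcat/K are reported in 1/(M*s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidInputError",
    "RateParamsPingPong",
    "RateParamsHill",
    "AssayCondition",
    "MMParams",
    "rate_pingpong",
    "rate_hill",
    "rate_mm_single",
    "apparent_params_at_fixed_acp",
    "specificity_constant",
]


class InvalidInputError(ValueError):
    """Raised when kinetic parameters or assay conditions are out of domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


def _positive_finite(name: str, value: float) -> None:
    _require(math.isfinite(value) and value > 0, f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class RateParamsPingPong:
    """Parameters of the ping-pong bi-bi rate law.

    kcat : turnover number, 1/s
    Km_XCoA : Michaelis constant of the acyl-CoA donor, uM
    Km_ACP : Michaelis constant of the ACP acceptor, uM
    """

    kcat: float
    Km_XCoA: float
    Km_ACP: float

    def __post_init__(self) -> None:
        _positive_finite("kcat", self.kcat)
        _positive_finite("Km_XCoA", self.Km_XCoA)
        _positive_finite("Km_ACP", self.Km_ACP)

    def to_dict(self) -> dict[str, float]:
        return {"kcat": self.kcat, "Km_XCoA": self.Km_XCoA, "Km_ACP": self.Km_ACP}


@dataclass(frozen=True)
class RateParamsHill:
    """Parameters of the Hill-cooperative ping-pong rate law.

    kcat : turnover number, 1/s
    Kp_XCoA, Kp_ACP : half-saturation constants K', uM^h (unit depends on h)
    h_XCoA, h_ACP : Hill exponents, dimensionless, in (0, 10]
    shared_h : if True both exponents are forced equal

    Because K' carries units of concentration^h, the derived quantity
    K'^(1/h) ("effective half-saturation concentration", uM) is exposed via
    :meth:`half_saturation_XCoA` / :meth:`half_saturation_ACP` and should be
    the value passed to :func:`specificity_constant`.
    """

    kcat: float
    Kp_XCoA: float
    Kp_ACP: float
    h_XCoA: float = 1.0
    h_ACP: float = 1.0
    shared_h: bool = True

    def __post_init__(self) -> None:
        _positive_finite("kcat", self.kcat)
        _positive_finite("Kp_XCoA", self.Kp_XCoA)
        _positive_finite("Kp_ACP", self.Kp_ACP)
        for name in ("h_XCoA", "h_ACP"):
            h = getattr(self, name)
            _require(math.isfinite(h) and 0 < h <= 10, f"{name} must lie in (0, 10], got {h!r}")
        if self.shared_h:
            _require(
                self.h_XCoA == self.h_ACP,
                "shared_h requires h_XCoA == h_ACP exactly",
            )

    @property
    def half_saturation_XCoA(self) -> float:
        """Effective donor half-saturation concentration K'^(1/h), uM."""
        return self.Kp_XCoA ** (1.0 / self.h_XCoA)

    @property
    def half_saturation_ACP(self) -> float:
        """Effective acceptor half-saturation concentration K'^(1/h), uM."""
        return self.Kp_ACP ** (1.0 / self.h_ACP)

    def to_dict(self) -> dict[str, float]:
        return {
            "kcat": self.kcat,
            "Kp_XCoA": self.Kp_XCoA,
            "Kp_ACP": self.Kp_ACP,
            "h_XCoA": self.h_XCoA,
            "h_ACP": self.h_ACP,
        }


@dataclass(frozen=True)
class AssayCondition:
    """Chemistry of one assay well.

    conc_XCoA : acyl-CoA donor concentration, uM
    conc_ACP : holo-ACP acceptor concentration, uM
    conc_E0 : total enzyme concentration [AT]0, uM
    """

    substrate_id: str
    conc_XCoA: float
    conc_ACP: float
    conc_E0: float
    temperature: float = 30.0

    def __post_init__(self) -> None:
        _require(self.conc_XCoA >= 0, f"conc_XCoA must be >= 0, got {self.conc_XCoA!r}")
        _require(self.conc_ACP >= 0, f"conc_ACP must be >= 0, got {self.conc_ACP!r}")
        _require(self.conc_E0 > 0, f"conc_E0 must be > 0, got {self.conc_E0!r}")


@dataclass(frozen=True)
class MMParams:
    """Apparent Michaelis-Menten parameters at a fixed acceptor concentration."""

    Km_app: float
    kcat_app: float

    def __post_init__(self) -> None:
        _positive_finite("Km_app", self.Km_app)
        _positive_finite("kcat_app", self.kcat_app)


# -- vectorized kernels (used by the fitting module) -------------------------

def pingpong_velocity(A, B, e0, kcat, km_a, km_b):
    """Ping-pong bi-bi velocity; A, B may be arrays. No validation."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = kcat * e0 * A * B
    den = A * km_b + B * km_a + A * B
    with np.errstate(invalid="ignore"):
        v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return v if v.ndim else float(v)


def hill_velocity(A, B, e0, kcat, kp_a, kp_b, h_a, h_b):
    """Hill-cooperative ping-pong velocity; A, B may be arrays. No validation."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ah = np.power(A, h_a)
    Bh = np.power(B, h_b)
    num = kcat * e0 * Ah * Bh
    den = Ah * kp_b + Bh * kp_a + Ah * Bh
    with np.errstate(invalid="ignore"):
        v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return v if v.ndim else float(v)


# -- public scalar API --------------------------------------------------------

def rate_pingpong(p: RateParamsPingPong, c: AssayCondition) -> float:
    """Velocity (uM/s) of the ping-pong bi-bi mechanism for one condition.

    Returns 0 when either substrate is absent; for finite concentrations the
    result is strictly below the saturating velocity kcat*E0.
    """
    if not isinstance(p, RateParamsPingPong):
        raise InvalidInputError("rate_pingpong requires RateParamsPingPong")
    return pingpong_velocity(c.conc_XCoA, c.conc_ACP, c.conc_E0, p.kcat, p.Km_XCoA, p.Km_ACP)


def rate_hill(p: RateParamsHill, c: AssayCondition) -> float:
    """Velocity (uM/s) of the Hill-cooperative rate law for one condition.

    Reduces exactly to :func:`rate_pingpong` when both exponents are 1 and
    the K' constants equal the Michaelis constants.
    """
    if not isinstance(p, RateParamsHill):
        raise InvalidInputError("rate_hill requires RateParamsHill")
    return hill_velocity(
        c.conc_XCoA, c.conc_ACP, c.conc_E0, p.kcat, p.Kp_XCoA, p.Kp_ACP, p.h_XCoA, p.h_ACP
    )


def rate_mm_single(p: MMParams, S: float, E0: float) -> float:
    """Single-substrate Michaelis-Menten velocity v = kcat_app*E0*S/(Km_app+S), uM/s."""
    _require(S >= 0, f"substrate concentration must be >= 0, got {S!r}")
    _require(E0 > 0, f"E0 must be > 0, got {E0!r}")
    return float(p.kcat_app * E0 * S / (p.Km_app + S))


def apparent_params_at_fixed_acp(p: RateParamsHill, conc_ACP: float) -> tuple[float, float]:
    """Factor the global Hill law into an apparent single-substrate Hill form.

    At a fixed acceptor concentration B the rate law in the donor A is
    exactly v = kcat_app * E0 * A^h / (A^h + K_app) with

        kcat_app = kcat * B^h / (B^h + Kp_ACP)
        K_app    = Kp_XCoA * B^h / (B^h + Kp_ACP)

    Returns (kcat_app, K_app). Useful for per-series plotting and for
    checking the global fit against single-series fits.
    """
    _require(conc_ACP > 0, f"conc_ACP must be > 0, got {conc_ACP!r}")
    bh = conc_ACP ** p.h_ACP
    frac = bh / (bh + p.Kp_ACP)
    return p.kcat * frac, p.Kp_XCoA * frac


def specificity_constant(kcat: float, K: float) -> float:
    """Second-order specificity constant kcat/K in 1/(M*s).

    kcat in 1/s, K in uM. For Hill parameters pass the effective
    half-saturation concentration K'^(1/h), not K' itself.
    """
    _require(K > 0, f"K must be > 0, got {K!r}")
    return kcat / (K * 1e-6)
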