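"""Global nonlinear regression of two-substrate velocity families.

Models are statsmodels-style: construct from data (or ``from_dataframe`` on
the velocities table), call ``fit()`` and get a results object with
estimates, asymptotic standard errors, covariance, residual diagnostics and
a ``summary()`` table.

Three models:

* :class:`MichaelisMentenModel` -- single-series v vs S at fixed acceptor.
* :class:`PingPongBiBiModel` -- one (kcat, Km_XCoA, Km_ACP) triple fit
  jointly to all fixed-acceptor series.
* :class:`HillKineticsModel` -- the cooperative variant with half-saturation
  constants K' (units uM^h) and one shared or two per-substrate Hill
  exponents.

"No parameter constraints" is honored structurally: the optimizer works in
log-parameter space, so positivity holds by parameterization rather than by
bounds; the Hill exponent alone is capped at 10 for numerical sanity and
flagged if it pins there. Standard errors come from the Jacobian at the
optimum via the delta method; a seeded nonparametric bootstrap is available
on the results object. Fits are unweighted by default (per-point 1/se^2
weighting by flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rate_models import InvalidInputError, hill_velocity, pingpong_velocity

__all__ = [
    "MichaelisMentenModel",
    "PingPongBiBiModel",
    "HillKineticsModel",
    "MMFitResult",
    "GlobalFitResult",
    "ModelComparison",
    "fit_mm",
    "fit_global_pingpong",
    "fit_global_hill",
    "residual_diagnostics",
    "runs_test",
    "compare_models",
]

_H_CAP = 10.0


# --------------------------------------------------------------------------
# runs test

def runs_test(signs: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on a sign sequence (zeros dropped).

    Returns (z, p) where p is the one-sided lower-tail probability: small p
    means fewer runs than expected by chance, i.e. residuals of like sign
    cluster -- the signature of a systematic misfit. All-zero residuals
    return (0, 1) by convention; so do one-sided sequences.
    """
    s = np.asarray(signs)
    s = s[s != 0]
    n1 = int(np.sum(s > 0))
    n2 = int(np.sum(s < 0))
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    runs = int(1 + np.sum(s[1:] != s[:-1]))
    n = n1 + n2
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(z), float(stats.norm.cdf(z))


# --------------------------------------------------------------------------
# results

@dataclass
class MMFitResult:
    """Apparent Michaelis-Menten fit of one fixed-acceptor series."""

    Km_app: float
    kcat_app: float
    bse: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    n_restarts_used: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {"Km_app": self.Km_app, "kcat_app": self.kcat_app}

    def summary(self) -> str:
        lines = [
            "Apparent Michaelis-Menten fit",
            f"  n = {self.n_points}, rss = {self.rss:.6g}, converged = {self.converged}",
            f"  Km_app   = {self.Km_app:.4g} +/- {self.bse['Km_app']:.2g} uM",
            f"  kcat_app = {self.kcat_app:.4g} +/- {self.bse['kcat_app']:.2g} 1/s",
        ]
        return "\n".join(lines)


@dataclass
class GlobalFitResult:
    """Results of a global two-substrate fit.

    ``params``/``bse`` are on the natural scale. ``cov_params`` is the
    delta-method covariance (DataFrame indexed by parameter name). ``resid``
    are observed - fitted, one per input point in input order.
    """

    model: str
    param_names: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    cov_params: pd.DataFrame
    resid: np.ndarray
    fittedvalues: np.ndarray
    rss: float
    n_points: int
    aic: float
    converged: bool
    n_restarts_used: int
    h_pinned: bool = False
    shared_h: bool | None = None
    data: pd.DataFrame | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def half_saturation(self) -> dict[str, float]:
        """Effective half-saturation concentrations K'^(1/h), uM (Hill only)."""
        if self.model != "hill":
            return {}
        h_a = self.params.get("h_XCoA", self.params.get("h"))
        h_b = self.params.get("h_ACP", self.params.get("h"))
        return {
            "K_half_XCoA": self.params["Kp_XCoA"] ** (1.0 / h_a),
            "K_half_ACP": self.params["Kp_ACP"] ** (1.0 / h_b),
        }

    def diagnostics(self) -> pd.DataFrame:
        """Per-series runs-test and end-bias diagnostics (see module docs)."""
        return residual_diagnostics(self)

    @property
    def systematic_deviation(self) -> bool:
        """Flag: do residuals cluster by sign along the donor axis?

        True when at least half of the testable fixed-acceptor series give a
        one-sided runs-test p < 0.05 -- the pattern seen when a
        non-cooperative law is forced onto sigmoidal series (deviations at
        low and high donor concentrations).
        """
        diag = self.diagnostics()
        ok = diag["runs_p"].notna()
        if not ok.any():
            return False
        return float((diag.loc[ok, "runs_p"] < 0.05).mean()) >= 0.5

    def to_dict(self) -> dict:
        """Flat key-value fit report."""
        out: dict = {"model": self.model, "rss": self.rss, "aic": self.aic,
                     "n_points": self.n_points, "converged": self.converged}
        for k in self.param_names:
            out[k] = self.params[k]
            out[f"se_{k}"] = self.bse[k]
        out.update(self.half_saturation())
        return out

    def summary(self) -> str:
        title = {
            "pingpong": "Global ping-pong bi-bi fit",
            "hill": "Global Hill-cooperative ping-pong fit",
        }[self.model]
        units = {"kcat": "1/s", "Km_XCoA": "uM", "Km_ACP": "uM",
                 "Kp_XCoA": "uM^h", "Kp_ACP": "uM^h", "h": "", "h_XCoA": "", "h_ACP": ""}
        lines = [title,
                 f"  n = {self.n_points}, rss = {self.rss:.6g}, aic = {self.aic:.4g}, "
                 f"converged = {self.converged} (restarts used: {self.n_restarts_used})"]
        for k in self.param_names:
            lines.append(f"  {k:9s} = {self.params[k]:10.4g} +/- {self.bse[k]:.3g} {units.get(k, '')}")
        for k, v in self.half_saturation().items():
            lines.append(f"  {k:12s} = {v:10.4g} uM  (derived, K'^(1/h))")
        if self.h_pinned:
            lines.append("  WARNING: Hill exponent pinned at the numerical cap")
        return "\n".join(lines)

    def bootstrap(self, n_resamples: int = 500, seed: int = 0) -> dict[str, float]:
        """Nonparametric bootstrap standard errors (resampling points).

        Refits from the point estimate for each resample; returns per-
        parameter standard deviations across successful resamples.
        """
        if self.data is None:
            raise InvalidInputError("results carry no data; bootstrap unavailable")
        rng = np.random.default_rng(seed)
        model_cls = {"pingpong": PingPongBiBiModel, "hill": HillKineticsModel}[self.model]
        a = self.data["conc_xcoa_uM"].to_numpy()
        b = self.data["conc_acp_uM"].to_numpy()
        v = self.data["v_uM_per_s"].to_numpy()
        e0 = self.data["conc_E0_uM"].to_numpy()
        draws: list[list[float]] = []
        x0 = np.log([self.params[k] for k in self.param_names])
        for _ in range(n_resamples):
            idx = rng.integers(0, len(v), size=len(v))
            kwargs = {"shared_h": self.shared_h} if self.model == "hill" else {}
            try:
                m = model_cls(v[idx], a[idx], b[idx], e0[idx], **kwargs)
                theta, _ = m._optimize(x0)
            except Exception:
                continue
            draws.append(list(np.exp(theta)))
        arr = np.array(draws)
        return {k: float(arr[:, i].std(ddof=1)) for i, k in enumerate(self.param_names)}

    def plot_fit(self, ax=None):
        """Overlay the fitted curves on the per-series data (donor on log x)."""
        import matplotlib.pyplot as plt

        if self.data is None:
            raise InvalidInputError("results carry no data; nothing to plot")
        if ax is None:
            _, ax = plt.subplots()
        e0 = float(self.data["conc_E0_uM"].iloc[0])
        for acp, grp in self.data.groupby("conc_acp_uM"):
            a = np.geomspace(grp["conc_xcoa_uM"].min(), grp["conc_xcoa_uM"].max(), 100)
            line = ax.plot(grp["conc_xcoa_uM"], grp["v_uM_per_s"], "o", ms=4,
                           label=f"[ACP] = {acp:g} uM")[0]
            ax.plot(a, _predict(self.model, self.params, a, np.full_like(a, acp), e0),
                    "-", color=line.get_color())
        ax.set_xscale("log")
        ax.set_xlabel("[X-CoA] (uM)")
        ax.set_ylabel("v (uM/s)")
        ax.legend(fontsize=7)
        return ax


def _predict(model: str, params: dict[str, float], a, b, e0):
    if model == "pingpong":
        return pingpong_velocity(a, b, e0, params["kcat"], params["Km_XCoA"], params["Km_ACP"])
    h_a = params.get("h_XCoA", params.get("h"))
    h_b = params.get("h_ACP", params.get("h"))
    return hill_velocity(a, b, e0, params["kcat"], params["Kp_XCoA"], params["Kp_ACP"], h_a, h_b)


# --------------------------------------------------------------------------
# models

class MichaelisMentenModel:
    """Unweighted least-squares Michaelis-Menten fit of v vs S.

    Parameters: velocities (uM/s), substrate concentrations S (uM) and the
    enzyme concentration E0 (uM). v = kcat_app * E0 * S / (Km_app + S).
    """

    def __init__(self, velocity, substrate, e0: float):
        self.v = np.asarray(velocity, dtype=float)
        self.s = np.asarray(substrate, dtype=float)
        if self.v.shape != self.s.shape:
            raise InvalidInputError("velocity and substrate must have the same length")
        if len(np.unique(self.s)) < 4:
            raise InvalidInputError("need >= 4 distinct substrate levels")
        if e0 <= 0:
            raise InvalidInputError("E0 must be positive")
        self.e0 = float(e0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, e0: float | None = None) -> "MichaelisMentenModel":
        if e0 is None:
            e0 = float(df["conc_E0_uM"].iloc[0])
        return cls(df["v_uM_per_s"].to_numpy(), df["conc_xcoa_uM"].to_numpy(), e0)

    def _resid(self, theta: np.ndarray) -> np.ndarray:
        km, kcat = np.exp(theta)
        return kcat * self.e0 * self.s / (km + self.s) - self.v

    def fit(self, n_starts: int = 5) -> MMFitResult:
        vmax = max(self.v.max(), 1e-12)
        kcat0 = vmax / self.e0
        starts = [
            np.log([np.median(self.s), kcat0]),
            np.log([np.quantile(self.s, 0.25), kcat0]),
            np.log([np.quantile(self.s, 0.75), 2 * kcat0]),
            np.log([self.s.max(), 2 * kcat0]),
            np.log([self.s.min(), kcat0]),
        ][:n_starts]
        best, used = None, 0
        for i, x0 in enumerate(starts):
            try:
                res = optimize.least_squares(self._resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best, used = res, i
            if best is not None and i == 0 and best.cost < 1e-30:
                break
        if best is None:
            raise InvalidInputError("Michaelis-Menten fit failed from every start")
        km, kcat = np.exp(best.x)
        rss = float(2 * best.cost)
        n, k = self.v.size, 2
        bse = _delta_bse(best.jac, best.fun, n, k, np.exp(best.x))
        converged = bool(best.success) and all(np.isfinite(list(bse)))
        return MMFitResult(
            Km_app=float(km),
            kcat_app=float(kcat),
            bse={"Km_app": bse[0], "kcat_app": bse[1]},
            rss=rss,
            n_points=n,
            converged=converged,
            n_restarts_used=used,
        )


def _cov_log(jac: np.ndarray, resid: np.ndarray, n: int, k: int) -> np.ndarray:
    """Heteroscedasticity-robust (sandwich) covariance in log-parameter space.

    cov = (J'J)^-1 J' diag(r^2) J (J'J)^-1 * n/(n-k). Velocity noise in this
    assay scales with the velocity itself, so the classical s^2 (J'J)^-1
    form undercovers the large-velocity parameters; the sandwich form stays
    calibrated without assuming a variance model.
    """
    try:
        bread = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)
    meat = jac.T @ (resid[:, None] ** 2 * jac)
    dof = max(n - k, 1)
    return bread @ meat @ bread * (n / dof)


def _delta_bse(jac: np.ndarray, resid: np.ndarray, n: int, k: int, p: np.ndarray) -> np.ndarray:
    """Natural-scale asymptotic ses from a log-space Jacobian (delta method)."""
    cov_log = _cov_log(jac, resid, n, k)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    return p * se_log


class _GlobalKineticModel:
    """Shared machinery for global two-substrate fits."""

    model_name: str = ""

    def __init__(self, velocity, conc_xcoa, conc_acp, e0, weights=None):
        self.v = np.asarray(velocity, dtype=float)
        self.a = np.asarray(conc_xcoa, dtype=float)
        self.b = np.asarray(conc_acp, dtype=float)
        e0 = np.asarray(e0, dtype=float)
        if e0.ndim == 0:
            e0 = np.full_like(self.v, float(e0))
        self.e0 = e0
        if not (self.v.shape == self.a.shape == self.b.shape == self.e0.shape):
            raise InvalidInputError("velocity, conc_xcoa, conc_acp, e0 must share a length")
        self.w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))
        series = np.unique(self.b)
        if series.size < 2:
            raise InvalidInputError("need >= 2 fixed-acceptor series for a global fit")
        for s in series:
            if len(np.unique(self.a[self.b == s])) < 4:
                raise InvalidInputError(
                    f"series at [ACP] = {s:g} uM has < 4 distinct donor levels"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, e0: float | None = None, weighted: bool = False, **kw):
        """Build from the velocities table (columns conc_xcoa_uM, conc_acp_uM, v_uM_per_s)."""
        e0_col = df["conc_E0_uM"].to_numpy() if e0 is None else e0
        weights = None
        if weighted:
            se = df["se_v"].to_numpy(dtype=float)
            weights = 1.0 / np.clip(se, np.nanmedian(se[se > 0]) * 1e-3, None) ** 2
        return cls(df["v_uM_per_s"].to_numpy(), df["conc_xcoa_uM"].to_numpy(),
                   df["conc_acp_uM"].to_numpy(), e0_col, weights=weights, **kw)

    # subclasses define param_names, _predict_theta, _starts

    def _resid(self, theta: np.ndarray) -> np.ndarray:
        r = self._predict_theta(theta) - self.v
        return r if self.w is None else self.w * r

    def _optimize(self, x0: np.ndarray):
        res = optimize.least_squares(
            self._resid, x0, method="trf", bounds=self._bounds(), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        return res.x, res

    def _bounds(self):
        k = len(self.param_names)
        return (np.full(k, -np.inf), np.full(k, np.inf))

    def fit(self, weighted: bool = False) -> GlobalFitResult:
        """Multi-start least squares; returns a :class:`GlobalFitResult`."""
        best, used, n_fail = None, 0, 0
        for i, x0 in enumerate(self._starts()):
            try:
                _, res = self._optimize(np.asarray(x0, dtype=float))
            except Exception:
                n_fail += 1
                continue
            if best is None or res.cost < best.cost * (1 - 1e-12):
                best, used = res, i
        if best is None:
            raise InvalidInputError(f"{self.model_name} global fit failed from every start")
        p = np.exp(best.x)
        rss = float(2 * best.cost)
        n, k = self.v.size, len(self.param_names)
        bse = _delta_bse(best.jac, best.fun, n, k, p)
        params = dict(zip(self.param_names, map(float, p)))
        resid = self.v - self._predict_theta(best.x)
        cov = pd.DataFrame(
            np.outer(p, p) * _cov_log(best.jac, best.fun, n, k),
            index=self.param_names, columns=self.param_names,
        )
        h_pinned = any(
            name.startswith("h") and params[name] > 0.999 * _H_CAP for name in self.param_names
        )
        converged = bool(best.success) and np.all(np.isfinite(bse)) and not h_pinned
        aic = n * math.log(max(rss, 1e-300) / n) + 2 * (k + 1)
        return GlobalFitResult(
            model=self.model_name,
            param_names=list(self.param_names),
            params=params,
            bse=dict(zip(self.param_names, map(float, bse))),
            cov_params=cov,
            resid=resid,
            fittedvalues=self.v - resid,
            rss=rss,
            n_points=n,
            aic=float(aic),
            converged=converged,
            n_restarts_used=used,
            h_pinned=h_pinned,
            shared_h=getattr(self, "shared_h", None),
            data=pd.DataFrame({
                "conc_xcoa_uM": self.a, "conc_acp_uM": self.b,
                "conc_E0_uM": self.e0, "v_uM_per_s": self.v,
            }),
        )


class PingPongBiBiModel(_GlobalKineticModel):
    """Global ping-pong bi-bi fit: one (kcat, Km_XCoA, Km_ACP) for all series."""

    model_name = "pingpong"
    param_names = ("kcat", "Km_XCoA", "Km_ACP")

    def _predict_theta(self, theta):
        kcat, km_a, km_b = np.exp(theta)
        return pingpong_velocity(self.a, self.b, self.e0, kcat, km_a, km_b)

    def _starts(self):
        kcat0 = max(self.v.max(), 1e-12) / np.median(self.e0)
        ka = [np.median(self.a), np.quantile(self.a, 0.25)]
        kb = [np.median(self.b), np.quantile(self.b, 0.75)]
        return [np.log([kcat0 * f, a, b]) for f in (1.0, 2.0) for a in ka for b in kb]


class HillKineticsModel(_GlobalKineticModel):
    """Global Hill-cooperative fit.

    With ``shared_h`` (default) one exponent applies to both substrates, as
    in the printed rate law; otherwise donor and acceptor get separate
    exponents. K' constants are in uM^h.
    """

    model_name = "hill"

    def __init__(self, velocity, conc_xcoa, conc_acp, e0, weights=None,
                 shared_h: bool = True, fix_h: float | None = None):
        super().__init__(velocity, conc_xcoa, conc_acp, e0, weights=weights)
        self.shared_h = bool(shared_h)
        self.fix_h = fix_h
        if fix_h is not None:
            if not shared_h:
                raise InvalidInputError("fix_h requires shared_h")
            self.param_names = ("kcat", "Kp_XCoA", "Kp_ACP")
        elif self.shared_h:
            self.param_names = ("kcat", "Kp_XCoA", "Kp_ACP", "h")
        else:
            self.param_names = ("kcat", "Kp_XCoA", "Kp_ACP", "h_XCoA", "h_ACP")

    def _bounds(self):
        k = len(self.param_names)
        lo, hi = np.full(k, -np.inf), np.full(k, np.inf)
        for i, name in enumerate(self.param_names):
            if name.startswith("h"):
                hi[i] = math.log(_H_CAP)
        return lo, hi

    def _predict_theta(self, theta):
        p = np.exp(theta)
        if self.fix_h is not None:
            kcat, kp_a, kp_b = p
            h_a = h_b = self.fix_h
        elif self.shared_h:
            kcat, kp_a, kp_b, h = p
            h_a = h_b = h
        else:
            kcat, kp_a, kp_b, h_a, h_b = p
        return hill_velocity(self.a, self.b, self.e0, kcat, kp_a, kp_b, h_a, h_b)

    def _starts(self):
        kcat0 = max(self.v.max(), 1e-12) / np.median(self.e0)
        ka = np.median(self.a)
        kb = np.median(self.b)
        h0s = (0.8, 1.0, 1.5, 2.0)
        starts = []
        if self.fix_h is not None:
            h = self.fix_h
            for f in (1.0, 2.0):
                for qa in (0.25, 0.5):
                    starts.append(np.log([kcat0 * f, np.quantile(self.a, qa) ** h, kb ** h]))
            return starts
        for h0 in h0s:
            for f in (1.0, 2.0):
                base = [kcat0 * f, ka ** h0, kb ** h0]
                if self.shared_h:
                    starts.append(np.log(base + [h0]))
                else:
                    starts.append(np.log(base + [h0, h0]))
        return starts


# --------------------------------------------------------------------------
# diagnostics & model comparison

def residual_diagnostics(fit: GlobalFitResult, min_points: int = 6) -> pd.DataFrame:
    """Per-series residual diagnostics of a converged global fit.

    Within each fixed-acceptor series, residuals are ordered by donor
    concentration and subjected to a Wald-Wolfowitz runs test on their
    signs (one-sided: too few runs = sign clustering). The end-bias scores
    are the mean residual signs in the bottom and top donor-concentration
    quartiles -- large same-sign values at both ends are the classic
    signature of fitting a non-cooperative law to sigmoidal data. Series
    with fewer than ``min_points`` points are skipped (runs_p = NaN).
    """
    if fit.data is None:
        raise InvalidInputError("fit carries no data")
    df = fit.data.assign(resid=fit.resid)
    rows = []
    for acp, grp in df.groupby("conc_acp_uM"):
        grp = grp.sort_values("conc_xcoa_uM")
        r = grp["resid"].to_numpy()
        signs = np.sign(np.where(np.abs(r) < 1e-300, 0.0, r))
        nq = max(len(r) // 4, 1)
        low_bias = float(np.mean(signs[:nq]))
        high_bias = float(np.mean(signs[-nq:]))
        if len(r) < min_points:
            z, p = np.nan, np.nan
        else:
            z, p = runs_test(signs)
        rows.append({
            "conc_acp_uM": float(acp), "n": len(r), "runs_z": z, "runs_p": p,
            "end_bias_low": low_bias, "end_bias_high": high_bias,
            "flagged": (p < 0.05) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """AIC (and, for nested pairs, F-test) comparison of two fits of one dataset."""

    preferred: str
    delta_aic: float
    f_stat: float | None = None
    f_pvalue: float | None = None

    def summary(self) -> str:
        s = f"Preferred model: {self.preferred} (delta AIC = {self.delta_aic:.3g})"
        if self.f_stat is not None:
            s += f"; F = {self.f_stat:.4g}, p = {self.f_pvalue:.3g}"
        return s


def compare_models(fit_a: GlobalFitResult, fit_b: GlobalFitResult,
                   delta_aic_threshold: float = 2.0) -> ModelComparison:
    """Compare two fits of the same dataset by AIC (and F-test when nested).

    The model with more parameters is preferred only when its AIC is lower
    by at least ``delta_aic_threshold``; ties and small differences go to
    the simpler model. The ping-pong law is the Hill law restricted to
    h = 1, so that pair also gets an extra-sum-of-squares F-test.
    """
    if fit_a.n_points != fit_b.n_points:
        raise InvalidInputError("fits are not on the same dataset (n differs)")
    if fit_a.data is not None and fit_b.data is not None:
        key = ["conc_xcoa_uM", "conc_acp_uM", "v_uM_per_s"]
        da = fit_a.data[key].sort_values(key).reset_index(drop=True)
        db = fit_b.data[key].sort_values(key).reset_index(drop=True)
        if not np.allclose(da.to_numpy(), db.to_numpy()):
            raise InvalidInputError("fits are not on the same dataset")
    simpler, complexer = sorted([fit_a, fit_b], key=lambda f: f.n_params)
    delta = simpler.aic - complexer.aic  # >0 favors the richer model
    preferred = complexer.model if delta >= delta_aic_threshold else simpler.model
    f_stat = f_p = None
    nested = {simpler.model, complexer.model} == {"pingpong", "hill"}
    if nested and complexer.n_params > simpler.n_params:
        dk = complexer.n_params - simpler.n_params
        dof = complexer.n_points - complexer.n_params
        num = max(simpler.rss - complexer.rss, 0.0) / dk
        den = complexer.rss / dof
        f_stat = num / den if den > 0 else np.inf
        f_p = float(stats.f.sf(f_stat, dk, dof))
    return ModelComparison(preferred=preferred, delta_aic=float(delta),
                           f_stat=f_stat, f_pvalue=f_p)


# --------------------------------------------------------------------------
# functional wrappers

def fit_mm(series: pd.DataFrame, e0: float | None = None) -> MMFitResult:
    """Fit one fixed-acceptor series with the Michaelis-Menten function."""
    return MichaelisMentenModel.from_dataframe(series, e0).fit()


def fit_global_pingpong(dataset: pd.DataFrame, e0: float | None = None,
                        weighted: bool = False) -> GlobalFitResult:
    """Globally fit all series of one substrate with the ping-pong bi-bi law."""
    return PingPongBiBiModel.from_dataframe(dataset, e0, weighted=weighted).fit()


def fit_global_hill(dataset: pd.DataFrame, e0: float | None = None,
                    shared_h: bool = True, weighted: bool = False) -> GlobalFitResult:
    """Globally fit all series of one substrate with the Hill-cooperative law."""
    return HillKineticsModel.from_dataframe(dataset, e0, weighted=weighted,
                                            shared_h=shared_h).fit()
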