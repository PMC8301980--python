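"""Soumpasis recovery model and nonlinear fitting of normalized FRAP traces.

The fractional recovery of a uniformly bleached circular spot of radius ``w``
refilled by free 2-D Brownian diffusion is the Soumpasis function

    f(t) = exp(-2 tau_D / t) * [I0(2 tau_D / t) + I1(2 tau_D / t)],

with characteristic diffusion time ``tau_D = w**2 / (4 D)`` and ``I0``,
``I1`` the modified Bessel functions of the first kind.  A measured trace is
modelled as the affine wrap ``F(t) = b + a f(t)`` where ``b`` is the
fluorescence remaining right after bleaching and ``a`` the recovery
amplitude; the plateau ``a + b`` relative to the pre-bleach level encodes the
mobile fraction.  Fitting ``(a, b, tau_D)`` to a normalized trace yields the
lipid lateral diffusion coefficient ``D = w**2 / (4 tau_D)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "RecoveryTrace",
    "BleachGeometry",
    "SoumpasisFit",
    "FitError",
    "NoBleachError",
    "soumpasis_f",
    "recovery_model",
    "fit_recovery",
    "half_time",
    "HALF_TIME_RATIO",
]

# Parameter box constraints for the least-squares fit.  Fits that terminate
# on a bound are flagged, never silently accepted.  The amplitude is fitted
# through the plateau a + b, capped just above the pre-bleach level: a
# recovery cannot overshoot its pre-bleach intensity beyond noise, and this
# constraint is what keeps the fit identifiable when only a fraction of the
# recovery falls inside the acquisition window (slow diffusion).
PLATEAU_BOUNDS = (1e-6, 1.05)
B_BOUNDS = (0.0, 1.0 - 1e-9)
TAU_BOUNDS = (1e-3, 1e4)

#: Intensity at or above which the first post-bleach frame is considered
#: unbleached and fitting refuses to proceed.
NO_BLEACH_THRESHOLD = 0.95


class FitError(RuntimeError):
    """Recovery-curve fit failed to converge; carries lmfit diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoBleachError(ValueError):
    """The trace shows no bleach signature (first intensity too high)."""


def soumpasis_f(t, tau_d):
    """Fractional fluorescence recovery of a uniformly bleached disk.

    Parameters
    ----------
    t : float or array-like
        Time since the end of bleaching, seconds.  Must be > 0.
    tau_d : float
        Characteristic diffusion time ``w**2 / (4 D)``, seconds.  Must be > 0.

    Returns
    -------
    float or ndarray
        Recovered fraction in (0, 1); strictly increasing in ``t``, tending
        to 1 as ``t -> inf`` and to 0 as ``t -> 0+``.

    Notes
    -----
    Evaluated through the exponentially scaled Bessel routines
    ``i0e``/``i1e`` so the huge arguments arising at early times for slow
    diffusion (``t << tau_d``) neither overflow nor lose the exponential
    cancellation.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("soumpasis_f requires t > 0")
    if not tau_d > 0:
        raise ValueError("soumpasis_f requires tau_d > 0")
    x = 2.0 * tau_d / t
    out = i0e(x) + i1e(x)
    return out if out.ndim else float(out)


def recovery_model(t, a, b, tau_d):
    """Affine Soumpasis recovery curve ``F(t) = b + a * f(t; tau_d)``.

    ``b`` is the fluorescence remaining immediately after bleaching, ``a``
    the recovery amplitude; the long-time plateau is ``a + b``.
    """
    return b + a * soumpasis_f(t, tau_d)


def _half_time_ratio() -> float:
    # t_half / tau_d solving f(t_half; tau_d) = 1/2 -- a universal constant.
    return brentq(lambda r: soumpasis_f(r, 1.0) - 0.5, 1e-3, 1e3, xtol=1e-12)


#: Universal ratio t_half / tau_d of the Soumpasis curve (~0.886).
HALF_TIME_RATIO = _half_time_ratio()


def half_time(tau_d: float) -> float:
    """Half-recovery time of the Soumpasis curve, ``t_half ~ 0.89 tau_d``."""
    if not tau_d > 0:
        raise ValueError("half_time requires tau_d > 0")
    return HALF_TIME_RATIO * tau_d


@dataclass(frozen=True)
class BleachGeometry:
    """Geometry and timing of the photobleaching experiment.

    Defaults follow the standard protocol: a 10 um diameter spot bleached in
    a 50 um x 50 um field, imaged at 0.5 s intervals.
    """

    spot_radius_w: float = 5.0  # um
    frame_interval: float = 0.5  # s
    field_size: float = 50.0  # um

    def __post_init__(self):
        if not self.spot_radius_w > 0:
            raise ValueError("spot_radius_w must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not 2 * self.spot_radius_w < self.field_size:
            raise ValueError("bleach spot must fit inside the field")


@dataclass(frozen=True)
class RecoveryTrace:
    """Normalized post-bleach recovery trace of the bleached ROI.

    ``times`` are seconds since the end of bleaching (strictly increasing,
    all > 0); ``intensities`` are normalized so the pre-bleach level is 1.
    """

    times: np.ndarray
    intensities: np.ndarray
    prebleach_level: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size and (t[0] <= 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and positive")
        if np.any(y < 0) or np.any(y > 1.5):
            raise ValueError("normalized intensities must lie in [0, 1.5]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.times, "intensity_norm": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RecoveryTrace":
        df = pd.read_csv(path)
        missing = {"time_s", "intensity_norm"} - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["intensity_norm"].to_numpy())


@dataclass(frozen=True)
class SoumpasisFit:
    """Fitted Soumpasis parameters and the derived diffusion coefficient."""

    a: float
    b: float
    tau_d: float  # s
    diffusion_coefficient_d: float  # um^2/s
    ci_low_d: float
    ci_high_d: float
    mobile_fraction: float
    residual_rms: float
    spot_radius_w: float
    converged: bool = True
    at_bounds: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "tau_d_s": self.tau_d,
            "d_um2_per_s": self.diffusion_coefficient_d,
            "ci_low": self.ci_low_d,
            "ci_high": self.ci_high_d,
            "mobile_fraction": self.mobile_fraction,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Derivative-free starting point: plateau tail, first frame, empirical
    half-recovery time divided by the universal ratio."""
    b0 = float(np.clip(y[0], *B_BOUNDS))
    tail = float(np.mean(y[-5:]))
    a0 = float(np.clip(tail - b0, 0.05, PLATEAU_BOUNDS[1] - b0))
    half_level = b0 + 0.5 * a0
    above = np.nonzero(y >= half_level)[0]
    # If recovery never crosses half within the window, the curve is slower
    # than the window: start tau at the window length scale.
    t_half_emp = float(t[above[0]]) if above.size else float(t[-1])
    tau0 = float(np.clip(t_half_emp / HALF_TIME_RATIO, *TAU_BOUNDS))
    return a0, b0, tau0


def fit_recovery(trace: RecoveryTrace, geometry: BleachGeometry) -> SoumpasisFit:
    """Least-squares fit of a normalized recovery trace.

    Returns the fitted ``(a, b, tau_D)``, the diffusion coefficient
    ``D = w**2 / (4 tau_D)`` and its 95% confidence bounds obtained from the
    linearized parameter covariance propagated to D by the delta method,
    and the mobile fraction ``a / (1 - b)`` clipped to [0, 1].

    Raises
    ------
    NoBleachError
        If the first post-bleach intensity is >= 0.95 (no bleach signature).
    FitError
        If the optimizer does not converge; carries diagnostics.
    """
    t, y = trace.times, trace.intensities
    if t.size < 10:
        raise ValueError("need at least 10 post-bleach frames to fit")
    if y[0] >= NO_BLEACH_THRESHOLD:
        raise NoBleachError(
            f"first post-bleach intensity {y[0]:.3f} >= {NO_BLEACH_THRESHOLD}: "
            "no bleach signature"
        )

    a0, b0, tau0 = _initial_guesses(t, y)
    model = Model(recovery_model, independent_vars=["t"])
    params = model.make_params(a=a0, b=b0, tau_d=tau0)
    params["b"].set(min=B_BOUNDS[0], max=B_BOUNDS[1])
    params["tau_d"].set(min=TAU_BOUNDS[0], max=TAU_BOUNDS[1])
    params.add("plateau", value=min(a0 + b0, PLATEAU_BOUNDS[1]),
               min=PLATEAU_BOUNDS[0], max=PLATEAU_BOUNDS[1])
    params["a"].set(expr="plateau - b")

    result = model.fit(y, params, t=t, method="least_squares")
    if not result.success:
        raise FitError(
            "recovery fit did not converge",
            diagnostics={"message": result.message, "nfev": result.nfev},
        )

    a = float(result.params["a"].value)
    b = float(result.params["b"].value)
    tau = float(result.params["tau_d"].value)
    w = geometry.spot_radius_w
    d = w * w / (4.0 * tau)

    tau_err = result.params["tau_d"].stderr
    if tau_err is None or not math.isfinite(tau_err):
        ci_low, ci_high = d, d
    else:
        # delta method: |dD/dtau| = D / tau
        d_err = d * tau_err / tau
        ci_low = max(d - 1.96 * d_err, 0.0)
        ci_high = d + 1.96 * d_err

    plateau = float(result.params["plateau"].value)
    at_bounds = any(
        math.isclose(v, lo, rel_tol=1e-6, abs_tol=1e-12)
        or math.isclose(v, hi, rel_tol=1e-6)
        for v, (lo, hi) in ((plateau, PLATEAU_BOUNDS), (tau, TAU_BOUNDS))
    ) or math.isclose(b, B_BOUNDS[1], rel_tol=1e-6)

    return SoumpasisFit(
        a=a,
        b=b,
        tau_d=tau,
        diffusion_coefficient_d=d,
        ci_low_d=ci_low,
        ci_high_d=ci_high,
        mobile_fraction=float(np.clip(a / (1.0 - b), 0.0, 1.0)),
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        spot_radius_w=w,
        converged=bool(result.success),
        at_bounds=at_bounds,
        diagnostics={"nfev": result.nfev, "redchi": result.redchi},
    )
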