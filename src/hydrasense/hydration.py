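"""Hydration sensing: D-RH calibration, inversion, waters per lipid.

The lateral diffusion coefficient of PC lipids in a supported bilayer falls
steeply as the membrane is dehydrated (most of the change between 100% and
~50% relative humidity, little below), which makes D a quantitative
hydration indicator.  This module builds monotone D(RH) calibration curves
from replicate FRAP fits, inverts them to estimate RH from a measured D,
maps RH to the number of water molecules per lipid head group through
literature anchors, locates the breaking point of the calibration (the
collapse of the clathrate water cage around the phosphocholine group), and
quantifies dehydration/rehydration hysteresis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "WATERS_ANCHORS",
    "WATERS_FLOOR_INTERVAL",
    "CalibrationPoint",
    "CalibrationCurve",
    "HydrationEstimate",
    "WatersEstimate",
    "BreakpointFit",
    "HysteresisSummary",
    "build_calibration",
    "rh_to_waters",
    "sense",
    "detect_breakpoint",
    "hysteresis_metric",
    "read_calibration_csv",
    "write_calibration_csv",
]

#: Literature anchors (X-ray diffraction / IR spectroscopy on stacked PC
#: multilayers): waters per lipid head group at a given % RH.
WATERS_ANCHORS: tuple[tuple[float, float], ...] = (
    (25.0, 2.4),
    (50.0, 3.6),
    (75.0, 6.3),
    (95.0, 10.5),
)

#: Residual-water floor below 25% RH: MD simulations find 3-4 water
#: molecules per lipid remain strongly hydrogen bonded even after drastic
#: drying, so "not more than four" is reported there.
WATERS_FLOOR_INTERVAL: tuple[float, float] = (3.0, 4.0)

ANCHORS_VERSION = "pc-stacked-multilayer-v1"

_BRANCHES = {"dehydration", "rehydration", "bulk"}


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate diffusion coefficients measured at one RH level."""

    rh: float
    d_values: tuple[float, ...]
    branch: str = "dehydration"

    def __post_init__(self):
        if not 0 <= self.rh <= 100:
            raise ValueError("rh must be in [0, 100]")
        vals = tuple(float(v) for v in self.d_values)
        if not vals or any(v <= 0 for v in vals):
            raise ValueError("need >= 1 strictly positive replicate D value")
        if self.branch not in _BRANCHES:
            raise ValueError(f"branch must be one of {sorted(_BRANCHES)}")
        object.__setattr__(self, "d_values", vals)

    @property
    def mean_d(self) -> float:
        return float(np.mean(self.d_values))

    @property
    def sd_d(self) -> float:
        return float(np.std(self.d_values, ddof=1)) if len(self.d_values) > 1 else 0.0


class WatersEstimate(NamedTuple):
    waters: float
    low: float
    high: float
    floor_applied: bool
    extrapolated: bool


@dataclass(frozen=True)
class HydrationEstimate:
    """RH and waters-per-lipid estimate for a queried D."""

    rh_estimate: float
    rh_low: float
    rh_high: float
    waters_per_lipid: float
    waters_low: float
    waters_high: float
    floor_applied: bool
    extrapolated: bool
    branch: str

    def to_dict(self) -> dict:
        return {
            "rh_percent": self.rh_estimate,
            "rh_ci": [self.rh_low, self.rh_high],
            "waters_per_lipid": self.waters_per_lipid,
            "waters_ci": [self.waters_low, self.waters_high],
            "floor_applied": self.floor_applied,
            "extrapolated": self.extrapolated,
            "branch": self.branch,
        }


def _pava_non_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            vals[i] = merged
            wts[i] = tot
            blocks[i] += blocks[i + 1]
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty_like(y)
    for v, idx in zip(vals, blocks):
        out[idx] = v
    return out


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone D(RH) mapping for one protocol branch.

    Knots are (RH, mean D over replicates) with the replicate SD carried as
    an uncertainty band; between knots the curve is a shape-preserving
    monotone piecewise cubic, clamped (never extrapolated) outside the knot
    range.
    """

    rh_knots: np.ndarray
    d_means: np.ndarray
    d_sds: np.ndarray
    n_replicates: np.ndarray
    branch: str
    monotonized: bool = False
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        rh = np.asarray(self.rh_knots, dtype=float)
        d = np.asarray(self.d_means, dtype=float)
        object.__setattr__(self, "rh_knots", rh)
        object.__setattr__(self, "d_means", d)
        object.__setattr__(self, "d_sds", np.asarray(self.d_sds, dtype=float))
        object.__setattr__(self, "n_replicates", np.asarray(self.n_replicates))
        if np.any(np.diff(rh) <= 0):
            raise ValueError("rh_knots must be strictly increasing")
        if np.any(np.diff(d) < 0):
            raise ValueError("knot means must be non-decreasing")
        object.__setattr__(self, "_interp", PchipInterpolator(rh, d))

    @property
    def rh_range(self) -> tuple[float, float]:
        return float(self.rh_knots[0]), float(self.rh_knots[-1])

    @property
    def d_range(self) -> tuple[float, float]:
        return float(self.d_means[0]), float(self.d_means[-1])

    def d_at(self, rh) -> np.ndarray | float:
        """Mean D at the queried RH, clamped to the knot range."""
        lo, hi = self.rh_range
        return self._interp(np.clip(rh, lo, hi))

    def band_at(self, rh) -> np.ndarray | float:
        """Replicate-SD band, linearly interpolated between knots."""
        lo, hi = self.rh_range
        return np.interp(np.clip(rh, lo, hi), self.rh_knots, self.d_sds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "branch": self.branch,
            "rh_knots": self.rh_knots.tolist(),
            "d_means": self.d_means.tolist(),
            "d_sds": self.d_sds.tolist(),
            "n_replicates": self.n_replicates.tolist(),
            "monotonized": self.monotonized,
            "anchors_version": ANCHORS_VERSION,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        p = json.loads(Path(path).read_text())
        return cls(
            rh_knots=np.array(p["rh_knots"]),
            d_means=np.array(p["d_means"]),
            d_sds=np.array(p["d_sds"]),
            n_replicates=np.array(p["n_replicates"]),
            branch=p["branch"],
            monotonized=p.get("monotonized", False),
        )


def build_calibration(
    points: list[CalibrationPoint], branch: str | None = None
) -> CalibrationCurve:
    """Build a monotone calibration curve from replicate measurements.

    Requires >= 3 distinct RH levels in one branch.  Mean-D dips within one
    pooled replicate SD are projected onto the nearest non-decreasing
    sequence (flagged on the curve); larger violations indicate the data do
    not support a monotone calibration and raise.
    """
    if branch is not None:
        points = [p for p in points if p.branch == branch]
    else:
        branches = {p.branch for p in points}
        if len(branches) != 1:
            raise ValueError("points span multiple branches; pass branch=")
        branch = branches.pop()
    if len({p.rh for p in points}) < 3:
        raise ValueError("need >= 3 distinct RH levels to calibrate")

    # Pool replicates measured at the same RH level.
    by_rh: dict[float, list[float]] = {}
    for p in points:
        by_rh.setdefault(p.rh, []).extend(p.d_values)
    rh = np.array(sorted(by_rh))
    means = np.array([np.mean(by_rh[r]) for r in rh])
    sds = np.array(
        [np.std(by_rh[r], ddof=1) if len(by_rh[r]) > 1 else 0.0 for r in rh]
    )
    nreps = np.array([len(by_rh[r]) for r in rh])

    dips = np.maximum(means[:-1] - means[1:], 0.0)
    if dips.any():
        pooled_sd = float(np.sqrt(np.mean(sds**2)))
        if np.max(dips) > max(pooled_sd, 1e-12):
            raise ValueError(
                "non-monotone calibration: mean D decreases with RH by more "
                "than one pooled replicate SD"
            )
        means = _pava_non_decreasing(means, nreps.astype(float))
        monotonized = True
    else:
        monotonized = False

    return CalibrationCurve(
        rh_knots=rh,
        d_means=means,
        d_sds=sds,
        n_replicates=nreps,
        branch=branch,
        monotonized=monotonized,
    )


_waters_interp = PchipInterpolator(
    np.array([a[0] for a in WATERS_ANCHORS]),
    np.array([a[1] for a in WATERS_ANCHORS]),
)


def rh_to_waters(rh: float) -> WatersEstimate:
    """Waters per lipid head group at a given % RH.

    Monotone interpolation through the stacked-multilayer anchors
    (25, 2.4), (50, 3.6), (75, 6.3), (95, 10.5).  Below 25% RH the
    interpolation no longer applies: drastic drying leaves 3-4 strongly
    hydrogen-bonded waters, so the floor interval [3, 4] is returned with
    point value 4 ("not more than four") and floor_applied set.  Above 95%
    RH the 95% anchor is reported as a lower bound with extrapolated set.
    """
    if not 0 <= rh <= 100:
        raise ValueError("rh must be in [0, 100]")
    lo_rh, hi_rh = WATERS_ANCHORS[0][0], WATERS_ANCHORS[-1][0]
    if rh < lo_rh:
        lo, hi = WATERS_FLOOR_INTERVAL
        return WatersEstimate(hi, lo, hi, floor_applied=True, extrapolated=False)
    if rh > hi_rh:
        anchor = WATERS_ANCHORS[-1][1]
        return WatersEstimate(anchor, anchor, np.inf,
                              floor_applied=False, extrapolated=True)
    w = float(_waters_interp(rh))
    return WatersEstimate(w, w, w, floor_applied=False, extrapolated=False)


def _invert_curve(curve: CalibrationCurve, d: float) -> tuple[float, bool]:
    """RH at which the curve equals d; clamped + flagged outside range."""
    rh_lo, rh_hi = curve.rh_range
    d_lo, d_hi = curve.d_range
    if d <= d_lo:
        return rh_lo, d < d_lo
    if d >= d_hi:
        return rh_hi, d > d_hi
    rh = brentq(lambda r: float(curve.d_at(r)) - d, rh_lo, rh_hi, xtol=1e-10)
    return float(rh), False


def sense(
    d: float,
    curve: CalibrationCurve,
    d_ci: tuple[float, float] | None = None,
) -> HydrationEstimate:
    """Estimate the hydration state of the membrane from a measured D.

    Inverts the monotone calibration by bracketed root finding to an RH
    estimate, propagates the D confidence interval endpoints through the
    inverse, and maps RH to waters per lipid via the literature anchors.
    Queries outside the calibrated D range are clamped to the end knots and
    flagged, never silent.
    """
    if not d > 0:
        raise ValueError("d must be > 0")
    rh, extrap = _invert_curve(curve, d)
    if d_ci is None:
        rh_lo = rh_hi = rh
    else:
        lo, hi = sorted(d_ci)
        rh_lo, e1 = _invert_curve(curve, lo)
        rh_hi, e2 = _invert_curve(curve, hi)
        extrap = extrap or e1 or e2
    w_mid = rh_to_waters(rh)
    w_lo = rh_to_waters(rh_lo)
    w_hi = rh_to_waters(rh_hi)
    return HydrationEstimate(
        rh_estimate=rh,
        rh_low=rh_lo,
        rh_high=rh_hi,
        waters_per_lipid=w_mid.waters,
        waters_low=w_lo.low,
        waters_high=w_hi.high,
        floor_applied=w_mid.floor_applied or w_lo.floor_applied,
        extrapolated=extrap or w_mid.extrapolated or w_hi.extrapolated,
        branch=curve.branch,
    )


@dataclass(frozen=True)
class BreakpointFit:
    """Continuous two-segment (hinge) fit of mean D against RH."""

    rh_breakpoint: float
    sse_two_segment: float
    sse_single_line: float
    improvement: float  # fractional SSE reduction over a single line
    significant: bool  # False -> no breakpoint supported by the data


def detect_breakpoint(
    curve: CalibrationCurve, min_improvement: float = 0.05
) -> BreakpointFit:
    """Locate the breaking point of the D(RH) calibration.

    Fits a continuous piecewise-linear model with a single hinge to the
    knot means, scanning candidate breakpoints on a 1% RH grid, and returns
    the breakpoint minimizing total SSE (ties -> lowest RH).  When the best
    hinge improves SSE by less than ``min_improvement`` over a single
    straight line the fit is flagged as not supporting a breakpoint.
    """
    rh = curve.rh_knots
    d = curve.d_means
    if rh.size < 4:
        raise ValueError("need >= 4 knots to fit a breakpoint")

    def sse_for(design: np.ndarray) -> float:
        coef, res, *_ = np.linalg.lstsq(design, d, rcond=None)
        pred = design @ coef
        return float(np.sum((d - pred) ** 2))

    ones = np.ones_like(rh)
    sse_line = sse_for(np.column_stack([ones, rh]))

    grid = np.arange(np.ceil(rh[0]), np.floor(rh[-1]) + 0.5, 1.0)
    best_c, best_sse = float(grid[0]), np.inf
    for c in grid:
        design = np.column_stack([ones, rh - c, np.maximum(rh - c, 0.0)])
        sse = sse_for(design)
        if sse < best_sse - 1e-12:  # strict: ties keep the lowest RH
            best_sse, best_c = sse, float(c)
    improvement = 0.0 if sse_line == 0 else 1.0 - best_sse / sse_line
    if sse_line == 0 and best_sse == 0:
        improvement = 0.0
    return BreakpointFit(
        rh_breakpoint=best_c,
        sse_two_segment=best_sse,
        sse_single_line=sse_line,
        improvement=improvement,
        significant=improvement >= min_improvement,
    )


@dataclass(frozen=True)
class HysteresisSummary:
    """Per-RH difference between dehydration and rehydration branches."""

    rh_grid: np.ndarray
    delta_d: np.ndarray  # D_dehydration - D_rehydration on the grid
    mean_delta: float
    max_delta: float
    frac_positive: float
    bulk_reversible: bool
    verdict: str


def hysteresis_metric(
    dehydration: CalibrationCurve,
    rehydration: CalibrationCurve,
    n_grid: int = 101,
) -> HysteresisSummary:
    """Quantify de/rehydration hysteresis and bulk reversibility.

    Evaluates Delta-D(RH) = D_dehydration - D_rehydration on the common RH
    domain; the reversibility verdict compares the top-of-range
    (bulk/fully hydrated) D of the two branches within their combined
    replicate SD.
    """
    lo = max(dehydration.rh_range[0], rehydration.rh_range[0])
    hi = min(dehydration.rh_range[1], rehydration.rh_range[1])
    if lo >= hi:
        raise ValueError("calibration branches have disjoint RH domains")
    grid = np.linspace(lo, hi, n_grid)
    delta = np.asarray(dehydration.d_at(grid)) - np.asarray(rehydration.d_at(grid))

    d_top_de = dehydration.d_means[-1]
    d_top_re = rehydration.d_means[-1]
    sd_comb = float(np.hypot(dehydration.d_sds[-1], rehydration.d_sds[-1]))
    bulk_ok = abs(d_top_de - d_top_re) <= max(sd_comb, 1e-9)

    mean_delta = float(delta.mean())
    has_hysteresis = mean_delta > max(1e-9, 0.01 * float(dehydration.d_means[-1]))
    if bulk_ok and not has_hysteresis:
        verdict = "fully reversible"
    elif bulk_ok:
        verdict = "reversible with hysteresis"
    else:
        verdict = "not reversible"
    return HysteresisSummary(
        rh_grid=grid,
        delta_d=delta,
        mean_delta=mean_delta,
        max_delta=float(delta.max()),
        frac_positive=float(np.mean(delta > 0)),
        bulk_reversible=bulk_ok,
        verdict=verdict,
    )


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    """Read `rh_percent, d_um2_per_s, branch, replicate_id` rows into
    per-(RH, branch) CalibrationPoints."""
    df = pd.read_csv(path)
    required = {"rh_percent", "d_um2_per_s", "branch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    points = []
    for (rh, branch), grp in df.groupby(["rh_percent", "branch"], sort=True):
        points.append(
            CalibrationPoint(
                rh=float(rh),
                d_values=tuple(grp["d_um2_per_s"]),
                branch=str(branch),
            )
        )
    return points


def write_calibration_csv(points: list[CalibrationPoint], path: str | Path) -> None:
    rows = [
        {
            "rh_percent": p.rh,
            "d_um2_per_s": d,
            "branch": p.branch,
            "replicate_id": i,
        }
        for p in points
        for i, d in enumerate(p.d_values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
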