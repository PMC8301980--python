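"""Synthetic FRAP data generator with known ground truth.

Stands in for the microscope: produces analytic recovery traces drawn from
the affine Soumpasis model, and full 2-D image stacks in which a uniformly
bleached disk refills by free Brownian diffusion (spectral evolution with
the exact Gaussian propagator on a periodic field).  Defaults emulate the
standard acquisition: 10 um diameter spot in a 50 um x 50 um field, 100
post-bleach frames at 0.5 s intervals, a handful of pre-bleach frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from hydrasense.frap_imaging import FrapStack
from hydrasense.frap_model import BleachGeometry, RecoveryTrace, soumpasis_f

__all__ = [
    "SimulationConfig",
    "simulate_trace",
    "simulate_stack",
    "simulate_rh_series",
    "single_component_d_of_rh",
    "phase_separated_d_of_rh",
]

# Photons per unit intensity used when Poisson shot noise is requested.
SHOT_NOISE_PHOTONS = 1000.0


def single_component_d_of_rh() -> list[tuple[float, float]]:
    """Canonical single-component (pure liquid-disordered) D(RH) table.

    Endpoints are measured values for DMoPC bilayers (5.35 um^2/s fully
    hydrated, 4.75 at 85% RH, 0.25 at ~0% RH); the intermediate levels
    follow the characteristic shape of the dehydration curve -- steep loss
    of mobility between 100% and ~50% RH (the breaking point where the
    clathrate water cage around the phosphocholine group collapses),
    nearly flat below.
    """
    return [(0.0, 0.25), (30.0, 0.35), (45.0, 0.42),
            (65.0, 1.8), (85.0, 4.75), (100.0, 5.35)]


def phase_separated_d_of_rh() -> list[tuple[float, float]]:
    """Canonical phase-separated (Ld + Lo) D(RH) table for the Ld phase.

    Endpoints are measured (1.66 um^2/s hydrated, 1.52 at 85% RH, 0.04 at
    ~0% RH); intermediates mirror the single-component shape scaled down.
    """
    return [(0.0, 0.04), (30.0, 0.06), (45.0, 0.08),
            (65.0, 0.55), (85.0, 1.52), (100.0, 1.66)]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic FRAP run.

    d_true in um^2/s; bleach_depth is the fraction of fluorescence
    destroyed inside the spot; immobile_fraction the fraction of
    fluorophores that never diffuse; noise_sd the relative Gaussian read
    noise; acquisition_bleach_rate the per-frame fractional loss of global
    signal.  A single integer seed drives every stochastic draw.
    """

    d_true: float
    geometry: BleachGeometry = field(default_factory=BleachGeometry)
    grid_size: int = 128
    n_frames: int = 100
    n_prebleach: int = 5
    immobile_fraction: float = 0.0
    bleach_depth: float = 1.0
    noise_sd: float = 0.0
    shot_noise: bool = False
    acquisition_bleach_rate: float = 0.0
    seed: int = 0
    pad_factor: int = 4

    def __post_init__(self):
        if self.d_true < 0:
            raise ValueError("d_true must be >= 0")
        if not 0 <= self.immobile_fraction < 1:
            raise ValueError("immobile_fraction must be in [0, 1)")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.noise_sd < 0 or self.acquisition_bleach_rate < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.n_frames < 1 or self.n_prebleach < 1:
            raise ValueError("need at least one frame on each side of the bleach")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    @property
    def tau_d(self) -> float:
        w = self.geometry.spot_radius_w
        return np.inf if self.d_true == 0 else w * w / (4.0 * self.d_true)

    def ground_truth(self) -> dict:
        b = 1.0 - self.bleach_depth
        a = self.bleach_depth * (1.0 - self.immobile_fraction)
        return {
            "d_true": self.d_true,
            "tau_d": self.tau_d,
            "a": a,
            "b": b,
            "mobile_fraction": 1.0 - self.immobile_fraction,
            "seed": self.seed,
        }


def simulate_trace(config: SimulationConfig) -> tuple[RecoveryTrace, dict]:
    """Analytic recovery trace: F(t) = b + a f(t; tau_D) plus read noise.

    Post-bleach frames are timed mid-exposure, t_i = (i + 1/2) dt.
    Deterministic for a fixed seed.
    """
    dt = config.geometry.frame_interval
    times = (np.arange(config.n_frames) + 0.5) * dt
    truth = config.ground_truth()
    a, b = truth["a"], truth["b"]
    if config.d_true == 0:
        y = np.full_like(times, b)
    else:
        y = b + a * soumpasis_f(times, truth["tau_d"])
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    trace = RecoveryTrace(times=times, intensities=np.clip(y, 0.0, 1.5))
    return trace, truth


def _diffusion_propagator(n: int, pixel: float, d: float, dt: float) -> np.ndarray:
    """Fourier multiplier of the 2-D heat kernel over one time step."""
    fx = np.fft.fftfreq(n, d=pixel)
    k2 = fx[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-4.0 * np.pi**2 * d * dt * k2)


def simulate_stack(config: SimulationConfig) -> tuple[FrapStack, dict]:
    """Full 2-D image-stack simulation of a disk-bleach FRAP experiment.

    Pre-bleach frames are uniform; at the bleach the fluorophore
    concentration inside the disk is multiplied by (1 - bleach_depth); the
    mobile pool then evolves by free diffusion via FFT with periodic
    boundaries (exact Gaussian propagator), the immobile pool stays frozen.
    The membrane is simulated on a computational domain ``pad_factor``
    times larger than the imaged field and only the central field is
    recorded, emulating the quasi-infinite reservoir of a real bilayer
    around the imaged area (``pad_factor=1`` keeps the closed periodic
    field, on which total fluorophore is exactly conserved).  Optional
    global exponential acquisition bleaching, Poisson shot noise and
    Gaussian read noise are applied in that order, all seeded.
    """
    geom = config.geometry
    w = geom.spot_radius_w
    if config.pad_factor * geom.field_size < 5.0 * w:
        raise ValueError(
            "computational field must be >= 5x the spot radius to avoid "
            "periodic-wrap contamination of the recovery"
        )
    n_field = config.grid_size
    pixel = geom.field_size / n_field
    n = n_field * config.pad_factor
    dt = geom.frame_interval
    center = (n - 1) / 2.0
    rr, cc = np.ogrid[:n, :n]
    disk = (rr - center) ** 2 + (cc - center) ** 2 <= (w / pixel) ** 2
    lo = (n - n_field) // 2
    crop = slice(lo, lo + n_field)

    mobile = np.full((n, n), 1.0 - config.immobile_fraction)
    frozen_field = np.full((n_field, n_field), config.immobile_fraction)

    n_total = config.n_prebleach + config.n_frames
    frames = np.empty((n_total, n_field, n_field))
    frames[: config.n_prebleach] = 1.0

    keep = 1.0 - config.bleach_depth
    mobile = np.where(disk, mobile * keep, mobile)
    frozen_field = np.where(disk[crop, crop], frozen_field * keep, frozen_field)

    # Mid-exposure sampling: first post-bleach frame is dt/2 after the
    # bleach, subsequent frames dt apart.
    spec = np.fft.fft2(mobile)
    half_step = _diffusion_propagator(n, pixel, config.d_true, dt / 2.0)
    full_step = _diffusion_propagator(n, pixel, config.d_true, dt)
    spec = spec * half_step
    for i in range(config.n_frames):
        frames[config.n_prebleach + i] = (
            np.fft.ifft2(spec).real[crop, crop] + frozen_field
        )
        spec = spec * full_step
    np.clip(frames, 0.0, None, out=frames)

    if config.acquisition_bleach_rate > 0:
        decay = (1.0 - config.acquisition_bleach_rate) ** np.arange(n_total)
        frames *= decay[:, None, None]

    rng = np.random.default_rng(config.seed)
    if config.shot_noise:
        frames = rng.poisson(frames * SHOT_NOISE_PHOTONS) / SHOT_NOISE_PHOTONS
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    center_field = center - lo
    stack = FrapStack(
        frames=frames,
        pixel_size=pixel,
        frame_interval=dt,
        bleach_frame_index=config.n_prebleach,
        roi_center=(center_field, center_field),
        roi_radius=w / pixel,
    )
    return stack, config.ground_truth()


def simulate_rh_series(
    d_of_rh: list[tuple[float, float]],
    protocol: list[float],
    config: SimulationConfig,
    lag_time_constant: float = 0.0,
) -> list[tuple[float, RecoveryTrace, dict]]:
    """Generate traces for a sequence of RH set-points.

    The diffusion coefficient at each set-point comes from monotone
    interpolation of ``d_of_rh``.  A nonzero ``lag_time_constant``
    (in units of protocol steps, one set-point dwell = 1) applies
    first-order equilibration: D relaxes toward each new target instead of
    jumping, emulating the finite hydration response of the bilayer.
    Per-step traces use independent substreams spawned from config.seed.
    """
    if not protocol:
        raise ValueError("protocol must contain at least one RH set-point")
    pts = sorted(d_of_rh)
    rh_knots = np.array([p[0] for p in pts])
    d_knots = np.array([p[1] for p in pts])
    lo, hi = rh_knots[0], rh_knots[-1]
    for rh in protocol:
        if not lo <= rh <= hi:
            raise ValueError(f"protocol RH {rh} outside table domain [{lo}, {hi}]")
    interp = PchipInterpolator(rh_knots, d_knots)

    seeds = np.random.SeedSequence(config.seed).spawn(len(protocol))
    out = []
    d_state = float(interp(protocol[0]))
    for step, (rh, ss) in enumerate(zip(protocol, seeds)):
        d_target = float(interp(rh))
        if lag_time_constant > 0 and step > 0:
            relax = np.exp(-1.0 / lag_time_constant)
            d_state = d_target + (d_state - d_target) * relax
        else:
            d_state = d_target
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        step_cfg = replace(config, d_true=d_state, seed=sub_seed)
        trace, truth = simulate_trace(step_cfg)
        truth = dict(truth, rh=rh, d_target=d_target, d_effective=d_state)
        out.append((rh, trace, truth))
    return out
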