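"""Spring-mass (SLIP) estimates of leg stiffness from treadmill GRF.

In the spring-mass model of running the stance leg is a massless linear
spring under a point-mass body.  From a single stance phase we recover:

* the leg contact angle from vertical,  theta = asin(v * t_c / (2 * L0)),
  assuming a symmetric leg sweep about vertical;
* the downward centre-of-mass excursion during stance, delta_y, by double
  integration of the vertical acceleration f_v / m - g over one stride with
  a zero-mean-velocity (steady running) closure;
* the maximum leg compression (McMahon & Cheng construction)
  delta_L = delta_y + L0 * (1 - cos(theta));
* leg stiffness k_leg = peak vGRF / delta_L, reported in kN/m; and
* the prosthesis spring displacement delta_RSP = peak resultant GRF / k_RSP
  from the bench-measured prosthesis stiffness.

Leg lengths are never swapped: the affected leg uses the trochanter-to-
prosthesis-tip length, the unaffected leg the trochanter-to-floor length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import DegenerateInputError, GeometryError, NonSteadyTrialError, ParameterError
from .gait import GRAVITY
from .io import TrialConfig
from .signal import StanceInterval

__all__ = [
    "SpringMassEstimate",
    "contact_angle",
    "com_vertical_displacement",
    "leg_compression",
    "leg_stiffness",
    "rsp_displacement",
    "refine_touchdown",
    "estimate_stance_stiffness",
]


@dataclass(frozen=True)
class SpringMassEstimate:
    """Spring-mass quantities for one stance."""

    leg: str
    theta: float  # leg contact angle from vertical, rad
    delta_y: float  # downward CoM excursion during stance, m (positive)
    delta_L: float  # maximum leg compression, m
    k_leg: float  # leg stiffness, kN/m
    peak_vgrf: float  # N
    onset: int = 0


def contact_angle(v: float, t_c: float, L0: float) -> float:
    """Leg angle from vertical at touchdown: asin(v * t_c / (2 * L0)).

    Assumes the leg sweeps symmetrically about vertical during contact, so
    half the contact length subtends the angle at leg length L0.
    """
    if v < 0:
        raise ParameterError(f"velocity must be non-negative, got {v}")
    if not t_c > 0:
        raise ParameterError(f"contact time must be positive, got {t_c}")
    if not L0 > 0:
        raise ParameterError(f"leg length must be positive, got {L0}")
    arg = v * t_c / (2.0 * L0)
    if arg > 1.0:
        raise GeometryError(
            f"contact length {v * t_c:.3f} m exceeds the 2*L0 = {2 * L0:.3f} m leg sweep"
        )
    return math.asin(arg)


def _com_height_curve(f_v_stride, body_mass: float, rate: float,
                      g: float = GRAVITY, steady_tol: float = 0.15) -> np.ndarray:
    """Relative CoM height over a stride window by double integration.

    The velocity constant is chosen so the trapezoid-weighted mean vertical
    velocity over the window vanishes (stride periodicity of steady
    running); position is relative to the first sample.
    """
    f_v = np.asarray(f_v_stride, dtype=float)
    if f_v.ndim != 1 or f_v.size < 4:
        raise ParameterError("stride window must be a 1-D series of at least 4 samples")
    weight = body_mass * g
    mean_ratio = float(np.mean(f_v)) / weight
    if abs(mean_ratio - 1.0) > steady_tol:
        raise NonSteadyTrialError(
            f"stride-mean vertical force is {mean_ratio:.2f} body weights; "
            f"outside 1 +/- {steady_tol} steady-state band"
        )
    dt = 1.0 / rate
    accel = f_v / body_mass - g
    vel = cumulative_trapezoid(accel, dx=dt, initial=0.0)
    duration = dt * (f_v.size - 1)
    vel = vel - np.trapezoid(vel, dx=dt) / duration
    return cumulative_trapezoid(vel, dx=dt, initial=0.0)


def com_vertical_displacement(
    f_v_stride,
    body_mass: float,
    rate: float,
    stance_samples: Optional[int] = None,
    steady_tol: float = 0.15,
    g: float = GRAVITY,
) -> float:
    """Downward CoM excursion during stance by double integration, m.

    ``f_v_stride`` must span exactly one stride (stance onset to the next
    same-leg onset).  Vertical acceleration f_v/m - g is integrated twice
    with the trapezoid rule; the free velocity constant is set so the mean
    vertical velocity over the stride is zero (steady running), which makes
    the position trace stride-periodic up to noise.  The excursion is read
    touchdown-to-minimum within the leading ``stance_samples`` samples
    (default: the whole window).

    Raises ``NonSteadyTrialError`` when the stride-mean force deviates from
    body weight by more than ``steady_tol`` — the trial is drifting and the
    periodicity closure is invalid.
    """
    pos = _com_height_curve(f_v_stride, body_mass, rate, g=g, steady_tol=steady_tol)
    n = pos.size if stance_samples is None else min(int(stance_samples), pos.size)
    return float(pos[0] - np.min(pos[:n]))


def leg_compression(delta_y: float, L0: float, theta: float) -> float:
    """Maximum leg compression: delta_y + L0 * (1 - cos(theta))."""
    if not L0 > 0:
        raise ParameterError(f"leg length must be positive, got {L0}")
    if not (math.isfinite(delta_y) and math.isfinite(theta)):
        raise ParameterError("delta_y and theta must be finite")
    return delta_y + L0 * (1.0 - math.cos(theta))


def leg_stiffness(peak_vgrf: float, delta_L: float) -> float:
    """Leg stiffness = peak vertical GRF / maximum leg compression, kN/m."""
    if not peak_vgrf > 0:
        raise ParameterError(f"peak vGRF must be positive, got {peak_vgrf}")
    if not delta_L > 0:
        raise DegenerateInputError(f"leg compression must be positive, got {delta_L}")
    return peak_vgrf / delta_L / 1000.0


def rsp_displacement(peak_resultant_grf: float, k_rsp: float) -> float:
    """Prosthesis spring displacement = peak resultant GRF / k_RSP, m.

    ``k_rsp`` is the bench-measured prosthesis stiffness in kN/m.
    """
    if not peak_resultant_grf > 0:
        raise ParameterError(f"peak resultant GRF must be positive, got {peak_resultant_grf}")
    if not k_rsp > 0:
        raise ParameterError(f"prosthesis stiffness must be positive, got {k_rsp}")
    return peak_resultant_grf / (k_rsp * 1000.0)


def refine_touchdown(
    f_v_raw,
    stance: StanceInterval,
    rate: float,
    band: tuple[float, float] = (50.0, 600.0),
    lookback: int = 10,
) -> Optional[float]:
    """Estimate the true touchdown time by extrapolating the raw rising edge.

    Zero-phase filtering smears the loading edge symmetrically in time, so
    the 30 N crossing on the filtered trace precedes the actual foot strike
    by a few milliseconds.  Fitting a line to the raw force samples in the
    ``band`` newton window of the rising edge and extrapolating to zero
    force recovers the touchdown instant to well under a millisecond.
    Returns the refined time in seconds, or None when the edge has too few
    usable samples.
    """
    f = np.asarray(f_v_raw, dtype=float)
    lo = max(stance.onset - lookback, 0)
    seg = f[lo : stance.offset]
    rising = np.flatnonzero((seg >= band[0]) & (seg <= band[1]))
    rising = rising[rising < int(np.argmax(seg))]
    if rising.size < 2:
        return None
    t = (lo + rising) / rate
    slope, intercept = np.polyfit(t, seg[rising], 1)
    if slope <= 0:
        return None
    return -intercept / slope


def estimate_stance_stiffness(
    stances: Sequence[StanceInterval],
    f_v,
    rate: float,
    config: TrialConfig,
    f_v_raw=None,
) -> list[SpringMassEstimate]:
    """Spring-mass estimates for every stance with a full stride window.

    For stance i of a given leg the stride window runs to the onset of
    stance i+2 (same leg); the trailing stance(s) without such a window are
    skipped.  Uses the configured belt velocity and the per-leg unloaded leg
    length; the marker-derived belt speed is a QC channel only.  When the
    raw (unfiltered) vertical GRF is supplied, the delta_y anchor uses the
    edge-extrapolated touchdown instant (see ``refine_touchdown``) instead
    of the threshold-crossing sample.
    """
    f_v = np.asarray(f_v, dtype=float)
    dt = 1.0 / rate
    estimates = []
    for i, stance in enumerate(stances[:-2]):
        nxt_same = stances[i + 2]
        window = f_v[stance.onset : nxt_same.onset]
        t_td = None
        if f_v_raw is not None:
            t_td = refine_touchdown(f_v_raw, stance, rate)
        if t_td is None:
            delta_y = com_vertical_displacement(
                window, config.body_mass, rate, stance_samples=stance.n_samples
            )
        else:
            pos = _com_height_curve(window, config.body_mass, rate)
            t_grid = stance.onset * dt + np.arange(window.size) * dt
            t_td = min(max(t_td, t_grid[0]), t_grid[stance.n_samples // 2])
            z_td = float(np.interp(t_td, t_grid, pos))
            delta_y = z_td - float(np.min(pos[: stance.n_samples]))
        t_c = stance.duration(rate)
        theta = contact_angle(config.belt_velocity, t_c, config.leg_length(stance.leg))
        delta_L = leg_compression(delta_y, config.leg_length(stance.leg), theta)
        peak = float(np.max(f_v[stance.slice()]))
        estimates.append(
            SpringMassEstimate(
                leg=stance.leg,
                theta=theta,
                delta_y=delta_y,
                delta_L=delta_L,
                k_leg=leg_stiffness(peak, delta_L),
                peak_vgrf=peak,
                onset=stance.onset,
            )
        )
    return estimates
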