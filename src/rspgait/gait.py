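"""Per-step spatiotemporal and force metrics, and trial-level aggregates.

A *step* runs from the onset of one stance to the onset of the next
(opposite-leg) stance and is attributed to the leg of the first stance:
step time = contact time + subsequent aerial time, step frequency its
reciprocal, contact length = belt velocity x contact time.  Trial summaries
report per-leg means over all complete steps plus the both-legs average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import DataError, MissingLegError
from .signal import StanceInterval

__all__ = [
    "StepRecord",
    "TrialSummary",
    "step_metrics",
    "summarize_trial",
    "vmax_trial_valid",
    "GRAVITY",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2, used for body-weight normalisation

#: StepRecord metrics aggregated in trial summaries.
STEP_METRICS = (
    "t_c",
    "t_a",
    "t_step",
    "f_step",
    "L_c",
    "F_avg",
    "F_avg_bw",
    "F_peak_v",
    "F_peak_res",
)


@dataclass(frozen=True)
class StepRecord:
    """Metric bundle for one step, attributed to the leg that starts it."""

    leg: str
    t_c: float  # contact time, s
    t_a: float  # subsequent aerial time, s
    t_step: float  # = t_c + t_a, s
    f_step: float  # = 1 / t_step, Hz
    L_c: float  # contact length = v * t_c, m
    F_avg: float  # stance-average vertical GRF, N
    F_avg_bw: float  # same, in body weights
    F_peak_v: float  # peak vertical GRF, N
    F_peak_res: float  # peak resultant GRF, N
    onset: int = 0  # sample index of the stance onset
    offset: int = 0  # sample index of the stance offset


@dataclass(frozen=True)
class TrialSummary:
    """Per-leg and both-legs means of each step metric over a trial."""

    per_leg: dict  # leg -> {metric: mean}
    both_legs: dict  # metric -> mean of the two per-leg means
    n_steps: dict  # leg -> count
    stride_count: int  # min(#AL, #UL)


def step_metrics(
    stances: Sequence[StanceInterval],
    f_v,
    f_ml,
    f_ap,
    rate: float,
    v: float,
    body_mass: float,
) -> list[StepRecord]:
    """Compute one StepRecord per stance that has a subsequent stance.

    The last stance is dropped (its aerial time is unobserved).  ``F_avg``
    is the mean filtered vertical GRF over [onset, offset); the peak
    resultant uses all three channels.
    """
    f_v = np.asarray(f_v, dtype=float)
    f_ml = np.asarray(f_ml, dtype=float)
    f_ap = np.asarray(f_ap, dtype=float)
    if len(stances) < 2:
        raise DataError("step metrics need at least 2 stances")
    for a, b in zip(stances, stances[1:]):
        if b.onset < a.offset:
            raise DataError(
                f"stances overlap: [{a.onset}, {a.offset}) and [{b.onset}, {b.offset})"
            )
    weight = body_mass * GRAVITY
    records = []
    for stance, nxt in zip(stances, stances[1:]):
        sl = stance.slice()
        t_c = stance.duration(rate)
        t_a = (nxt.onset - stance.offset) / rate
        t_step = t_c + t_a
        resultant = np.sqrt(f_v[sl] ** 2 + f_ap[sl] ** 2 + f_ml[sl] ** 2)
        f_avg = float(np.mean(f_v[sl]))
        records.append(
            StepRecord(
                leg=stance.leg,
                t_c=t_c,
                t_a=t_a,
                t_step=t_step,
                f_step=1.0 / t_step,
                L_c=v * t_c,
                F_avg=f_avg,
                F_avg_bw=f_avg / weight,
                F_peak_v=float(np.max(f_v[sl])),
                F_peak_res=float(np.max(resultant)),
                onset=stance.onset,
                offset=stance.offset,
            )
        )
    return records


def summarize_trial(records: Sequence[StepRecord]) -> TrialSummary:
    """Per-leg means of every step metric, plus the both-legs average.

    Step frequency is averaged per step (mean of per-step frequencies), not
    as the reciprocal of the mean step time.
    """
    per_leg = {}
    n_steps = {}
    for leg in ("AL", "UL"):
        leg_records = [r for r in records if r.leg == leg]
        if not leg_records:
            raise MissingLegError(f"no complete steps for leg {leg}")
        n_steps[leg] = len(leg_records)
        per_leg[leg] = {
            m: float(np.mean([getattr(r, m) for r in leg_records])) for m in STEP_METRICS
        }
    both = {m: 0.5 * (per_leg["AL"][m] + per_leg["UL"][m]) for m in STEP_METRICS}
    return TrialSummary(
        per_leg=per_leg,
        both_legs=both,
        n_steps=n_steps,
        stride_count=min(n_steps.values()),
    )


def vmax_trial_valid(
    records: Sequence[StepRecord],
    touchdown_positions: Optional[Sequence[float]] = None,
    *,
    f_ap=None,
    rate: Optional[float] = None,
    body_mass: Optional[float] = None,
    min_strides: int = 8,
    drift_limit: float = 0.3,
) -> tuple[bool, dict]:
    """Check the top-speed trial criterion: enough strides, stable position.

    A trial counts as a valid maximum-velocity attempt when the athlete
    completes at least ``min_strides`` strides while holding fore-aft
    position.  Position drift is the difference between the last and first
    stance-onset fore-aft marker positions; without markers, a fore-aft
    impulse double integral of ``f_ap / body_mass`` stands in (logged).
    """
    n_al = sum(1 for r in records if r.leg == "AL")
    n_ul = sum(1 for r in records if r.leg == "UL")
    strides = min(n_al, n_ul)
    diagnostics: dict = {"stride_count": strides, "drift_m": None, "drift_source": None}
    if strides < min_strides:
        return False, diagnostics
    if touchdown_positions is not None and len(touchdown_positions) >= 2:
        drift = float(abs(touchdown_positions[-1] - touchdown_positions[0]))
        diagnostics["drift_source"] = "marker"
    elif f_ap is not None and rate is not None and body_mass is not None:
        logger.info("no touchdown marker positions; using fore-aft impulse drift")
        accel = np.asarray(f_ap, dtype=float) / body_mass
        vel = cumulative_trapezoid(accel, dx=1.0 / rate, initial=0.0)
        pos = cumulative_trapezoid(vel, dx=1.0 / rate, initial=0.0)
        drift = float(abs(pos[-1] - pos[0]))
        diagnostics["drift_source"] = "impulse"
    else:
        raise DataError("need touchdown positions or (f_ap, rate, body_mass) for drift check")
    diagnostics["drift_m"] = drift
    return drift <= drift_limit, diagnostics
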