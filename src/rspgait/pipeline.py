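"""End-to-end trial analysis: session directory -> tidy results table.

Chains the preprocessing (30 Hz zero-phase Butterworth, 30 N contact
threshold, alternating leg labels), the per-step spatiotemporal/force
metrics, the spring-mass stiffness estimates, and the between-leg symmetry
indices for one trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import gait, signal, springmass, stats
from .io import Session, TrialConfig, read_session, results_table

__all__ = ["TrialAnalysis", "analyze_session", "analyze"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialAnalysis:
    """Everything the pipeline computed for one trial."""

    config: TrialConfig
    stances: list  # labeled StanceInterval
    records: list  # StepRecord per complete step
    summary: gait.TrialSummary
    spring: list  # SpringMassEstimate per stance with a stride window
    spring_per_leg: dict  # leg -> mean k_leg (kN/m)
    delta_rsp: float  # prosthesis displacement from mean AL peak resultant, m
    symmetry: dict  # variable -> SI
    belt_speed_marker: Optional[float]  # QC estimate from markers, m/s
    results: pd.DataFrame  # long-format rows

    def si(self, variable: str) -> float:
        return self.symmetry[variable]


#: StepRecord attribute -> results-table variable name.
_RECORD_VARS = {
    "t_c": "contact_time",
    "t_a": "aerial_time",
    "t_step": "step_time",
    "f_step": "step_frequency",
    "L_c": "contact_length",
    "F_avg": "stance_avg_vgrf",
    "F_avg_bw": "stance_avg_vgrf_bw",
    "F_peak_v": "peak_vgrf",
    "F_peak_res": "peak_resultant_grf",
}


def analyze(
    session: Session,
    cutoff_grf: float = 30.0,
    cutoff_marker: float = 7.0,
    threshold: float = signal.CONTACT_THRESHOLD_N,
    min_contact: float = signal.MIN_CONTACT_S,
    min_aerial: float = signal.MIN_AERIAL_S,
) -> TrialAnalysis:
    """Run the full measurement chain on an in-memory session."""
    config = session.config
    rate = config.force_rate
    grf_spec = signal.FilterSpec(cutoff=cutoff_grf)
    f_v = signal.butterworth_lowpass(session.forces.f_v, rate, grf_spec)
    f_ap = signal.butterworth_lowpass(session.forces.f_ap, rate, grf_spec)
    f_ml = signal.butterworth_lowpass(session.forces.f_ml, rate, grf_spec)

    stances = signal.detect_stances(
        f_v, rate, threshold=threshold, min_contact=min_contact, min_aerial=min_aerial
    )
    stances = signal.assign_legs(stances, config.first_contact_leg)
    records = gait.step_metrics(
        stances, f_v, f_ml, f_ap, rate, config.belt_velocity, config.body_mass
    )
    summary = gait.summarize_trial(records)
    spring = springmass.estimate_stance_stiffness(
        stances, f_v, rate, config, f_v_raw=session.forces.f_v
    )

    spring_per_leg = {}
    for leg in ("AL", "UL"):
        ks = [e.k_leg for e in spring if e.leg == leg]
        spring_per_leg[leg] = float(np.mean(ks)) if ks else float("nan")

    al_peaks = [r.F_peak_res for r in records if r.leg == "AL"]
    delta_rsp = springmass.rsp_displacement(float(np.mean(al_peaks)), config.k_RSP)

    per_leg_vars = {
        leg: {
            **{_RECORD_VARS[m]: summary.per_leg[leg][m] for m in _RECORD_VARS},
            "leg_stiffness": spring_per_leg[leg],
        }
        for leg in ("AL", "UL")
    }
    symmetry = stats.symmetry_indices(per_leg_vars)

    belt_speed = None
    if session.markers is not None and stances:
        first = next((s for s in stances if s.leg == config.first_contact_leg), None)
        if first is not None:
            ap = signal.butterworth_lowpass(
                session.markers.ap(first.leg), config.marker_rate,
                signal.FilterSpec(cutoff=cutoff_marker),
            )
            try:
                belt_speed = signal.belt_speed_from_marker(
                    session.markers.time, ap, first.onset / rate, first.offset / rate
                )
            except Exception as exc:  # QC channel only; never fails the trial
                logger.warning("belt-speed QC estimate failed: %s", exc)

    rows = []
    key = {
        "subject": config.subject_id,
        "rsp_model": config.rsp_model,
        "stiffness_category": config.stiffness_category,
        "height_offset": config.height_offset,
        "velocity": config.belt_velocity,
    }
    for leg in ("AL", "UL"):
        for var, value in per_leg_vars[leg].items():
            rows.append({**key, "variable": var, "leg": leg, "value": value})
    for m, var in _RECORD_VARS.items():
        rows.append({**key, "variable": var, "leg": "both", "value": summary.both_legs[m]})
    rows.append({
        **key, "variable": "leg_stiffness", "leg": "both",
        "value": 0.5 * (spring_per_leg["AL"] + spring_per_leg["UL"]),
    })
    for var, value in symmetry.items():
        rows.append({**key, "variable": f"si_{var}", "leg": "trial", "value": value})
    rows.append({**key, "variable": "delta_rsp", "leg": "AL", "value": delta_rsp})
    if belt_speed is not None:
        rows.append({**key, "variable": "belt_speed_marker", "leg": "trial", "value": belt_speed})

    return TrialAnalysis(
        config=config,
        stances=stances,
        records=records,
        summary=summary,
        spring=spring,
        spring_per_leg=spring_per_leg,
        delta_rsp=delta_rsp,
        symmetry=symmetry,
        belt_speed_marker=belt_speed,
        results=results_table(rows),
    )


def analyze_session(session_dir, **kwargs) -> TrialAnalysis:
    """Read a session directory and run the full measurement chain."""
    return analyze(read_session(session_dir), **kwargs)
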