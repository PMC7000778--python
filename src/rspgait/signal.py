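"""Filtering, ground-contact detection and leg labelling.

Raw force traces are low-pass filtered (Butterworth, 30 Hz cutoff for GRF,
7 Hz for markers) before a 30 N vertical-force threshold segments the trace
into stance intervals.  "4th order" filtering is realised as a 2nd-order
design applied forward and backward (zero phase), the standard biomechanics
reading; a single-pass variant is available through ``FilterSpec.zero_phase``
for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .exceptions import DataError, InsufficientDataError, ParameterError

__all__ = [
    "FilterSpec",
    "GRF_FILTER",
    "MARKER_FILTER",
    "StanceInterval",
    "butterworth_lowpass",
    "detect_stances",
    "assign_legs",
    "belt_speed_from_marker",
]

logger = logging.getLogger(__name__)

#: Vertical-force threshold for ground-contact detection, newtons.
CONTACT_THRESHOLD_N = 30.0
#: Contacts shorter than this are discarded (spurious crossings), seconds.
MIN_CONTACT_S = 0.05
#: Aerial gaps shorter than this are merged into the surrounding contact.
MIN_AERIAL_S = 0.02


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification.

    ``design_order`` is the order of the underlying design; with
    ``zero_phase`` the filter runs forward and backward, squaring the
    magnitude response (a 2nd-order design yields an effective 4th-order
    magnitude roll-off and no phase shift).
    """

    cutoff: float  # Hz
    design_order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.design_order not in (2, 4):
            raise ParameterError(f"design_order must be 2 or 4, got {self.design_order}")
        if not self.cutoff > 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")


GRF_FILTER = FilterSpec(cutoff=30.0)
MARKER_FILTER = FilterSpec(cutoff=7.0)


@dataclass(frozen=True)
class StanceInterval:
    """Half-open sample interval [onset, offset) of one ground contact.

    ``onset`` is the first sample at/above the contact threshold, ``offset``
    the first sample below it again, so contact time is
    ``(offset - onset) / rate`` and stance plus aerial samples partition the
    trace exactly.
    """

    onset: int
    offset: int
    leg: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise DataError(f"stance offset {self.offset} must exceed onset {self.onset}")

    @property
    def n_samples(self) -> int:
        return self.offset - self.onset

    def duration(self, rate: float) -> float:
        return self.n_samples / rate

    def slice(self) -> slice:
        return slice(self.onset, self.offset)


def butterworth_lowpass(x, rate: float, spec: FilterSpec = GRF_FILTER) -> np.ndarray:
    """Low-pass filter a uniformly sampled series.

    Zero-phase mode applies the design forward and backward
    (``sosfiltfilt``), giving unit DC gain, a symmetric impulse response and
    a squared magnitude response; single-pass mode uses ``sosfilt``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError("butterworth_lowpass expects a 1-D series")
    if np.any(~np.isfinite(x)):
        raise DataError("input series contains NaN or infinite values")
    if spec.cutoff >= rate / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {rate / 2} Hz"
        )
    if x.size <= 6 * spec.design_order:
        raise DataError(
            f"series of length {x.size} too short for order-{spec.design_order} filtering"
        )
    sos = sps.butter(spec.design_order, spec.cutoff, btype="low", fs=rate, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_stances(
    f_v,
    rate: float,
    threshold: float = CONTACT_THRESHOLD_N,
    min_contact: float = MIN_CONTACT_S,
    min_aerial: float = MIN_AERIAL_S,
) -> list[StanceInterval]:
    """Segment a filtered vertical-GRF trace into stance intervals.

    Samples at/above ``threshold`` form candidate contacts; aerial gaps
    shorter than ``min_aerial`` are merged (filter ringing, brief unloading)
    and contacts shorter than ``min_contact`` discarded.  The caller is
    responsible for filtering the input first.  An empty list is a valid
    result.
    """
    f_v = np.asarray(f_v, dtype=float)
    if not threshold > 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    runs = _runs_above(f_v >= threshold)
    if not runs:
        return []
    # merge aerial gaps shorter than min_aerial
    max_gap = int(round(min_aerial * rate))
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    # purge contacts shorter than min_contact
    min_len = int(round(min_contact * rate))
    return [
        StanceInterval(onset=start, offset=stop)
        for start, stop in merged
        if stop - start >= min_len
    ]


def assign_legs(stances: list[StanceInterval], first_contact_leg: str) -> list[StanceInterval]:
    """Label time-ordered stances with strictly alternating leg identities."""
    if first_contact_leg not in ("AL", "UL"):
        raise ParameterError(f"first_contact_leg must be 'AL' or 'UL', got {first_contact_leg!r}")
    other = "UL" if first_contact_leg == "AL" else "AL"
    order = (first_contact_leg, other)
    return [replace(s, leg=order[i % 2]) for i, s in enumerate(stances)]


def belt_speed_from_marker(time, ap, t_on: float, t_off: float) -> float:
    """Mean fore-aft marker speed over one stance, m/s.

    ``ap`` should already be low-pass filtered at 7 Hz.  The stance window
    [t_on, t_off) is mapped onto the marker timebase; the return value is the
    mean magnitude of the finite-difference fore-aft velocity, which for a
    marker riding the belt equals the belt speed.
    """
    time = np.asarray(time, dtype=float)
    ap = np.asarray(ap, dtype=float)
    window = (time >= t_on) & (time < t_off)
    if np.count_nonzero(window) < 3:
        raise InsufficientDataError(
            f"stance [{t_on:.3f}, {t_off:.3f}) s covers fewer than 3 marker samples"
        )
    velocity = np.gradient(ap[window], time[window])
    return float(np.mean(np.abs(velocity)))
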