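"""Saturable canalicular efflux, bile routing and the meal-triggered
gallbladder state machine that produces enterohepatic recirculation.

Hepatic MRP2 efflux delivers drug to bile.  While the gallbladder is filling,
a configurable fraction of bile flows continuously to the duodenum and the
remainder is stored.  A meal event moves a fixed fraction of the stored
content into an ejecting pool that drains exponentially (half-time from the
EHC parameters) into the duodenum; for the refractory ``refill_time`` after a
meal, hepatic bile bypasses the contracted gallbladder entirely.  Dosing is
fasted: no emptying event occurs before the first scheduled meal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import EHCParameters, RangeError

__all__ = [
    "GallbladderState",
    "saturable_rate",
    "bile_split",
    "meal_schedule",
    "emptying_event",
    "nonfilling_windows",
]

LN2 = math.log(2.0)

PHASES = ("filling", "emptying", "refractory")


@dataclass
class GallbladderState:
    """Stored drug amount and emptying phase of the gallbladder."""

    stored_umol: float = 0.0
    phase: str = "filling"
    phase_start_h: float = 0.0
    ejectable_umol: float = 0.0   # amount committed at the start of an event

    def __post_init__(self):
        if self.stored_umol < 0:
            raise RangeError("stored_umol", self.stored_umol, "must be >= 0")
        if self.phase not in PHASES:
            raise RangeError("phase", self.phase, f"must be one of {PHASES}")


def saturable_rate(c_unbound: float, kcat: float, enzyme_amount: float,
                   km: float) -> float:
    """Michaelis-Menten rate in µmol/min: kcat*E*c/(km + c).

    Shared by CYP3A4 metabolism and MRP2 transport; ``enzyme_amount`` is the
    tissue enzyme/transporter amount in µmol (reference concentration times
    organ volume), ``kcat`` in 1/min.
    """
    if c_unbound < 0 or kcat < 0 or enzyme_amount < 0:
        raise RangeError("saturable_rate args", (c_unbound, kcat, enzyme_amount),
                         "must be >= 0")
    if not km > 0:
        raise RangeError("km", km, "must be > 0")
    return kcat * enzyme_amount * c_unbound / (km + c_unbound)


def bile_split(efflux: float, continuous_fraction: float,
               filling: bool = True) -> tuple[float, float]:
    """Split canalicular efflux into (to_duodenum, to_gallbladder) µmol/min.

    While filling, ``continuous_fraction`` of bile bypasses the gallbladder;
    during the emptying/refractory phases the contracted gallbladder cannot
    fill and all bile routes to the duodenum.
    """
    if not (0.0 <= continuous_fraction <= 1.0):
        raise RangeError("continuous_fraction", continuous_fraction,
                         "must lie in [0,1]")
    if not filling:
        return efflux, 0.0
    to_duo = efflux * continuous_fraction
    return to_duo, efflux - to_duo


def meal_schedule(ehc: EHCParameters, horizon_h: float) -> np.ndarray:
    """Ordered gallbladder-emptying event times (h) up to ``horizon_h``.

    The first-day meal times repeat with a 24 h period.  No event fires
    before the first meal time (fasted dosing).
    """
    if not horizon_h > 0:
        raise RangeError("horizon", horizon_h, "must be > 0")
    base = np.asarray(ehc.meal_times, dtype=float)
    if base.size == 0:
        raise RangeError("meal_times", base, "must be non-empty")
    n_days = int(math.floor(horizon_h / 24.0)) + 1
    times = (base[None, :] + 24.0 * np.arange(n_days)[:, None]).ravel()
    return np.sort(times[times <= horizon_h])


def emptying_event(state: GallbladderState, ehc: EHCParameters,
                   t_since_event_min: float) -> float:
    """Cumulative amount ejected (µmol) ``t_since_event_min`` into an event.

    cumulative(t) = ejection_fraction * content0 * (1 - 2^(-t/half_time)); the
    asymptote is the committed ejectable amount, and half of it has left the
    gallbladder at t = emptying_half_time.
    """
    if state.phase != "emptying":
        raise RangeError("phase", state.phase,
                         "emptying_event requires the gallbladder to be in the "
                         "'emptying' phase")
    if t_since_event_min < 0:
        raise RangeError("t_since_event", t_since_event_min, "must be >= 0")
    asymptote = ehc.ejection_fraction * state.ejectable_umol
    return asymptote * (1.0 - 2.0 ** (-t_since_event_min / ehc.emptying_half_time))


def nonfilling_windows(meal_times_h: np.ndarray,
                       refill_time_min: float) -> list[tuple[float, float]]:
    """Merged intervals (h) during which the gallbladder cannot fill.

    Each meal opens a window of ``refill_time`` minutes (emptying followed by
    refilling); overlapping windows from closely spaced meals are merged.
    """
    refill_h = refill_time_min / 60.0
    windows: list[tuple[float, float]] = []
    for t in np.sort(np.asarray(meal_times_h, dtype=float)):
        lo, hi = float(t), float(t) + refill_h
        if windows and lo <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(hi, windows[-1][1]))
        else:
            windows.append((lo, hi))
    return windows
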