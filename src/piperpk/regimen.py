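"""Dosing-regimen construction.

A regimen is either interval-based (a maintenance dose repeated every
``interval`` hours, each given as a zero-order infusion) or continuous
(a single uninterrupted infusion delivering ``daily_dose_continuous`` mg
per 24 h), optionally preceded by a loading dose given as a short
infusion at t = 0 with the maintenance phase starting immediately at its
end.  Amounts refer to the piperacillin component only.

``PRESETS`` holds the ten strategies evaluated in the dosing simulations:
4 g q6h/q8h short (30 min) infusions, 4 g extended infusions over half
the interval (3 h q6h, 4 h q8h) with and without a 2 g loading dose,
2 g loading dose + 8/12/16 g per 24 h continuous infusion, and a
high-dose 22 g/day extended-infusion strategy (5.5 g q6h over 3 h after
a 2 g loading dose; the total daily dose, 22 g, is the defining figure).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .pk_core import DoseEvent

__all__ = ["RegimenSpec", "build", "trough_times", "daily_dose", "PRESETS"]


@dataclass(frozen=True)
class RegimenSpec:
    """Specification of a dosing strategy over a simulation horizon."""

    label: str
    maintenance_dose: Optional[float] = None  #: mg per administration (interval mode)
    interval: Optional[float] = None  #: h between administrations
    infusion_duration: Optional[float] = None  #: h per maintenance infusion
    daily_dose_continuous: Optional[float] = None  #: mg per 24 h (continuous mode)
    loading_dose: Optional[float] = None  #: mg, given at t = 0
    loading_duration: float = 0.5  #: h, loading infusion length
    horizon: float = 48.0  #: h simulated
    first_dose_short_infusion: bool = False  #: give the first maintenance dose over 0.5 h

    def __post_init__(self) -> None:
        interval_mode = self.maintenance_dose is not None
        continuous_mode = self.daily_dose_continuous is not None
        if interval_mode == continuous_mode:
            raise ValueError("exactly one of interval or continuous mode must be set")
        if interval_mode:
            if self.interval is None or self.infusion_duration is None:
                raise ValueError("interval mode needs interval and infusion_duration")
            if self.maintenance_dose <= 0 or self.interval <= 0 or self.infusion_duration <= 0:
                raise ValueError("doses, interval and durations must be > 0")
            if self.infusion_duration > self.interval:
                raise ValueError("infusion_duration must not exceed the dosing interval")
        else:
            if self.daily_dose_continuous <= 0:
                raise ValueError("daily_dose_continuous must be > 0")
        if self.loading_dose is not None and self.loading_dose <= 0:
            raise ValueError("loading_dose must be > 0 when present")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    @property
    def is_continuous(self) -> bool:
        return self.daily_dose_continuous is not None

    @property
    def maintenance_start(self) -> float:
        """Start of the maintenance phase: 0, or the end of the loading infusion."""
        return self.loading_duration if self.loading_dose is not None else 0.0


def build(spec: RegimenSpec) -> list[DoseEvent]:
    """Expand a regimen into the dose events covering [0, horizon]."""
    if spec.horizon == 0:
        return []
    events: list[DoseEvent] = []
    if spec.loading_dose is not None:
        events.append(DoseEvent(0.0, spec.loading_dose, spec.loading_duration))
    t0 = spec.maintenance_start
    if spec.is_continuous:
        rate = spec.daily_dose_continuous / 24.0
        span = spec.horizon - t0
        if span > 0:
            events.append(DoseEvent(t0, rate * span, span))
    else:
        start = t0
        first = True
        while start < spec.horizon:
            dur = (
                0.5
                if (first and spec.first_dose_short_infusion)
                else spec.infusion_duration
            )
            events.append(DoseEvent(start, spec.maintenance_dose, dur))
            start += spec.interval
            first = False
    return events


def trough_times(spec: RegimenSpec, dense_step: float = 0.05) -> np.ndarray:
    """Evaluation times for target attainment.

    Interval mode: the instants immediately before each maintenance dose
    after the first, plus the horizon (a dose contributes nothing at its own
    start time, so evaluating exactly at a dose time gives the pre-dose
    trough).  Continuous mode: a dense grid from the end of the loading
    infusion (exclusive) to the horizon, for minimum-seeking.
    """
    if spec.is_continuous:
        t0 = spec.maintenance_start
        return np.arange(t0 + dense_step, spec.horizon + 1e-9, dense_step)
    t0 = spec.maintenance_start
    dose_times = np.arange(t0, spec.horizon, spec.interval)
    times = list(dose_times[1:])
    if not times or times[-1] < spec.horizon:
        times.append(spec.horizon)
    return np.asarray(times, dtype=float)


def daily_dose(spec: RegimenSpec) -> float:
    """Nominal maintenance daily dose, mg/24 h (loading dose excluded)."""
    if spec.is_continuous:
        return spec.daily_dose_continuous
    return spec.maintenance_dose * 24.0 / spec.interval


def _with_ld(spec: RegimenSpec, label: str) -> RegimenSpec:
    return replace(spec, label=label, loading_dose=2000.0)


_q8_si = RegimenSpec("4g_q8h_si30min", maintenance_dose=4000.0, interval=8.0, infusion_duration=0.5)
_q6_si = RegimenSpec("4g_q6h_si30min", maintenance_dose=4000.0, interval=6.0, infusion_duration=0.5)
_q8_ei = RegimenSpec("4g_q8h_ei4h", maintenance_dose=4000.0, interval=8.0, infusion_duration=4.0)
_q6_ei = RegimenSpec("4g_q6h_ei3h", maintenance_dose=4000.0, interval=6.0, infusion_duration=3.0)

#: The ten dosing strategies of the 48 h Monte Carlo evaluation.
PRESETS: dict[str, RegimenSpec] = {
    s.label: s
    for s in [
        _q8_si,
        _q6_si,
        _q8_ei,
        _q6_ei,
        _with_ld(_q8_ei, "2gld_4g_q8h_ei4h"),
        _with_ld(_q6_ei, "2gld_4g_q6h_ei3h"),
        RegimenSpec("2gld_8g_ci", daily_dose_continuous=8000.0, loading_dose=2000.0),
        RegimenSpec("2gld_12g_ci", daily_dose_continuous=12000.0, loading_dose=2000.0),
        RegimenSpec("2gld_16g_ci", daily_dose_continuous=16000.0, loading_dose=2000.0),
        RegimenSpec(
            "2gld_22g_q6h_ei3h",
            maintenance_dose=5500.0,
            interval=6.0,
            infusion_duration=3.0,
            loading_dose=2000.0,
        ),
    ]
}
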