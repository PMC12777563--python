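"""Closed-form one-compartment kinetics with zero-order (infusion) input.

All of the dosing regimens studied here are infusions, so the only input
model needed is zero-order input over a finite duration; bolus doses are
represented as short infusions.  For a single infusion event starting at
``t0`` with rate ``R0 = amount/duration`` the plasma concentration of a
one-compartment model with first-order elimination (rate constant
``k = CL/V``) is

    C(t) = (R0/CL) * (1 - exp(-k * (t - t0)))                t0 <= t <= t_end
    C(t) = C(t_end) * exp(-k * (t - t_end))                  t  >  t_end

and arbitrary regimens follow by superposition (the model is linear).

Between-occasion variability makes clearance piecewise constant in time;
:func:`conc_piecewise_cl` propagates the compartment amount exactly across
occasion boundaries, so the profile stays continuous while ``k`` switches.

Units: time in hours from first-dose start, amounts in mg, volumes in L,
concentrations in mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FU_PIPERACILLIN",
    "StructuralParams",
    "DoseEvent",
    "conc_total",
    "unbound",
    "profile",
    "events_to_array",
    "conc_events",
    "conc_piecewise_cl",
]

#: Unbound fraction of piperacillin in plasma (30% protein binding assumed).
FU_PIPERACILLIN = 0.70


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters of the one-compartment model."""

    cl: float  #: clearance, L/h
    v: float  #: apparent volume of distribution, L

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cl) and self.cl > 0):
            raise ValueError(f"clearance must be finite and > 0, got {self.cl}")
        if not (np.isfinite(self.v) and self.v > 0):
            raise ValueError(f"volume must be finite and > 0, got {self.v}")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion of piperacillin.

    A continuous infusion is one long event; a "bolus" is a short event.
    """

    start_time: float  #: h since simulation origin
    amount: float  #: mg of piperacillin
    duration: float  #: h of zero-order input

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.amount <= 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not np.isfinite(self.amount / self.duration):
            raise ValueError("infusion rate must be finite")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


def events_to_array(doses: Iterable[DoseEvent]) -> np.ndarray:
    """Pack dose events into an (E, 3) array of [start, amount, duration]."""
    arr = np.array([[d.start_time, d.amount, d.duration] for d in doses], dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 3)
    return arr


def conc_events(
    cl: np.ndarray | float,
    v: np.ndarray | float,
    events: np.ndarray,
    times: np.ndarray | float,
) -> np.ndarray:
    """Superposed one-compartment concentration for an event array.

    Vectorized over an arbitrary batch shape of ``cl``/``v`` and a trailing
    time axis.  ``events`` is (E, 3) as produced by :func:`events_to_array`.

    Returns an array of shape ``batch_shape + times.shape``.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    t = np.asarray(times, dtype=float)
    batch = np.broadcast_shapes(cl.shape, v.shape)
    cl_b = np.broadcast_to(cl, batch)[(...,) + (np.newaxis,) * t.ndim]
    v_b = np.broadcast_to(v, batch)[(...,) + (np.newaxis,) * t.ndim]
    k = cl_b / v_b
    out = np.zeros(batch + t.shape, dtype=float)
    for start, amount, dur in events:
        dt = t - start
        # time infused so far, clipped to [0, dur]
        te = np.clip(dt, 0.0, dur)
        rise = (amount / dur / cl_b) * -np.expm1(-k * te)
        decay = np.exp(-k * np.clip(dt - dur, 0.0, None))
        out += rise * decay
    return out


def conc_piecewise_cl(
    cl_occ: np.ndarray,
    v: np.ndarray | float,
    events: np.ndarray,
    boundaries: Sequence[float],
    times: np.ndarray,
) -> np.ndarray:
    """Concentration with clearance piecewise constant over occasion windows.

    ``cl_occ`` has shape ``batch + (M,)`` giving the clearance in each of the
    M occasion windows ``[boundaries[m], boundaries[m+1])``; ``boundaries``
    has length M + 1, starting at (or before) the first event and covering
    every requested time.  The amount in the compartment is carried across
    each boundary, so the profile is continuous and exact for piecewise
    constant ``k``; a time falling exactly on a boundary takes the value of
    the window that ends there (left-continuous convention).
    """
    cl_occ = np.asarray(cl_occ, dtype=float)
    v = np.asarray(v, dtype=float)
    t = np.asarray(times, dtype=float)
    bounds = np.asarray(boundaries, dtype=float)
    n_occ = bounds.size - 1
    if cl_occ.shape[-1] != n_occ:
        raise ValueError("cl_occ last axis must match number of occasion windows")
    if np.any(t < bounds[0] - 1e-9) or np.any(t > bounds[-1] + 1e-9):
        raise ValueError("times must lie within the occasion boundaries")
    t = np.clip(t, bounds[0], bounds[-1])
    batch = np.broadcast_shapes(cl_occ.shape[:-1], v.shape)
    v_b = np.broadcast_to(v, batch)
    amount = np.zeros(batch, dtype=float)  # compartment amount at window start
    out = np.zeros(batch + t.shape, dtype=float)
    for m in range(n_occ):
        b0, b1 = bounds[m], bounds[m + 1]
        cl_m = np.broadcast_to(cl_occ[..., m], batch)
        k_m = cl_m / v_b
        # clip events to this window; earlier input is already in `amount`
        sub = []
        for start, amt, dur in events:
            s = max(start, b0)
            e = min(start + dur, b1)
            if e > s:
                rate = amt / dur
                sub.append([s, rate * (e - s), e - s])
        sub = np.asarray(sub, dtype=float).reshape(-1, 3)

        def window_conc(tw: np.ndarray) -> np.ndarray:
            carry = (amount / v_b)[(...,) + (np.newaxis,) * tw.ndim] * np.exp(
                -k_m[(...,) + (np.newaxis,) * tw.ndim] * (tw - b0)
            )
            return carry + conc_events(cl_m, v_b, sub, tw)

        if m == 0:
            mask = (t >= b0) & (t <= b1)
        else:
            mask = (t > b0) & (t <= b1)
        if np.any(mask):
            out[..., mask] = window_conc(t[mask])
        if m < n_occ - 1:
            amount = window_conc(np.asarray(b1)) * v_b
    return out


def conc_total(params: StructuralParams, doses: Sequence[DoseEvent], t) -> np.ndarray | float:
    """Total plasma concentration at time(s) ``t`` under superposed dosing.

    ``t`` may be a scalar or array; all times must be >= 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if len(doses) == 0:
        raise ValueError("doses must be non-empty")
    out = conc_events(params.cl, params.v, events_to_array(doses), t_arr)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def unbound(conc: np.ndarray | float) -> np.ndarray | float:
    """Unbound concentration assuming 30% protein binding (fu = 0.70)."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = FU_PIPERACILLIN * c
    return float(out) if np.isscalar(conc) else out


def profile(params: StructuralParams, doses: Sequence[DoseEvent], time_grid) -> np.ndarray:
    """Vectorized :func:`conc_total` on a strictly increasing time grid."""
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1:
        raise ValueError("time_grid must be one-dimensional")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    return conc_total(params, doses, grid)
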