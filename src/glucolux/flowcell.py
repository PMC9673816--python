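"""In-silico flow-cell validation protocol: glucose steps and lifetime TSS.

Reproduces the bench "flow-through" test of the enzymatic
phosphorescence-lifetime sensor: a glucose/buffer solution steps through
0 -> 11.1 mol/m^3 in five holds while the sensor-mean phosphorescence
lifetime is recorded; the response speed of each transition is summarized
by the time-to-steady-state (TSS), defined as the interval from the
lifetime first exceeding its initial plateau by 5% to its first entry
within 5% of the next steady-state plateau (thresholds mirrored for
falling transitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, SternVolmerParams
from .rd_solver import Mesh2D, RDSolver, TransportParams, build_flowcell_mesh, poiseuille_flow

__all__ = [
    "GlucoseProtocol",
    "LifetimeTrace",
    "TSSUndefinedError",
    "run_protocol",
    "compute_tss",
    "summarize_tss",
]

#: Steady-state detection tolerance: |d tau/dt| below this (us/min) over a
#: 2-min trailing window flags a plateau.
STEADY_SLOPE_US_PER_MIN = 1e-3


class TSSUndefinedError(ValueError):
    """The 5%/5% thresholds are never crossed (degenerate transition)."""


@dataclass(frozen=True)
class GlucoseProtocol:
    """Ordered inlet holds: ``[(concentration mol/m^3, duration min), ...]``."""

    steps: tuple = ((0.0, 45.0), (2.78, 45.0), (5.55, 45.0), (8.34, 45.0), (11.1, 45.0))

    def __post_init__(self):
        for c, d in self.steps:
            if c < 0:
                raise ValueError("hold concentrations must be >= 0")
            if d <= 0:
                raise ValueError("hold durations must be > 0")

    @property
    def total_minutes(self) -> float:
        return sum(d for _, d in self.steps)


@dataclass
class LifetimeTrace:
    """Sensor lifetime vs. time with per-step plateaus and per-transition TSS."""

    time_min: np.ndarray
    tau_us: np.ndarray
    step_index: np.ndarray
    inlet_G: np.ndarray
    steady_tau: np.ndarray          # one per hold
    steady_reached: np.ndarray      # bool per hold (slope criterion)
    tss_min: np.ndarray             # one per transition; NaN when undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "tau_us": self.tau_us,
                "step_index": self.step_index,
                "inlet_G": self.inlet_G,
            }
        )


def compute_tss(time_min, tau_us, tau_initial: float, tau_final: float) -> float:
    """Time-to-steady-state (min) of one transition segment.

    Start: first crossing of ``tau_initial * 1.05`` (rising) or ``* 0.95``
    (falling).  End: first entry of the band ``|tau - tau_final| <= 0.05 *
    tau_final``.  Crossing times are linearly interpolated; if both occur at
    the same sample the transition is effectively instantaneous and 0 is
    returned.  Raises :class:`TSSUndefinedError` when a threshold is never
    crossed (including the degenerate case ``tau_initial == tau_final``).
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(tau_us, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 2:
        raise ValueError("need matching 1-D time and lifetime arrays")
    if tau_initial <= 0 or tau_final <= 0:
        raise ValueError("lifetimes must be positive")
    rising = tau_final > tau_initial
    thr_start = tau_initial * (1.05 if rising else 0.95)
    lo, hi = 0.95 * tau_final, 1.05 * tau_final

    def first_cross(mask):
        idx = np.where(mask)[0]
        return int(idx[0]) if idx.size else None

    i_start = first_cross(y >= thr_start if rising else y <= thr_start)
    i_end = first_cross((y >= lo) & (y <= hi))
    if i_start is None or i_end is None or i_end < i_start:
        raise TSSUndefinedError(
            f"lifetime never crossed the 5% thresholds "
            f"(tau_i={tau_initial:.4g}, tau_f={tau_final:.4g})"
        )
    if i_start == i_end:
        return 0.0

    def interp_time(i, level, from_below):
        if i == 0:
            return t[0]
        y0, y1 = y[i - 1], y[i]
        if y1 == y0:
            return t[i]
        return t[i - 1] + (level - y0) / (y1 - y0) * (t[i] - t[i - 1])

    t_start = interp_time(i_start, thr_start, rising)
    t_end = interp_time(i_end, lo if rising else hi, rising)
    return float(max(t_end - t_start, 0.0))


def summarize_tss(trace: LifetimeTrace) -> float:
    """Arithmetic mean TSS (min) over the protocol's defined transitions."""
    vals = np.asarray(trace.tss_min, dtype=float)
    good = vals[np.isfinite(vals)]
    if good.size == 0:
        raise TSSUndefinedError("no transition produced a defined TSS")
    return float(good.mean())


def run_protocol(
    protocol: GlucoseProtocol = GlucoseProtocol(),
    mesh: Mesh2D | None = None,
    transport: TransportParams | None = None,
    kinetics: KineticParams | None = None,
    sv: SternVolmerParams | None = None,
    mean_velocity: float = 0.009,
    inlet_O2: float = 0.009,
    dt: float = 1.0,
    cadence_s: float = 15.0,
) -> LifetimeTrace:
    """Step the inlet glucose through the protocol and record sensor lifetime.

    The inlet Dirichlet value follows the hold sequence; the volume-weighted
    mean lifetime over the enzymatic sensor is sampled every ``cadence_s``
    seconds.  Each hold's plateau lifetime is the final sample of the hold
    (with a trailing-slope flag when the plateau criterion is not met), and
    TSS is computed for every transition between consecutive holds.
    """
    if mesh is None:
        mesh = build_flowcell_mesh(inlet={"G": protocol.steps[0][0], "O2": inlet_O2})
    flow = poiseuille_flow(mesh, mean_velocity)
    solver = RDSolver(
        mesh,
        transport=transport,
        kinetics=kinetics,
        flow=flow,
        dt=dt,
        sv=sv,
        init={"G": protocol.steps[0][0], "O2": inlet_O2},
    )
    probe_every = max(1, int(round(cadence_s / dt)))

    times, taus, steps_ix, inlet = [], [], [], []
    steady_tau, steady_ok = [], []
    for k, (conc, dur_min) in enumerate(protocol.steps):
        solver.set_boundary_value("left", "G", conc)
        t0 = solver.t

        def probe(s):
            times.append(s.t / 60.0)
            taus.append(s.sensor_lifetime())
            steps_ix.append(k)
            inlet.append(conc)

        solver.run(dur_min * 60.0, probe=probe, probe_every=probe_every)
        # plateau value & trailing-slope steadiness over the last 2 minutes
        tt = np.asarray(times)
        yy = np.asarray(taus)
        seg = (np.asarray(steps_ix) == k) & (tt >= tt[-1] - 2.0)
        slope = 0.0
        if seg.sum() >= 2:
            slope = np.polyfit(tt[seg], yy[seg], 1)[0]
        steady_tau.append(yy[-1])
        steady_ok.append(abs(slope) < STEADY_SLOPE_US_PER_MIN)

    tt = np.asarray(times)
    yy = np.asarray(taus)
    steps_arr = np.asarray(steps_ix)
    tss = []
    for k in range(1, len(protocol.steps)):
        seg = steps_arr == k
        try:
            tss.append(
                compute_tss(tt[seg] - tt[seg][0], yy[seg], steady_tau[k - 1], steady_tau[k])
            )
        except TSSUndefinedError:
            tss.append(np.nan)
    return LifetimeTrace(
        time_min=tt,
        tau_us=yy,
        step_index=steps_arr,
        inlet_G=np.asarray(inlet),
        steady_tau=np.asarray(steady_tau),
        steady_reached=np.asarray(steady_ok, dtype=bool),
        tss_min=np.asarray(tss),
    )
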