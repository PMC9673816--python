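"""Interstitial (in-vivo) sensor model and the spacer crosstalk study.

The inserted barcode sensor is modeled in a 1-mm-tall 2-D slice of
subcutaneous tissue ~2 mm below the skin surface.  Capillary beds 0.05 mm
above and below the sensor hold glucose at the capillary waveform value
Pw(t) and O2 at a constant 0.009 mol/m^3 (Dirichlet top/bottom boundaries);
the background tissue consumes both species at zeroth-order rates.  The
sensor itself is a row of alternating 0.36-mm enzymatic / nonenzymatic
sensing domains separated by inert hydrogel spacers of variable width, with
0.05-mm tissue end caps (total length 4.53 mm at 0.01-mm spacers up to
15.42 mm at 1.0-mm spacers).

The crosstalk question: does glucose consumption by the enzymatic domains
depress the glucose seen by the neighboring nonenzymatic (competitive
binding) domains, and does the spacer width matter?  The metric is the
per-domain percent difference in steady-state mean glucose between two
spacer widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .rd_solver import REGIONS, Mesh2D, RDSolver, TransportParams, steady_state

__all__ = [
    "InterstitialGeometry",
    "TissueSinks",
    "build_interstitial_mesh",
    "nonenzymatic_domain_masks",
    "run_invivo",
    "steady_domain_means",
    "crosstalk_metric",
    "spacer_crosstalk_study",
]


@dataclass(frozen=True)
class InterstitialGeometry:
    """Layout of the interstitial slice (all mm)."""

    height: float = 1.0
    domain_thickness: float = 0.36
    n_domains_per_assay: int = 6
    standoff: float = 0.05       # capillary-to-sensor gap, above and below
    end_cap: float = 0.05        # tissue margin beyond the sensor ends
    dx: float = 0.01
    dy: float = 0.025

    def total_length(self, spacer: float) -> float:
        n = 2 * self.n_domains_per_assay
        return n * self.domain_thickness + (n - 1) * spacer + 2 * self.end_cap

    @property
    def sensor_height(self) -> float:
        return self.height - 2 * self.standoff


@dataclass(frozen=True)
class TissueSinks:
    """Zeroth-order tissue consumption and capillary supply concentrations.

    ``RG``/``RO2`` are consumption magnitudes (mol m^-3 s^-1, positive);
    ``Pw`` is the capillary glucose concentration (constant default; the
    time-varying waveform enters through :func:`run_invivo`), ``CO2`` the
    constant capillary O2.
    """

    RG: float = 0.027
    RO2: float = 1.04e-5
    Pw: float = 2.78
    CO2: float = 0.009

    def __post_init__(self):
        if self.RG < 0 or self.RO2 < 0:
            raise ValueError("sink magnitudes must be >= 0 (consumption)")
        if self.Pw < 0 or self.CO2 < 0:
            raise ValueError("capillary concentrations must be >= 0")


def _domain_edges(geom: InterstitialGeometry, spacer: float):
    """(x0, x1, label) spans (mm) of the 12 alternating sensing domains."""
    spans = []
    x = geom.end_cap
    for k in range(2 * geom.n_domains_per_assay):
        label = "sensor_enzymatic" if k % 2 == 0 else "sensor_nonenzymatic"
        spans.append((x, x + geom.domain_thickness, label))
        x += geom.domain_thickness
        if k < 2 * geom.n_domains_per_assay - 1:
            x += spacer
    return spans


def build_interstitial_mesh(
    geom: InterstitialGeometry = InterstitialGeometry(),
    spacer: float = 0.1,
    sinks: TissueSinks = TissueSinks(),
    capillary_ends: bool = True,
) -> Mesh2D:
    """Mesh the interstitial slice for one spacer width (mm).

    Capillary Dirichlet boundaries hold G and O2 at the capillary values on
    all four domain edges by default: the capillary bed surrounds the sensor
    at ~0.05-mm distance in every direction, and a no-enzyme control shows
    that impermeable end walls would starve the end-cap tissue (the
    zeroth-order sink then depresses the end domains by several percent, an
    artifact unrelated to assay crosstalk).  Set ``capillary_ends=False``
    for cut (zero-flux) left/right ends.
    """
    if not 0.0 <= spacer <= 1.0 + 1e-9:
        raise ValueError("spacer must be within [0, 1] mm")
    length = geom.total_length(spacer)
    nx = int(round(length / geom.dx))
    ny = int(round(geom.height / geom.dy))
    region = np.full((ny, nx), REGIONS["tissue"], dtype=np.int8)
    x = (np.arange(nx) + 0.5) * geom.dx
    y = (np.arange(ny) + 0.5) * geom.dy
    band = (y > geom.standoff) & (y < geom.height - geom.standoff)
    in_sensor_x = (x > geom.end_cap) & (x < length - geom.end_cap)
    region[np.ix_(band, in_sensor_x)] = REGIONS["spacer"]
    for x0, x1, label in _domain_edges(geom, spacer):
        cols = (x > x0) & (x < x1)
        region[np.ix_(band, cols)] = REGIONS[label]
    bc_val = {"G": sinks.Pw, "O2": sinks.CO2}
    ends = ("dirichlet", bc_val) if capillary_ends else ("zero_flux",)
    bc = {
        "top": ("dirichlet", dict(bc_val)),
        "bottom": ("dirichlet", dict(bc_val)),
        "left": (ends[0], dict(bc_val)) if capillary_ends else ("zero_flux",),
        "right": (ends[0], dict(bc_val)) if capillary_ends else ("zero_flux",),
    }
    return Mesh2D(region=region, dx=geom.dx * 1e-3, dy=geom.dy * 1e-3, bc=bc)


def nonenzymatic_domain_masks(mesh: Mesh2D, geom: InterstitialGeometry, spacer: float):
    """Boolean cell masks of the tracked nonenzymatic domains, left to right."""
    ny, nx = mesh.shape
    x = (np.arange(nx) + 0.5) * geom.dx
    y = (np.arange(ny) + 0.5) * geom.dy
    band = (y > geom.standoff) & (y < geom.height - geom.standoff)
    masks = []
    for x0, x1, label in _domain_edges(geom, spacer):
        if label != "sensor_nonenzymatic":
            continue
        cols = (x > x0) & (x < x1)
        masks.append(band[:, None] & cols[None, :])
    return masks


def run_invivo(
    mesh: Mesh2D,
    geom: InterstitialGeometry,
    spacer: float,
    sinks: TissueSinks = TissueSinks(),
    kinetics: KineticParams | None = None,
    transport: TransportParams | None = None,
    duration_s: float = 3600.0,
    waveform=None,
    dt: float = 2.0,
    cadence_s: float = 60.0,
):
    """Advance the interstitial model, tracking nonenzymatic-domain glucose.

    ``waveform(t_s)`` gives the capillary glucose Pw at time t (defaults to
    the constant ``sinks.Pw``).  Returns ``(trace, solver)`` where ``trace``
    is a tidy DataFrame (time_min, domain, mean_G).
    """
    solver = RDSolver(
        mesh,
        transport=transport,
        kinetics=kinetics,
        sink_G=sinks.RG,
        sink_O2=sinks.RO2,
        dt=dt,
        init={"G": sinks.Pw, "O2": sinks.CO2},
    )
    masks = nonenzymatic_domain_masks(mesh, geom, spacer)
    rows = []
    probe_every = max(1, int(round(cadence_s / dt)))

    capillary_edges = [e for e, v in mesh.bc.items() if v[0] == "dirichlet"]

    def probe(s):
        if waveform is not None:
            pw = float(waveform(s.t))
            for e in capillary_edges:
                s.set_boundary_value(e, "G", pw)
        for d, m in enumerate(masks):
            rows.append({"time_min": s.t / 60.0, "domain": d + 1, "mean_G": s.state.G[m].mean()})

    if waveform is not None:
        pw0 = float(waveform(0.0))
        for e in capillary_edges:
            solver.set_boundary_value(e, "G", pw0)
    solver.run(duration_s, probe=probe, probe_every=probe_every)
    return pd.DataFrame(rows), solver


def steady_domain_means(
    geom: InterstitialGeometry,
    spacer: float,
    sinks: TissueSinks = TissueSinks(),
    kinetics: KineticParams | None = None,
    transport: TransportParams | None = None,
) -> np.ndarray:
    """Steady-state mean glucose in each nonenzymatic domain (left to right)."""
    mesh = build_interstitial_mesh(geom, spacer, sinks)
    G, _, _ = steady_state(
        mesh,
        transport=transport,
        kinetics=kinetics,
        sink_G=sinks.RG,
        sink_O2=sinks.RO2,
    )
    masks = nonenzymatic_domain_masks(mesh, geom, spacer)
    return np.array([G[m].mean() for m in masks])


def crosstalk_metric(means_s1, means_s2):
    """Per-domain percent difference of domain-mean glucose, s1 vs s2.

    ``100 * (C_s1 - C_s2) / C_s2`` per nonenzymatic domain, plus the maximum
    absolute value.  Raises on zero reference concentration.
    """
    a = np.asarray(means_s1, dtype=float)
    b = np.asarray(means_s2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("domain count mismatch between the two runs")
    if np.any(b <= 0):
        raise ValueError("zero reference concentration: percent difference undefined")
    pct = 100.0 * (a - b) / b
    return pct, float(np.max(np.abs(pct)))


def spacer_crosstalk_study(
    spacer_large: float = 1.0,
    spacer_small: float = 0.01,
    geom: InterstitialGeometry = InterstitialGeometry(),
    sinks: TissueSinks = TissueSinks(),
    kinetics: KineticParams | None = None,
    transport: TransportParams | None = None,
):
    """Steady-state glucose crosstalk between the extreme spacer widths.

    Returns a DataFrame (domain, mean_G at each spacer, percent difference)
    and the maximum absolute percent difference.
    """
    m_large = steady_domain_means(geom, spacer_large, sinks, kinetics, transport)
    m_small = steady_domain_means(geom, spacer_small, sinks, kinetics, transport)
    pct, max_abs = crosstalk_metric(m_large, m_small)
    table = pd.DataFrame(
        {
            "domain": np.arange(1, len(pct) + 1),
            f"mean_G_spacer_{spacer_large}mm": m_large,
            f"mean_G_spacer_{spacer_small}mm": m_small,
            "percent_difference": pct,
        }
    )
    return table, max_abs
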