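"""Geometry-design experiments on the Monte Carlo optical model.

Drives the four optical design questions for the insertable barcode sensor:

* :func:`compare_designs` - total luminescent output of the candidate
  designs at the centered placement, with pairwise ratios;
* :func:`offset_sensitivity` - relative luminescent intensity under X/Y
  lateral displacement and Z depth changes of the sensor w.r.t. the source;
* :func:`compute_fwhm` + :func:`select_length` - beam full-width at half
  maximum at the target depth, which sets the ideal sensor length;
* :func:`unit_convergence` - per-assay luminescence vs. repeating-unit
  thickness at worst-case offsets, which sets the unit size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Placement, SensorDesign, VoxelScene, build_design, rasterize, tissue_scene
from .optics import LEDSource, default_optical_properties, propagate, run_luminescence

__all__ = [
    "MCSettings",
    "SweepSpec",
    "ConvergenceSpec",
    "AnalysisError",
    "luminescence_of",
    "compare_designs",
    "offset_sensitivity",
    "compute_fwhm",
    "unit_convergence",
    "select_length",
]


class AnalysisError(ValueError):
    """A profile or sweep cannot be analyzed as requested."""


@dataclass(frozen=True)
class MCSettings:
    """Photon budgets and seed policy shared by the study drivers."""

    n_photons: int = 100_000
    n_emission: int = 100_000
    repeats: int = 3
    seed: int = 0
    source: LEDSource = LEDSource()

    def run_seed(self, *tags: int) -> tuple[int, int]:
        """Deterministic (excitation, emission) seeds for a tagged run."""
        ss = np.random.SeedSequence([self.seed, *[int(t) & 0x7FFFFFFF for t in tags]])
        s = ss.generate_state(2, dtype=np.uint64) & np.uint64(2**63 - 1)
        return int(s[0]), int(s[1])


@dataclass(frozen=True)
class SweepSpec:
    """Offset grids of the displacement-sensitivity experiment."""

    x_offsets: tuple = (-5.0, -3.0, 0.0, 3.0, 5.0)
    y_offsets: tuple = (-5.0, -3.0, 0.0, 3.0, 5.0)
    z_offsets: tuple = (1.25, 2.0, 2.75)
    base_depth: float = 2.0
    settings: MCSettings = MCSettings()


@dataclass(frozen=True)
class ConvergenceSpec:
    """Repeating-unit-count sweep at fixed total length and +-5 mm offsets."""

    counts_per_assay: tuple = (1, 3, 5, 7, 9, 11, 13, 15)
    total_length: float = 6.5
    offsets: tuple = (("x", -5.0), ("x", 5.0), ("y", -5.0), ("y", 5.0))
    depth: float = 2.0
    threshold: float = 0.05
    design_id: str = "stacked_cylinder"
    settings: MCSettings = MCSettings()

    def __post_init__(self):
        c = self.counts_per_assay
        if any(n % 2 == 0 for n in c) or list(c) != sorted(c):
            raise ValueError("counts_per_assay must be odd and increasing")
        if not 0.0 < self.threshold:
            raise ValueError("threshold must be positive")


def luminescence_of(
    design: SensorDesign,
    placement: Placement,
    scene: VoxelScene,
    settings: MCSettings,
    props: dict | None = None,
    tags: tuple = (0,),
) -> pd.DataFrame:
    """Replicated two-stage luminescence of one placed design.

    Returns one row per replicate with per-assay and total top-surface
    emission weight.
    """
    if props is None:
        props = default_optical_properties()
    placed = rasterize(design, placement, scene)
    rows = []
    for rep in range(settings.repeats):
        s_ex, s_em = settings.run_seed(*tags, rep)
        ex = propagate(placed, props, settings.source, settings.n_photons, s_ex)
        em = run_luminescence(ex, placed, props, settings.n_emission, s_em)
        rows.append(
            {
                "replicate": rep,
                "assay1": em.per_assay_luminescence["assay1"],
                "assay2": em.per_assay_luminescence["assay2"],
                "total": em.total_luminescence,
                "seed_ex": s_ex,
                "seed_em": s_em,
            }
        )
    return pd.DataFrame(rows)


def compare_designs(
    designs: dict,
    placement: Placement = Placement(0.0, 0.0, 2.0),
    settings: MCSettings = MCSettings(),
    scene: VoxelScene | None = None,
    props: dict | None = None,
):
    """Total luminescence of each design at one placement, with pairwise ratios.

    Returns ``(summary, ratios)``: a per-design DataFrame (mean, sd over
    replicates) ranked by output, and a DataFrame of pairwise ratios with
    the propagated standard error of the ratio of replicate means.
    """
    if len(designs) < 2:
        raise ValueError("need at least two designs to compare")
    if scene is None:
        scene = tissue_scene()
    rows = []
    for k, (name, design) in enumerate(designs.items()):
        df = luminescence_of(design, placement, scene, settings, props, tags=(k,))
        sem = df["total"].std(ddof=1) / np.sqrt(len(df)) if len(df) > 1 else 0.0
        rows.append(
            {
                "design": name,
                "mean_total": df["total"].mean(),
                "sd_total": df["total"].std(ddof=1) if len(df) > 1 else 0.0,
                "sem_total": sem,
                "mean_assay1": df["assay1"].mean(),
                "mean_assay2": df["assay2"].mean(),
            }
        )
    summary = pd.DataFrame(rows).sort_values("mean_total", ascending=False, ignore_index=True)
    ratio_rows = []
    for i, a in summary.iterrows():
        for j, b in summary.iterrows():
            if i == j:
                continue
            r = a["mean_total"] / b["mean_total"]
            rel = np.sqrt(
                (a["sem_total"] / max(a["mean_total"], 1e-300)) ** 2
                + (b["sem_total"] / max(b["mean_total"], 1e-300)) ** 2
            )
            ratio_rows.append(
                {
                    "numerator": a["design"],
                    "denominator": b["design"],
                    "ratio": r,
                    "ratio_se": r * rel,
                }
            )
    return summary, pd.DataFrame(ratio_rows)


def offset_sensitivity(
    designs: dict,
    sweep: SweepSpec = SweepSpec(),
    scene: VoxelScene | None = None,
    props: dict | None = None,
) -> pd.DataFrame:
    """Relative luminescent intensity over the X/Y/Z offset grids.

    For each design and axis, intensities are normalized to that design's
    maximum over the axis (so the best placement reads exactly 1).  Per-assay
    columns are carried for the X-axis asymmetry analysis.  Returns a tidy
    DataFrame (design, axis, offset, totals, per-assay, relatives).
    """
    if scene is None:
        scene = tissue_scene()
    settings = sweep.settings
    axes = [("x", sweep.x_offsets), ("y", sweep.y_offsets), ("z", sweep.z_offsets)]
    rows = []
    for k, (name, design) in enumerate(designs.items()):
        for a, (axis, offsets) in enumerate(axes):
            for o, off in enumerate(offsets):
                if axis == "x":
                    pl = Placement(off, 0.0, sweep.base_depth)
                elif axis == "y":
                    pl = Placement(0.0, off, sweep.base_depth)
                else:
                    pl = Placement(0.0, 0.0, off)
                df = luminescence_of(design, pl, scene, settings, props, tags=(k, a, o))
                rows.append(
                    {
                        "design": name,
                        "axis": axis,
                        "offset": off,
                        "total": df["total"].mean(),
                        "sd": df["total"].std(ddof=1) if len(df) > 1 else 0.0,
                        "assay1": df["assay1"].mean(),
                        "assay2": df["assay2"].mean(),
                    }
                )
    out = pd.DataFrame(rows)
    out["relative"] = out.groupby(["design", "axis"])["total"].transform(lambda s: s / s.max())
    for col in ("assay1", "assay2"):
        out[f"relative_{col}"] = out.groupby(["design", "axis"])[col].transform(
            lambda s: s / s.max()
        )
    return out


def compute_fwhm(coords, profile, merge_gap: int = 2) -> float:
    """Full width at half maximum of a single-peaked sampled profile (mm).

    Linear interpolation at half of the peak value.  Raises
    :class:`AnalysisError` for flat or multi-modal profiles (more than one
    above-half region after merging sub-``merge_gap``-sample noise gaps).
    """
    x = np.asarray(coords, dtype=float)
    y = np.asarray(profile, dtype=float)
    if x.shape != y.shape or y.size < 3:
        raise ValueError("coords and profile must be same-length 1-D arrays")
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise AnalysisError("flat profile has no FWHM")
    half = hi / 2.0
    idx = np.where(y >= half)[0]
    regions = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > merge_gap + 1:
            regions.append((start, prev))
            start = i
        prev = i
    regions.append((start, prev))
    if len(regions) > 1:
        raise AnalysisError(f"profile is multi-modal ({len(regions)} above-half regions)")
    i0, i1 = regions[0]
    if i0 == 0:
        xl = x[0]
    else:
        y0, y1 = y[i0 - 1], y[i0]
        xl = x[i0 - 1] + (half - y0) / (y1 - y0) * (x[i0] - x[i0 - 1])
    if i1 == y.size - 1:
        xr = x[-1]
    else:
        y0, y1 = y[i1], y[i1 + 1]
        xr = x[i1] + (y0 - half) / (y0 - y1) * (x[i1 + 1] - x[i1])
    return float(xr - xl)


def select_length(fwhm: float, unit_thickness: float):
    """Ideal sensor length and number of sensing domains.

    The length equals the excitation-beam FWHM at the target depth; the
    domain count is the nearest integer number of repeating units fitting it.
    """
    if fwhm <= 0 or unit_thickness <= 0:
        raise ValueError("fwhm and unit_thickness must be > 0")
    if unit_thickness > fwhm:
        raise ValueError("unit_thickness exceeds the selected length")
    return float(fwhm), int(round(fwhm / unit_thickness))


def unit_convergence(
    spec: ConvergenceSpec = ConvergenceSpec(),
    scene: VoxelScene | None = None,
    props: dict | None = None,
):
    """Per-assay luminescence vs. repeating-unit thickness at worst-case offsets.

    Returns ``(table, selected_thickness, warning)``.  The selected thickness
    is the largest tested thickness whose per-assay outputs change by less
    than ``spec.threshold`` (relative) to the next-finer subdivision at every
    tested offset; if none qualifies, the finest tested thickness is
    returned with ``warning = True``.
    """
    if scene is None:
        scene = tissue_scene()
    settings = spec.settings
    rows = []
    for c_i, count in enumerate(spec.counts_per_assay):
        design = build_design(spec.design_id, spec.total_length, n_units_per_assay=count)
        for o_i, (axis, off) in enumerate(spec.offsets):
            pl = (
                Placement(off, 0.0, spec.depth)
                if axis == "x"
                else Placement(0.0, off, spec.depth)
            )
            df = luminescence_of(design, pl, scene, settings, props, tags=(100 + c_i, o_i))
            rows.append(
                {
                    "count_per_assay": count,
                    "unit_thickness": spec.total_length / (2 * count),
                    "axis": axis,
                    "offset": off,
                    "assay1": df["assay1"].mean(),
                    "assay2": df["assay2"].mean(),
                }
            )
    table = pd.DataFrame(rows)
    counts = list(spec.counts_per_assay)
    selected = None
    for k in range(len(counts) - 1):
        coarse = table[table.count_per_assay == counts[k]]
        fine = table[table.count_per_assay == counts[k + 1]]
        ok = True
        for (axis, off) in spec.offsets:
            a = coarse[(coarse.axis == axis) & (coarse.offset == off)].iloc[0]
            b = fine[(fine.axis == axis) & (fine.offset == off)].iloc[0]
            for col in ("assay1", "assay2"):
                ref = max(abs(b[col]), 1e-300)
                if abs(a[col] - b[col]) / ref >= spec.threshold:
                    ok = False
        if ok:
            selected = spec.total_length / (2 * counts[k])
            break
    warning = selected is None
    if warning:
        selected = spec.total_length / (2 * counts[-1])
    return table, float(selected), warning
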