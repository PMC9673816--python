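"""Seed-deterministic generators for protocol waveforms and test scenes.

Everything the experiments consume is configuration, not data: glucose
concentration protocols for the flow cell, a configurable capillary glucose
waveform for the interstitial model (the physiological meal-like excursion
is a synthetic stand-in, since only its qualitative shape is specified),
and small voxel scenes with analytically known optical behavior for the
Monte Carlo oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowcell import GlucoseProtocol
from .geometry import (
    MEDIA,
    Placement,
    VoxelScene,
    build_design,
    rasterize,
    tissue_scene,
)

__all__ = [
    "ProtocolSpec",
    "make_protocol",
    "waveform_fn",
    "save_waveform",
    "make_test_scene",
]

GLUCOSE_LEVELS_DEFAULT = (0.0, 2.78, 5.55, 8.34, 11.1)


@dataclass(frozen=True)
class ProtocolSpec:
    """Specification of a glucose input signal.

    ``kind``: ``step_ladder`` (ordered holds), ``constant`` or
    ``meal_excursion`` (piecewise-linear unimodal rise/fall).  ``noise_sd``
    adds Gaussian noise (clipped at 0) to sampled waveforms.
    """

    kind: str = "step_ladder"
    levels: tuple = GLUCOSE_LEVELS_DEFAULT
    durations_min: tuple = (45.0,) * 5
    baseline: float = 2.78
    peak: float = 11.1
    rise_min: float = 30.0
    fall_min: float = 60.0
    total_min: float = 180.0
    sample_min: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    max_level: float = 11.1

    def __post_init__(self):
        vals = list(self.levels) + [self.baseline, self.peak]
        if any(v < 0 or v > self.max_level for v in vals):
            raise ValueError(f"glucose levels must lie in [0, {self.max_level}] mol/m^3")
        if any(d <= 0 for d in self.durations_min):
            raise ValueError("durations must be > 0")


def make_protocol(spec: ProtocolSpec = ProtocolSpec()):
    """Build the input described by ``spec``.

    ``step_ladder`` returns a :class:`glucolux.flowcell.GlucoseProtocol`;
    ``constant`` and ``meal_excursion`` return sampled waveform arrays
    ``(t_min, conc)``; generation is deterministic given ``spec.seed``.
    """
    if spec.kind == "step_ladder":
        if len(spec.levels) != len(spec.durations_min):
            raise ValueError("levels and durations must have equal length")
        return GlucoseProtocol(tuple(zip(spec.levels, spec.durations_min)))
    t = np.arange(0.0, spec.total_min + spec.sample_min / 2, spec.sample_min)
    if spec.kind == "constant":
        c = np.full_like(t, spec.baseline)
    elif spec.kind == "meal_excursion":
        t_peak = spec.rise_min
        t_back = spec.rise_min + spec.fall_min
        c = np.interp(
            t,
            [0.0, t_peak, t_back, spec.total_min],
            [spec.baseline, spec.peak, spec.baseline, spec.baseline],
        )
    else:
        raise ValueError(f"unknown protocol kind {spec.kind!r}")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        c = np.clip(c + rng.normal(0.0, spec.noise_sd, c.shape), 0.0, None)
    return t, c


def waveform_fn(t_min: np.ndarray, conc: np.ndarray):
    """Interpolating Pw(t) callable (t in seconds) over a sampled waveform."""
    t_min = np.asarray(t_min, dtype=float)
    conc = np.asarray(conc, dtype=float)

    def pw(t_s: float) -> float:
        return float(np.interp(t_s / 60.0, t_min, conc))

    return pw


def save_waveform(path, t_min, conc) -> None:
    """Two-column tabular file: time (min), concentration (mol/m^3)."""
    pd.DataFrame({"time_min": t_min, "conc_mol_per_m3": conc}).to_csv(path, index=False)


def make_test_scene(kind: str, **kw) -> VoxelScene:
    """Small labeled scenes with analytically known optical behavior.

    * ``homogeneous_slab`` - uniformly dermis-labeled block (pair with
      custom optical properties, e.g. for absorption-only comparisons);
    * ``point_emitter`` - transparent hydrogel block with a single assay1
      voxel at ``depth_mm`` under the center (half-space escape checks);
    * ``two_compartment_sensor`` - small skin block with a mirror-symmetric
      two-compartment barcode at its center (symmetry checks).
    """
    voxel = kw.get("voxel_mm", 0.05)
    if kind == "homogeneous_slab":
        shape = kw.get("shape", (80, 80, 60))
        labels = np.full(shape, MEDIA["dermis"], dtype=np.uint8)
        return VoxelScene(labels, voxel, (voxel / 2, voxel))
    if kind == "point_emitter":
        shape = kw.get("shape", (80, 80, 60))
        depth = kw.get("depth_mm", 1.0)
        labels = np.full(shape, MEDIA["hydrogel"], dtype=np.uint8)
        iz = int(depth / voxel)
        labels[shape[0] // 2, shape[1] // 2, iz] = MEDIA["assay1"]
        return VoxelScene(labels, voxel, (voxel / 2, voxel))
    if kind == "two_compartment_sensor":
        extent = kw.get("extent_mm", (8.0, 8.0, 4.0))
        scene = tissue_scene(extent_mm=extent, voxel_mm=voxel)
        design = build_design("rect_barcode", kw.get("length_mm", 2.0), n_units_per_assay=1)
        return rasterize(design, Placement(0.0, 0.0, kw.get("depth_mm", 2.0)), scene)
    raise ValueError(f"unknown test scene kind {kind!r}")
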