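"""Voxel Monte Carlo transport of excitation and luminescent emission photons.

Two-stage (two-pass) luminescence simulation:

1. :func:`propagate` launches 680-nm photons from an LED-like source (1.75-mm
   square top-hat near field, Lambertian far field) at the tissue surface and
   tallies absorbed energy per voxel plus top-surface escape.
2. :func:`run_luminescence` re-samples the absorbed-energy distribution in
   the sensing-assay voxels (weighted by quantum yield), launches isotropic
   800-nm emission photons from those voxels, and scores the emission weight
   that reaches the top surface, attributed to the source assay.

All media are refractive-index matched (n = 1), so there are no Fresnel
events; lateral and bottom boundaries absorb.  The absorption and scattering
coefficients are stored in cm^-1 (the conventional tissue-optics unit) and
converted to mm^-1 internally to match the voxel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _mc
from .geometry import MEDIA, VoxelScene

__all__ = [
    "OpticalProperties",
    "LEDSource",
    "MCResult",
    "default_optical_properties",
    "media_arrays",
    "sample_scatter",
    "propagate",
    "run_luminescence",
    "excitation_fluence_profile",
]

#: MCML-standard Russian-roulette settings.
ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class OpticalProperties:
    """Per-medium optical properties at the excitation and emission bands.

    ``mua``/``mus`` are (excitation, emission) pairs in cm^-1; ``g`` is the
    Henyey-Greenstein anisotropy; ``n`` is the refractive index (1 for all
    media here); ``quantum_yield`` converts absorbed excitation into emitted
    luminescence.
    """

    mua: tuple
    mus: tuple
    g: float
    n: float = 1.0
    quantum_yield: float = 0.0

    def __post_init__(self):
        if min(self.mua) < 0 or min(self.mus) < 0:
            raise ValueError("mua and mus must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy must satisfy -1 < g < 1")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum_yield must be in [0, 1]")


def default_optical_properties() -> dict:
    """Skin/sensor optical properties at 680 nm (excitation) / 800 nm (emission).

    The hypodermis is assigned dermis values (its properties are close to
    dermis at these wavelengths and the sensing depth of interest lies near
    the dermal/subcutaneous junction); this is a documented assumption.
    """
    dermis = OpticalProperties(mua=(0.48, 0.30), mus=(195.3, 140.8), g=0.9)
    return {
        "epidermis": OpticalProperties(mua=(0.78, 0.46), mus=(294.1, 250.0), g=0.9),
        "dermis": dermis,
        "hypodermis": dermis,
        "hydrogel": OpticalProperties(mua=(1e-6, 1e-6), mus=(5e-4, 5e-4), g=0.75),
        "assay1": OpticalProperties(
            mua=(5.0, 1e-6), mus=(1e-6, 1e-6), g=0.75, quantum_yield=1.0
        ),
        "assay2": OpticalProperties(
            mua=(5.0, 1e-6), mus=(1e-6, 1e-6), g=0.75, quantum_yield=1.0
        ),
    }


@dataclass(frozen=True)
class LEDSource:
    """Square LED at the surface origin: top-hat near field, Lambertian far field.

    ``collimated=True`` replaces the Lambertian angular distribution with
    normal incidence (used by analytic-oracle fixtures, e.g. Beer-Lambert).
    """

    side_length: float = 1.75  # mm
    wavelength: float = 680.0  # nm
    collimated: bool = False


@dataclass
class MCResult:
    """Tallies of one Monte Carlo run (all weights per launched photon = 1)."""

    absorbed: np.ndarray
    surface_escape: np.ndarray
    escaped_top: float
    escaped_other: float
    roulette_net: float
    absorbed_total: float
    n_photons: int
    seed: int
    wavelength: str
    per_assay_luminescence: dict = field(default_factory=dict)
    emitted_total: float = 0.0
    layer_fluence: np.ndarray | None = None
    fluence_depth_mm: float | None = None
    voxel_mm: float = 0.05

    @property
    def launched(self) -> float:
        return float(self.n_photons)

    @property
    def total_luminescence(self) -> float:
        return float(sum(self.per_assay_luminescence.values()))

    def energy_balance(self) -> float:
        """Relative ledger residual; ~0 up to float accumulation error."""
        out = self.absorbed_total + self.escaped_top + self.escaped_other + self.roulette_net
        return abs(self.launched - out) / max(self.launched, 1.0)


def media_arrays(props: dict, stage: str):
    """(mua, mus, g) arrays in mm^-1 indexed by medium code, for one stage."""
    idx = 0 if stage in ("excitation", "ex") else 1
    n = max(MEDIA.values()) + 1
    mua = np.zeros(n)
    mus = np.zeros(n)
    g = np.zeros(n)
    for name, code in MEDIA.items():
        p = props[name]
        mua[code] = p.mua[idx] / 10.0  # cm^-1 -> mm^-1
        mus[code] = p.mus[idx] / 10.0
        g[code] = p.g
    return mua, mus, g


def sample_scatter(g: float, u):
    """Henyey-Greenstein inverse-CDF: cos(theta) for uniform deviate(s) ``u``.

    Isotropic limit at g = 0; E[cos theta] = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("|g| must be < 1")
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-6:
        out = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    return out[()] if out.ndim == 0 else out


def _check_scene(scene: VoxelScene, props: dict):
    codes = np.unique(scene.labels)
    known = set(MEDIA.values())
    bad = [c for c in codes if int(c) not in known]
    if bad:
        raise ValueError(f"scene contains unlabeled media codes {bad}")


def propagate(
    scene: VoxelScene,
    props: dict | None = None,
    source: LEDSource = LEDSource(),
    n_photons: int = 100_000,
    seed: int = 0,
    wavelength: str = "excitation",
    fluence_depth_mm: float | None = None,
) -> MCResult:
    """Excitation-stage transport from the surface LED.

    ``fluence_depth_mm`` optionally enables a track-length fluence tally in
    the 0.05-mm voxel layer containing that depth.
    """
    if props is None:
        props = default_optical_properties()
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    _check_scene(scene, props)
    mua, mus, g = media_arrays(props, wavelength)
    nx, ny, nz = scene.shape
    absorbed = np.zeros((nx, ny, nz))
    surface = np.zeros((nx, ny))
    layer_fluence = np.zeros((nx, ny))
    layer_iz = -1
    if fluence_depth_mm is not None:
        layer_iz = int(fluence_depth_mm / scene.voxel_mm)
        if not 0 <= layer_iz < nz:
            raise IndexError(f"depth {fluence_depth_mm} mm outside the grid")
    escape_by_tag = np.zeros(8)
    totals = np.zeros(4)
    empty_f = np.zeros(0)
    empty_i = np.zeros(0, dtype=np.int32)
    _mc.transport(
        scene.labels, scene.voxel_mm, mua, mus, g,
        int(n_photons), np.uint64(seed) & np.uint64(2**63 - 1),
        0, source.side_length / 2.0, 1 if source.collimated else 0,
        empty_f, empty_i, empty_i, empty_i,
        absorbed, surface, layer_iz, layer_fluence,
        escape_by_tag, totals,
        ROULETTE_WEIGHT, ROULETTE_SURVIVAL,
    )
    if not np.isfinite(totals).all():
        raise FloatingPointError("non-finite Monte Carlo tally")
    return MCResult(
        absorbed=absorbed,
        surface_escape=surface,
        escaped_top=totals[0],
        escaped_other=totals[1],
        roulette_net=totals[2],
        absorbed_total=totals[3],
        n_photons=int(n_photons),
        seed=int(seed),
        wavelength=wavelength,
        layer_fluence=layer_fluence if layer_iz >= 0 else None,
        fluence_depth_mm=fluence_depth_mm,
        voxel_mm=scene.voxel_mm,
    )


def run_luminescence(
    excitation: MCResult,
    scene: VoxelScene,
    props: dict | None = None,
    n_photons: int = 100_000,
    seed: int = 1,
) -> MCResult:
    """Emission-stage transport from the excited assay voxels.

    Emission sources are drawn with probability proportional to absorbed
    excitation weight times quantum yield; each launched photon represents
    ``emitted_total / n_photons`` of luminescent energy.  The per-assay
    outputs in the result are already scaled to that energy.
    """
    if props is None:
        props = default_optical_properties()
    _check_scene(scene, props)
    qy = np.zeros(max(MEDIA.values()) + 1)
    for name, code in MEDIA.items():
        qy[code] = props[name].quantum_yield
    weights = excitation.absorbed * qy[scene.labels]
    src = np.argwhere(weights > 0)
    wsel = weights[weights > 0]
    emitted_total = float(wsel.sum())
    nx, ny, nz = scene.shape
    if emitted_total <= 0.0:
        warnings.warn("no absorbed excitation energy in luminescent voxels; zero output")
        return MCResult(
            absorbed=np.zeros((nx, ny, nz)),
            surface_escape=np.zeros((nx, ny)),
            escaped_top=0.0, escaped_other=0.0, roulette_net=0.0,
            absorbed_total=0.0, n_photons=0, seed=int(seed),
            wavelength="emission",
            per_assay_luminescence={"assay1": 0.0, "assay2": 0.0},
            emitted_total=0.0, voxel_mm=scene.voxel_mm,
        )
    cdf = np.cumsum(wsel)
    cdf /= cdf[-1]
    mua, mus, g = media_arrays(props, "emission")
    absorbed = np.zeros((nx, ny, nz))
    surface = np.zeros((nx, ny))
    layer_fluence = np.zeros((nx, ny))
    escape_by_tag = np.zeros(8)
    totals = np.zeros(4)
    _mc.transport(
        scene.labels, scene.voxel_mm, mua, mus, g,
        int(n_photons), np.uint64(seed) & np.uint64(2**63 - 1),
        1, 0.0, 0,
        cdf,
        src[:, 0].astype(np.int32), src[:, 1].astype(np.int32), src[:, 2].astype(np.int32),
        absorbed, surface, -1, layer_fluence,
        escape_by_tag, totals,
        ROULETTE_WEIGHT, ROULETTE_SURVIVAL,
    )
    scale = emitted_total / n_photons
    per_assay = {
        "assay1": float(escape_by_tag[MEDIA["assay1"]]) * scale,
        "assay2": float(escape_by_tag[MEDIA["assay2"]]) * scale,
    }
    return MCResult(
        absorbed=absorbed,
        surface_escape=surface * scale,
        escaped_top=totals[0],
        escaped_other=totals[1],
        roulette_net=totals[2],
        absorbed_total=totals[3],
        n_photons=int(n_photons),
        seed=int(seed),
        wavelength="emission",
        per_assay_luminescence=per_assay,
        emitted_total=emitted_total,
        voxel_mm=scene.voxel_mm,
    )


def excitation_fluence_profile(
    result: MCResult,
    depth_mm: float,
    axis: str = "x",
    strip_halfwidth_mm: float = 0.25,
):
    """Normalized lateral fluence profile at the given depth.

    Uses the track-length tally of the voxel layer at ``depth_mm`` (the run
    must have been made with ``fluence_depth_mm`` at the same depth),
    averaged over a thin central strip of the transverse axis.  Returns
    ``(coords_mm, profile)`` with the profile normalized to unit peak.
    """
    if result.layer_fluence is None:
        raise ValueError("run propagate() with fluence_depth_mm to tally a profile")
    if result.fluence_depth_mm is None or int(depth_mm / result.voxel_mm) != int(
        result.fluence_depth_mm / result.voxel_mm
    ):
        raise IndexError("requested depth does not match the tallied layer")
    f = result.layer_fluence
    nx, ny = f.shape
    h = result.voxel_mm
    half = max(1, int(round(strip_halfwidth_mm / h)))
    if axis == "x":
        c0 = ny // 2
        prof = f[:, c0 - half : c0 + half].mean(axis=1)
        coords = (np.arange(nx) + 0.5) * h - nx * h / 2.0
    elif axis == "y":
        c0 = nx // 2
        prof = f[c0 - half : c0 + half, :].mean(axis=0)
        coords = (np.arange(ny) + 0.5) * h - ny * h / 2.0
    else:
        raise ValueError("axis must be 'x' or 'y'")
    peak = prof.max()
    if peak <= 0:
        raise ValueError("empty fluence profile")
    return coords, prof / peak
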