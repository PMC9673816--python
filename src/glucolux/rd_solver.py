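"""2-D finite-volume advection-diffusion-reaction solver for sensor chemistry.

Glucose and O2 are transported by diffusion (region-wise coefficients,
harmonic-mean interface conductances, concentration and flux continuity at
interfaces) and, in the flow channel, by advection along an analytic
flux-conserving parabolic (plane-Poiseuille) profile; the immobile GOx
network of :mod:`glucolux.kinetics` reacts locally in the enzymatic cells,
and background tissue consumes both species through zeroth-order sinks
clamped at zero concentration.

Time integration is operator-split per step: (1) implicit (backward-Euler)
transport of G and O2 via a prefactorized sparse LU, (2) clamped tissue
sinks, (3) an L-stable backward-Euler update of the full six-species
reaction network, solved per cell by a vectorized damped Newton iteration.
The split is first-order in dt, which resolves the minutes-scale sensor
dynamics at the default sub-second steps; a nonlinear Picard solver is also
provided for steady states (used by the interstitial crosstalk study).

Geometry units are meters internally; the mesh builders accept mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import kinetics as kin
from .kinetics import KineticParams, SpeciesState, SternVolmerParams

__all__ = [
    "REGIONS",
    "TransportParams",
    "Mesh2D",
    "FlowField",
    "build_flowcell_mesh",
    "poiseuille_flow",
    "transport_operator",
    "RDSolver",
    "steady_state",
    "SolverError",
]


class SolverError(RuntimeError):
    """Implicit solve or Newton iteration failed to converge."""


#: Region label codes of the structured mesh.
REGIONS = {
    "channel": 0,
    "sensor_enzymatic": 1,
    "sensor_nonenzymatic": 2,
    "spacer": 3,
    "tissue": 4,
}

#: Regularization scale (mol/m^3) below which zeroth-order sinks ramp to zero.
SINK_EPS = 1e-3


@dataclass(frozen=True)
class TransportParams:
    """Diffusion coefficients (m^2/s) per region code.

    Sensor regions (enzymatic, nonenzymatic, spacer) use the sensing-hydrogel
    values; channel and tissue use the subcutaneous-space values (transport
    in the channel is advection-dominated, so its diffusivity is not
    critical).
    """

    DG: tuple = (2.64e-10, 4.0e-10, 4.0e-10, 4.0e-10, 2.64e-10)
    DO2: tuple = (1.5e-9, 2.45e-9, 2.45e-9, 2.45e-9, 1.5e-9)

    def __post_init__(self):
        if min(self.DG) <= 0 or min(self.DO2) <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass
class Mesh2D:
    """Structured rectilinear cell-centered mesh.

    ``region[j, i]`` holds a :data:`REGIONS` code for the cell centered at
    ``x = (i + 1/2) dx``, ``y = (j + 1/2) dy`` (y upward from the bottom
    wall).  ``bc`` maps each edge (left/right/top/bottom) to
    ``("dirichlet", {"G": v, "O2": v})``, ``("zero_flux",)`` or
    ``("outflow",)``.
    """

    region: np.ndarray
    dx: float
    dy: float
    bc: dict

    @property
    def shape(self):
        return self.region.shape

    @property
    def n_cells(self):
        return self.region.size

    def cell_centers(self):
        ny, nx = self.region.shape
        x = (np.arange(nx) + 0.5) * self.dx
        y = (np.arange(ny) + 0.5) * self.dy
        return x, y

    def mask(self, name: str) -> np.ndarray:
        return self.region == REGIONS[name]


@dataclass
class FlowField:
    """Discretely divergence-free channel flow on cell faces (m/s).

    ``u_face[j, i]`` is the horizontal velocity on the vertical face between
    columns ``i-1`` and ``i`` (shape (ny, nx+1)); ``v_face[j, i]`` the
    vertical velocity on the horizontal face below row ``j`` (shape
    (ny+1, nx)), reconstructed from continuity.  ``u`` is the cell-centered
    horizontal velocity for inspection.  All face velocities vanish on solid
    (non-channel) cells.
    """

    u_face: np.ndarray
    v_face: np.ndarray
    u: np.ndarray
    mean_inflow: float


def build_flowcell_mesh(
    length_mm: float = 7.6,
    height_mm: float = 2.8,
    sensor_length_mm: float = 4.0,
    sensor_height_mm: float = 0.5,
    fillet_radius_mm: float = 0.1,
    dx_mm: float = 0.05,
    dy_mm: float = 0.05,
    inlet: dict | None = None,
) -> Mesh2D:
    """Vertical cross section of the bench flow cell.

    A ``length x height`` channel with the enzymatic sensor slab centered on
    the bottom wall; the sensor's upper corners are rounded by a
    quarter-disc fillet mask of the given radius (mimicking the cylindrical
    sensor's cross-section).  Inflow is a Dirichlet condition on the left
    edge, outflow on the right; walls are impermeable.
    """
    if sensor_length_mm > length_mm or sensor_height_mm >= height_mm:
        raise ValueError("sensor does not fit inside the channel")
    nx = int(round(length_mm / dx_mm))
    ny = int(round(height_mm / dy_mm))
    region = np.full((ny, nx), REGIONS["channel"], dtype=np.int8)
    x = (np.arange(nx) + 0.5) * dx_mm
    y = (np.arange(ny) + 0.5) * dy_mm
    xl = (length_mm - sensor_length_mm) / 2.0
    xr = xl + sensor_length_mm
    in_sensor = (x[None, :] > xl) & (x[None, :] < xr) & (y[:, None] < sensor_height_mm)
    r = fillet_radius_mm
    if r > 0:
        # carve the fillet out of the sensor's two upper corners
        cxl, cxr, cy = xl + r, xr - r, sensor_height_mm - r
        corner_l = (x[None, :] < cxl) & (y[:, None] > cy)
        corner_r = (x[None, :] > cxr) & (y[:, None] > cy)
        out_l = ((x[None, :] - cxl) ** 2 + (y[:, None] - cy) ** 2) > r**2
        out_r = ((x[None, :] - cxr) ** 2 + (y[:, None] - cy) ** 2) > r**2
        in_sensor &= ~(corner_l & out_l) & ~(corner_r & out_r)
    region[in_sensor] = REGIONS["sensor_enzymatic"]
    if inlet is None:
        inlet = {"G": 0.0, "O2": 0.009}
    bc = {
        "left": ("dirichlet", dict(inlet)),
        "right": ("outflow",),
        "top": ("zero_flux",),
        "bottom": ("zero_flux",),
    }
    return Mesh2D(region=region, dx=dx_mm * 1e-3, dy=dy_mm * 1e-3, bc=bc)


def poiseuille_flow(mesh: Mesh2D, mean_velocity: float = 0.009) -> FlowField:
    """Flux-conserving laminar profile over the open channel height.

    On each vertical face the open (channel on both sides, contiguous from
    the top wall) height carries a parabolic no-slip profile normalized so
    the face-integrated flux equals the inlet flux ``mean_velocity *
    full_height``; vertical face velocities follow from discrete continuity
    (so the field is exactly divergence-free cell by cell and the top-wall
    normal velocity closes to zero).
    """
    ny, nx = mesh.shape
    u_face = np.zeros((ny, nx + 1))
    v_face = np.zeros((ny + 1, nx))
    if mean_velocity == 0.0:
        return FlowField(u_face=u_face, v_face=v_face, u=np.zeros((ny, nx)), mean_inflow=0.0)
    channel = mesh.region == REGIONS["channel"]
    full_h = ny * mesh.dy
    flux = mean_velocity * full_h
    yc = (np.arange(ny) + 0.5) * mesh.dy
    for i in range(nx + 1):
        if i == 0:
            open_col = channel[:, 0]
        elif i == nx:
            open_col = channel[:, -1]
        else:
            open_col = channel[:, i - 1] & channel[:, i]
        # contiguous open run touching the top wall
        j = ny - 1
        while j >= 0 and open_col[j]:
            j -= 1
        j_bot = j + 1
        if j_bot >= ny:
            continue
        y0 = j_bot * mesh.dy
        h = full_h - y0
        s = (yc[j_bot:] - y0) / h
        prof = 6.0 * (flux / h) * s * (1.0 - s)
        prof *= flux / (prof.sum() * mesh.dy)  # exact discrete flux
        u_face[j_bot:, i] = prof
    # vertical velocities from continuity, integrated up from the bottom wall
    div_x = (u_face[:, 1:] - u_face[:, :-1]) / mesh.dx
    v_face[1:, :] = -np.cumsum(div_x, axis=0) * mesh.dy
    v_face[np.abs(v_face) < 1e-15] = 0.0
    u = 0.5 * (u_face[:, :-1] + u_face[:, 1:])
    return FlowField(u_face=u_face, v_face=v_face, u=u, mean_inflow=mean_velocity)


# ---------------------------------------------------------------------------
# discrete transport operator

def transport_operator(mesh: Mesh2D, D_region, flow: FlowField | None = None):
    """Sparse FV operator ``T`` with ``dc/dt = T c + sum_e w_e * value_e``.

    ``D_region`` is the per-region diffusivity for one species.  Returns
    ``(T, bweights)`` where ``bweights[edge]`` is the vector multiplying the
    Dirichlet value of that edge (empty for non-Dirichlet edges).  Advection
    is first-order upwind on channel-channel faces only.
    """
    ny, nx = mesh.shape
    N = ny * nx
    Dc = np.asarray(D_region, dtype=float)[mesh.region]
    idx = np.arange(N).reshape(ny, nx)
    dx, dy = mesh.dx, mesh.dy
    rows, cols, vals = [], [], []
    diag = np.zeros(N)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # x faces
    a = idx[:, :-1].ravel()
    b = idx[:, 1:].ravel()
    Da = Dc[:, :-1].ravel()
    Db = Dc[:, 1:].ravel()
    cf = (2.0 * Da * Db / (Da + Db)) / dx**2
    add(a, b, cf)
    add(b, a, cf)
    np.add.at(diag, a, -cf)
    np.add.at(diag, b, -cf)
    if flow is not None:
        uf = flow.u_face[:, 1:-1].ravel()
        pos = uf > 0
        neg = uf < 0
        add(b[pos], a[pos], uf[pos] / dx)
        np.add.at(diag, a[pos], -uf[pos] / dx)
        add(a[neg], b[neg], -uf[neg] / dx)
        np.add.at(diag, b[neg], uf[neg] / dx)

    # y faces
    a = idx[:-1, :].ravel()
    b = idx[1:, :].ravel()
    Da = Dc[:-1, :].ravel()
    Db = Dc[1:, :].ravel()
    cf = (2.0 * Da * Db / (Da + Db)) / dy**2
    add(a, b, cf)
    add(b, a, cf)
    np.add.at(diag, a, -cf)
    np.add.at(diag, b, -cf)
    if flow is not None:
        vf = flow.v_face[1:-1, :].ravel()
        pos = vf > 0
        neg = vf < 0
        add(b[pos], a[pos], vf[pos] / dy)
        np.add.at(diag, a[pos], -vf[pos] / dy)
        add(a[neg], b[neg], -vf[neg] / dy)
        np.add.at(diag, b[neg], vf[neg] / dy)

    # boundaries
    edges = {
        "left": (idx[:, 0], Dc[:, 0], dx, flow.u_face[:, 0] if flow is not None else None),
        "right": (idx[:, -1], Dc[:, -1], dx, flow.u_face[:, -1] if flow is not None else None),
        "bottom": (idx[0, :], Dc[0, :], dy, None),
        "top": (idx[-1, :], Dc[-1, :], dy, None),
    }
    bweights = {}
    for edge, (cells, Dedge, d, uedge) in edges.items():
        kind = mesh.bc[edge][0]
        if kind == "dirichlet":
            coef = 2.0 * Dedge / d**2
            diag[cells] -= coef
            # advective inflow feeds the source vector only: the inflow face
            # carries no outgoing advective flux from the cell
            w = np.zeros(N)
            w[cells] = coef
            if uedge is not None and edge == "left":
                w[cells] += np.maximum(uedge, 0.0) / d
            bweights[edge] = w
        elif kind == "outflow":
            if uedge is not None and edge == "right":
                diag[cells] -= np.maximum(uedge, 0.0) / d
        elif kind != "zero_flux":
            raise ValueError(f"unknown boundary kind {kind!r} on {edge}")

    all_r = np.concatenate(rows + [np.arange(N)])
    all_c = np.concatenate(cols + [np.arange(N)])
    all_v = np.concatenate(vals + [diag])
    T = sp.coo_matrix((all_v, (all_r, all_c)), shape=(N, N)).tocsc()
    return T, bweights


def _bvec(bweights: dict, bc: dict, species: str, n: int) -> np.ndarray:
    b = np.zeros(n)
    for edge, w in bweights.items():
        b += w * bc[edge][1][species]
    return b


# ---------------------------------------------------------------------------
# time-dependent solver

class RDSolver:
    """Operator-split integrator of the coupled transport-reaction system.

    Parameters
    ----------
    mesh : Mesh2D
    transport : TransportParams
    kinetics : KineticParams
        ``Et`` applies in enzymatic cells only.
    flow : FlowField, optional
    sink_G, sink_O2 : float
        Zeroth-order tissue consumption magnitudes, mol m^-3 s^-1
        (positive = consumption; applied in tissue cells, clamped at zero).
    dt : float
        Split step in seconds.
    sv : SternVolmerParams
        Lifetime calibration used by :meth:`sensor_lifetime`.
    """

    def __init__(
        self,
        mesh: Mesh2D,
        transport: TransportParams | None = None,
        kinetics: KineticParams | None = None,
        flow: FlowField | None = None,
        sink_G: float = 0.0,
        sink_O2: float = 0.0,
        dt: float = 0.5,
        sv: SternVolmerParams | None = None,
        init: dict | None = None,
    ):
        self.mesh = mesh
        self.transport = transport or TransportParams()
        self.kin = kinetics or KineticParams()
        self.flow = flow
        self.sink_G = float(sink_G)
        self.sink_O2 = float(sink_O2)
        self.dt = float(dt)
        self.sv = sv or SternVolmerParams()
        self.t = 0.0

        ny, nx = mesh.shape
        N = ny * nx
        self._TG, self._bwG = transport_operator(mesh, self.transport.DG, flow)
        self._TO, self._bwO = transport_operator(mesh, self.transport.DO2, flow)
        I = sp.identity(N, format="csc")
        self._luG = splu((I - self.dt * self._TG).tocsc())
        self._luO = splu((I - self.dt * self._TO).tocsc())
        self._enz = mesh.mask("sensor_enzymatic")
        self._tissue = mesh.mask("tissue")

        init = init or {}
        G0 = float(init.get("G", 0.0))
        O20 = float(init.get("O2", 0.009))
        self.state = SpeciesState(
            G=np.full((ny, nx), G0),
            O2=np.full((ny, nx), O20),
            E=np.where(self._enz, self.kin.Et, 0.0).astype(float),
            Eprime=np.zeros((ny, nx)),
            X1=np.zeros((ny, nx)),
            X2=np.zeros((ny, nx)),
        )

    # -- boundary control ------------------------------------------------
    def set_boundary_value(self, edge: str, species: str, value: float) -> None:
        kind = self.mesh.bc[edge][0]
        if kind != "dirichlet":
            raise ValueError(f"{edge} edge has no Dirichlet value")
        if value < 0:
            raise ValueError("boundary concentrations must be >= 0")
        self.mesh.bc[edge][1][species] = float(value)

    # -- stepping --------------------------------------------------------
    def _reaction_update(self, dt: float, n_sub: int = 1) -> None:
        """Backward-Euler reaction update on the enzymatic cells."""
        m = self._enz
        if not m.any():
            return
        u = np.stack(
            [self.state.G[m], self.state.O2[m], self.state.E[m],
             self.state.Eprime[m], self.state.X1[m], self.state.X2[m]],
            axis=-1,
        )
        h = dt / n_sub
        eye = np.eye(6)
        for _ in range(n_sub):
            u_old = u.copy()
            for it in range(30):
                st = SpeciesState(*[np.clip(u[:, k], 0.0, None) for k in range(6)])
                R = kin.reaction_rates(st, self.kin)
                Rv = np.stack([R.G, R.O2, R.E, R.Eprime, R.X1, R.X2], axis=-1)
                J = kin.reaction_jacobian(st, self.kin)
                F = u - u_old - h * Rv
                A = eye[None, :, :] - h * J
                du = np.linalg.solve(A, F[..., None])[..., 0]
                u = u - du
                if np.max(np.abs(du)) < 1e-12 * (1.0 + np.max(np.abs(u))):
                    break
            else:
                if n_sub < 1024:
                    # restart this whole dt with finer sub-steps
                    return self._reaction_update(dt, n_sub * 4)
                raise SolverError("reaction Newton failed to converge")
            u = np.clip(u, 0.0, None)
        for k, name in enumerate(("G", "O2", "E", "Eprime", "X1", "X2")):
            getattr(self.state, name)[m] = u[:, k]

    def step(self) -> None:
        """One operator-split step of length ``self.dt``."""
        dt = self.dt
        bc = self.mesh.bc
        n = self.state.G.size
        bG = _bvec(self._bwG, bc, "G", n)
        bO = _bvec(self._bwO, bc, "O2", n)
        shape = self.state.G.shape
        g = self._luG.solve(self.state.G.ravel() + dt * bG).reshape(shape)
        o = self._luO.solve(self.state.O2.ravel() + dt * bO).reshape(shape)
        # implicit solves of the M-matrix system cannot produce negatives
        # beyond round-off; clip those
        np.clip(g, 0.0, None, out=g)
        np.clip(o, 0.0, None, out=o)
        if not (np.isfinite(g).all() and np.isfinite(o).all()):
            raise SolverError("transport solve diverged (non-finite concentrations)")
        if self.sink_G or self.sink_O2:
            m = self._tissue
            ramp_g = np.minimum(1.0, g[m] / SINK_EPS)
            ramp_o = np.minimum(1.0, o[m] / SINK_EPS)
            g[m] = np.maximum(g[m] - dt * self.sink_G * ramp_g, 0.0)
            o[m] = np.maximum(o[m] - dt * self.sink_O2 * ramp_o, 0.0)
        self.state.G = g
        self.state.O2 = o
        self._reaction_update(dt)
        self.t += dt

    def run(self, duration: float, probe=None, probe_every: int = 1):
        """Advance ``duration`` seconds; return list of probe outputs.

        ``probe(solver)`` is called every ``probe_every`` steps (and once at
        the start of the run).
        """
        out = []
        n = int(round(duration / self.dt))
        if probe is not None:
            out.append(probe(self))
        for k in range(n):
            self.step()
            if probe is not None and (k + 1) % probe_every == 0:
                out.append(probe(self))
        return out

    # -- readouts --------------------------------------------------------
    def lifetime_field(self) -> np.ndarray:
        o2 = kin.o2_in_unit(self.state.O2, self.sv.o2_unit)
        return kin.lifetime(o2, self.sv)

    def sensor_lifetime(self) -> float:
        """Volume-weighted mean lifetime over the enzymatic sensing cells."""
        return kin.aggregate_lifetime(self.lifetime_field()[self._enz])

    def total_mass(self, species: str = "G") -> float:
        c = getattr(self.state, species)
        return float(c.sum() * self.mesh.dx * self.mesh.dy)


# ---------------------------------------------------------------------------
# steady state (Picard)

def steady_state(
    mesh: Mesh2D,
    transport: TransportParams | None = None,
    kinetics: KineticParams | None = None,
    flow: FlowField | None = None,
    sink_G: float = 0.0,
    sink_O2: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 300,
    damping: float = 0.5,
):
    """Steady G and O2 fields by damped Picard iteration.

    Enzymatic consumption uses the quasi-steady cycle flux
    :func:`glucolux.kinetics.quasi_steady_consumption` linearized implicitly
    in each species (which preserves positivity); zeroth-order tissue sinks
    are linearized below :data:`SINK_EPS` for the same reason.  Returns
    ``(G, O2, n_iter)`` as (ny, nx) arrays.
    """
    transport = transport or TransportParams()
    kinetics = kinetics or KineticParams()
    ny, nx = mesh.shape
    N = ny * nx
    TG, bwG = transport_operator(mesh, transport.DG, flow)
    TO, bwO = transport_operator(mesh, transport.DO2, flow)
    bG = _bvec(bwG, mesh.bc, "G", N)
    bO = _bvec(bwO, mesh.bc, "O2", N)
    enz = mesh.mask("sensor_enzymatic").ravel()
    tis = mesh.mask("tissue").ravel()

    # start from the boundary-fed values
    dval = [v[1] for v in mesh.bc.values() if v[0] == "dirichlet"]
    G = np.full(N, max((d["G"] for d in dval), default=0.0))
    O2 = np.full(N, max((d["O2"] for d in dval), default=0.009))

    it = 0
    for it in range(1, max_iter + 1):
        rate, _ = kin.quasi_steady_consumption(
            np.clip(G[enz], 0.0, None), np.clip(O2[enz], 0.0, None), kinetics
        )
        lamG = np.zeros(N)
        lamO = np.zeros(N)
        lamG[enz] = rate / np.maximum(G[enz], 1e-12)
        lamO[enz] = rate / np.maximum(O2[enz], 1e-12)
        lamG[tis] += sink_G / np.maximum(G[tis], SINK_EPS)
        lamO[tis] += sink_O2 / np.maximum(O2[tis], SINK_EPS)
        AG = (-TG + sp.diags(lamG)).tocsc()
        AO = (-TO + sp.diags(lamO)).tocsc()
        G_new = splu(AG).solve(bG)
        O2_new = splu(AO).solve(bO)
        G_next = damping * G + (1.0 - damping) * G_new
        O2_next = damping * O2 + (1.0 - damping) * O2_new
        dG = np.max(np.abs(G_next - G)) / (np.max(np.abs(G_next)) + 1e-300)
        dO = np.max(np.abs(O2_next - O2)) / (np.max(np.abs(O2_next)) + 1e-300)
        G, O2 = G_next, O2_next
        if max(dG, dO) < tol:
            break
    else:
        warnings.warn(f"steady_state: not converged to {tol} in {max_iter} iterations")
    return G.reshape(ny, nx), O2.reshape(ny, nx), it
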