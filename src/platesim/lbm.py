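"""D3Q19 lattice Boltzmann fluid with BGK collision and Guo forcing.

All fields live in lattice units (h = dt = 1, quiescent density 1).  The
x and y directions are periodic; the z faces carry on-site velocity boundary
conditions (Hecht-Harting closure) so a plane Couette flow is driven by
moving the z = Lz wall.  The kinematic viscosity is nu = c_s^2 (tau - 1/2)
with c_s^2 = 1/3.

Arrays are laid out f[i, x, y, z] with the velocity set

    index 0        : rest
    indices 1..6   : +x, -x, +y, -y, +z, -z            (weight 1/18)
    indices 7..18  : the 12 axis-diagonal pairs         (weight 1/36)

Macroscopic fields: rho = sum_i f_i, momentum rho u = sum_i c_i f_i, and the
Navier-Stokes velocity in the presence of a body force F is v = u + F/(2 rho)
(second-order Guo scheme; the forcing term carries the (1 - 1/2tau) factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --- velocity set ----------------------------------------------------------

C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: index of the direction opposite to each c_i
OPP = np.array([int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C])

CS2 = 1.0 / 3.0

#: unknown post-streaming populations entering from the bottom (z=0) wall
UNKNOWN_BOTTOM = np.flatnonzero(C[:, 2] > 0)
UNKNOWN_TOP = np.flatnonzero(C[:, 2] < 0)

_TANG = np.flatnonzero(C[:, 2] == 0)
_INTO_BOTTOM = np.flatnonzero(C[:, 2] == -1)
_INTO_TOP = np.flatnonzero(C[:, 2] == 1)
#: direction lookup (cx, cy, cz) -> index
_FI = {tuple(int(x) for x in c): i for i, c in enumerate(C)}


class FluidInstabilityError(RuntimeError):
    """NaN or non-positive density detected in the lattice state."""


@dataclass
class BoundarySpec:
    """z-face boundary velocities; x/y faces are always periodic.

    ``v_bottom``/``v_top`` are wall velocities in lattice units.  Setting a
    face to None makes that face periodic as well (used for unbounded-shear
    style test flows)."""

    v_bottom: np.ndarray | None = field(
        default_factory=lambda: np.zeros(3))
    v_top: np.ndarray | None = field(default_factory=lambda: np.zeros(3))


@dataclass
class LatticeState:
    """Distribution field on an Nx x Ny x Nz grid."""

    f: np.ndarray                       # (19, Nx, Ny, Nz)
    bounds: BoundarySpec = field(default_factory=BoundarySpec)

    @classmethod
    def quiescent(cls, shape: tuple[int, int, int],
                  bounds: BoundarySpec | None = None) -> "LatticeState":
        f = np.broadcast_to(W[:, None, None, None], (19, *shape)).copy()
        return cls(f=f, bounds=bounds or BoundarySpec())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f.shape[1:]


def equilibrium(rho: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Second-order D3Q19 equilibrium; moments reproduce (rho, rho v) exactly.

    ``rho``: (...,) density; ``v``: (..., 3) velocity in lattice units.
    Returns an array with a leading direction axis of length 19.
    """
    rho = np.asarray(rho, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(np.linalg.norm(v, axis=-1) >= 1.0):
        raise FluidInstabilityError("velocity at or above lattice speed")
    cv = np.tensordot(C, np.moveaxis(v, -1, 0), axes=(1, 0))  # (19, ...)
    v2 = np.einsum("...k,...k->...", v, v)
    feq = W.reshape((19,) + (1,) * rho.ndim) * rho * (
        1.0 + 3.0 * cv + 4.5 * cv * cv - 1.5 * v2
    )
    return feq


def macroscopic(state: LatticeState, force: np.ndarray | None = None):
    """Density, bare streaming velocity u and corrected velocity v = u + F/2rho."""
    f = state.f
    rho = f.sum(axis=0)
    mom = np.tensordot(C, f, axes=(0, 0))        # (3, Nx, Ny, Nz)
    u = np.moveaxis(mom, 0, -1) / rho[..., None]
    if force is None:
        return rho, u, u
    v = u + force / (2.0 * rho[..., None])
    return rho, u, v


def _guo_source(v: np.ndarray, force: np.ndarray, tau: float) -> np.ndarray:
    """Guo forcing term S_i with the (1 - 1/2tau) prefactor."""
    pref = (1.0 - 0.5 / tau)
    cv = np.tensordot(C, np.moveaxis(v, -1, 0), axes=(1, 0))       # (19,...)
    cF = np.tensordot(C, np.moveaxis(force, -1, 0), axes=(1, 0))
    vF = np.einsum("...k,...k->...", v, force)
    S = pref * W.reshape((19,) + (1,) * (v.ndim - 1)) * (
        3.0 * (cF - vF) + 9.0 * cv * cF
    )
    return S


def collide_stream_numpy(state: LatticeState, tau: float,
                         force: np.ndarray | None = None) -> LatticeState:
    """Reference numpy implementation of one BGK + Guo + streaming step."""
    f = state.f
    if force is None:
        rho = f.sum(axis=0)
        mom = np.tensordot(C, f, axes=(0, 0))
        v = np.moveaxis(mom, 0, -1) / rho[..., None]
    else:
        rho, _, v = macroscopic(state, force)
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise FluidInstabilityError("non-finite or non-positive density")
    feq = equilibrium(rho, v)
    f = f - (f - feq) / tau
    if force is not None:
        f = f + _guo_source(v, force, tau)
    # streaming: pull-free roll per direction (periodic everywhere; wall
    # nodes are then repaired by the on-site BC)
    for i in range(1, 19):
        f[i] = np.roll(f[i], shift=tuple(C[i]), axis=(0, 1, 2))
    state.f = f
    if state.bounds.v_bottom is not None:
        apply_velocity_bc(state, "bottom", state.bounds.v_bottom)
    if state.bounds.v_top is not None:
        apply_velocity_bc(state, "top", state.bounds.v_top)
    return state


try:  # fused single-pass kernel; falls back to numpy when numba is absent
    import numba as _nb

    @_nb.njit(cache=False, fastmath=False)
    def _collide_stream_kernel(f, tau, force, has_force, fnew, Ci, Wi):
        nx, ny, nz = f.shape[1], f.shape[2], f.shape[3]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    rho = 0.0
                    mx = 0.0
                    my = 0.0
                    mz = 0.0
                    for i in range(19):
                        fi = f[i, x, y, z]
                        rho += fi
                        mx += Ci[i, 0] * fi
                        my += Ci[i, 1] * fi
                        mz += Ci[i, 2] * fi
                    if not (rho > 0.0) or rho != rho:
                        return False
                    Fx = force[x, y, z, 0]
                    Fy = force[x, y, z, 1]
                    Fz = force[x, y, z, 2]
                    vx = (mx + 0.5 * Fx) / rho
                    vy = (my + 0.5 * Fy) / rho
                    vz = (mz + 0.5 * Fz) / rho
                    v2 = vx * vx + vy * vy + vz * vz
                    pref = 1.0 - 0.5 / tau
                    vF = vx * Fx + vy * Fy + vz * Fz
                    for i in range(19):
                        cv = Ci[i, 0] * vx + Ci[i, 1] * vy + Ci[i, 2] * vz
                        feq = Wi[i] * rho * (1.0 + 3.0 * cv + 4.5 * cv * cv
                                             - 1.5 * v2)
                        out = f[i, x, y, z] - (f[i, x, y, z] - feq) / tau
                        if has_force:
                            cF = (Ci[i, 0] * Fx + Ci[i, 1] * Fy
                                  + Ci[i, 2] * Fz)
                            out += pref * Wi[i] * (3.0 * (cF - vF)
                                                   + 9.0 * cv * cF)
                        xs = x + Ci[i, 0]
                        if xs == nx:
                            xs = 0
                        elif xs < 0:
                            xs = nx - 1
                        ys = y + Ci[i, 1]
                        if ys == ny:
                            ys = 0
                        elif ys < 0:
                            ys = ny - 1
                        zs = z + Ci[i, 2]
                        if zs == nz:
                            zs = 0
                        elif zs < 0:
                            zs = nz - 1
                        fnew[i, xs, ys, zs] = out
                    continue
        return True

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def collide_stream(state: LatticeState, tau: float,
                   force: np.ndarray | None = None) -> LatticeState:
    """One BGK collision + streaming step with optional body-force field.

    ``force``: (Nx, Ny, Nz, 3) body force density in lattice units (or None).
    After streaming, the z-face velocity boundary conditions from
    ``state.bounds`` are applied.  Uses a fused numba kernel when available,
    numerically equivalent to the numpy reference path
    (:func:`collide_stream_numpy`), which the test suite cross-checks.
    """
    if not _HAVE_NUMBA:
        return collide_stream_numpy(state, tau, force)
    f = state.f
    has_force = force is not None
    if not has_force:
        force = _zero_force(state.shape)
    fnew = np.empty_like(f)
    ok = _collide_stream_kernel(f, float(tau), force, has_force, fnew,
                                C, W)
    if not ok:
        raise FluidInstabilityError("non-finite or non-positive density")
    state.f = fnew
    if state.bounds.v_bottom is not None:
        apply_velocity_bc(state, "bottom", state.bounds.v_bottom)
    if state.bounds.v_top is not None:
        apply_velocity_bc(state, "top", state.bounds.v_top)
    return state


_ZERO_FORCE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _zero_force(shape) -> np.ndarray:
    arr = _ZERO_FORCE_CACHE.get(shape)
    if arr is None:
        arr = np.zeros((*shape, 3))
        _ZERO_FORCE_CACHE[shape] = arr
    return arr


def apply_velocity_bc(state: LatticeState, face: str, v_wall) -> LatticeState:
    """On-site velocity boundary condition on a z-face (Hecht-Harting).

    Reconstructs the five unknown post-streaming populations so the node
    moments equal (rho_wall, v_wall) exactly, with rho_wall computed from the
    known populations and transverse momentum corrections N_x, N_y.
    """
    v = np.asarray(v_wall, dtype=float)
    vx, vy, vz = v
    f = state.f
    if face == "bottom":
        sl = f[:, :, :, 0]
        sgn = 1.0
    elif face == "top":
        sl = f[:, :, :, -1]
        sgn = -1.0
    else:
        raise ValueError("face must be 'bottom' or 'top'")
    # incoming populations travel with c_z = -sgn; tangential have c_z = 0
    tang = _TANG
    into_wall = _INTO_BOTTOM if face == "bottom" else _INTO_TOP
    rho_w = (sl[tang].sum(axis=0) + 2.0 * sl[into_wall].sum(axis=0)) / (1.0 - sgn * vz)

    fi = _FI

    # transverse momentum corrections from the in-plane populations
    N_x = 0.5 * (sl[fi[1, 0, 0]] + sl[fi[1, 1, 0]] + sl[fi[1, -1, 0]]
                 - sl[fi[-1, 0, 0]] - sl[fi[-1, 1, 0]] - sl[fi[-1, -1, 0]]) \
        - rho_w * vx / 3.0
    N_y = 0.5 * (sl[fi[0, 1, 0]] + sl[fi[1, 1, 0]] + sl[fi[-1, 1, 0]]
                 - sl[fi[0, -1, 0]] - sl[fi[1, -1, 0]] - sl[fi[-1, -1, 0]]) \
        - rho_w * vy / 3.0

    s = 1 if face == "bottom" else -1   # c_z of the unknown populations
    sl[fi[0, 0, s]] = sl[fi[0, 0, -s]] + sgn * rho_w * vz / 3.0
    sl[fi[1, 0, s]] = sl[fi[-1, 0, -s]] + rho_w * (sgn * vz + vx) / 6.0 - N_x
    sl[fi[-1, 0, s]] = sl[fi[1, 0, -s]] + rho_w * (sgn * vz - vx) / 6.0 + N_x
    sl[fi[0, 1, s]] = sl[fi[0, -1, -s]] + rho_w * (sgn * vz + vy) / 6.0 - N_y
    sl[fi[0, -1, s]] = sl[fi[0, 1, -s]] + rho_w * (sgn * vz - vy) / 6.0 + N_y
    return state


def lattice_viscosity(tau: float) -> float:
    """nu = c_s^2 (tau - 1/2) in lattice units."""
    return CS2 * (tau - 0.5)


def write_vtk_snapshot(state: LatticeState, path, force=None) -> None:
    """Velocity/density snapshot as a VTK legacy structured-points file."""
    rho, _, v = macroscopic(state, force)
    nx, ny, nz = state.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nplatesim fluid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\nSPACING 1 1 1\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS density double 1\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{rho[i, j, k]:.9g}\n")
        fh.write("VECTORS velocity double\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{v[i, j, k, 0]:.9g} {v[i, j, k, 1]:.9g} "
                             f"{v[i, j, k, 2]:.9g}\n")
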