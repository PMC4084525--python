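"""Synthetic test assets: analytic meshes, constructed trajectories,
exponential pause-duration samples.

Every generator is a pure function of its arguments (and seed), so
regeneration is bit-identical; nothing is ever stored on disk by the test
suite.
"""

from __future__ import annotations

import numpy as np

from .mesh import PlateletMesh, _orient_outward


def make_sphere_mesh(n_subdiv: int = 2, radius: float = 1.0) -> PlateletMesh:
    """Icosphere by recursive subdivision: 12, 42, 162, 642, 2562 ... vertices.

    Deterministic; used where an analytic curvature/area oracle is needed.
    """
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(n_subdiv):
        verts, faces = _subdivide(verts, faces)
    verts = verts * radius
    faces = _orient_outward(verts, faces)
    return PlateletMesh(vertices=verts, triangles=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    cache: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (np.asarray(verts[i]) + np.asarray(verts[j])) / 2.0
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(out, dtype=np.int64)


def make_synthetic_trajectory(
    stops: list[tuple[float, float]],
    speed: float = 100.0e-6,
    total_time: float | None = None,
    dt: float = 1.0e-3,
):
    """Centroid trajectory moving at ``speed`` except during the given stops.

    ``stops`` is a list of (start time, duration) pairs in seconds.  Returns
    (times, y positions).
    """
    for (t0, d0), (t1, _) in zip(stops, stops[1:]):
        if t1 < t0 + d0:
            raise ValueError("stops must be non-overlapping and ordered")
    if total_time is None:
        total_time = (max((t + d for t, d in stops), default=0.0) + 0.2)
    times = np.arange(0.0, total_time, dt)
    v = np.full_like(times, speed)
    for t0, d0 in stops:
        v[(times >= t0) & (times < t0 + d0)] = 0.0
    y = np.concatenate([[0.0], np.cumsum(v[:-1]) * dt])
    return times, y


def make_exponential_durations(rate: float, n: int, seed: int = 0) -> np.ndarray:
    """n i.i.d. exponential(rate) pause durations (s); reproducible by seed."""
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / rate, size=n)
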