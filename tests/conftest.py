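"""Shared fixtures: small procedural scenes and a posed stereo rig.

Everything is generated at test time; session scope keeps the expensive
pieces (scene construction, numba compilation, renders) to one instance.
"""

from __future__ import annotations

import numpy as np
import pytest

from stereofix.geometry import HeadState, fixate
from stereofix.render import CameraIntrinsics, render
from stereofix.scene import Scene, TriangleMesh, make_synthetic_scene, value_noise_texture


def textured_plane(z_mm: float, half_extent_mm: float, seed: int = 0,
                   center=(0.0, 0.0), name: str = "plane") -> TriangleMesh:
    """Fronto-parallel textured square at world z = z_mm (normal along z)."""
    cx, cy = center
    h = half_extent_mm
    verts = np.array([[cx - h, cy - h, z_mm], [cx + h, cy - h, z_mm],
                      [cx + h, cy + h, z_mm], [cx - h, cy + h, z_mm]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    uv = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    rng = np.random.default_rng(seed)
    return TriangleMesh(vertices=verts, faces=faces, name=name, uv=uv,
                        texture=value_noise_texture(rng, size=256, base_cells=5,
                                                    octaves=3))


def ground_plane(half_extent_mm: float = 3000.0, seed: int = 3) -> Scene:
    """Huge textured horizontal plane at y = 0 (every protocol grid ray hits)."""
    h = half_extent_mm
    verts = np.array([[-h, 0.0, -h], [h, 0.0, -h], [h, 0.0, h], [-h, 0.0, h]])
    faces = np.array([[0, 2, 1], [0, 3, 2]])
    uv = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    rng = np.random.default_rng(seed)
    mesh = TriangleMesh(vertices=verts, faces=faces, name="ground", uv=uv,
                        texture=value_noise_texture(rng, size=256))
    return Scene(meshes=[mesh])


def brute_force_depth(scene: Scene, origin: np.ndarray, dirs: np.ndarray):
    """Independent numpy nearest-hit oracle (Moller-Trumbore over all triangles).

    Returns (t, tri_index) with t = -1 on miss; ties at equal distance go to
    the lowest triangle index.
    """
    packed = scene.packed()
    v0 = packed.vertices[packed.faces[:, 0]]
    e1 = packed.vertices[packed.faces[:, 1]] - v0
    e2 = packed.vertices[packed.faces[:, 2]] - v0
    ts = np.full(len(dirs), -1.0)
    tris = np.full(len(dirs), -1, dtype=int)
    for r, d in enumerate(dirs):
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origin - v0
        u = np.einsum("ij,ij->i", tvec, p) * inv
        q = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-6)
        if np.any(hit):
            tmin = t[hit].min()
            # lowest index among hits within the tie tolerance
            cand = np.nonzero(hit & (t <= tmin + 1e-6))[0]
            tris[r] = cand.min()
            ts[r] = t[cand.min()]
    return ts, tris


@pytest.fixture(scope="session")
def tabletop_scene() -> Scene:
    """The default cluttered-tabletop world (8 textured primitives)."""
    return make_synthetic_scene(1, n_objects=8)


@pytest.fixture(scope="session")
def small_scene() -> Scene:
    """A lighter scene for brute-force oracle comparisons."""
    return make_synthetic_scene(5, n_objects=2)


@pytest.fixture(scope="session")
def small_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(width=96, height=54)


@pytest.fixture(scope="session")
def default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics()


@pytest.fixture(scope="session")
def frontal_rig():
    """Head at the origin fixating a textured wall straight ahead.

    Scene: background wall at z = -2000 mm plus a small box-face plane at
    z = -1000 mm; fixation on the wall above the box, so the box is nearer
    than fixation.
    """
    wall = textured_plane(-2000.0, 1500.0, seed=11, name="wall")
    box = textured_plane(-1000.0, 120.0, seed=12, name="box")
    scene = Scene(meshes=[wall, box])
    head = HeadState(position=np.zeros(3))
    state = fixate(head, np.array([0.0, 500.0, -2000.0]))
    return scene, head, state


@pytest.fixture(scope="session")
def rendered_fixation(tabletop_scene, default_intrinsics):
    """One mid-grid fixation on the tabletop scene, all three views rendered."""
    from stereofix.protocol import vantage_points
    from stereofix.render import fixation_targets

    vp = vantage_points(tabletop_scene)[4]  # azimuth 0, elevation 30
    pts, hit = fixation_targets(tabletop_scene, vp.head.pose, default_intrinsics)
    assert hit[4, 7]
    state = fixate(vp.head, pts[4, 7])
    views = {side: render(tabletop_scene, state.eye(side).pose_world,
                          default_intrinsics)
             for side in ("left", "right", "cyclopic")}
    return tabletop_scene, vp, state, views
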