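"""Metric textured triangle-mesh scenes.

A :class:`Scene` is a list of :class:`TriangleMesh` objects in a
right-handed metric world frame (millimetres): ``x`` left-to-right, ``y``
up (perpendicular to the table surface), ``z`` toward the viewer, origin
at the centre of the table.  Meshes carry appearance either as per-vertex
RGB colours or as per-vertex UV coordinates plus a texture image; the
renderer treats both as baked radiance (no lighting model).

:func:`make_synthetic_scene` procedurally emulates the cluttered tabletop
worlds the fixation protocol was designed for: a 1 m x 1 m textured table
plane with a handful of mutually non-intersecting textured primitives
(boxes, spheres, cylinders, cones) whose depth spread supports viewing
distances of roughly 500-2,200 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import trimesh

from .raycast import TriangleIndex

__all__ = [
    "SceneError",
    "SceneFormatError",
    "PlacementError",
    "TriangleMesh",
    "Scene",
    "load_scene",
    "save_scene",
    "make_synthetic_scene",
    "build_spatial_index",
]

DEFAULT_WORKSPACE_MM = 1000.0
_MIN_TRIANGLE_AREA = 1e-9  # mm^2


class SceneError(ValueError):
    pass


class SceneFormatError(SceneError):
    pass


class PlacementError(SceneError):
    pass


@dataclass
class TriangleMesh:
    """One textured, opaque mesh in world millimetres.

    Exactly one appearance channel must be present: ``vertex_colors``
    ((N, 3) uint8) or ``uv`` ((N, 2) float in [0, 1]) together with
    ``texture`` ((Ht, Wt, 3) uint8).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"
    vertex_colors: np.ndarray | None = None
    uv: np.ndarray | None = None
    texture: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, np.uint8).reshape(-1, 3)
        if self.uv is not None:
            self.uv = np.asarray(self.uv, dtype=np.float64).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise SceneError(f"{self.name}: non-finite vertex coordinates")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise SceneError(f"{self.name}: face index out of range")
        if self.vertex_colors is None and (self.uv is None or self.texture is None):
            raise SceneFormatError(
                f"{self.name}: mesh needs per-vertex colors or UV + texture "
                "(the renderer has no other appearance source)"
            )
        a = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        if np.any(areas < _MIN_TRIANGLE_AREA):
            raise SceneError(f"{self.name}: degenerate triangle (area < 1e-9 mm^2)")

    @property
    def bounds(self) -> np.ndarray:
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class _Packed:
    """Scene flattened into triangle-soup arrays for casting and shading."""

    vertices: np.ndarray
    faces: np.ndarray
    tri_mesh: np.ndarray          # (M,) mesh index per triangle
    corner_uv: np.ndarray | None  # (M, 3, 2) per-corner UV (NaN where colors used)
    corner_color: np.ndarray      # (M, 3, 3) per-corner RGB float (NaN where UV used)
    textures: list[np.ndarray | None]


@dataclass
class Scene:
    """A list of textured meshes plus world-frame metadata."""

    meshes: list[TriangleMesh]
    metadata: dict = field(default_factory=lambda: {
        "axes": "x: left-to-right, y: up (table normal), z: toward viewer",
        "origin": "center of the table surface",
        "units": "mm",
    })
    _index: TriangleIndex | None = field(default=None, repr=False, compare=False)
    _packed: _Packed | None = field(default=None, repr=False, compare=False)

    @property
    def n_triangles(self) -> int:
        return sum(len(m.faces) for m in self.meshes)

    @property
    def bounds(self) -> np.ndarray:
        if not self.meshes:
            raise SceneError("empty scene has no bounds")
        b = np.stack([m.bounds for m in self.meshes])
        return np.stack([b[:, 0].min(axis=0), b[:, 1].max(axis=0)])

    @property
    def center(self) -> np.ndarray:
        return self.bounds.mean(axis=0)

    def packed(self) -> _Packed:
        if self._packed is None:
            verts, faces, tri_mesh = [], [], []
            corner_uv, corner_color, textures = [], [], []
            offset = 0
            for mi, m in enumerate(self.meshes):
                verts.append(m.vertices)
                faces.append(m.faces + offset)
                tri_mesh.append(np.full(len(m.faces), mi, dtype=np.int64))
                if m.uv is not None:
                    corner_uv.append(m.uv[m.faces])
                    corner_color.append(np.full((len(m.faces), 3, 3), np.nan))
                    textures.append(m.texture)
                else:
                    corner_uv.append(np.full((len(m.faces), 3, 2), np.nan))
                    corner_color.append(m.vertex_colors[m.faces].astype(np.float64))
                    textures.append(None)
                offset += len(m.vertices)
            self._packed = _Packed(
                vertices=np.concatenate(verts),
                faces=np.concatenate(faces),
                tri_mesh=np.concatenate(tri_mesh),
                corner_uv=np.concatenate(corner_uv),
                corner_color=np.concatenate(corner_color),
                textures=textures,
            )
        return self._packed

    def spatial_index(self) -> TriangleIndex:
        if self._index is None:
            self._index = build_spatial_index(self)
        return self._index

    def shade(self, tri: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """RGB (float 0-255) for hit triangles at barycentric (u, v).

        UV textures are sampled bilinearly; per-vertex colours are
        interpolated barycentrically.
        """
        packed = self.packed()
        out = np.zeros(tri.shape + (3,), dtype=np.float64)
        w0 = 1.0 - u - v
        bary = np.stack([w0, u, v], axis=-1)  # weights for corners 0,1,2
        mesh_of = packed.tri_mesh[tri]
        for mi, tex in enumerate(packed.textures):
            sel = mesh_of == mi
            if not np.any(sel):
                continue
            if tex is None:
                col = packed.corner_color[tri[sel]]  # (k, 3 corners, 3 rgb)
                out[sel] = np.einsum("kc,kcr->kr", bary[sel], col)
            else:
                uv = np.einsum("kc,kcd->kd", bary[sel], packed.corner_uv[tri[sel]])
                out[sel] = _sample_bilinear(tex, uv)
        return out


def _sample_bilinear(texture: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Bilinear texture lookup, UV in [0,1] with clamping, texel centres at 0.5."""
    h, w = texture.shape[:2]
    x = np.clip(uv[:, 0] * w - 0.5, 0.0, w - 1.0)
    y = np.clip(uv[:, 1] * h - 0.5, 0.0, h - 1.0)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (x - x0)[:, None]
    fy = (y - y0)[:, None]
    tex = texture.astype(np.float64)
    return ((tex[y0, x0] * (1 - fx) + tex[y0, x1] * fx) * (1 - fy)
            + (tex[y1, x0] * (1 - fx) + tex[y1, x1] * fx) * fy)


def build_spatial_index(scene: Scene) -> TriangleIndex:
    """BVH over all scene triangles; equivalent to brute force by contract."""
    if not scene.meshes or scene.n_triangles == 0:
        raise SceneError("cannot index an empty scene")
    packed = scene.packed()
    return TriangleIndex(packed.vertices, packed.faces)


# ---------------------------------------------------------------------------
# file I/O (OBJ / PLY via trimesh)
# ---------------------------------------------------------------------------

def _to_trimesh(mesh: TriangleMesh) -> trimesh.Trimesh:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if mesh.uv is not None:
        from PIL import Image

        img = Image.fromarray(mesh.texture)
        tm.visual = trimesh.visual.TextureVisuals(
            uv=mesh.uv, material=trimesh.visual.material.SimpleMaterial(image=img)
        )
    else:
        tm.visual = trimesh.visual.ColorVisuals(
            tm, vertex_colors=np.column_stack(
                [mesh.vertex_colors,
                 np.full(len(mesh.vertices), 255, dtype=np.uint8)])
        )
    return tm


def _vertex_colors_from_texture(mesh: TriangleMesh) -> np.ndarray:
    return np.clip(np.rint(_sample_bilinear(mesh.texture, mesh.uv)), 0, 255
                   ).astype(np.uint8)


def save_scene(scene: Scene, path: str | Path, format: str | None = None) -> Path:
    """Write a scene to OBJ (textures preserved) or PLY (per-vertex RGB).

    PLY carries no texture images, so UV-textured meshes are baked to
    per-vertex colours on export (lossy for coarse meshes).  All meshes are
    concatenated into the single PLY element; OBJ keeps named objects.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise SceneFormatError(f"unsupported scene format {fmt!r} (use obj or ply)")
    if fmt == "obj":
        ts = trimesh.Scene()
        for m in scene.meshes:
            ts.add_geometry(_to_trimesh(m), node_name=m.name, geom_name=m.name)
        ts.export(str(path))
    else:
        parts = []
        for m in scene.meshes:
            tm = trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)
            colors = (m.vertex_colors if m.vertex_colors is not None
                      else _vertex_colors_from_texture(m))
            tm.visual = trimesh.visual.ColorVisuals(
                tm, vertex_colors=np.column_stack(
                    [colors, np.full(len(m.vertices), 255, dtype=np.uint8)]))
            parts.append(tm)
        combined = trimesh.util.concatenate(parts)
        combined.export(str(path), encoding="ascii")
    return path


def load_scene(path: str | Path, format: str | None = None) -> Scene:
    """Load an OBJ or PLY file into a :class:`Scene` (units assumed mm)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise SceneFormatError(f"unsupported scene format {fmt!r} (use obj or ply)")
    if not path.exists():
        raise SceneFormatError(f"scene file not found: {path}")
    if path.stat().st_size == 0:
        raise SceneFormatError(f"scene file is empty: {path}")
    try:
        loaded = trimesh.load(str(path), process=False, maintain_order=True,
                              force="scene" if fmt == "obj" else None)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise SceneFormatError(f"cannot parse {path}: {exc}") from exc

    geoms: list[tuple[str, trimesh.Trimesh]]
    if isinstance(loaded, trimesh.Scene):
        if not loaded.geometry:
            raise SceneFormatError(f"{path}: no geometry found")
        geoms = list(loaded.geometry.items())
    else:
        geoms = [(path.stem, loaded)]

    meshes = []
    for name, tm in geoms:
        if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
            raise SceneFormatError(f"{path}: object {name!r} has no triangles")
        visual = tm.visual
        if isinstance(visual, trimesh.visual.TextureVisuals) and visual.uv is not None:
            material = visual.material
            image = getattr(material, "image", None)
            if image is None:
                raise SceneFormatError(f"{path}: object {name!r} lacks a texture image")
            meshes.append(TriangleMesh(
                vertices=np.asarray(tm.vertices, float),
                faces=np.asarray(tm.faces, np.int64),
                name=str(name),
                uv=np.asarray(visual.uv, float),
                texture=np.asarray(image.convert("RGB"), np.uint8),
            ))
        elif (getattr(visual, "vertex_colors", None) is not None
              and len(visual.vertex_colors) == len(tm.vertices)):
            meshes.append(TriangleMesh(
                vertices=np.asarray(tm.vertices, float),
                faces=np.asarray(tm.faces, np.int64),
                name=str(name),
                vertex_colors=np.asarray(visual.vertex_colors)[:, :3],
            ))
        else:
            raise SceneFormatError(
                f"{path}: object {name!r} has neither vertex colors nor texture"
            )
    return Scene(meshes=meshes)


# ---------------------------------------------------------------------------
# procedural textures
# ---------------------------------------------------------------------------

def value_noise_texture(rng: np.random.Generator, size: int = 256,
                        base_cells: int = 4, octaves: int = 3,
                        lo: float = 40.0, hi: float = 230.0) -> np.ndarray:
    """Smooth fractal value-noise RGB texture.

    Octave lattices are bilinearly upsampled and summed with halving
    amplitude; the band limit keeps on-screen gradients gentle, emulating
    the smoothness of photographic object textures.
    """
    acc = np.zeros((size, size, 3))
    amp = 1.0
    total = 0.0
    for o in range(octaves):
        cells = base_cells * (2 ** o)
        lattice = rng.random((cells + 1, cells + 1, 3))
        up = np.stack([
            ndi.zoom(lattice[:, :, c], size / (cells + 1), order=1,
                     grid_mode=True, mode="nearest")
            for c in range(3)
        ], axis=-1)
        acc += amp * up
        total += amp
        amp *= 0.5
    acc /= total
    return np.clip(np.rint(lo + (hi - lo) * acc), 0, 255).astype(np.uint8)


def stripe_texture(rng: np.random.Generator, size: int = 256,
                   periods: float = 6.0) -> np.ndarray:
    """Sinusoidal two-colour grating at a random orientation."""
    angle = rng.uniform(0, np.pi)
    c1 = rng.uniform(40, 230, 3)
    c2 = rng.uniform(40, 230, 3)
    yy, xx = np.mgrid[0:size, 0:size] / size
    phase = np.sin(2 * np.pi * periods * (np.cos(angle) * xx + np.sin(angle) * yy))
    t = (phase[..., None] + 1.0) / 2.0
    return np.clip(np.rint(c1 + (c2 - c1) * t), 0, 255).astype(np.uint8)


def checker_texture(rng: np.random.Generator, size: int = 256,
                    cells: int = 8, blur_px: float = 4.0) -> np.ndarray:
    """Gaussian-smoothed checkerboard (band-limited to avoid point-sample alias)."""
    c1 = rng.uniform(40, 230, 3)
    c2 = rng.uniform(40, 230, 3)
    yy, xx = np.mgrid[0:size, 0:size]
    board = ((xx * cells // size + yy * cells // size) % 2).astype(float)
    board = ndi.gaussian_filter(board, blur_px, mode="wrap")
    return np.clip(np.rint(c1 + (c2 - c1) * board[..., None]), 0, 255).astype(np.uint8)


def _random_texture(rng: np.random.Generator) -> np.ndarray:
    kind = rng.integers(0, 3)
    if kind == 0:
        return value_noise_texture(rng, base_cells=int(rng.integers(3, 6)))
    if kind == 1:
        return stripe_texture(rng, periods=float(rng.uniform(3, 7)))
    return checker_texture(rng, cells=int(rng.integers(4, 9)))


# ---------------------------------------------------------------------------
# primitive meshes (UV-mapped, no degenerate triangles)
# ---------------------------------------------------------------------------

def _box_mesh(size: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sx, sy, sz = np.asarray(size, float) / 2.0
    verts, faces, uvs = [], [], []
    # each face gets its own 4 vertices with planar UV
    axes = [  # (normal axis, sign, u axis, v axis)
        (0, +1, 2, 1), (0, -1, 2, 1),
        (1, +1, 0, 2), (1, -1, 0, 2),
        (2, +1, 0, 1), (2, -1, 0, 1),
    ]
    half = np.array([sx, sy, sz])
    for ax, sign, ua, va in axes:
        base = len(verts)
        for du, dv in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
            p = np.zeros(3)
            p[ax] = sign * half[ax]
            p[ua] = du * half[ua]
            p[va] = dv * half[va]
            verts.append(p)
            uvs.append([(du + 1) / 2, (dv + 1) / 2])
        faces += [[base, base + 1, base + 2], [base, base + 2, base + 3]]
    return np.array(verts), np.array(faces), np.array(uvs)


def _sphere_mesh(radius: float, n_lat: int = 12, n_lon: int = 18):
    verts, uvs = [], []
    for i in range(n_lat + 1):
        theta = np.pi * i / n_lat
        for j in range(n_lon + 1):
            phi = 2 * np.pi * j / n_lon
            verts.append([radius * np.sin(theta) * np.cos(phi),
                          radius * np.cos(theta),
                          radius * np.sin(theta) * np.sin(phi)])
            uvs.append([j / n_lon, i / n_lat])
    faces = []
    cols = n_lon + 1
    for i in range(n_lat):
        for j in range(n_lon):
            a = i * cols + j
            b = (i + 1) * cols + j
            if i > 0:
                faces.append([a, b, a + 1])
            if i < n_lat - 1:
                faces.append([a + 1, b, b + 1])
    return np.array(verts), np.array(faces), np.array(uvs)


def _lathe_mesh(profile: list[tuple[float, float]], n_seg: int = 24):
    """Surface of revolution about +y; profile is (radius, height) pairs."""
    verts, uvs = [], []
    rows = len(profile)
    for i, (r, h) in enumerate(profile):
        for j in range(n_seg + 1):
            phi = 2 * np.pi * j / n_seg
            verts.append([r * np.cos(phi), h, r * np.sin(phi)])
            uvs.append([j / n_seg, i / (rows - 1)])
    faces = []
    cols = n_seg + 1
    for i in range(rows - 1):
        r0, r1 = profile[i][0], profile[i + 1][0]
        for j in range(n_seg):
            a = i * cols + j
            b = (i + 1) * cols + j
            if r0 > 1e-9:
                faces.append([a, b, a + 1])
            if r1 > 1e-9:
                faces.append([a + 1, b, b + 1])
    return np.array(verts), np.array(faces), np.array(uvs)


def _cylinder_mesh(radius: float, height: float):
    return _lathe_mesh([(0.0, 0.0), (radius, 0.0), (radius, height), (0.0, height)])


def _cone_mesh(radius: float, height: float):
    return _lathe_mesh([(0.0, 0.0), (radius, 0.0), (0.0, height)])


def _make_primitive(rng: np.random.Generator, name: str) -> TriangleMesh:
    kind = rng.integers(0, 4)
    if kind == 0:
        size = rng.uniform([80, 80, 80], [220, 320, 220])
        v, f, uv = _box_mesh(size)
        v[:, 1] += size[1] / 2.0  # rest on the table
    elif kind == 1:
        r = rng.uniform(50, 130)
        v, f, uv = _sphere_mesh(r)
        v[:, 1] += r
    elif kind == 2:
        r, h = rng.uniform(40, 110), rng.uniform(100, 350)
        v, f, uv = _cylinder_mesh(r, h)
    else:
        r, h = rng.uniform(60, 130), rng.uniform(120, 350)
        v, f, uv = _cone_mesh(r, h)
    return TriangleMesh(vertices=v, faces=f, name=name, uv=uv,
                        texture=_random_texture(rng))


def _table_mesh(rng: np.random.Generator, extent: float) -> TriangleMesh:
    h = extent / 2.0
    verts = np.array([[-h, 0.0, -h], [h, 0.0, -h], [h, 0.0, h], [-h, 0.0, h]])
    faces = np.array([[0, 2, 1], [0, 3, 2]])
    uv = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return TriangleMesh(vertices=verts, faces=faces, name="table", uv=uv,
                        texture=value_noise_texture(rng, size=512, base_cells=6,
                                                    octaves=3))


def make_synthetic_scene(seed: int, n_objects: int = 8,
                         workspace: float = DEFAULT_WORKSPACE_MM) -> Scene:
    """Deterministic cluttered-tabletop scene.

    A textured table plane at ``y = 0`` spanning ``workspace`` mm square,
    plus ``n_objects`` textured primitives placed by rejection sampling so
    that object bounding boxes never overlap and stay inside the workspace
    footprint.  Identical seeds produce bit-identical scenes.
    """
    if n_objects < 0:
        raise SceneError("n_objects must be >= 0")
    rng = np.random.default_rng(seed)
    meshes = [_table_mesh(rng, workspace)]
    placed_boxes: list[np.ndarray] = []
    half = workspace / 2.0
    for k in range(n_objects):
        for attempt in range(200):
            mesh = _make_primitive(rng, name=f"object_{k}")
            span = mesh.bounds[1] - mesh.bounds[0]
            max_x = half - span[0] / 2.0
            max_z = half - span[2] / 2.0
            if max_x <= 0 or max_z <= 0:
                continue
            cx = rng.uniform(-max_x, max_x)
            cz = rng.uniform(-max_z, max_z)
            mesh.vertices[:, 0] += cx
            mesh.vertices[:, 2] += cz
            box = mesh.bounds
            margin = 5.0  # mm clearance between objects
            ok = all(
                not (box[0, 0] - margin < other[1, 0]
                     and box[1, 0] + margin > other[0, 0]
                     and box[0, 2] - margin < other[1, 2]
                     and box[1, 2] + margin > other[0, 2])
                for other in placed_boxes
            )
            if ok:
                placed_boxes.append(box)
                meshes.append(mesh)
                break
        else:
            raise PlacementError(
                f"could not place object {k} without intersection after 200 tries"
            )
    return Scene(meshes=meshes)
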