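"""Pinhole ray-casting renderer with eye-space depth output.

Cameras have unit focal length and look along ``-z`` in their own frame,
so the eye-space depth ``lambda`` of a visible point is negative; public
helpers also expose its magnitude in mm.  Homogeneous image coordinates
follow the two-view reprojection convention ``x = X / lambda`` (with
``lambda = z_eye < 0``): a consequence is that crossed (nearer than
fixation) horizontal disparity comes out positive.

Pixels are 0-based with half-pixel centres and the principal point at the
image centre ``((W-1)/2, (H-1)/2)``.  The image-plane half extent at unit
focal length is ``tan(HFOV/2)`` horizontally and ``tan(VFOV/2)``
vertically (anisotropic pixels allowed; ``vfov=None`` derives square
pixels from the aspect ratio).

There is no lighting model: mesh textures are treated as baked radiance,
one primary ray per pixel centre, no anti-aliasing — geometric fidelity of
the ground truth is the point, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, OutOfRangeError, invert_pose
from .scene import Scene

__all__ = [
    "BehindCameraError",
    "CameraIntrinsics",
    "RenderResult",
    "DATASET_PRESET",
    "project_point",
    "backproject_pixel",
    "render",
    "encode_depth_buffer",
    "decode_depth_buffer",
    "fixation_targets",
]


class BehindCameraError(GeometryError):
    """Point projected from behind the camera centre."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera: image size, field of view and clip planes.

    ``near``/``far`` (mm) bound the usable depth range and parameterise the
    nonlinear z-buffer; ``focal_distance`` is informational only.
    """

    width: int = 480
    height: int = 270
    hfov: float = 40.0
    vfov: float | None = None
    near: float = 400.0
    far: float = 3000.0
    focal_distance: float | None = None

    def __post_init__(self) -> None:
        if not (self.width >= 2 and self.height >= 2):
            raise OutOfRangeError("image must be at least 2x2 pixels")
        if not 0.0 < self.near < self.far:
            raise OutOfRangeError("need 0 < near < far")
        if not 0.0 < self.hfov < 180.0:
            raise OutOfRangeError("HFOV must be in (0, 180) degrees")
        if self.vfov is not None and not 0.0 < self.vfov < 180.0:
            raise OutOfRangeError("VFOV must be in (0, 180) degrees")

    @property
    def tan_half_h(self) -> float:
        return float(np.tan(np.deg2rad(self.hfov) / 2.0))

    @property
    def tan_half_v(self) -> float:
        if self.vfov is None:  # square pixels
            return self.tan_half_h * self.height / self.width
        return float(np.tan(np.deg2rad(self.vfov) / 2.0))

    @property
    def principal_point(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    # pixels per unit of homogeneous image coordinate
    @property
    def scale_x(self) -> float:
        return self.width / 2.0 / self.tan_half_h

    @property
    def scale_y(self) -> float:
        return self.height / 2.0 / self.tan_half_v

    def pixels_from_homogeneous(self, xh: np.ndarray, yh: np.ndarray):
        cx, cy = self.principal_point
        return cx + self.scale_x * xh, cy + self.scale_y * yh

    def homogeneous_from_pixels(self, px: np.ndarray, py: np.ndarray):
        cx, cy = self.principal_point
        return (np.asarray(px, float) - cx) / self.scale_x, \
               (np.asarray(py, float) - cy) / self.scale_y


#: Resolution preset of the published fixation database.
DATASET_PRESET = CameraIntrinsics(width=1921, height=1081)


@dataclass
class RenderResult:
    """Colour image plus eye-space depth for one camera.

    ``depth`` stores the signed eye-space ``lambda`` (negative in front of
    the camera, NaN on background); ``valid`` masks pixels that hit scene
    geometry inside the [near, far] range; ``zbuffer`` optionally stores
    the nonlinear depth-buffer value ``w`` in [0, 1].
    """

    image: np.ndarray
    depth: np.ndarray
    valid: np.ndarray
    zbuffer: np.ndarray | None = None

    @property
    def depth_mm(self) -> np.ndarray:
        """Unsigned eye-space depth in mm (NaN on background)."""
        return np.abs(self.depth)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_point(pose: np.ndarray, intr: CameraIntrinsics, point_world: np.ndarray
                  ) -> tuple[tuple[float, float], float]:
    """Project one world point; returns ((px, py), lambda) with lambda < 0."""
    X = np.asarray(point_world, float).reshape(3)
    Xc = invert_pose(pose)[:3, :3] @ X + invert_pose(pose)[:3, 3]
    lam = Xc[2]
    if lam >= 0.0:
        raise BehindCameraError("point lies at or behind the camera centre")
    px, py = intr.pixels_from_homogeneous(Xc[0] / lam, Xc[1] / lam)
    return (float(px), float(py)), float(lam)


def backproject_pixel(pose: np.ndarray, intr: CameraIntrinsics,
                      pixel: tuple[float, float], lam: float) -> np.ndarray:
    """Inverse of :func:`project_point`; ``lam`` may be signed or magnitude."""
    mag = abs(float(lam))
    if not intr.near <= mag <= intr.far:
        raise OutOfRangeError(
            f"|lambda|={mag:.3f} mm outside [{intr.near}, {intr.far}]")
    xh, yh = intr.homogeneous_from_pixels(pixel[0], pixel[1])
    Xc = -mag * np.array([float(xh), float(yh), 1.0])
    return pose[:3, :3] @ Xc + pose[:3, 3]


def encode_depth_buffer(lam: np.ndarray, near: float, far: float) -> np.ndarray:
    """Signed eye-space depth -> nonlinear z-buffer value ``w`` in [0, 1]."""
    lam = np.where(np.asarray(lam, float) > 0, -np.asarray(lam, float),
                   np.asarray(lam, float))
    mag = np.abs(lam)
    if np.any((mag < near - 1e-9) | (mag > far + 1e-9)):
        raise OutOfRangeError("lambda magnitude outside [near, far]")
    return far * (lam + near) / (lam * (far - near))


def decode_depth_buffer(w: np.ndarray, near: float, far: float) -> np.ndarray:
    """Nonlinear z-buffer -> signed eye-space depth: lambda = f n / (w (f-n) - f).

    ``w = 0`` maps to the near plane (lambda = -n), ``w = 1`` to the far
    plane (lambda = -f); the map is a bijection between [0, 1] and [-f, -n].
    """
    w = np.asarray(w, float)
    if np.any((w < 0.0) | (w > 1.0)):
        raise OutOfRangeError("depth-buffer values must lie in [0, 1]")
    return far * near / (w * (far - near) - far)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _pixel_ray_dirs(pose: np.ndarray, intr: CameraIntrinsics,
                    px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """World-frame ray directions through pixel centres.

    Directions are scaled so the ray parameter t equals the eye-space depth
    magnitude |lambda| of the hit.
    """
    xh, yh = intr.homogeneous_from_pixels(px, py)
    dirs_cam = np.stack([-xh, -yh, -np.ones_like(xh)], axis=-1)
    return dirs_cam @ pose[:3, :3].T


def render(scene: Scene, pose: np.ndarray, intr: CameraIntrinsics,
           with_zbuffer: bool = False) -> RenderResult:
    """Render one camera: one primary ray per pixel centre, nearest hit.

    Returns flat-albedo colour (texture / vertex-colour lookup, no
    lighting), the signed eye-space depth map and the validity mask;
    deterministic for identical inputs.
    """
    H, W = intr.height, intr.width
    if not scene.meshes or scene.n_triangles == 0:
        return RenderResult(
            image=np.zeros((H, W, 3), np.uint8),
            depth=np.full((H, W), np.nan),
            valid=np.zeros((H, W), bool),
            zbuffer=np.ones((H, W)) if with_zbuffer else None,
        )
    py, px = np.mgrid[0:H, 0:W].astype(float)
    dirs = _pixel_ray_dirs(pose, intr, px.ravel(), py.ravel())
    origin = pose[:3, 3]
    hits = scene.spatial_index().cast(origin, dirs)

    t = hits.t.reshape(H, W)
    valid = hits.hit.reshape(H, W) & (t >= intr.near) & (t <= intr.far)
    depth = np.where(valid, -t, np.nan)

    image = np.zeros((H, W, 3), np.uint8)
    sel = valid.ravel()
    if np.any(sel):
        colors = scene.shade(hits.tri[sel], hits.u[sel], hits.v[sel])
        image.reshape(-1, 3)[sel] = np.clip(np.rint(colors), 0, 255).astype(np.uint8)

    zbuf = None
    if with_zbuffer:
        zbuf = np.ones((H, W))
        zbuf[valid] = encode_depth_buffer(depth[valid], intr.near, intr.far)
    return RenderResult(image=image, depth=depth, valid=valid, zbuffer=zbuf)


def fixation_targets(scene: Scene, cyclopic_pose: np.ndarray,
                     intr: CameraIntrinsics, grid_rows: int = 9,
                     grid_cols: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """3-D fixation candidates: a grid of cyclopic rays cast onto the scene.

    The image is divided into ``grid_rows x grid_cols`` equal tiles and a
    ray is cast through each tile centre; the nearest surface intersection
    becomes the candidate fixation point.  Returns ``(points, hit)`` with
    ``points`` of shape (rows, cols, 3) world mm (NaN where the ray missed
    all geometry) and ``hit`` the boolean mask of usable targets.
    """
    px = (np.arange(grid_cols) + 0.5) * intr.width / grid_cols - 0.5
    py = (np.arange(grid_rows) + 0.5) * intr.height / grid_rows - 0.5
    pxg, pyg = np.meshgrid(px, py)
    points = np.full((grid_rows, grid_cols, 3), np.nan)
    if not scene.meshes or scene.n_triangles == 0:
        return points, np.zeros((grid_rows, grid_cols), bool)
    dirs = _pixel_ray_dirs(cyclopic_pose, intr, pxg.ravel(), pyg.ravel())
    origin = cyclopic_pose[:3, 3]
    hits = scene.spatial_index().cast(origin, dirs)
    hit = hits.hit.reshape(grid_rows, grid_cols)
    pts = origin[None, :] + hits.t[:, None] * dirs
    points[hit] = pts.reshape(grid_rows, grid_cols, 3)[hit]
    return points, hit
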