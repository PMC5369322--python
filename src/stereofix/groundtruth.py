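"""Ground-truth vector disparity, occlusion and depth-edge maps.

Disparity is derived analytically, not estimated: every valid pixel of a
reference depth map is back-projected to its 3-D point, re-projected into
the left and right cameras, and the per-pixel difference of the two image
positions is the vector disparity ``(d_x, d_y) = (x_R - x_L, y_R - y_L)``
in pixels.  With the toe-in convention used here, crossed disparity
(nearer than fixation) is positive and disparity vanishes at the fixation
point.

Occlusions are detected from the disparity map itself: forward-mapping
each pixel by its disparity, a pixel is occluded when it lands (within a
tolerance radius) where another pixel lands with a larger crossed
(nearer) disparity.  Depth edges are pixels whose neighbouring disparity
vectors differ by more than a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BinocularState
from .render import CameraIntrinsics

__all__ = [
    "DisparityMap",
    "BinaryMap",
    "reproject",
    "disparity_from_cyclopic",
    "disparity_from_left",
    "mirrored_disparity",
    "occlusion_map",
    "depth_edge_map",
    "evaluate_disparity_estimate",
]

# Forward-splat collision settings: pixels landing within this radius of a
# grid position compete; a competitor must be nearer by more than the tie
# tolerance (in disparity pixels) to mark a pixel occluded.
OCCLUSION_RADIUS_PX = 0.5
OCCLUSION_TIE_PX = 0.05
DEPTH_EDGE_THRESHOLD_PX = 1.0


@dataclass
class DisparityMap:
    """Vector disparity referenced to the cyclopic or the left camera.

    ``dx``/``dy`` are (H, W) float arrays in pixels with the sign
    convention ``d = x_R - x_L``; ``valid`` masks pixels with defined
    disparity (foreground in the source depth map, in front of both
    cameras).
    """

    dx: np.ndarray
    dy: np.ndarray
    reference: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.reference not in ("cyclopic", "left"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if not (self.dx.shape == self.dy.shape == self.valid.shape):
            raise ValueError("disparity component shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


@dataclass
class BinaryMap:
    """Boolean pixel mask attached to a disparity map (occlusion/depth edges)."""

    mask: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("occlusion", "depth_edge"):
            raise ValueError(f"unknown binary-map kind {self.kind!r}")


# ---------------------------------------------------------------------------
# reprojection
# ---------------------------------------------------------------------------

def reproject(x_a: np.ndarray, lam_a: np.ndarray, pose_a: np.ndarray,
              pose_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transfer homogeneous image coordinates from camera A to camera B.

    ``x_a`` is (..., 2) homogeneous image coordinates (x, y) = (X, Y)/lambda
    and ``lam_a`` the signed eye-space depth (negative in front).  Returns
    ``(x_b, lam_b, in_front)`` where ``in_front`` flags points that end up
    strictly in front of camera B (points at or behind its centre get NaN
    coordinates).
    """
    x_a = np.asarray(x_a, float)
    lam_a = np.asarray(lam_a, float)
    P_a = lam_a[..., None] * np.concatenate(
        [x_a, np.ones(x_a.shape[:-1] + (1,))], axis=-1)
    R_a, t_a = pose_a[:3, :3], pose_a[:3, 3]
    R_b, t_b = pose_b[:3, :3], pose_b[:3, 3]
    P_world = P_a @ R_a.T + t_a
    P_b = (P_world - t_b) @ R_b
    lam_b = P_b[..., 2]
    in_front = lam_b < -1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        x_b = P_b[..., :2] / lam_b[..., None]
    x_b = np.where(in_front[..., None], x_b, np.nan)
    return x_b, lam_b, in_front


def _pixel_grid_homogeneous(intr: CameraIntrinsics, shape: tuple[int, int]):
    H, W = shape
    py, px = np.mgrid[0:H, 0:W].astype(float)
    xh, yh = intr.homogeneous_from_pixels(px, py)
    return px, py, xh, yh


def _disparity_from_depth(lam_map: np.ndarray, pose_ref: np.ndarray,
                          pose_l: np.ndarray, pose_r: np.ndarray,
                          intr: CameraIntrinsics, reference: str,
                          valid: np.ndarray | None) -> DisparityMap:
    lam = np.asarray(lam_map, float)
    lam = np.where(lam > 0, -lam, lam)  # accept magnitudes
    if valid is None:
        valid = np.isfinite(lam)
    if valid.shape != lam.shape:
        raise ValueError("validity mask shape does not match the depth map")
    _, _, xh, yh = _pixel_grid_homogeneous(intr, lam.shape)
    x_ref = np.stack([xh, yh], axis=-1)
    lam_safe = np.where(valid, lam, -intr.near)  # placeholder for masked pixels
    x_l, _, ok_l = reproject(x_ref, lam_safe, pose_ref, pose_l)
    x_r, _, ok_r = reproject(x_ref, lam_safe, pose_ref, pose_r)
    good = valid & ok_l & ok_r
    px_l, py_l = intr.pixels_from_homogeneous(x_l[..., 0], x_l[..., 1])
    px_r, py_r = intr.pixels_from_homogeneous(x_r[..., 0], x_r[..., 1])
    dx = np.where(good, px_r - px_l, np.nan)
    dy = np.where(good, py_r - py_l, np.nan)
    return DisparityMap(dx=dx, dy=dy, reference=reference, valid=good)


def disparity_from_cyclopic(lam_c: np.ndarray, state: BinocularState,
                            intr: CameraIntrinsics,
                            valid: np.ndarray | None = None) -> DisparityMap:
    """Cyclopic-referenced vector disparity from the cyclopic depth map.

    For each valid cyclopic pixel the scene point is re-projected into the
    left and the right camera and the difference of the two pixel
    positions is returned; this symmetric reference avoids the left/right
    asymmetry of conventional disparity maps.
    """
    return _disparity_from_depth(lam_c, state.cyclopic.pose_world,
                                 state.left.pose_world, state.right.pose_world,
                                 intr, "cyclopic", valid)


def disparity_from_left(lam_l: np.ndarray, state: BinocularState,
                        intr: CameraIntrinsics,
                        valid: np.ndarray | None = None) -> DisparityMap:
    """Left-referenced disparity: pixel p of the left image maps to p + d."""
    return _disparity_from_depth(lam_l, state.left.pose_world,
                                 state.left.pose_world, state.right.pose_world,
                                 intr, "left", valid)


def mirrored_disparity(lam_c: np.ndarray, state: BinocularState,
                       intr: CameraIntrinsics,
                       valid: np.ndarray | None = None) -> DisparityMap:
    """Disparity of the left-right mirrored cyclopic depth map.

    The depth map (and its validity mask) is mirrored about the middle
    vertical image line (column j -> W-1-j) and the cyclopic disparity
    computation is applied unchanged; the protocol uses this to double the
    fixation count while cancelling object-layout bias.
    """
    lam_m = np.asarray(lam_c, float)[:, ::-1]
    valid_m = None if valid is None else np.asarray(valid, bool)[:, ::-1]
    return disparity_from_cyclopic(lam_m, state, intr, valid_m)


# ---------------------------------------------------------------------------
# binary maps
# ---------------------------------------------------------------------------

def occlusion_map(disparity: DisparityMap) -> BinaryMap:
    """Occluded pixels by forward splatting with a disparity z-test.

    Each valid pixel is mapped to ``p + d(p)`` and binned on the integer
    grid (bin radius ~0.5 px).  Within a bin the largest crossed disparity
    wins; any pixel beaten by more than the tie tolerance is occluded by a
    nearer surface.  Depends on geometry only, not on texture.
    """
    H, W = disparity.shape
    py, px = np.mgrid[0:H, 0:W].astype(float)
    valid = disparity.valid
    tx = px[valid] + disparity.dx[valid]
    ty = py[valid] + disparity.dy[valid]
    dxv = disparity.dx[valid]

    ix = np.rint(tx).astype(np.int64)
    iy = np.rint(ty).astype(np.int64)
    # keep a border of one bin outside the image so border landings still compete
    inb = (ix >= -1) & (ix <= W) & (iy >= -1) & (iy <= H)
    cells = (iy + 1) * (W + 2) + (ix + 1)
    best = np.full((H + 2) * (W + 2), -np.inf)
    np.maximum.at(best, cells[inb], dxv[inb])
    occluded_v = np.zeros(len(dxv), bool)
    occluded_v[inb] = best[cells[inb]] > dxv[inb] + OCCLUSION_TIE_PX

    mask = np.zeros((H, W), bool)
    mask[valid] = occluded_v
    return BinaryMap(mask=mask, kind="occlusion")


def depth_edge_map(disparity: DisparityMap,
                   threshold: float = DEPTH_EDGE_THRESHOLD_PX) -> BinaryMap:
    """Depth-discontinuity pixels: disparity-vector jumps over a threshold.

    A pixel is marked when the Euclidean norm of the difference between its
    disparity vector and any of its 8 neighbours' exceeds ``threshold``
    pixels; comparisons against invalid neighbours are ignored, so the
    background boundary itself is not an edge.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dx, dy, valid = disparity.dx, disparity.dy, disparity.valid
    H, W = disparity.shape
    mask = np.zeros((H, W), bool)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for si, sj in shifts:
        i0, i1 = max(si, 0), H + min(si, 0)
        j0, j1 = max(sj, 0), W + min(sj, 0)
        a = np.s_[i0:i1, j0:j1]
        b = np.s_[i0 - si:i1 - si, j0 - sj:j1 - sj]
        both = valid[a] & valid[b]
        jump = np.hypot(dx[a] - dx[b], dy[a] - dy[b]) > threshold
        mask[a] |= both & jump
    return BinaryMap(mask=mask & valid, kind="depth_edge")


def evaluate_disparity_estimate(estimate: DisparityMap, truth: DisparityMap,
                                mask: np.ndarray | None = None
                                ) -> tuple[float, float, float, float]:
    """Score an estimated disparity map against the ground truth.

    Returns component-wise ``(MAE_x, MAE_y, SD_x, SD_y)`` of the error
    ``estimate - truth`` over the evaluation mask.
    """
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth shapes differ")
    if estimate.reference != truth.reference:
        raise ValueError("estimate and truth use different reference cameras")
    m = estimate.valid & truth.valid
    if mask is not None:
        m &= np.asarray(mask, bool)
    if not np.any(m):
        raise ValueError("empty evaluation mask")
    ex = estimate.dx[m] - truth.dx[m]
    ey = estimate.dy[m] - truth.dy[m]
    return (float(np.mean(np.abs(ex))), float(np.mean(np.abs(ey))),
            float(np.std(ex)), float(np.std(ey)))
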