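"""Warp-based validation of rendered stereo pairs.

If the geometry and the renderer are correct, warping the right image by
the ground-truth left-referenced disparity must reconstruct the left image
up to resampling error.  The reconstruction is scored with three image
quality indexes on 8-bit gray levels — MAE, NCC (global 2-D Pearson
correlation) and SSIM — over four regions: the full valid area (the same
mask scored on the unwarped pair gives the ORIG baseline and on the warped
pair the WARP score), the area without occlusions (NO-OCC), the area
without occlusions and depth edges (NO-DE), and the occlusion+edge area
alone (OCC).  Batch summaries report median, quartiles and range per
index and region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .groundtruth import BinaryMap, DisparityMap

__all__ = [
    "MetricError",
    "WarpSample",
    "ValidationReport",
    "to_gray",
    "warp_right_to_left",
    "mae",
    "ncc",
    "ssim",
    "region_masks",
    "score_sample",
    "validate_batch",
    "REGIONS",
    "METRICS",
]

REGIONS = ("ORIG", "WARP", "NO_OCC", "NO_DE", "OCC")
METRICS = ("MAE", "NCC", "SSIM")

# SSIM constants: standard reference values for 8-bit dynamic range,
# 11x11 Gaussian window with sigma 1.5.
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_SIGMA = 1.5
SSIM_RADIUS = 5
SSIM_DATA_RANGE = 255.0


class MetricError(ValueError):
    pass


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB (0-255) to gray levels (float, 0-255) with the standard luma weights."""
    img = np.asarray(image, float)
    if img.ndim == 2:
        return img
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


def warp_right_to_left(right_gray: np.ndarray, disparity: DisparityMap,
                       right_valid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the left image by sampling the right at ``p + d(p)``.

    Bilinear interpolation; samples whose 2x2 support leaves the image (or
    touches a background pixel of the right view, when ``right_valid`` is
    given) are marked invalid rather than extrapolated.  Returns
    ``(reconstruction, warp_valid)``.
    """
    if disparity.reference != "left":
        raise MetricError("warping requires a left-referenced disparity map")
    right = np.asarray(right_gray, float)
    H, W = right.shape
    if disparity.shape != (H, W):
        raise MetricError("disparity and image shapes differ")
    py, px = np.mgrid[0:H, 0:W].astype(float)
    sx = px + disparity.dx
    sy = py + disparity.dy
    ok = disparity.valid & (sx >= 0) & (sx <= W - 1) & (sy >= 0) & (sy <= H - 1)
    sx_c = np.where(ok, sx, 0.0)
    sy_c = np.where(ok, sy, 0.0)
    x0 = np.floor(sx_c).astype(np.int64)
    y0 = np.floor(sy_c).astype(np.int64)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = sx_c - x0
    fy = sy_c - y0
    recon = ((right[y0, x0] * (1 - fx) + right[y0, x1] * fx) * (1 - fy)
             + (right[y1, x0] * (1 - fx) + right[y1, x1] * fx) * fy)
    if right_valid is not None:
        rv = np.asarray(right_valid, bool)
        support_ok = rv[y0, x0] & rv[y0, x1] & rv[y1, x0] & rv[y1, x1]
        ok = ok & support_ok
    recon = np.where(ok, recon, np.nan)
    return recon, ok


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_pair(a: np.ndarray, b: np.ndarray, mask: np.ndarray):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mask = np.asarray(mask, bool)
    if not (a.shape == b.shape == mask.shape):
        raise MetricError("image/mask shapes differ")
    if not np.any(mask):
        raise MetricError("empty evaluation mask")
    return a, b, mask


def mae(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute gray-level difference over the mask."""
    a, b, mask = _check_pair(a, b, mask)
    return float(np.mean(np.abs(a[mask] - b[mask])))


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Global 2-D Pearson correlation over the mask (location/scale invariant)."""
    a, b, mask = _check_pair(a, b, mask)
    x = a[mask] - a[mask].mean()
    y = b[mask] - b[mask].mean()
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0.0:
        raise MetricError("zero variance: correlation undefined")
    return float(np.sum(x * y) / denom)


def _ssim_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    truncate = SSIM_RADIUS / SSIM_SIGMA
    f = lambda img: ndi.gaussian_filter(img, SSIM_SIGMA, truncate=truncate)  # noqa: E731
    c1 = (SSIM_K1 * SSIM_DATA_RANGE) ** 2
    c2 = (SSIM_K2 * SSIM_DATA_RANGE) ** 2
    mu_a = f(a)
    mu_b = f(b)
    var_a = f(a * a) - mu_a ** 2
    var_b = f(b * b) - mu_b ** 2
    cov = f(a * b) - mu_a * mu_b
    return (((2 * mu_a * mu_b + c1) * (2 * cov + c2))
            / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


def ssim(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean structural similarity over windows fully inside the mask.

    Uses the standard 11x11 Gaussian window (sigma 1.5) and K1=0.01,
    K2=0.03 at 8-bit dynamic range.  Window centres are kept only where the
    whole window lies inside the mask (erosion by the window radius);
    returns NaN when no window fits, which happens for thin regions such as
    occlusion bands.
    """
    a, b, mask = _check_pair(a, b, mask)
    a = np.nan_to_num(a)
    b = np.nan_to_num(b)
    size = 2 * SSIM_RADIUS + 1
    inner = ndi.binary_erosion(mask, structure=np.ones((size, size)),
                               border_value=0)
    if not np.any(inner):
        return float("nan")
    return float(np.mean(_ssim_map(a, b)[inner]))


def region_masks(occlusion: BinaryMap, depth_edges: BinaryMap,
                 valid: np.ndarray, guard_px: int = 1) -> dict[str, np.ndarray]:
    """The four scoring regions; NO_DE and OCC partition ORIG.

    ``guard_px`` grows the excluded occlusion/edge areas by a morphological
    ring before they are removed: the bilinear warp reads a 2x2
    neighbourhood, so reconstruction artefacts extend one pixel beyond the
    marked discontinuity itself.  Set to 0 for the strict set algebra.
    """
    valid = np.asarray(valid, bool)
    occ = occlusion.mask & valid
    edge = depth_edges.mask & valid
    if guard_px:
        ring = np.ones((2 * guard_px + 1,) * 2, bool)
        occ = ndi.binary_dilation(occ, structure=ring) & valid
        edge = ndi.binary_dilation(edge, structure=ring) & valid
    bad = occ | edge
    return {
        "ORIG": valid,
        "NO_OCC": valid & ~occ,
        "NO_DE": valid & ~bad,
        "OCC": valid & bad,
    }


# ---------------------------------------------------------------------------
# batch validation
# ---------------------------------------------------------------------------

@dataclass
class WarpSample:
    """Everything needed to score one fixation record.

    ``left_valid``/``right_valid`` are the renderer's foreground masks;
    metrics are evaluated where the left view is valid and the warp
    produced a defined sample.
    """

    left_gray: np.ndarray
    right_gray: np.ndarray
    disparity: DisparityMap  # left-referenced
    occlusion: BinaryMap
    depth_edges: BinaryMap
    left_valid: np.ndarray
    right_valid: np.ndarray | None = None
    label: str = ""


def score_sample(sample: WarpSample) -> dict[tuple[str, str], float]:
    """All metric x region scores for one stereo fixation.

    ORIG scores the unwarped pair on the full valid mask; WARP/NO_OCC/
    NO_DE/OCC score the reconstruction (right warped onto left) on the
    region masks.  Keys are ``(region, metric)``.
    """
    recon, warp_ok = warp_right_to_left(sample.right_gray, sample.disparity,
                                        sample.right_valid)
    valid = np.asarray(sample.left_valid, bool) & warp_ok
    if not np.any(valid):
        raise MetricError("no valid pixels survive the warp")
    regions = region_masks(sample.occlusion, sample.depth_edges, valid)
    scores: dict[tuple[str, str], float] = {}
    for metric, fn in (("MAE", mae), ("NCC", ncc), ("SSIM", ssim)):
        scores[("ORIG", metric)] = fn(sample.left_gray, sample.right_gray,
                                      regions["ORIG"])
        for region in ("WARP", "NO_OCC", "NO_DE", "OCC"):
            m = regions["ORIG"] if region == "WARP" else regions[region]
            if not np.any(m):
                scores[(region, metric)] = float("nan")
                continue
            try:
                scores[(region, metric)] = fn(sample.left_gray, recon, m)
            except MetricError:
                scores[(region, metric)] = float("nan")
    return scores


@dataclass
class ValidationReport:
    """Per-record scores plus batch summary statistics."""

    per_record: pd.DataFrame  # columns: record, region, metric, value
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        def stat(fn):
            # NaN-dropping aggregate; all-NaN groups (e.g. SSIM on thin
            # occlusion bands) summarise to NaN without complaint
            def agg(s):
                s = s.dropna()
                return float(fn(s)) if len(s) else float("nan")
            return agg

        g = self.per_record.groupby(["region", "metric"])["value"]
        self.summary = g.agg(
            median=stat(np.median),
            q1=stat(lambda s: np.percentile(s, 25)),
            q3=stat(lambda s: np.percentile(s, 75)),
            min=stat(np.min),
            max=stat(np.max),
            n="count",
        ).reset_index()
        bad_q = self.summary["q1"] > self.summary["q3"]
        if bad_q.any():
            raise MetricError("quartiles out of order")

    def median(self, region: str, metric: str) -> float:
        row = self.summary[(self.summary.region == region)
                           & (self.summary.metric == metric)]
        if row.empty:
            raise KeyError((region, metric))
        return float(row["median"].iloc[0])

    def to_csv(self, path) -> None:
        self.per_record.to_csv(path, index=False)

    def to_json_summary(self) -> dict:
        out: dict[str, dict[str, dict[str, float]]] = {}
        for _, row in self.summary.iterrows():
            out.setdefault(row.region, {})[row.metric] = {
                k: float(row[k]) for k in ("median", "q1", "q3", "min", "max")
            }
        return out


def validate_batch(samples) -> ValidationReport:
    """Score every sample and aggregate medians/quartiles/ranges per region."""
    rows = []
    n = 0
    for i, sample in enumerate(samples):
        n += 1
        label = sample.label or str(i)
        for (region, metric), value in score_sample(sample).items():
            rows.append({"record": label, "region": region,
                         "metric": metric, "value": value})
    if n == 0:
        raise MetricError("validate_batch needs at least one record")
    return ValidationReport(per_record=pd.DataFrame(rows))
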