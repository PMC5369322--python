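"""Readers and writers for the on-disk fixation-dataset layout.

One folder per head vantage point, named ``#scn_HP_#a_#e`` (scene letter,
head-azimuth index -2..2, head-elevation index 1..2); inside, each file is
named ``XX_HP_#a_#e_H_#h_V_#v`` where ``XX`` is the data name (e.g.
``cycdepth`` for the cyclopic depth map) and #h (-7..7) / #v (-4..4) index
the gaze direction within the 9 x 15 grid.

Formats: 8-bit RGB PNG for camera images; 16-bit grayscale PNG for depth
maps with a linear mm normalisation recorded in the info file (PNG value 0
is reserved for background); raw little-endian float32 row-major binaries
for disparity components; 1-bit PNG for masks; a line-oriented
``key: values`` TXT info file carrying the full stereo-head geometry.

The released archive's exact info-file key spelling is not published; the
grammar here is this package's own, the parser is permissive (unknown keys
are preserved as extras) and ``KEY_ALIASES`` is the documented stub where a
mapping onto the released files can be added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import (BinocularState, rotation_to_quaternion)

__all__ = [
    "DatasetIOError",
    "RecordPaths",
    "DepthNormalization",
    "CameraInfo",
    "InfoFile",
    "record_paths",
    "write_image_png",
    "read_image_png",
    "write_depth_png",
    "read_depth_png",
    "write_mask_png",
    "read_mask_png",
    "write_disparity_bin",
    "read_disparity_bin",
    "write_info",
    "read_info",
    "info_from_state",
]

SCENE_LABELS = ("K", "O")
DATA_NAMES = (
    "left", "right", "cyc", "cycdepth", "leftdepth", "info",
    "cycdispx", "cycdispy", "leftdispx", "leftdispy",
    "mircycdispx", "mircycdispy",
    "cycocc", "leftocc", "cycedges", "leftedges",
)
_EXTENSIONS = {"info": "txt",
               "cycdispx": "bin", "cycdispy": "bin",
               "leftdispx": "bin", "leftdispy": "bin",
               "mircycdispx": "bin", "mircycdispy": "bin"}

#: Stub mapping from this package's info keys onto the released archive's
#: (unknown) spelling; identity until the real files can be inspected.
KEY_ALIASES: dict[str, str] = {}


class DatasetIOError(ValueError):
    pass


@dataclass(frozen=True)
class RecordPaths:
    """Folder and per-data-name file names of one fixation record."""

    folder: str
    stem: str
    files: dict


def record_paths(scene_label: str, a: int, e: int, h: int, v: int) -> RecordPaths:
    """Validated folder/file names for record (#scn, #a, #e, #h, #v)."""
    if scene_label not in SCENE_LABELS:
        raise DatasetIOError(f"scene label must be one of {SCENE_LABELS}")
    if not -2 <= a <= 2:
        raise DatasetIOError(f"head azimuth index {a} outside -2..2")
    if e not in (1, 2):
        raise DatasetIOError(f"head elevation index {e} not in {{1, 2}}")
    if not -7 <= h <= 7:
        raise DatasetIOError(f"gaze azimuth index {h} outside -7..7")
    if not -4 <= v <= 4:
        raise DatasetIOError(f"gaze elevation index {v} outside -4..4")
    folder = f"{scene_label}_HP_{a}_{e}"
    stem = f"HP_{a}_{e}_H_{h}_V_{v}"
    files = {name: f"{name}_{stem}.{_EXTENSIONS.get(name, 'png')}"
             for name in DATA_NAMES}
    return RecordPaths(folder=folder, stem=stem, files=files)


# ---------------------------------------------------------------------------
# images, depth maps, masks, disparity binaries
# ---------------------------------------------------------------------------

def write_image_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(np.asarray(image, np.uint8)).save(path)
    return path


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), np.uint8)


@dataclass(frozen=True)
class DepthNormalization:
    """Linear PNG-value <-> mm mapping: code 1 -> dmin, code 65535 -> dmax.

    Code 0 is reserved for background pixels.
    """

    dmin: float
    dmax: float

    def __post_init__(self) -> None:
        if not (self.dmin > 0 and self.dmax > 0 and np.isfinite(self.dmin)
                and np.isfinite(self.dmax) and self.dmax > self.dmin):
            raise DatasetIOError("normalization constants must be positive "
                                 "with dmax > dmin")


def write_depth_png(lam_map: np.ndarray, path: str | Path
                    ) -> DepthNormalization:
    """Write |lambda| (mm) as 16-bit grayscale PNG; returns the constants."""
    d = np.abs(np.asarray(lam_map, float))
    valid = np.isfinite(d)
    if np.any(d[valid] <= 0):
        raise DatasetIOError("depth values must be positive")
    if np.any(valid):
        dmin = float(d[valid].min())
        dmax = float(d[valid].max())
        if dmax - dmin < 1e-9:
            dmax = dmin + 1.0
    else:
        dmin, dmax = 1.0, 2.0  # fully masked output
    norm = DepthNormalization(dmin=dmin, dmax=dmax)
    code = np.zeros(d.shape, np.uint16)
    code[valid] = 1 + np.clip(
        np.rint((d[valid] - dmin) / (dmax - dmin) * 65534), 0, 65534
    ).astype(np.uint16)
    Image.fromarray(code).save(Path(path))
    return norm


def read_depth_png(path: str | Path, constants: DepthNormalization | None
                   ) -> np.ndarray:
    """Invert :func:`write_depth_png`; background decodes to NaN."""
    if constants is None:
        raise DatasetIOError("depth normalization constants are required")
    img = Image.open(Path(path))
    code = np.asarray(img, np.uint16).astype(np.float64)
    d = constants.dmin + (code - 1) / 65534.0 * (constants.dmax - constants.dmin)
    return np.where(code == 0, np.nan, d)


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(np.asarray(mask, bool)).convert("1").save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("1"), bool)


def write_disparity_bin(arr: np.ndarray, path: str | Path) -> Path:
    """Raw little-endian float32, row-major, no header (NaN on invalid)."""
    arr = np.asarray(arr)
    path = Path(path)
    path.write_bytes(np.ascontiguousarray(arr, dtype="<f4").tobytes())
    return path


def read_disparity_bin(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    data = Path(path).read_bytes()
    expected = shape[0] * shape[1] * 4
    if len(data) != expected:
        raise DatasetIOError(
            f"{path}: size {len(data)} B does not match shape {shape} "
            f"({expected} B expected)")
    return np.frombuffer(data, dtype="<f4").reshape(shape).astype(np.float64)


# ---------------------------------------------------------------------------
# info file
# ---------------------------------------------------------------------------

@dataclass
class CameraInfo:
    position_world: np.ndarray
    position_head: np.ndarray
    quaternion_world: np.ndarray  # (w, x, y, z), unit
    quaternion_head: np.ndarray


@dataclass
class InfoFile:
    """Full geometric description of one fixation record.

    Positions in mm; orientations as unit quaternions (w, x, y, z); the
    binocular gaze as version (binocular azimuth), cyclopic elevation and
    vergence in degrees, head frame, plus the cyclopic-rotation quaternion
    in both frames; and the depth-map normalisation constants.
    """

    head_position: np.ndarray
    head_target: np.ndarray
    head_quaternion_world: np.ndarray
    cameras: dict  # side -> CameraInfo, sides "left", "cyc", "right"
    gaze_version: float
    gaze_elevation: float
    gaze_vergence: float
    gaze_quaternion_world: np.ndarray
    gaze_quaternion_head: np.ndarray
    cyc_depth_norm: DepthNormalization
    left_depth_norm: DepthNormalization
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        quats = [self.head_quaternion_world, self.gaze_quaternion_world,
                 self.gaze_quaternion_head]
        for cam in self.cameras.values():
            quats += [cam.quaternion_world, cam.quaternion_head]
        for q in quats:
            if abs(np.linalg.norm(q) - 1.0) > 1e-9:
                raise DatasetIOError("non-unit quaternion in info file")
        from .geometry import quaternion_to_rotation

        R_h = quaternion_to_rotation(self.head_quaternion_world)
        for side, cam in self.cameras.items():
            pos = R_h @ cam.position_head + self.head_position
            if np.max(np.abs(pos - cam.position_world)) > 1e-6:
                raise DatasetIOError(
                    f"{side}: world pose inconsistent with head-frame pose")
            R_world = quaternion_to_rotation(cam.quaternion_world)
            R_head = quaternion_to_rotation(cam.quaternion_head)
            if np.max(np.abs(R_h @ R_head - R_world)) > 1e-6:
                raise DatasetIOError(
                    f"{side}: world orientation inconsistent with head frame")


_MANDATORY_KEYS = (
    "head_position", "head_target", "head_quaternion_world",
    "gaze_version_elevation_vergence",
    "gaze_quaternion_world", "gaze_quaternion_head",
    "cyc_depth_normalization", "left_depth_normalization",
    *(f"{side}_{part}" for side in ("left", "cyc", "right")
      for part in ("position_world", "position_head",
                   "quaternion_world", "quaternion_head")),
)


def info_from_state(state: BinocularState, cyc_norm: DepthNormalization,
                    left_norm: DepthNormalization) -> InfoFile:
    """Collect the info-file fields from a posed binocular state."""
    head = state.head
    cams = {}
    for side, eye in (("left", state.left), ("cyc", state.cyclopic),
                      ("right", state.right)):
        cams[side] = CameraInfo(
            position_world=eye.pose_world[:3, 3].copy(),
            position_head=eye.origin.copy(),
            quaternion_world=rotation_to_quaternion(eye.pose_world[:3, :3]),
            quaternion_head=rotation_to_quaternion(eye.rotation),
        )
    return InfoFile(
        head_position=head.position.copy(),
        head_target=np.asarray(state.fixation, float),
        head_quaternion_world=rotation_to_quaternion(head.rotation),
        cameras=cams,
        gaze_version=state.version,
        gaze_elevation=state.cyclopic.alpha,
        gaze_vergence=state.vergence,
        gaze_quaternion_world=rotation_to_quaternion(
            state.cyclopic.pose_world[:3, :3]),
        gaze_quaternion_head=rotation_to_quaternion(state.cyclopic.rotation),
        cyc_depth_norm=cyc_norm,
        left_depth_norm=left_norm,
    )


def write_info(info: InfoFile, path: str | Path) -> Path:
    info.validate()
    lines = [
        ("head_position", info.head_position),
        ("head_target", info.head_target),
        ("head_quaternion_world", info.head_quaternion_world),
    ]
    for side in ("left", "cyc", "right"):
        cam = info.cameras[side]
        lines += [
            (f"{side}_position_world", cam.position_world),
            (f"{side}_position_head", cam.position_head),
            (f"{side}_quaternion_world", cam.quaternion_world),
            (f"{side}_quaternion_head", cam.quaternion_head),
        ]
    lines += [
        ("gaze_version_elevation_vergence",
         [info.gaze_version, info.gaze_elevation, info.gaze_vergence]),
        ("gaze_quaternion_world", info.gaze_quaternion_world),
        ("gaze_quaternion_head", info.gaze_quaternion_head),
        ("cyc_depth_normalization",
         [info.cyc_depth_norm.dmin, info.cyc_depth_norm.dmax]),
        ("left_depth_normalization",
         [info.left_depth_norm.dmin, info.left_depth_norm.dmax]),
    ]
    lines += list(info.extras.items())
    text = "".join(
        f"{KEY_ALIASES.get(key, key)}: "
        + " ".join(f"{float(x):.12g}" for x in np.atleast_1d(values)) + "\n"
        for key, values in lines
    )
    path = Path(path)
    path.write_text(text)
    return path


def read_info(path: str | Path) -> InfoFile:
    """Parse an info TXT (whitespace tolerant; unknown keys kept as extras)."""
    values: dict[str, np.ndarray] = {}
    extras: dict[str, np.ndarray] = {}
    reverse = {v: k for k, v in KEY_ALIASES.items()}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise DatasetIOError(f"{path}:{lineno}: expected 'key: values'")
        key, _, rest = line.partition(":")
        key = reverse.get(key.strip(), key.strip())
        try:
            vec = np.array([float(tok) for tok in rest.split()])
        except ValueError as exc:
            raise DatasetIOError(f"{path}:{lineno}: non-numeric value") from exc
        (values if key in _MANDATORY_KEYS else extras)[key] = vec
    missing = [k for k in _MANDATORY_KEYS if k not in values]
    if missing:
        raise DatasetIOError(f"{path}: missing mandatory key(s) {missing}")

    cams = {
        side: CameraInfo(
            position_world=values[f"{side}_position_world"],
            position_head=values[f"{side}_position_head"],
            quaternion_world=values[f"{side}_quaternion_world"],
            quaternion_head=values[f"{side}_quaternion_head"],
        )
        for side in ("left", "cyc", "right")
    }
    gaze = values["gaze_version_elevation_vergence"]
    info = InfoFile(
        head_position=values["head_position"],
        head_target=values["head_target"],
        head_quaternion_world=values["head_quaternion_world"],
        cameras=cams,
        gaze_version=float(gaze[0]), gaze_elevation=float(gaze[1]),
        gaze_vergence=float(gaze[2]),
        gaze_quaternion_world=values["gaze_quaternion_world"],
        gaze_quaternion_head=values["gaze_quaternion_head"],
        cyc_depth_norm=DepthNormalization(*values["cyc_depth_normalization"]),
        left_depth_norm=DepthNormalization(*values["left_depth_normalization"]),
        extras=extras,
    )
    info.validate()
    return info
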