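"""The acquisition protocol: head vantage points, gaze grid, full enumeration.

For each scene the head orbits the scene centre at a configurable distance
(default 1,550 mm) over 5 azimuths (-60..60 degrees, step 30) x 2
elevations (30, 45 degrees), nose pointing at the centre.  From every
vantage point a 9 x 15 grid of cyclopic image points is projected onto the
scene; each surface intersection becomes a binocular fixation, and each
fixation is emitted twice (plain and mirrored), giving
``scenes x 10 x 135 x 2`` records when every grid ray hits — 5,400 for two
scenes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from . import dataset_io
from .geometry import BinocularState, HeadState, fixate
from .groundtruth import (depth_edge_map, disparity_from_cyclopic,
                          disparity_from_left, mirrored_disparity, occlusion_map)
from .render import CameraIntrinsics, fixation_targets, render
from .scene import Scene

__all__ = [
    "ProtocolConfig",
    "VantagePoint",
    "FixationRecord",
    "vantage_points",
    "enumerate_protocol",
    "count_records",
    "run_protocol",
    "warp_validation_samples",
]

logger = logging.getLogger(__name__)

AZIMUTHS_DEG = (-60.0, -30.0, 0.0, 30.0, 60.0)
ELEVATIONS_DEG = (30.0, 45.0)
#: soft expectation for the protocol's viewing range, mm (logged, not enforced)
EXPECTED_DEPTH_RANGE_MM = (500.0, 2200.0)


@dataclass
class ProtocolConfig:
    """All knobs of the acquisition protocol (text-serialisable)."""

    baseline: float = 60.0
    delta: float = 0.8
    listing_mode: str = "l2"
    grid_rows: int = 9
    grid_cols: int = 15
    azimuths_deg: tuple = AZIMUTHS_DEG
    elevations_deg: tuple = ELEVATIONS_DEG
    distance: float = 1550.0
    width: int = 480
    height: int = 270
    hfov: float = 40.0
    vfov: float | None = None
    near: float = 400.0
    far: float = 3000.0
    seed: int = 0

    @property
    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(width=self.width, height=self.height,
                                hfov=self.hfov, vfov=self.vfov,
                                near=self.near, far=self.far)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["azimuths_deg"] = list(self.azimuths_deg)
        d["elevations_deg"] = list(self.elevations_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        for key in ("azimuths_deg", "elevations_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VantagePoint:
    """One head placement: scene label, orbit indices, resulting head state."""

    scene_label: str
    azimuth_index: int     # -2..2  <->  -60..60 degrees, step 30
    elevation_index: int   # 1..2   <->  30, 45 degrees
    azimuth_deg: float
    elevation_deg: float
    head: HeadState


@dataclass
class FixationRecord:
    """One protocol entry: where the head is, what it fixates, its pose."""

    scene_label: str
    vantage: VantagePoint
    h_index: int   # -7..7, gaze azimuth within the grid
    v_index: int   # -4..4, gaze elevation within the grid
    fixation: np.ndarray
    state: BinocularState
    mirrored: bool


def vantage_points(scene: Scene, distance: float = 1550.0,
                   azimuths_deg=AZIMUTHS_DEG, elevations_deg=ELEVATIONS_DEG,
                   scene_label: str = "K") -> list[VantagePoint]:
    """Head placements orbiting the scene centre, nose toward the centre.

    The head's Fick elevation is the negative of the orbit elevation (the
    head sits above the table looking down); by construction the nose
    direction passes through the scene centre.
    """
    center = scene.center
    out = []
    for a_idx, az in enumerate(azimuths_deg):
        for e_idx, el in enumerate(elevations_deg):
            head = HeadState(position=np.zeros(3), elevation=-el, azimuth=az)
            head = HeadState(position=center - distance * head.nose_direction,
                             elevation=-el, azimuth=az)
            out.append(VantagePoint(
                scene_label=scene_label,
                azimuth_index=a_idx - (len(azimuths_deg) - 1) // 2,
                elevation_index=e_idx + 1,
                azimuth_deg=az, elevation_deg=el, head=head,
            ))
    return out


def _grid_indices(config: ProtocolConfig):
    """(row, col) traversal order and the (v, h) indices they map to.

    Columns follow gaze azimuth (#h, -7..7) and rows gaze elevation
    (#v, -4..4, positive up = top image rows); emission is #v then #h
    ascending.
    """
    rows, cols = config.grid_rows, config.grid_cols
    v_max = rows - 1 - rows // 2
    for v in range(-(rows // 2), v_max + 1):
        i = v_max - v  # top image row carries the highest gaze elevation
        for h in range(-(cols // 2), cols - cols // 2):
            j = h + cols // 2
            yield i, j, v, h


def enumerate_protocol(scenes: list[tuple[str, Scene]],
                       config: ProtocolConfig | None = None
                       ) -> Iterator[FixationRecord]:
    """Yield every fixation record in deterministic order.

    Order: scene, vantage point (azimuth then elevation), gaze elevation
    #v, gaze azimuth #h, then the mirrored copy of each record.  Grid rays
    that miss all geometry are skipped (and logged); the reference worlds
    never miss, synthetic ones may.
    """
    config = config or ProtocolConfig()
    intr = config.intrinsics
    for label, scene in scenes:
        if not scene.meshes or scene.n_triangles == 0:
            logger.warning("scene %s is empty: no records emitted", label)
            continue
        for vantage in vantage_points(scene, config.distance,
                                      config.azimuths_deg, config.elevations_deg,
                                      scene_label=label):
            cyclopic_pose = vantage.head.pose  # cyclopic camera at head origin
            points, hit = fixation_targets(scene, cyclopic_pose, intr,
                                           config.grid_rows, config.grid_cols)
            for i, j, v, h in _grid_indices(config):
                if not hit[i, j]:
                    logger.info("grid point (v=%d, h=%d) at %s misses the scene",
                                v, h, label)
                    continue
                state = fixate(vantage.head, points[i, j], config.baseline,
                               config.delta, config.listing_mode)
                for mirrored in (False, True):
                    yield FixationRecord(
                        scene_label=label, vantage=vantage, h_index=h,
                        v_index=v, fixation=points[i, j], state=state,
                        mirrored=mirrored,
                    )


def count_records(scenes, config: ProtocolConfig | None = None) -> int:
    return sum(1 for _ in enumerate_protocol(scenes, config))


def warp_validation_samples(scenes, config: ProtocolConfig,
                            max_samples: int | None = None,
                            stride: int = 1):
    """Render protocol fixations into scorable warp samples.

    Walks the (unmirrored) protocol records, optionally subsampling every
    ``stride``-th one, and for each renders the left and right views,
    derives the left-referenced ground-truth disparity with its occlusion
    and depth-edge maps, and yields a
    :class:`~stereofix.validation.WarpSample`.
    """
    from .validation import WarpSample, to_gray

    intr = config.intrinsics
    scene_by_label = dict(scenes)
    emitted = 0
    for k, record in enumerate(
            r for r in enumerate_protocol(scenes, config) if not r.mirrored):
        if k % stride:
            continue
        scene = scene_by_label[record.scene_label]
        state = record.state
        res_l = render(scene, state.left.pose_world, intr)
        res_r = render(scene, state.right.pose_world, intr)
        disp = disparity_from_left(res_l.depth, state, intr, res_l.valid)
        yield WarpSample(
            left_gray=to_gray(res_l.image), right_gray=to_gray(res_r.image),
            disparity=disp, occlusion=occlusion_map(disp),
            depth_edges=depth_edge_map(disp), left_valid=res_l.valid,
            right_valid=res_r.valid,
            label=(f"{record.scene_label}_HP_{record.vantage.azimuth_index}_"
                   f"{record.vantage.elevation_index}_H_{record.h_index}_"
                   f"V_{record.v_index}"),
        )
        emitted += 1
        if max_samples is not None and emitted >= max_samples:
            return


def run_protocol(scenes: list[tuple[str, Scene]], config: ProtocolConfig,
                 output_dir: str | Path) -> dict:
    """Render and write the full dataset for the given scenes.

    Per plain record: left/right/cyclopic PNGs, cyclopic and left 16-bit
    depth PNGs, the info TXT, cyclopic and left disparity binaries and
    occlusion/depth-edge masks.  The mirrored twin adds only the mirrored
    cyclopic disparity binaries (``mircycdispx/y``), matching how the
    protocol doubles the record count without re-rendering.  Returns the
    manifest (also written as ``manifest.json``).
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    intr = config.intrinsics
    manifest: dict = {"config": config.to_dict(), "records": []}
    cache: dict = {}
    depth_seen: list[float] = [np.inf, -np.inf]

    for record in enumerate_protocol(scenes, config):
        scene = dict(scenes)[record.scene_label]
        paths = dataset_io.record_paths(
            record.scene_label, record.vantage.azimuth_index,
            record.vantage.elevation_index, record.h_index, record.v_index)
        folder = output_dir / paths.folder
        folder.mkdir(exist_ok=True)
        state = record.state
        key = (record.scene_label, record.vantage.azimuth_index,
               record.vantage.elevation_index, record.h_index, record.v_index)

        if not record.mirrored:
            res_l = render(scene, state.left.pose_world, intr)
            res_r = render(scene, state.right.pose_world, intr)
            res_c = render(scene, state.cyclopic.pose_world, intr)
            cache = {"key": key, "lam_c": res_c.depth, "valid_c": res_c.valid}

            disp_c = disparity_from_cyclopic(res_c.depth, state, intr, res_c.valid)
            disp_l = disparity_from_left(res_l.depth, state, intr, res_l.valid)
            occ_c = occlusion_map(disp_c)
            occ_l = occlusion_map(disp_l)
            edge_c = depth_edge_map(disp_c)
            edge_l = depth_edge_map(disp_l)

            for name, img in (("left", res_l.image), ("right", res_r.image),
                              ("cyc", res_c.image)):
                dataset_io.write_image_png(img, folder / paths.files[name])
            norm_c = dataset_io.write_depth_png(res_c.depth,
                                                folder / paths.files["cycdepth"])
            norm_l = dataset_io.write_depth_png(res_l.depth,
                                                folder / paths.files["leftdepth"])
            for name, arr in (("cycdispx", disp_c.dx), ("cycdispy", disp_c.dy),
                              ("leftdispx", disp_l.dx), ("leftdispy", disp_l.dy)):
                dataset_io.write_disparity_bin(arr, folder / paths.files[name])
            for name, bm in (("cycocc", occ_c), ("leftocc", occ_l),
                             ("cycedges", edge_c), ("leftedges", edge_l)):
                dataset_io.write_mask_png(bm.mask, folder / paths.files[name])
            info = dataset_io.info_from_state(state, norm_c, norm_l)
            dataset_io.write_info(info, folder / paths.files["info"])

            d = np.abs(res_c.depth[res_c.valid])
            if d.size:
                depth_seen[0] = min(depth_seen[0], float(d.min()))
                depth_seen[1] = max(depth_seen[1], float(d.max()))
        else:
            if cache.get("key") != key:
                raise RuntimeError(f"mirrored record {key} arrived without its twin")
            disp_m = mirrored_disparity(cache["lam_c"], state, intr,
                                        cache["valid_c"])
            for name, arr in (("mircycdispx", disp_m.dx),
                              ("mircycdispy", disp_m.dy)):
                dataset_io.write_disparity_bin(arr, folder / paths.files[name])

        manifest["records"].append({
            "scene": record.scene_label,
            "a": record.vantage.azimuth_index, "e": record.vantage.elevation_index,
            "h": record.h_index, "v": record.v_index,
            "mirrored": record.mirrored, "folder": paths.folder,
        })

    if np.isfinite(depth_seen[0]):
        lo, hi = EXPECTED_DEPTH_RANGE_MM
        if depth_seen[0] < lo * 0.8 or depth_seen[1] > hi * 1.2:
            logger.warning(
                "observed depth range [%.0f, %.0f] mm departs from the "
                "protocol's expected ~[%.0f, %.0f] mm", *depth_seen, lo, hi)
        else:
            logger.info("observed depth range [%.0f, %.0f] mm", *depth_seen)
        manifest["depth_range_mm"] = depth_seen

    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
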