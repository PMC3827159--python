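"""File formats: multi-page TIFF stacks, JSON transforms/ROIs, YAML
configs, and a raw ``.npy`` sidecar for dense displacement fields."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .cnr import ROISet
from .elastic import BSplineDeformation
from .motion_contrast import MotionContrastMap
from .rigid import FrameStack, RigidTransform
from .synthetic import GroundTruth, MotionConfig, SceneConfig

__all__ = [
    "read_stack", "write_stack", "write_map",
    "write_transforms", "read_transforms",
    "write_deformations", "read_deformations",
    "write_roiset", "read_roiset", "roiset_from_points_csv",
    "write_configs", "read_configs",
    "write_ground_truth",
]


def read_stack(path, frame_rate_hz: float = 32.0) -> FrameStack:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError("expected a multi-page TIFF stack, got a single page")
    return FrameStack(arr.astype(np.float64), frame_rate_hz)


def write_stack(path, stack: FrameStack) -> None:
    """8-bit multi-page TIFF (values rounded and clipped)."""
    data = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_map(path_tiff, m: MotionContrastMap, path_png=None) -> None:
    """32-bit float variance TIFF plus optional 8-bit PNG rendering."""
    tifffile.imwrite(path_tiff, m.values.astype(np.float32))
    if path_png is not None:
        iio.imwrite(path_png, m.display)


def write_transforms(path, transforms: list[RigidTransform]) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in transforms], indent=1))


def read_transforms(path) -> list[RigidTransform]:
    return [RigidTransform.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_deformations(path, deformations: list[BSplineDeformation]) -> None:
    Path(path).write_text(json.dumps([d.to_dict() for d in deformations]))


def read_deformations(path) -> list[BSplineDeformation]:
    return [BSplineDeformation.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_roiset(path, rois: ROISet) -> None:
    Path(path).write_text(json.dumps(rois.to_dict(), indent=1))


def read_roiset(path) -> ROISet:
    return ROISet.from_dict(json.loads(Path(path).read_text()))


def roiset_from_points_csv(polyline_csv, squares_csv) -> ROISet:
    """Import an ROI set from ImageJ-style point lists: one CSV of
    polyline x,y vertices and one CSV of square top-left x,y corners."""
    poly = np.loadtxt(polyline_csv, delimiter=",", ndmin=2)
    sq = np.loadtxt(squares_csv, delimiter=",", ndmin=2)
    return ROISet(poly[:, :2], [tuple(row[:2]) for row in sq])


def write_configs(path, scene: SceneConfig, motion: MotionConfig) -> None:
    doc = {
        "scene": dataclasses.asdict(scene),
        "motion": dataclasses.asdict(motion),
    }
    doc["motion"]["intraframe_grid"] = list(doc["motion"]["intraframe_grid"])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_configs(path) -> tuple[SceneConfig, MotionConfig]:
    doc = yaml.safe_load(Path(path).read_text())
    m = doc.get("motion", {})
    if "intraframe_grid" in m:
        m["intraframe_grid"] = tuple(m["intraframe_grid"])
    return SceneConfig(**doc.get("scene", {})), MotionConfig(**m)


def write_ground_truth(json_path, truth: GroundTruth, fields_path=None) -> None:
    """Transforms, tracks and ROIs as JSON; the dense displacement
    fields go to a binary ``.npy`` sidecar."""
    doc = {
        "rigid_transforms": [t.to_dict() for t in truth.rigid_transforms],
        "particle_tracks": truth.particle_tracks.tolist(),
        "roi_set": truth.roi_set.to_dict() if truth.roi_set is not None else None,
        "displacement_fields_sidecar": str(fields_path) if fields_path else None,
    }
    Path(json_path).write_text(json.dumps(doc))
    if fields_path is not None:
        np.save(fields_path, truth.displacement_fields.astype(np.float32))
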