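"""Serialization: JSON pullback documents, CSV alignment and ground truth.

Pullback annotations nest per frame (contour point lists, branch boxes, a
180-flag calcium arc), so they are stored as a JSON document with strict,
frame-naming validation. Alignment results and phantom ground truth are
flat, diffable CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .phantom import GroundTruth
from .pipeline import CoregistrationResult
from .pullback import BranchBox, CalciumArc, Contour, Frame, N_ANGLE_BINS, Pullback

ALIGNMENT_COLUMNS = (
    "ivus_frame",
    "oct_frame_continuous",
    "rotation_deg",
    "is_path_node",
    "is_landmark",
)


def write_pullback(pullback: Pullback, path) -> None:
    doc = {
        "modality": pullback.modality,
        "frame_spacing_mm": pullback.frame_spacing_mm,
        "frames": [
            {
                "index": int(f.index),
                "position_mm": float(f.position_mm),
                "is_ed": bool(f.is_ed),
                "contour": np.asarray(f.lumen.points).round(6).tolist(),
                "branches": [
                    {
                        "center": [float(b.center[0]), float(b.center[1])],
                        "width": float(b.width),
                        "height": float(b.height),
                    }
                    for b in f.branches
                ],
                "calcium": f.calcium.flags.astype(int).tolist(),
            }
            for f in pullback.frames
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def _frame_from_record(rec: dict, modality: str, pos: int) -> Frame:
    where = f"frame record {pos}"
    for key in ("index", "position_mm", "is_ed", "contour", "branches", "calcium"):
        if key not in rec:
            raise SchemaError(f"{where}: missing field {key!r}")
    calcium = rec["calcium"]
    if len(calcium) != N_ANGLE_BINS:
        raise SchemaError(
            f"{where} (index {rec['index']}): calcium has {len(calcium)} flags, "
            f"expected {N_ANGLE_BINS}"
        )
    try:
        return Frame(
            modality=modality,
            index=int(rec["index"]),
            position_mm=float(rec["position_mm"]),
            is_ed=bool(rec["is_ed"]),
            lumen=Contour(np.asarray(rec["contour"], dtype=float)),
            branches=tuple(
                BranchBox((b["center"][0], b["center"][1]), b["width"], b["height"])
                for b in rec["branches"]
            ),
            calcium=CalciumArc(np.asarray(calcium)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where} (index {rec.get('index')}): {exc}") from exc


def read_pullback(path) -> Pullback:
    """Read and strictly validate a JSON pullback document."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("modality", "frame_spacing_mm", "frames"):
        if key not in doc:
            raise SchemaError(f"{path}: missing top-level field {key!r}")
    frames = [
        _frame_from_record(rec, doc["modality"], pos)
        for pos, rec in enumerate(doc["frames"])
    ]
    try:
        return Pullback(doc["modality"], tuple(frames), float(doc["frame_spacing_mm"]))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_alignment(result: CoregistrationResult, path) -> None:
    """Write a co-registration result as the flat alignment CSV."""
    df = pd.DataFrame(
        {
            "ivus_frame": result.ivus_frames,
            "oct_frame_continuous": np.round(result.oct_frame_continuous, 6),
            "rotation_deg": np.round(result.rotation_deg, 6),
            "is_path_node": result.is_path_node.astype(int),
            "is_landmark": result.is_landmark.astype(int),
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_alignment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    return df


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Ground-truth CSV: one row per IVUS frame with its true OCT match."""
    from .phantom import true_correspondence

    idx, rot = true_correspondence(gt)
    df = pd.DataFrame(
        {
            "ivus_frame": np.arange(len(gt.ivus_s)),
            "true_oct_index": np.round(idx, 6),
            "true_rotation_deg": np.round(rot, 6),
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"ivus_frame", "true_oct_index", "true_rotation_deg"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    return df
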