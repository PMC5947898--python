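"""Disk formats: PNG frame sequences, landmark CSV tracks, JSON sidecars.

A clip directory holds zero-padded PNG frames (``frame_000001.png`` ...)
plus a ``scene.json`` sidecar with the frame rate, size and seed; landmark
tracks are CSV with columns ``frame,point_id,x,y``; ground truth and
models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import FrameStack, LandmarkTrack

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_landmark_track",
    "read_landmark_track",
    "write_truth",
    "write_mesh",
    "read_mesh",
    "patch_count_table",
]


def write_frame_stack(stack: FrameStack, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(stack.n_frames):
        iio.imwrite(out / f"frame_{i + 1:06d}.png", stack.frames[i])
    sidecar = {
        "frame_rate": stack.frame_rate,
        "size": list(stack.frame_size),
        "n_frames": stack.n_frames,
        **{k: v for k, v in stack.meta.items() if isinstance(v, (int, float, str))},
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_frame_stack(in_dir: str | Path) -> FrameStack:
    src = Path(in_dir)
    sidecar = json.loads((src / "scene.json").read_text())
    paths = sorted(src.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {src}")
    frames = np.stack([iio.imread(p) for p in paths])
    if frames.ndim == 3:  # grayscale sequence
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return FrameStack(frames.astype(np.uint8), float(sidecar["frame_rate"]), meta=sidecar)


def write_landmark_track(track: LandmarkTrack, path: str | Path) -> Path:
    n_frames, k, _ = track.points.shape
    frames = np.repeat(np.arange(n_frames), k)
    points = np.tile(np.arange(k), n_frames)
    flat = track.points.reshape(-1, 2)
    df = pd.DataFrame(
        {"frame": frames, "point_id": points, "x": flat[:, 0], "y": flat[:, 1]}
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_landmark_track(path: str | Path) -> LandmarkTrack:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1
    k = int(df["point_id"].max()) + 1
    pts = np.full((n_frames, k, 2), np.nan)
    pts[df["frame"].to_numpy(), df["point_id"].to_numpy(), 0] = df["x"].to_numpy()
    pts[df["frame"].to_numpy(), df["point_id"].to_numpy(), 1] = df["y"].to_numpy()
    return LandmarkTrack(pts)


def write_truth(truth, path: str | Path) -> Path:
    payload = {
        "hr_true": truth.hr_true,
        "pulse_signal": np.asarray(truth.pulse_signal).tolist(),
        "unstable_landmark_ids": list(truth.unstable_landmark_ids),
        "patch_stability_labels": np.asarray(
            truth.patch_stability_labels, dtype=bool
        ).tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def write_mesh(mesh, path: str | Path) -> Path:
    """Triangle mesh as JSON (list of landmark-index triples)."""
    path = Path(path)
    path.write_text(json.dumps({"triangles": mesh.vertex_ids.tolist()}))
    return path


def read_mesh(path: str | Path):
    from .patch_mesh import TriangleMesh

    d = json.loads(Path(path).read_text())
    return TriangleMesh(np.array(d["triangles"], dtype=int))


def patch_count_table(track_set) -> pd.DataFrame:
    """Long-form per-frame pixel counts: frame, triangle_id, pixel_count."""
    rows = []
    for track in track_set.tracks:
        for frame, count in enumerate(track.counts):
            rows.append(
                {
                    "frame": frame,
                    "triangle_id": track.triangle_id,
                    "pixel_count": int(count),
                }
            )
    return pd.DataFrame(rows)
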