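"""Text file formats for tracking streams and digitization sessions.

Sessions: line-oriented ``kind label x y z`` (mm, head frame), ``#``
comments, fixed 6-decimal formatting.  Streams: a delimited table with
header ``t,receiver,x,y,z,error_index`` (error_index blank when absent;
unit-quaternion columns ``qw,qx,qy,qz`` appended for 6-DOF receivers).
Round-trips are lossless at 1e-6 mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .digitize import CARDINAL_LABELS, DigitizationSession, DigitizedPoint
from .emt_sim import TrackingStream

__all__ = [
    "write_session",
    "read_session",
    "write_stream",
    "read_stream",
    "SessionParseError",
]


class SessionParseError(ValueError):
    pass


def write_session(session: DigitizationSession, path) -> None:
    path = Path(path)
    lines = ["# emtdig digitization session (head frame, mm)"]
    for p in session.points:
        x, y, z = p.position
        lines.append(f"{p.kind} {p.label} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_session(path) -> DigitizationSession:
    path = Path(path)
    points: list[DigitizedPoint] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise SessionParseError(
                f"{path}:{lineno}: expected 'kind label x y z', got {raw!r}"
            )
        kind, label = parts[0], parts[1]
        try:
            pos = np.array([float(v) for v in parts[2:]])
        except ValueError as exc:
            raise SessionParseError(f"{path}:{lineno}: bad coordinate: {exc}") from exc
        points.append(DigitizedPoint(label, kind, pos, frame="head"))
    labels = {p.label for p in points if p.kind == "cardinal"}
    missing = [lab for lab in CARDINAL_LABELS if lab not in labels]
    if missing:
        raise SessionParseError(
            f"{path}: missing cardinal point(s): {', '.join(missing)}"
        )
    return DigitizationSession(tuple(points))


def write_stream(stream: TrackingStream, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": [f"{v:.6f}" for v in stream.t],
            "receiver": stream.receiver_id,
            "x": [f"{v:.6f}" for v in stream.positions[:, 0]],
            "y": [f"{v:.6f}" for v in stream.positions[:, 1]],
            "z": [f"{v:.6f}" for v in stream.positions[:, 2]],
            "error_index": (
                [""] * len(stream)
                if stream.error_index is None
                else [f"{v:.6f}" for v in stream.error_index]
            ),
        }
    )
    if stream.orientations is not None:
        # scalar-last quaternions stored scalar-first for readability
        df["qw"] = [f"{v:.9f}" for v in stream.orientations[:, 3]]
        df["qx"] = [f"{v:.9f}" for v in stream.orientations[:, 0]]
        df["qy"] = [f"{v:.9f}" for v in stream.orientations[:, 1]]
        df["qz"] = [f"{v:.9f}" for v in stream.orientations[:, 2]]
    df.to_csv(path, index=False)


def read_stream(path, rate: float | None = None) -> TrackingStream:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"t", "receiver", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    receivers = df["receiver"].unique()
    if len(receivers) != 1:
        raise ValueError(
            f"{path}: one stream file per receiver; found {sorted(map(str, receivers))}"
        )
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    ei = None
    if "error_index" in df.columns and not df["error_index"].isna().all():
        ei = df["error_index"].to_numpy(dtype=float)
    quat = None
    if {"qw", "qx", "qy", "qz"}.issubset(df.columns):
        quat = df[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return TrackingStream(
        t,
        df[["x", "y", "z"]].to_numpy(dtype=float),
        rate=rate,
        receiver_id=str(receivers[0]),
        error_index=ei,
        orientations=quat,
    )
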