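"""Cluster-based digitization of continuous tracking streams.

The pipeline mirrors how a switchless EMT stylus is turned into discrete
digitization points: the stylus stream is first re-expressed relative to the
head-bound reference receiver (movement compensation), low-quality samples
are optionally discarded using the per-sample error index, dwell clusters
are detected as time-contiguous runs of samples staying within a small
radius, each cluster is averaged to a single point, labels are assigned in
dwell order, and finally everything is expressed in the head coordinate
frame constructed from the three cardinal points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .emt_sim import TrackingStream
from .geometry import FiducialSet, RigidTransform, head_frame_from_fiducials

__all__ = [
    "Cluster",
    "DigitizedPoint",
    "DigitizationSession",
    "ClusterCountMismatchError",
    "compensate_reference",
    "filter_error_index",
    "detect_clusters",
    "depth_compensate",
    "run_session",
]

CARDINAL_LABELS = ("nasion", "lpa", "rpa")


@dataclass(frozen=True)
class Cluster:
    """A detected stylus dwell: member sample indices and their centroid."""

    indices: np.ndarray
    centroid: np.ndarray
    spread: float  # max member-to-centroid distance (mm)
    mean_error_index: float | None = None

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class DigitizedPoint:
    label: str
    kind: str
    position: np.ndarray  # mm
    frame: str = "head"  # global | reference | head

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass(frozen=True)
class DigitizationSession:
    """Labeled digitized points in the head frame plus provenance metadata."""

    points: tuple[DigitizedPoint, ...]
    head_transform: RigidTransform | None = None  # reference -> head
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        cardinals = [p for p in self.points if p.kind == "cardinal"]
        if len(cardinals) != 3:
            raise ValueError(
                f"session must contain exactly 3 cardinal points, got {len(cardinals)}"
            )

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    def point(self, label: str) -> DigitizedPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(label)


class ClusterCountMismatchError(ValueError):
    def __init__(self, n_clusters: int, n_labels: int):
        self.n_clusters = n_clusters
        self.n_labels = n_labels
        super().__init__(
            f"detected {n_clusters} clusters but {n_labels} labels were expected"
        )


def compensate_reference(
    stylus: TrackingStream, reference: TrackingStream
) -> TrackingStream:
    """Re-express the stylus stream in the reference receiver's frame.

    Compensates head (fixture) movement during digitization: each stylus
    sample is mapped through the simultaneous reference pose.  When the
    reference stream carries orientations the full rigid pose is inverted;
    a position-only reference yields translation compensation.  A motionless
    reference at pose (I, r) reduces to subtracting the constant r.
    """
    if len(stylus) != len(reference):
        raise ValueError(
            f"sample counts differ: stylus {len(stylus)} vs reference {len(reference)}"
        )
    if np.max(np.abs(stylus.t - reference.t), initial=0.0) > 1e-6:
        raise ValueError("stylus and reference timestamps are not aligned")
    delta = stylus.positions - reference.positions
    if reference.orientations is not None:
        rot = Rotation.from_quat(reference.orientations)
        out = rot.inv().apply(delta)
    else:
        out = delta
    return TrackingStream(
        stylus.t,
        out,
        rate=stylus.rate,
        receiver_id=stylus.receiver_id,
        error_index=stylus.error_index,
    )


def filter_error_index(stream: TrackingStream, max_index: float) -> TrackingStream:
    """Drop samples whose error index exceeds ``max_index`` (order kept)."""
    if stream.error_index is None:
        raise ValueError("stream carries no error index")
    return stream.subset(stream.error_index <= max_index)


def detect_clusters(
    stream: TrackingStream,
    radius: float = 1.0,
    min_count: int = 100,
    rule: str = "centroid",
) -> list[Cluster]:
    """Detect stylus dwells as time-contiguous compact runs of samples.

    A sample joins the current run if its distance to the running centroid
    (``rule='centroid'``, default) or to every current member
    (``rule='pairwise'``) is <= ``radius`` mm; otherwise the run is closed
    and kept as a cluster when it has at least ``min_count`` samples.
    Clusters are returned in time order and each sample belongs to at most
    one cluster.
    """
    if len(stream) == 0:
        raise ValueError("stream is empty")
    if rule not in ("centroid", "pairwise"):
        raise ValueError(f"unknown rule {rule!r}")
    pos = stream.positions
    clusters: list[Cluster] = []
    start = 0
    csum = pos[0].copy()
    count = 1

    def close(start: int, stop: int):
        if stop - start >= min_count:
            members = np.arange(start, stop)
            centroid = pos[members].mean(axis=0)
            spread = float(
                np.linalg.norm(pos[members] - centroid, axis=1).max()
            )
            mei = None
            if stream.error_index is not None:
                mei = float(stream.error_index[members].mean())
            clusters.append(Cluster(members, centroid, spread, mei))

    for k in range(1, len(stream)):
        if rule == "centroid":
            ok = np.linalg.norm(pos[k] - csum / count) <= radius
        else:
            ok = np.all(
                np.linalg.norm(pos[start:k] - pos[k], axis=1) <= radius
            )
        if ok:
            csum += pos[k]
            count += 1
        else:
            close(start, k)
            start, csum, count = k, pos[k].copy(), 1
    close(start, len(stream))
    return clusters


def depth_compensate(
    p: DigitizedPoint, outward_normal, depth: float = 2.0
) -> DigitizedPoint:
    """Correct a blunt-tip measurement of an excavated point.

    The stylus tip rests ``depth`` mm above the true point along the outward
    surface normal; the correction moves the measured position by
    ``-depth * normal``.
    """
    n = np.asarray(outward_normal, dtype=float).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("outward normal must be unit length")
    return replace(p, position=p.position - depth * n)


def run_session(
    stylus: TrackingStream,
    reference: TrackingStream | None,
    labels: list[tuple[str, str]],
    radius: float = 1.0,
    min_count: int = 100,
    max_error_index: float | None = None,
    depth: float = 0.0,
    normals=None,
    rule: str = "centroid",
    metadata: dict | None = None,
) -> DigitizationSession:
    """Full digitization pipeline from raw streams to a head-frame session.

    ``labels`` is the ordered list of ``(label, kind)`` the operator dwelt
    on; the first three must be the cardinals nasion, LPA, RPA.  Steps:
    movement compensation (skipped when ``reference`` is None), optional
    error-index filtering, cluster detection, per-cluster averaging, label
    assignment in dwell order, optional blunt-tip depth compensation (needs
    per-label ``normals``), then transformation of every point into the head
    frame built from the three cardinal centroids.
    """
    if len(labels) < 3:
        raise ValueError("need at least the three cardinal labels")
    kinds = dict(labels)
    first = [lab for lab, _ in labels[:3]]
    if sorted(first) != sorted(CARDINAL_LABELS) or any(
        kinds[lab] != "cardinal" for lab in first
    ):
        raise ValueError(
            "first three labels must be the cardinal points nasion/lpa/rpa"
        )

    stream = (
        compensate_reference(stylus, reference) if reference is not None else stylus
    )
    if max_error_index is not None:
        stream = filter_error_index(stream, max_error_index)
    clusters = detect_clusters(stream, radius=radius, min_count=min_count, rule=rule)
    if len(clusters) != len(labels):
        raise ClusterCountMismatchError(len(clusters), len(labels))

    pts = [
        DigitizedPoint(lab, kind, cl.centroid, frame="reference")
        for (lab, kind), cl in zip(labels, clusters)
    ]
    if depth != 0.0:
        if normals is None:
            raise ValueError("depth compensation requires per-label normals")
        pts = [
            depth_compensate(p, normals[p.label], depth) if p.label in normals else p
            for p in pts
        ]

    by_label = {p.label: p for p in pts}
    fids = FiducialSet(
        nasion=by_label["nasion"].position,
        lpa=by_label["lpa"].position,
        rpa=by_label["rpa"].position,
    )
    T = head_frame_from_fiducials(fids)
    head_pts = tuple(
        replace(p, position=T.apply(p.position), frame="head") for p in pts
    )
    meta = dict(metadata or {})
    meta.setdefault("n_clusters", len(clusters))
    meta.setdefault(
        "mean_cluster_error_index",
        None
        if clusters[0].mean_error_index is None
        else float(np.mean([c.mean_error_index for c in clusters])),
    )
    return DigitizationSession(head_pts, head_transform=T, metadata=meta)
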