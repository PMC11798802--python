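"""Consensus features, binary occurrence matrix, frequency-band thresholds.

Per-frame features are clustered class-by-class into consensus features by
greedy leader clustering (O(N*K), deterministic for a fixed frame order).
Each consensus feature carries the fraction of frames in which at least one
member occurs; the binary conformation x feature matrix therefore has column
means exactly equal to those frequencies.  Frequency bands retain only
features whose frequency lies in [low, high] — the rare-feature bands used
to focus the ranking on features of minority conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perception import PharmacophoreFeature

__all__ = [
    "ConsensusFeature",
    "OccurrenceMatrix",
    "build_consensus",
    "encode_binary",
    "threshold_by_frequency",
]


@dataclass
class ConsensusFeature:
    id: str
    cls: str
    center: tuple[float, float, float]
    radius: float
    frequency: float
    member_count: int
    member_frames: frozenset = field(default_factory=frozenset, repr=False)

    def __post_init__(self):
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must lie in (0, 1]")


@dataclass
class OccurrenceMatrix:
    """Binary frames x consensus-features table plus per-frame labels.

    Rows keep the original time order (the recurrence analysis depends on
    it); ``labels[i] = 1`` marks a binding-selected conformation.
    """

    data: pd.DataFrame          # index = frame_ids, columns = feature ids
    labels: np.ndarray
    frequencies: dict[str, float]
    features: dict[str, ConsensusFeature]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.data):
            raise ValueError("label vector length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["label"] = self.labels
        out.to_csv(path, index_label="frame_id")

    @classmethod
    def from_csv(cls, path) -> "OccurrenceMatrix":
        df = pd.read_csv(path, index_col="frame_id")
        labels = df.pop("label").to_numpy()
        freqs = {c: float(df[c].mean()) for c in df.columns}
        feats = {c: ConsensusFeature(c, c.split("_", 1)[-1], (0.0, 0.0, 0.0),
                                     1.0, max(freqs[c], 1e-12), int(df[c].sum()))
                 for c in df.columns}
        return cls(df.astype(int), labels, freqs, feats)


def build_consensus(per_frame_features: dict[int, list[PharmacophoreFeature]],
                    cluster_radius: float = 1.5) -> list[ConsensusFeature]:
    """Greedy leader clustering of all frames' features, per class.

    Features are visited class-by-class in frame order; a feature joins the
    first existing cluster of its class whose running centroid lies within
    ``cluster_radius``, else founds a new cluster.  Frequency counts the
    distinct frames contributing at least one member (a frame with two
    members of one cluster counts once).  Ids are assigned in descending
    frequency order: "F1_<class>" is the most frequent feature.
    """
    if cluster_radius <= 0:
        raise ValueError("cluster_radius must be > 0")
    n_frames = len(per_frame_features)
    frame_order = list(per_frame_features.keys())
    by_class: dict[str, list[tuple[int, PharmacophoreFeature]]] = {}
    for fid in frame_order:
        for feat in per_frame_features[fid]:
            by_class.setdefault(feat.cls, []).append((fid, feat))

    clusters = []  # (cls, centroid, members:[(fid, feat)])
    for cls in sorted(by_class):
        cls_clusters: list[dict] = []
        for fid, feat in by_class[cls]:
            pos = np.asarray(feat.center)
            joined = False
            for c in cls_clusters:
                if np.linalg.norm(c["centroid"] - pos) <= cluster_radius:
                    c["members"].append((fid, feat))
                    m = len(c["members"])
                    c["centroid"] = c["centroid"] + (pos - c["centroid"]) / m
                    joined = True
                    break
            if not joined:
                cls_clusters.append({"centroid": pos.copy(),
                                     "members": [(fid, feat)]})
        clusters.extend((cls, c) for c in cls_clusters)

    # order by descending frequency, ties by class then centroid
    def freq(c):
        return len({fid for fid, _ in c[1]["members"]}) / n_frames

    clusters.sort(key=lambda c: (-freq(c), c[0], tuple(c[1]["centroid"])))
    out = []
    for rank, (cls, c) in enumerate(clusters, start=1):
        frames = frozenset(fid for fid, _ in c["members"])
        radius = max(f.radius for _, f in c["members"])
        out.append(ConsensusFeature(
            id=f"F{rank}_{cls}", cls=cls, center=tuple(c["centroid"]),
            radius=float(radius), frequency=len(frames) / n_frames,
            member_count=len(c["members"]), member_frames=frames))
    return out


def encode_binary(consensus: list[ConsensusFeature],
                  per_frame_features: dict[int, list[PharmacophoreFeature]],
                  labels) -> OccurrenceMatrix:
    """Binary encoding: entry (i, k) = 1 iff frame i contributed >=1 member
    to consensus feature k.  Column means equal the consensus frequencies."""
    frame_ids = list(per_frame_features.keys())
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(frame_ids):
        raise ValueError(
            f"label vector length {len(labels)} != number of frames {len(frame_ids)}")
    data = pd.DataFrame(0, index=pd.Index(frame_ids, name="frame_id"),
                        columns=[c.id for c in consensus], dtype=int)
    for c in consensus:
        data.loc[list(c.member_frames), c.id] = 1
    freqs = {c.id: c.frequency for c in consensus}
    feats = {c.id: c for c in consensus}
    return OccurrenceMatrix(data, labels, freqs, feats)


def threshold_by_frequency(matrix: OccurrenceMatrix,
                           low: float | None = 0.01,
                           high: float | None = None) -> OccurrenceMatrix:
    """Retain the columns whose frequency lies in [low, high].

    ``high=None`` keeps everything above ``low``; ``low=None`` with
    ``high=None`` is the no-threshold run (all columns kept).
    """
    lo = 0.0 if low is None else float(low)
    hi = 1.0 if high is None else float(high)
    if lo > hi:
        raise ValueError(f"low {lo} > high {hi}")
    keep = [c for c in matrix.data.columns
            if lo <= matrix.frequencies[c] <= hi]
    return OccurrenceMatrix(
        matrix.data[keep].copy(), matrix.labels.copy(),
        {c: matrix.frequencies[c] for c in keep},
        {c: matrix.features[c] for c in keep})
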