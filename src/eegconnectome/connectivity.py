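"""Absolute-Pearson functional connectivity matrices.

Connectivity between two channels is the Pearson correlation of their
within-segment time series; the absolute value is taken per segment and the
per-segment matrices are averaged across all retained segments of a subject,
yielding a symmetric weighted adjacency matrix with zero diagonal and entries
in [0, 1].  Averaging |r| per segment (rather than correlating concatenated
data) damps nonstationarity across the recording.  The "local" scope is the
principal submatrix over the parietal electrode cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateVarianceError, MontageError
from .preprocess import SegmentedEEG


@dataclass
class ConnectivityMatrix:
    """Symmetric |Pearson r| adjacency with ordered electrode labels."""

    labels: tuple[str, ...]
    weights: np.ndarray
    scope: str = "global"       # "global" | "local"
    n_segments_used: int = 0

    def __post_init__(self):
        w = self.weights
        n = len(self.labels)
        if w.shape != (n, n):
            raise ConfigError(f"weights shape {w.shape} != ({n}, {n})")
        if np.isnan(w).any():
            raise ConfigError("connectivity matrix contains NaN")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ConfigError("connectivity matrix is not symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ConfigError("connectivity diagonal must be exactly zero")
        off = w[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ConfigError("off-diagonal weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("pearson needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ConfigError("pearson needs at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise DegenerateVarianceError("constant input vector in pearson")
    return float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))


def segment_matrix(segment: np.ndarray, labels: tuple[str, ...] | None = None,
                   scope: str = "global") -> ConnectivityMatrix:
    """|r| between every channel pair within one segment; diagonal zeroed."""
    segment = np.asarray(segment, float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ConfigError("segment must be a channels x samples matrix, >= 2 channels")
    if labels is None:
        labels = tuple(f"E{i + 1}" for i in range(segment.shape[0]))
    sd = segment.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateVarianceError(
            f"constant channel(s) in segment: {[labels[i] for i in dead]}"
        )
    r = np.corrcoef(segment)
    w = np.abs(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(labels=tuple(labels), weights=w, scope=scope,
                              n_segments_used=1)


def subject_matrix(seg: SegmentedEEG, scope: str = "global") -> ConnectivityMatrix:
    """Element-wise mean of per-segment |r| matrices over retained segments."""
    if seg.n_segments < 2:
        raise ConfigError(
            f"subject {seg.subject_id}: need >= 2 retained segments, "
            f"have {seg.n_segments}"
        )
    # batched equivalent of averaging segment_matrix() over segments
    x = seg.segments - seg.segments.mean(axis=2, keepdims=True)
    norms = np.sqrt(np.einsum("scw,scw->sc", x, x))
    dead = np.argwhere(norms == 0)
    if dead.size:
        s, c = dead[0]
        raise DegenerateVarianceError(
            f"constant channel {seg.labels[c]} in segment {s} of "
            f"subject {seg.subject_id}"
        )
    y = x / norms[:, :, None]
    r = np.matmul(y, np.swapaxes(y, 1, 2))
    acc = np.abs(np.clip(r, -1.0, 1.0)).mean(axis=0)
    acc = (acc + acc.T) / 2.0
    np.fill_diagonal(acc, 0.0)
    return ConnectivityMatrix(
        labels=seg.labels, weights=acc, scope=scope,
        n_segments_used=seg.n_segments,
    )


def extract_local(matrix: ConnectivityMatrix,
                  parietal_set: tuple[str, ...]) -> ConnectivityMatrix:
    """Principal submatrix over the parietal labels, in parietal order."""
    lookup = {lab: i for i, lab in enumerate(matrix.labels)}
    missing = [lab for lab in parietal_set if lab not in lookup]
    if missing:
        raise MontageError(f"labels absent from matrix: {missing}")
    idx = np.array([lookup[lab] for lab in parietal_set], dtype=int)
    sub = matrix.weights[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    return ConnectivityMatrix(
        labels=tuple(parietal_set), weights=sub, scope="local",
        n_segments_used=matrix.n_segments_used,
    )


def group_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Mean adjacency over subjects (reporting convenience)."""
    if not matrices:
        raise ConfigError("cannot average an empty list of matrices")
    labels = matrices[0].labels
    scope = matrices[0].scope
    for m in matrices[1:]:
        if m.labels != labels:
            raise ConfigError("matrices have mismatched labels")
    w = np.mean([m.weights for m in matrices], axis=0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        labels=labels, weights=w, scope=scope,
        n_segments_used=sum(m.n_segments_used for m in matrices),
    )


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Delimited matrix with a label header and a scope comment line."""
    with open(path, "w") as fh:
        fh.write(f"# scope={matrix.scope} n_segments_used={matrix.n_segments_used}\n")
        df = pd.DataFrame(matrix.weights, columns=list(matrix.labels))
        df.to_csv(fh, index=False, float_format="%.10g")


def read_matrix(path) -> ConnectivityMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            item.split("=") for item in header.lstrip("# ").split() if "=" in item
        )
        df = pd.read_csv(fh)
    w = df.to_numpy(float)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        labels=tuple(df.columns), weights=w,
        scope=meta.get("scope", "global"),
        n_segments_used=int(meta.get("n_segments_used", 0)),
    )
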