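"""Electrode montage: labels, 3-D sensor positions and the parietal subset.

The geodesic sensor net used for high-density recordings carries 256 scalp
electrodes labelled ``E1``..``E256`` plus a vertex reference ``Cz``; only the
256 scalp channels enter the networks.  No public coordinate file ships with
this package, so :func:`synthetic_montage` lays the sensors out
deterministically on the unit sphere (a Fibonacci lattice) — a synthetic
stand-in geometry whose only analytical role is providing neighbour distances
for bad-channel interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MontageError

#: Parietal electrode list as printed for the EGI numbering, verbatim order.
#: It contains 29 entries with electrodes 87 and 63 each appearing twice.
PARIETAL_LIST_RAW: tuple[int, ...] = (
    78, 87, 100, 101, 63, 142, 154, 35, 87, 99, 110, 119, 63, 141, 153, 163,
    86, 98, 109, 118, 127, 140, 152, 162, 96, 97, 108, 170, 161,
)

#: De-duplicated parietal labels in first-appearance order (27 electrodes).
PARIETAL_LABELS: tuple[str, ...] = tuple(
    dict.fromkeys(f"E{i}" for i in PARIETAL_LIST_RAW)
)


@dataclass(frozen=True)
class Montage:
    """Sensor labels plus unit-sphere positions; reference excluded."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) float, unit norm
    parietal_set: tuple[str, ...] = field(default=PARIETAL_LABELS)
    reference: str = "Cz"

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise MontageError("montage labels are not unique")
        if self.positions.shape != (len(self.labels), 3):
            raise MontageError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.labels)} labels"
            )
        missing = [p for p in self.parietal_set if p not in set(self.labels)]
        if missing:
            raise MontageError(f"parietal labels not in montage: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise MontageError(f"unknown electrode label: {exc.args[0]}") from exc

    @property
    def parietal_indices(self) -> np.ndarray:
        return self.index_of(self.parietal_set)


def default_parietal_labels(n_channels: int) -> tuple[str, ...]:
    """Parietal subset for a montage of ``n_channels`` sensors.

    The full 256-channel net uses the printed 27-electrode parietal cluster.
    Reduced montages (simulation scale-downs) keep the parietal fraction by
    taking ``max(4, round(27 * n/256))`` evenly spaced channels from the
    middle of the index range, which mimics a contiguous scalp patch.
    """
    if n_channels >= 256:
        return PARIETAL_LABELS
    k = max(4, round(27 * n_channels / 256))
    # a contiguous block centred in the channel range
    start = (n_channels - k) // 2
    return tuple(f"E{i + 1}" for i in range(start, start + k))


def synthetic_montage(
    n_channels: int = 256, parietal_set: tuple[str, ...] | None = None
) -> Montage:
    """Deterministic synthetic sensor layout on the unit sphere.

    Sensors are placed on a Fibonacci lattice restricted to the upper
    hemisphere-ish band (z > -0.3), roughly emulating scalp coverage.  The
    layout is synthetic: it is not the vendor's digitised geometry and is only
    used for distance-weighted interpolation of bad channels.
    """
    if n_channels < 2:
        raise MontageError("montage needs at least 2 channels")
    i = np.arange(n_channels, dtype=float)
    golden = (1 + 5**0.5) / 2
    # z spans the scalp band; azimuth steps by the golden angle
    z = 1.0 - 1.3 * (i + 0.5) / n_channels  # in (-0.3, 1)
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{k + 1}" for k in range(n_channels))
    if parietal_set is None:
        parietal_set = default_parietal_labels(n_channels)
    return Montage(labels=labels, positions=positions, parietal_set=parietal_set)


def write_montage(montage: Montage, path) -> None:
    """Write the montage as a delimited table (label, x, y, z)."""
    df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
    df.insert(0, "label", list(montage.labels))
    df.to_csv(path, index=False)


def read_montage(path, parietal_set: tuple[str, ...] | None = None) -> Montage:
    """Read a montage table written by :func:`write_montage`."""
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise MontageError(f"montage file {path} lacks columns {sorted(required)}")
    labels = tuple(df["label"].astype(str))
    if parietal_set is None:
        parietal_set = default_parietal_labels(len(labels))
    return Montage(
        labels=labels,
        positions=df[["x", "y", "z"]].to_numpy(float),
        parietal_set=parietal_set,
    )
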