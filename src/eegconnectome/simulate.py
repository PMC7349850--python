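"""Synthetic resting-state cohort with a known connectivity structure.

The study conditions emulated here are a four-group cohort (healthy controls
and three stages of the Alzheimer's continuum: subjective cognitive decline,
mild cognitive impairment, dementia) of high-density resting EEG recordings.
Each channel is a latent-factor mixture

    x_c(t) = signal_scale * ( a_c * s_P(t) + beta * s_G(t) + eps_c(t) )

where ``s_P`` (parietal cluster source) and ``s_G`` (whole-head common
source) are independent unit-variance AR(1) processes, ``eps_c`` is
independent AR(1) channel noise, and the parietal loading ``a_c`` equals the
group coupling ``alpha_g`` on parietal channels and 0 elsewhere.  The
population absolute correlation between two parietal channels is then the
closed form

    rho_P = (alpha_g**2 + beta**2) / (alpha_g**2 + beta**2 + noise_sd**2)

and ``beta**2 / (beta**2 + noise_sd**2)`` between two non-parietal channels,
which makes every downstream stage testable against an analytic oracle.  The
default couplings (1.9 / 1.5 / 1.4 / 1.2 with beta = 0.6) give parietal
correlations of roughly 0.80 / 0.72 / 0.70 / 0.64 — the monotone weakening
with disease stage that the analysis is designed to detect.

Occasional high-amplitude square-pulse artifacts and high-variance bad
channels are injected so the rejection and interpolation stages have real
work to do.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigError
from .montage import Montage, default_parietal_labels, synthetic_montage

GROUPS: tuple[str, ...] = ("HC", "SCD", "MCI", "AD")

_DEFAULT_GROUP_SIZES = {"HC": 22, "SCD": 20, "MCI": 30, "AD": 20}
_DEFAULT_COUPLING = {"HC": 1.9, "SCD": 1.5, "MCI": 1.4, "AD": 1.2}

#: analysis window length in samples, fixed by the segmentation convention
WINDOW_SAMPLES = 500


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (units in comments)."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_SIZES)
    )
    n_channels: int = 256
    fs: float = 250.0            # Hz
    duration_s: float = 120.0    # seconds per subject
    parietal_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUPLING)
    )
    global_coupling: float = 0.6     # beta, shared by all channels
    ar_coefficient: float = 0.95     # phi of the AR(1) sources/noise
    noise_sd: float = 1.0            # channel noise sd, source units
    signal_scale: float = 10.0       # uV per source unit
    artifact_rate: float = 0.05      # P(artifact) per 500-sample window
    artifact_amplitude: float = 150.0  # uV, must exceed the 100 uV threshold
    bad_channel_count: int = 2
    seed: int = 0
    parietal_labels: tuple[str, ...] | None = None  # None -> montage default

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g!r} needs >= 2 subjects, got {n}")
        for g, a in self.parietal_coupling.items():
            if not np.isfinite(a) or a < 0:
                raise ConfigError(f"parietal coupling for {g!r} must be >= 0")
        if not np.isfinite(self.global_coupling) or self.global_coupling < 0:
            raise ConfigError("global_coupling must be finite and >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigError("artifact_rate must lie in [0, 1]")
        if self.bad_channel_count < 0:
            raise ConfigError("bad_channel_count must be >= 0")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if self.n_samples // WINDOW_SAMPLES < 2:
            raise ConfigError(
                "fs * duration_s must cover at least 2 windows of "
                f"{WINDOW_SAMPLES} samples"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def n_windows(self) -> int:
        return self.n_samples // WINDOW_SAMPLES

    def resolved_parietal(self) -> tuple[str, ...]:
        if self.parietal_labels is not None:
            return tuple(self.parietal_labels)
        return default_parietal_labels(self.n_channels)

    def montage(self) -> Montage:
        return synthetic_montage(self.n_channels, self.resolved_parietal())


@dataclass
class EEGRecording:
    """One subject's multichannel signal block, in microvolts."""

    subject_id: str
    group: str
    data: np.ndarray          # (n_channels, n_samples), uV
    fs: float
    montage_ref: str = "synthetic-gsn"
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ConfigError("recording data must be channels x samples")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ConfigError(f"recording {self.subject_id} contains NaN")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class NeuropsychScores:
    """Per-subject synthetic neuropsychological battery values."""

    subject_id: str
    scores: dict[str, float]


def expected_abs_pcc(alpha: float, beta: float, noise_sd: float = 1.0) -> float:
    """Population |Pearson r| between two parietal channels of the model."""
    s = alpha * alpha + beta * beta
    return s / (s + noise_sd * noise_sd)


_DECAY_CACHE: dict[tuple[float, int], np.ndarray] = {}


def _ar1(rng: np.random.Generator, phi: float, shape) -> np.ndarray:
    """Stationary unit-variance AR(1) sample paths along the last axis."""
    shape = tuple(np.atleast_1d(shape))
    innov = rng.standard_normal(shape)
    innov *= np.sqrt(1.0 - phi * phi)
    x = lfilter([1.0], [1.0, -phi], innov, axis=-1)
    # add the stationary initial condition so there is no start-up transient
    key = (phi, shape[-1])
    if key not in _DECAY_CACHE:
        _DECAY_CACHE[key] = phi ** np.arange(shape[-1])
    x0 = rng.standard_normal(shape[:-1] + (1,))
    x += x0 * _DECAY_CACHE[key]
    return x


def generate_subject(
    group: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str | None = None,
) -> EEGRecording:
    """Simulate one clean recording (no artifacts, no bad channels)."""
    if group not in config.group_sizes or group not in config.parietal_coupling:
        raise ConfigError(f"unknown group {group!r}")
    alpha = config.parietal_coupling[group]
    beta = config.global_coupling
    phi = config.ar_coefficient
    n = config.n_samples
    c = config.n_channels

    montage_labels = [f"E{i + 1}" for i in range(c)]
    parietal = config.resolved_parietal()
    unknown = set(parietal) - set(montage_labels)
    if unknown:
        raise ConfigError(f"parietal labels outside montage: {sorted(unknown)}")
    p_idx = np.array([montage_labels.index(lab) for lab in parietal], dtype=int)

    s_p = _ar1(rng, phi, n)
    s_g = _ar1(rng, phi, n)
    noise = _ar1(rng, phi, (c, n)) * config.noise_sd

    loadings = np.zeros(c)
    loadings[p_idx] = alpha
    data = config.signal_scale * (
        loadings[:, None] * s_p[None, :] + beta * s_g[None, :] + noise
    )
    return EEGRecording(
        subject_id=subject_id or f"{group}-unnamed",
        group=group,
        data=data,
        fs=config.fs,
    )


def inject_artifacts(
    recording: EEGRecording,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> EEGRecording:
    """Add square-pulse artifacts and overwrite bad channels in place.

    Each 500-sample window is independently selected with probability
    ``artifact_rate``; in a selected window one random channel is overwritten
    with a 50-sample square pulse of height ``+-artifact_amplitude`` so the
    window is rejectable by the amplitude rule by construction.  Bad channels
    are replaced wholesale with white noise at five times the subject's RMS,
    which trips the variance-based bad-channel detector downstream.
    """
    if not 0 <= config.artifact_rate <= 1:
        raise ConfigError("artifact_rate must lie in [0, 1]")
    if config.artifact_rate > 0 and config.artifact_amplitude <= 100:
        raise ConfigError(
            "artifact_amplitude must exceed the 100 uV rejection threshold"
        )
    data = recording.data.copy()
    c, n = data.shape
    n_win = n // WINDOW_SAMPLES

    hit = rng.random(n_win) < config.artifact_rate
    pulse_len = 50
    for w in np.flatnonzero(hit):
        ch = rng.integers(0, c)
        start = w * WINDOW_SAMPLES + rng.integers(0, WINDOW_SAMPLES - pulse_len)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[ch, start : start + pulse_len] = sign * config.artifact_amplitude

    bad: list[str] = list(recording.bad_channels)
    if config.bad_channel_count > 0:
        rms = float(np.sqrt(np.mean(data**2)))
        bad_idx = rng.choice(c, size=min(config.bad_channel_count, c), replace=False)
        for ch in bad_idx:
            data[ch] = rng.standard_normal(n) * 5.0 * rms
            bad.append(f"E{ch + 1}")

    return EEGRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        data=data,
        fs=recording.fs,
        montage_ref=recording.montage_ref,
        bad_channels=sorted(set(bad), key=lambda s: int(s[1:])),
    )


def iter_cohort(config: SimulationConfig, clean: bool = False):
    """Yield the cohort subject by subject; randomness flows from the seed.

    Per-subject generators are spawned from a single seed sequence, so any
    subject can be regenerated independently and the cohort is reproducible
    bit-for-bit.  Streaming keeps the memory footprint at one recording (a
    full-size default cohort would not fit in memory all at once).
    ``clean=True`` skips artifact/bad-channel injection (used when
    validating the closed-form correlation oracle).
    """
    for group in config.group_sizes:
        # subject streams keyed by (seed, group, index): invariant to the
        # mapping's insertion order, so a config round-trip through sorted
        # YAML reproduces the identical cohort
        gkey = zlib.crc32(group.encode())
        for i in range(config.group_sizes[group]):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, gkey, i])
            )
            rec = generate_subject(group, config, rng, subject_id=f"{group}-{i + 1:02d}")
            if not clean:
                rec = inject_artifacts(rec, config, rng)
            yield rec


def generate_cohort(
    config: SimulationConfig,
    clean: bool = False,
) -> list[EEGRecording]:
    """Materialized :func:`iter_cohort` (small/reduced configurations)."""
    return list(iter_cohort(config, clean=clean))


# ---------------------------------------------------------------------------
# Neuropsychological battery
# ---------------------------------------------------------------------------

#: test-name -> (per-group anchor means, sd of subject noise, correlation sign
#: with local betweenness centrality, target |r|, (lo, hi) clamp or None).
#: Anchors follow the published battery group means; the sleep item is a
#: 0-3 ordinal-like scale.
NEUROPSYCH_BATTERY: dict[str, tuple[dict[str, float], float, int, float, tuple | None]] = {
    "MMSE-like": ({"HC": 29.13, "SCD": 29.25, "MCI": 27.13, "AD": 22.30}, 2.0, -1, 0.254, (0.0, 30.0)),
    "FUCAS-like": ({"HC": 42.00, "SCD": 42.55, "MCI": 44.77, "AD": 50.38}, 4.0, +1, 0.281, None),
    "FRSSD-sleep-like": ({"HC": 0.30, "SCD": 0.50, "MCI": 0.80, "AD": 1.20}, 0.8, +1, 0.522, (0.0, 3.0)),
    "RBMT-like": ({"HC": 15.40, "SCD": 13.09, "MCI": 12.04, "AD": 9.50}, 3.0, -1, 0.362, None),
    "ROCFT-like": ({"HC": 33.50, "SCD": 33.68, "MCI": 30.23, "AD": 22.80}, 5.0, -1, 0.501, None),
}


def generate_neuropsych(
    cohort: list[EEGRecording],
    metric_per_subject: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    battery: Mapping[str, tuple] | None = None,
) -> list[NeuropsychScores]:
    """Scores anchored at group means plus a term tied to a network metric.

    ``metric_per_subject`` is typically the subject's local betweenness
    centrality.  Within the cohort the metric is z-scored; each test adds
    ``sign * c * z`` with ``c = sd * r / sqrt(1 - r**2)``, which makes the
    population correlation between score and metric equal ``sign * r``.
    """
    if not cohort:
        raise ConfigError("cannot generate scores for an empty cohort")
    missing = [r.subject_id for r in cohort if r.subject_id not in metric_per_subject]
    if missing:
        raise ConfigError(f"missing metric values for subjects: {missing}")
    battery = dict(battery if battery is not None else NEUROPSYCH_BATTERY)

    metric = np.array([metric_per_subject[r.subject_id] for r in cohort], float)
    sd = metric.std(ddof=0)
    z = (metric - metric.mean()) / sd if sd > 0 else np.zeros_like(metric)

    out: list[NeuropsychScores] = []
    for i, rec in enumerate(cohort):
        scores: dict[str, float] = {}
        for name, (anchors, noise_sd, sign, r_target, clamp) in battery.items():
            if rec.group not in anchors:
                raise ConfigError(f"no anchor mean for group {rec.group!r} in {name}")
            coeff = noise_sd * r_target / np.sqrt(1.0 - r_target**2)
            val = anchors[rec.group] + sign * coeff * z[i] + rng.normal(0.0, noise_sd)
            if clamp is not None:
                val = float(np.clip(val, *clamp))
            scores[name] = float(val)
        out.append(NeuropsychScores(subject_id=rec.subject_id, scores=scores))
    return out


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def write_recording(recording: EEGRecording, path) -> None:
    """Samples-by-channels delimited matrix with an electrode-label header."""
    labels = [f"E{i + 1}" for i in range(recording.n_channels)]
    df = pd.DataFrame(recording.data.T, columns=labels)
    df.to_csv(path, index=False, float_format="%.8g")


def read_recording(path, subject_id: str, group: str, fs: float,
                   bad_channels: list[str] | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(
        subject_id=subject_id,
        group=group,
        data=df.to_numpy(float).T,
        fs=fs,
        bad_channels=bad_channels or [],
    )


def write_manifest(cohort: list[EEGRecording], files: Mapping[str, str], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "file": files[r.subject_id],
            "bad_channels": ";".join(r.bad_channels),
        }
        for r in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["bad_channels"] = df["bad_channels"].fillna("").astype(str)
    return df
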