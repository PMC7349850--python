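"""End-to-end orchestration: simulate -> preprocess -> connect -> metrics
-> stats -> ROC, with one config, one seed and full provenance.

Every run is deterministic given its seed: re-running with the same config
produces byte-identical delimited outputs.  Heavy raw signals are written
only on request (``write_signals``); connectivity matrices, per-subject
summaries, the statistics table, ROC table and synthetic neuropsychological
scores are always written, along with a log recording the package version,
seed, per-stage wall time, retained-segment counts and parietal
de-duplication decisions.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import extract_local, subject_matrix, write_matrix
from .errors import (
    ConfigError,
    DegenerateVarianceError,
    EEGConnectomeError,
    PipelineStageError,
)
from .metrics import summarize
from .montage import PARIETAL_LIST_RAW, write_montage
from .preprocess import preprocess_recording
from .roc import results_table, run_contrasts
from .simulate import (
    NEUROPSYCH_BATTERY,
    SimulationConfig,
    generate_neuropsych,
    iter_cohort,
    write_manifest,
    write_recording,
)
from .stats import compare_groups, pearson_test

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

_RUN_DEFAULTS = {
    "band_low": 0.3,
    "band_high": 75.0,
    "filter_order": 5,
    "window_samples": 500,
    "threshold_uv": 100.0,
    "alpha": 0.05,
    "scope": "both",
    "write_signals": False,
    "log_level": "info",
}


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band_low: float = 0.3
    band_high: float = 75.0
    filter_order: int = 5
    window_samples: int = 500
    threshold_uv: float = 100.0
    parietal_list: tuple[str, ...] | None = None
    alpha: float = 0.05
    scope: str = "both"
    write_signals: bool = False
    log_level: str = "info"
    warnings: tuple[str, ...] = ()

    @property
    def scopes(self) -> tuple[str, ...]:
        return ("local", "global") if self.scope == "both" else (self.scope,)


def _normalize_parietal(raw) -> tuple[tuple[str, ...], list[str]]:
    """Labels from a mixed int/str list; returns (unique labels, warnings)."""
    labels = [x if isinstance(x, str) else f"E{int(x)}" for x in raw]
    seen: dict[str, int] = {}
    dupes: list[str] = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        if seen[lab] == 2:
            dupes.append(lab)
    unique = tuple(dict.fromkeys(labels))
    warnings = []
    if dupes:
        warnings.append(
            f"parietal list contains duplicate labels {dupes}; "
            f"de-duplicated to {len(unique)} unique electrodes"
        )
    return unique, warnings


def validate_config(source) -> RunConfig:
    """Normalize a YAML file/dict into a RunConfig; collect all errors.

    Unknown keys, Nyquist violations and malformed values are gathered and
    reported together rather than first-fail.  Every default is materialized
    explicitly on the returned object (echoed verbatim by ``run_all``).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    errors: list[str] = []
    warnings: list[str] = []

    sim_raw = raw.pop("simulation", {}) or {}
    unknown_sim = set(sim_raw) - _SIM_FIELDS
    for key in sorted(unknown_sim):
        errors.append(f"unknown simulation key: {key!r}")
    sim_kwargs = {k: v for k, v in sim_raw.items() if k in _SIM_FIELDS}
    if "seed" in raw:
        sim_kwargs["seed"] = raw.pop("seed")
    if "parietal_labels" in sim_kwargs:
        sim_kwargs["parietal_labels"], w = _normalize_parietal(
            sim_kwargs["parietal_labels"])
        warnings += w

    parietal_list = None
    if "parietal_list" in raw:
        parietal_list, w = _normalize_parietal(raw.pop("parietal_list"))
        warnings += w

    known = set(_RUN_DEFAULTS)
    for key in sorted(set(raw) - known):
        errors.append(f"unknown config key: {key!r}")
    run_kwargs = {**_RUN_DEFAULTS, **{k: v for k, v in raw.items() if k in known}}

    sim = None
    try:
        sim = SimulationConfig(**sim_kwargs)
    except (ConfigError, TypeError) as exc:
        errors.append(f"simulation config: {exc}")

    if sim is not None and run_kwargs["band_high"] >= sim.fs / 2:
        errors.append(
            f"band_high {run_kwargs['band_high']} Hz violates the Nyquist "
            f"limit {sim.fs / 2} Hz at fs={sim.fs}"
        )
    if not 0 < run_kwargs["band_low"] < run_kwargs["band_high"]:
        errors.append("need 0 < band_low < band_high")
    if run_kwargs["scope"] not in ("local", "global", "both"):
        errors.append(f"scope must be local|global|both, got {run_kwargs['scope']!r}")
    if not 0 < run_kwargs["alpha"] < 1:
        errors.append("alpha must lie in (0, 1)")

    if errors:
        raise ConfigError("; ".join(errors))
    cfg = RunConfig(simulation=sim, parietal_list=parietal_list,
                    warnings=tuple(warnings), **run_kwargs)
    if parietal_list is not None:
        cfg.simulation = dataclasses.replace(sim, parietal_labels=parietal_list)
    return cfg


def echo_config(cfg: RunConfig) -> dict:
    """Fully materialized config as a plain mapping (for the YAML echo)."""
    sim = dataclasses.asdict(cfg.simulation)
    sim["group_sizes"] = dict(sim["group_sizes"])
    sim["parietal_coupling"] = dict(sim["parietal_coupling"])
    if sim["parietal_labels"] is not None:
        sim["parietal_labels"] = list(sim["parietal_labels"])
    out = {k: getattr(cfg, k) for k in _RUN_DEFAULTS}
    out["simulation"] = sim
    out["parietal_list"] = list(cfg.parietal_list) if cfg.parietal_list else None
    return out


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Run the full pipeline; returns the in-memory result tables.

    Writes the artifact tree under ``out_dir``.  Any stage failure raises
    :class:`PipelineStageError` carrying the stage name and subject id; a
    ``STALE`` marker file flags partially written output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    stale.write_text("run in progress; outputs incomplete\n")
    log_lines: list[str] = [
        f"eegconnectome {__version__}",
        f"seed {cfg.simulation.seed}",
    ]
    log_lines += [f"warning: {w}" for w in cfg.warnings]
    t_all = time.perf_counter()

    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(echo_config(cfg), fh, sort_keys=True)

    montage = cfg.simulation.montage()
    parietal = tuple(cfg.parietal_list or montage.parietal_set)
    if len(set(PARIETAL_LIST_RAW)) != len(PARIETAL_LIST_RAW) and len(parietal) == 27:
        log_lines.append(
            "parietal list: printed 29-entry list de-duplicated to 27 unique "
            "electrodes (E87 and E63 repeated)"
        )
    write_montage(montage, out / "montage.csv")

    # ---- simulate + preprocess + connectivity + metrics --------------------
    # subjects are streamed so a full-size cohort never sits in memory whole
    t0 = time.perf_counter()
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    if cfg.write_signals:
        (out / "signals").mkdir(exist_ok=True)
    subjects: list[SimpleNamespace] = []
    files: dict[str, str] = {}
    rows = []
    for rec in iter_cohort(cfg.simulation):
        subjects.append(SimpleNamespace(
            subject_id=rec.subject_id, group=rec.group,
            bad_channels=list(rec.bad_channels),
        ))
        if cfg.write_signals:
            fname = f"signals/{rec.subject_id}.csv"
            write_recording(rec, out / fname)
            files[rec.subject_id] = fname
        else:
            files[rec.subject_id] = "(in-memory)"
        try:
            seg = preprocess_recording(
                rec, montage, low=cfg.band_low, high=cfg.band_high,
                order=cfg.filter_order, window_samples=cfg.window_samples,
                threshold_uv=cfg.threshold_uv,
            )
        except EEGConnectomeError as exc:
            raise PipelineStageError("preprocess", rec.subject_id, str(exc)) from exc
        log_lines.append(
            f"{rec.subject_id}: retained {seg.n_segments}/"
            f"{seg.retained_mask.size} segments, interpolated "
            f"{len(seg.interpolated_channels)} channels"
        )
        try:
            gmat = subject_matrix(seg, scope="global")
        except EEGConnectomeError as exc:
            raise PipelineStageError("connect", rec.subject_id, str(exc)) from exc
        lmat = extract_local(gmat, parietal)
        for scope, mat in (("global", gmat), ("local", lmat)):
            if scope not in cfg.scopes:
                continue
            write_matrix(mat, conn_dir / f"{rec.subject_id}_{scope}.csv")
            try:
                summ = summarize(mat)
            except EEGConnectomeError as exc:
                raise PipelineStageError("metrics", rec.subject_id, str(exc)) from exc
            rows.append({
                "subject_id": rec.subject_id,
                "group": rec.group,
                "scope": scope,
                "cc": summ.cc_graph,
                "strength": summ.strength_graph,
                "bc": summ.bc_graph,
            })
    write_manifest(subjects, files, out / "manifest.csv")
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "summaries.csv", index=False, float_format="%.10g")
    log_lines.append(f"preprocess+connect+metrics ({time.perf_counter() - t0:.2f}s)")

    # ---- group statistics --------------------------------------------------
    t0 = time.perf_counter()
    stat_rows = []
    for scope in cfg.scopes:
        block = summaries[summaries["scope"] == scope]
        for metric in ("cc", "strength", "bc"):
            samples = {g: block.loc[block["group"] == g, metric].to_numpy()
                       for g in cfg.simulation.group_sizes}
            try:
                cmp_res = compare_groups(samples, metric, scope, alpha=cfg.alpha)
            except EEGConnectomeError as exc:
                raise PipelineStageError("stats", None, str(exc)) from exc
            stat_rows.append({
                "metric": metric, "scope": scope, "F": cmp_res.F,
                "df_between": cmp_res.df_between,
                "df_within": cmp_res.df_within,
                "p_anova": cmp_res.p_anova,
                "bonferroni_level": cmp_res.bonferroni_level,
                "pairwise": "; ".join(
                    f"{a}-{b}: t({pr.df})={pr.t:.3f}, p={pr.p:.4g}"
                    f"{' *' if pr.p < cmp_res.bonferroni_level else ''}"
                    for pr in cmp_res.pairwise
                    for a, b in [pr.groups]
                ),
            })
    stats_df = pd.DataFrame(stat_rows)
    stats_df.to_csv(out / "stats.csv", index=False, float_format="%.10g")
    log_lines.append(f"stats ({time.perf_counter() - t0:.2f}s)")

    # ---- ROC ---------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        roc_results = run_contrasts(
            summaries, scopes=cfg.scopes,
            groups=tuple(cfg.simulation.group_sizes),
        )
    except EEGConnectomeError as exc:
        raise PipelineStageError("roc", None, str(exc)) from exc
    roc_df = results_table(roc_results)
    roc_df.to_csv(out / "roc.csv", index=False, float_format="%.10g")
    log_lines.append(f"roc ({time.perf_counter() - t0:.2f}s)")

    # ---- synthetic neuropsychological scores -------------------------------
    t0 = time.perf_counter()
    local_bc = {
        r["subject_id"]: r["bc"] for r in rows if r["scope"] == "local"
    }
    neuro_df = pd.DataFrame()
    corr_df = pd.DataFrame()
    if local_bc:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.simulation.seed, 1])
        )
        try:
            scores = generate_neuropsych(subjects, local_bc, cfg.simulation, rng)
        except EEGConnectomeError as exc:
            raise PipelineStageError("neuropsych", None, str(exc)) from exc
        neuro_df = pd.DataFrame(
            [{"subject_id": s.subject_id, **s.scores} for s in scores]
        )
        neuro_df.to_csv(out / "neuropsych.csv", index=False, float_format="%.10g")
        corr_rows = []
        bc_vec = [local_bc[s.subject_id] for s in scores]
        for test in NEUROPSYCH_BATTERY:
            try:
                r, p = pearson_test([s.scores[test] for s in scores], bc_vec)
            except DegenerateVarianceError:
                # a constant metric (e.g. zero betweenness on a tiny complete
                # local graph) has no defined correlation with anything
                r, p = float("nan"), float("nan")
            corr_rows.append({"test": test, "metric": "bc_local", "r": r, "p": p})
        corr_df = pd.DataFrame(corr_rows)
        corr_df.to_csv(out / "neuropsych_correlations.csv", index=False,
                       float_format="%.10g")
    log_lines.append(f"neuropsych ({time.perf_counter() - t0:.2f}s)")

    log_lines.append(f"total ({time.perf_counter() - t_all:.2f}s)")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    stale.unlink()
    return {
        "summaries": summaries,
        "stats": stats_df,
        "roc": roc_df,
        "neuropsych": neuro_df,
        "neuropsych_correlations": corr_df,
    }
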