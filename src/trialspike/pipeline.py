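"""End-to-end pipeline orchestration: synthetic sessions -> PETH -> bin-wise
GLM -> peak clustering -> population decoding -> summary report.

Every stage writes plain CSV/JSON to the run directory before the next stage
starts, so any stage can be inspected or re-run in isolation, and a manifest
records the config snapshot, per-file checksums, and timestamps.  Runs are
fully deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clus
from . import decoding as dec
from . import glm, peth, stats, synth

log = logging.getLogger("trialspike")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; round-trips losslessly via JSON."""

    seed: int = 0
    out_dir: str = "run"
    # synthesis
    n_sessions: int = 3
    n_units: int = 20
    n_trials: int = 56
    frac_difficulty_tuned: float = 0.2
    frac_location_tuned: float = 0.4
    kernel_amplitude: float = 8.0        # Hz
    kernel_width_sd: float = 0.3         # s
    fs_fraction: float = 0.1
    # analysis
    window: tuple[float, float] = (-2.0, 3.0)
    binwidth: float = 0.2
    alignment: str = "t_touch"
    alpha: float = 0.05
    n_shuffles: int = 100
    with_interaction: bool = False
    cut_fraction: float = 0.95
    # decoding
    decoding_enabled: bool = True
    decode_window: tuple[float, float] = (-1.0, 1.0)
    svm_win_len: float = 0.4
    svm_step: float = 0.1
    n_per_cond: int = 20
    n_iter: int = 15
    svm_C: float = 1.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("window", "decode_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, str] = field(default_factory=dict)   # name -> status
    checksums: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_units(cfg: RunConfig, rng: np.random.Generator,
                  base_uid: int) -> list[synth.UnitSpec]:
    """Draw a session's unit specs with the configured tuning mix."""
    units = []
    for i in range(cfg.n_units):
        uid = base_uid + i
        is_fs = rng.random() < cfg.fs_fraction
        ct = "FS" if is_fs else "RS"
        u = rng.random()
        if u < cfg.frac_difficulty_tuned:
            var = "difficulty"
        elif u < cfg.frac_difficulty_tuned + cfg.frac_location_tuned:
            var = "location"
        else:
            var = "none"
        if var == "none":
            kernel = synth.PreferenceKernel()
        else:
            kernel = synth.PreferenceKernel(
                variable=var,
                preferred_code=int(rng.choice([-1, 1])),
                peak_latency=float(rng.uniform(-1.5, 2.0)),
                width_sd=cfg.kernel_width_sd,
                amplitude=cfg.kernel_amplitude)
        units.append(synth.UnitSpec(
            unit_id=uid, cell_type=ct,
            baseline_rate=synth.DEFAULT_BASELINE[ct],
            kernel=kernel,
            peak_to_trough_ms=synth.DEFAULT_PEAK_TO_TROUGH[ct]))
    return units


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every stage, writing outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(cfg), version=__version__,
                           started=time.time())
    written: list[Path] = []

    def emit(name: str, obj) -> Path:
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False, float_format="%.6f")
        else:
            path.write_text(json.dumps(obj, indent=2))
        written.append(path)
        return path

    # -- stage 1: synthesis ------------------------------------------------
    log.info("stage synth: %d sessions x %d units", cfg.n_sessions, cfg.n_units)
    root_ss = np.random.SeedSequence(cfg.seed)
    session_seeds = root_ss.generate_state(cfg.n_sessions + 2)
    rng_units = np.random.default_rng(int(session_seeds[-1] % 2**31))
    sessions: list[synth.SyntheticSession] = []
    for s in range(cfg.n_sessions):
        units = _random_units(cfg, rng_units, base_uid=s * 1000)
        ses = synth.generate_session(units=units, n_trials=cfg.n_trials,
                                     seed=int(session_seeds[s] % 2**31))
        sessions.append(ses)
        trials = ses.trials.copy()
        trials.insert(0, "session", s)
        emit(f"trials_s{s:02d}.csv", trials)
        emit(f"spikes_s{s:02d}.csv", ses.spike_table())
    manifest.stages["synth"] = "completed"

    # -- stage 2: behavior -------------------------------------------------
    all_trials = pd.concat(
        [s.trials.assign(session=i) for i, s in enumerate(sessions)],
        ignore_index=True)
    behav = stats.behavior_summary(all_trials)
    emit("behavior.csv", behav.table)
    manifest.stages["behavior"] = "completed"

    # -- stage 3: PETH + GLM -----------------------------------------------
    spec = peth.BinSpec(window=cfg.window, binwidth=cfg.binwidth,
                        alignment=cfg.alignment)
    glm_seed_rng = np.random.default_rng(int(session_seeds[-2] % 2**31))
    series_by_unit: dict[int, glm.CoefficientSeries] = {}
    zpeth_by_unit: dict[int, peth.ZScoredPETH] = {}
    cond_by_unit: dict[str, dict[int, np.ndarray]] = {v: {} for v
                                                      in glm.MAIN_VARIABLES}
    calls_by_unit: dict[int, dict[str, glm.PreferenceCall]] = {}
    cell_types: dict[int, str] = {}
    nulls: list[glm.ShuffleNull] = []
    for s_i, ses in enumerate(sessions):
        X, names = glm.design_matrix(ses.trials,
                                     with_interaction=cfg.with_interaction)
        correct = ses.trials[ses.trials["correct"]]
        baselines = {u.unit_id: peth.baseline_stats(ses.spikes[u.unit_id],
                                                    ses.trials,
                                                    binwidth=cfg.binwidth)
                     for u in ses.units}
        pooled_sd = peth.pooled_baseline_sd(list(baselines.values()))
        for u in ses.units:
            uid = u.unit_id
            cell_types[uid] = u.cell_type
            events = correct[cfg.alignment].to_numpy(dtype=float)
            counts = peth.bin_spikes(ses.spikes[uid], events, spec)
            z = peth.zscore_peth(counts, baselines[uid], spec=spec,
                                 unit_id=uid, fallback_sd=pooled_sd)
            zpeth_by_unit[uid] = z
            for var in glm.MAIN_VARIABLES:
                cond_by_unit[var][uid] = correct[var].to_numpy(dtype=int)
            series = glm.fit_binwise_glm(z, X, names, unit_id=uid)
            series_by_unit[uid] = series
            null = glm.shuffle_null(z, X, names, n_shuffles=cfg.n_shuffles,
                                    alpha=cfg.alpha,
                                    seed=int(glm_seed_rng.integers(2**31)))
            nulls.append(null)
            calls_by_unit[uid] = glm.classify_preference(series, null,
                                                         alpha=cfg.alpha)
    emit("coefficients.csv",
         pd.concat([s.to_frame() for s in series_by_unit.values()],
                   ignore_index=True))
    emit("preference_calls.csv",
         glm.calls_to_frame(list(calls_by_unit.values())))
    threshold = glm.pooled_threshold(nulls)
    emit("glm_manifest.json", {"alpha": cfg.alpha,
                               "n_shuffles": cfg.n_shuffles,
                               "run_threshold": threshold,
                               "min_contiguous_bins": threshold + 1})
    manifest.stages["glm"] = "completed"

    # -- stage 4: clustering -----------------------------------------------
    family_rows = []
    for var in glm.MAIN_VARIABLES:
        groups = clus.collect_peaks(calls_by_unit, cell_types, var)
        for sign, recs in groups.items():
            if len(recs) < 2:
                continue
            Z = clus.ward_cluster(np.array([r.peak_time for r in recs]))
            fams = clus.cut_tree_families(Z, recs, fraction=cfg.cut_fraction)
            for fam in fams:
                clus.summarize_family(fam, series_by_unit, zpeth_by_unit,
                                      cond_by_unit[var], var)
                for uid in fam.unit_ids:
                    family_rows.append((var, sign, fam.family_id, uid))
    emit("cluster_families.csv",
         pd.DataFrame(family_rows, columns=["variable", "sign", "family_id",
                                            "unit_id"]))
    manifest.stages["cluster"] = "completed"

    # -- stage 5: decoding ---------------------------------------------------
    if cfg.decoding_enabled:
        dec_rng = np.random.default_rng(int(session_seeds[-1] % 2**31) ^ 0x5EED)
        for var in glm.MAIN_VARIABLES:
            feats = []
            for ses in sessions:
                correct = ses.trials[ses.trials["correct"]]
                feats.append(dec.sliding_fr(
                    {u.unit_id: ses.spikes[u.unit_id] for u in ses.units},
                    correct[cfg.alignment].to_numpy(dtype=float),
                    correct[var].to_numpy(dtype=int),
                    window=cfg.decode_window, win_len=cfg.svm_win_len,
                    step=cfg.svm_step))
            n_per = min(cfg.n_per_cond,
                        min(int((f.labels == c).sum())
                            for f in feats for c in (-1, 1)))
            test = dec.pooled_pseudo_decode(
                feats, n_per_cond=n_per, n_iter=cfg.n_iter,
                seed=int(dec_rng.integers(2**31)), C=cfg.svm_C)
            shuf = dec.pooled_pseudo_decode(
                feats, n_per_cond=n_per, n_iter=cfg.n_iter,
                seed=int(dec_rng.integers(2**31)), shuffle=True, C=cfg.svm_C)
            result = dec.decoding_result(feats[0].bin_centers, test, shuf,
                                         alpha=cfg.alpha)
            lo, hi = result.ci95("test")
            emit(f"decoding_{var}.csv", pd.DataFrame({
                "bin_center_s": result.bin_centers,
                "test_acc": result.mean_test,
                "shuffle_acc": result.mean_shuffle,
                "ci_lo": lo, "ci_hi": hi,
                "significant": result.significant,
            }))
        manifest.stages["decoding"] = "completed"
    else:
        manifest.stages["decoding"] = "skipped"

    # -- stage 6: report -----------------------------------------------------
    labels = {uid: glm.preference_label(c) for uid, c in calls_by_unit.items()}
    counts = stats.unit_count_table(labels, cell_types)
    emit("unit_counts.csv", counts)
    n_pref = sum(1 for v in labels.values() if v != "none")
    report = {
        "n_units": len(labels),
        "n_preferring": n_pref,
        "pct_preferring": stats.proportion_pct(n_pref, len(labels)),
        "run_threshold": threshold,
        "behavior_rt_test": behav.rt_difficulty_test,
    }
    emit("report.json", report)
    manifest.stages["report"] = "completed"

    manifest.checksums = {p.name: _sha256(p) for p in written}
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

def validate_tables(path) -> list[dict]:
    """Schema checks for trial/spike CSV tables.

    Returns machine-readable violations: each a dict with ``file``,
    ``rule``, optional ``column`` / ``row``.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    violations: list[dict] = []
    for f in files:
        try:
            df = pd.read_csv(f)
        except Exception as e:   # unreadable file is an I/O error
            raise OSError(f"cannot read {f}: {e}") from e
        cols = set(df.columns)
        if {"t_init", "t_touch", "difficulty", "location"} <= cols:
            for col in ("difficulty", "location"):
                bad = ~df[col].isin([-1, 1])
                if bad.any():
                    violations.append({
                        "file": f.name, "column": col,
                        "rule": "codes must be exactly -1/+1",
                        "row": int(np.flatnonzero(bad)[0])})
            bad = df["t_touch"] <= df["t_init"]
            if bad.any():
                violations.append({
                    "file": f.name, "column": "t_touch",
                    "rule": "t_init must precede t_touch",
                    "row": int(np.flatnonzero(bad)[0])})
            if "t_reward" in cols and "correct" in cols:
                on_correct = df["correct"].astype(bool)
                bad = on_correct & ~(df["t_reward"] > df["t_touch"])
                if bad.any():
                    violations.append({
                        "file": f.name, "column": "t_reward",
                        "rule": "t_touch must precede t_reward on correct trials",
                        "row": int(np.flatnonzero(bad)[0])})
        elif {"unit_id", "spike_time_s"} <= cols:
            grouped = df.groupby("unit_id")["spike_time_s"]
            for uid, g in grouped:
                if (np.diff(g.to_numpy()) < 0).any():
                    violations.append({
                        "file": f.name, "column": "spike_time_s",
                        "rule": f"spike times of unit {uid} not sorted"})
    return violations
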