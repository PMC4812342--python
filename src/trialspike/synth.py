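"""Synthetic session generator for trial-structured single-unit recordings.

Emulates a self-paced two-alternative forced-choice visual discrimination
session: a trial/event table (initiation, stimulus touch, reward), interleaved
easy/hard contrast conditions and left/right target locations, per-unit spike
trains from an inhomogeneous Poisson process with condition-dependent Gaussian
rate bumps ("preference kernels"), and optionally a broadband voltage trace
with embedded spike waveforms.  Every generator is seed-deterministic and
returns full ground truth so downstream stages can be tested by parameter
recovery.

Conventions
-----------
* All times are in seconds from session start; rates in Hz.
* Condition codes are exactly -1/+1: difficulty easy=-1 hard=+1,
  location left=-1 right=+1.
* The target location never repeats more than three consecutive trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Defaults describing a typical session
# ---------------------------------------------------------------------------

#: (mean, sd) of the truncated-normal reaction time to touch, per difficulty.
DEFAULT_RT_PARAMS: dict[int, tuple[float, float]] = {
    -1: (4.5, 1.0),   # easy
    +1: (5.5, 1.0),   # hard
}
RT_TRUNC_LO = 0.5     # s; reaction times below this are physically implausible
RT_TRUNC_HI = 15.0    # s; trials slower than this are excluded from analysis
DEFAULT_ITI = 10.0    # s; guarantees a full 7-s pre-initiation baseline
DEFAULT_ACCURACY = {-1: 0.99, +1: 0.80}   # per-difficulty P(correct)
DEFAULT_DRINK_RT = (1.5, 0.3)             # touch -> reward retrieval, s
TIMEOUT_DUR = 5.0     # s houselight-off period after an incorrect response

#: Baseline firing-rate defaults by cell type (Hz).
DEFAULT_BASELINE = {"RS": 2.88, "FS": 6.56}
#: Waveform peak-to-trough defaults by cell type (ms).
DEFAULT_PEAK_TO_TROUGH = {"RS": 0.8, "FS": 0.3}

TRIAL_COLUMNS = ["trial_id", "t_init", "t_touch", "t_reward",
                 "difficulty", "location", "correct"]


@dataclass(frozen=True)
class PreferenceKernel:
    """Ground-truth condition preference: a transient Gaussian rate bump.

    On trials whose ``variable`` code equals ``preferred_code`` the unit's
    rate is modulated by ``amplitude * exp(-(t - t_align - peak_latency)**2 /
    (2 * width_sd**2))``; other trials stay at baseline.  ``variable='none'``
    encodes an untuned unit (amplitude must be 0).
    """

    variable: str = "none"          # 'difficulty' | 'location' | 'none'
    preferred_code: int = +1
    peak_latency: float = 0.0       # s relative to the alignment event
    width_sd: float = 0.3           # s
    amplitude: float = 0.0          # Hz; negative values model suppression
    align: str = "t_touch"          # 't_touch' | 't_init'

    def __post_init__(self) -> None:
        if self.variable not in ("difficulty", "location", "none"):
            raise ValueError(f"unknown kernel variable {self.variable!r}")
        if self.width_sd <= 0:
            raise ValueError("width_sd must be positive")
        if (self.variable == "none") != (self.amplitude == 0):
            raise ValueError("amplitude must be 0 iff variable is 'none'")
        if self.preferred_code not in (-1, 1):
            raise ValueError("preferred_code must be -1 or +1")


@dataclass(frozen=True)
class UnitSpec:
    """Specification of one synthetic unit, including its ground truth."""

    unit_id: int
    cell_type: str = "RS"                       # 'RS' | 'FS'
    baseline_rate: float = DEFAULT_BASELINE["RS"]
    kernel: PreferenceKernel = field(default_factory=PreferenceKernel)
    peak_to_trough_ms: float = DEFAULT_PEAK_TO_TROUGH["RS"]
    waveform_amplitude: float = 1.0             # peak voltage, arbitrary units

    def __post_init__(self) -> None:
        if self.cell_type not in ("RS", "FS"):
            raise ValueError(f"cell_type must be RS or FS, got {self.cell_type!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")


@dataclass
class SyntheticSession:
    """A generated session: trial table, unit specs, and spike trains."""

    trials: pd.DataFrame
    units: list[UnitSpec]
    spikes: dict[int, np.ndarray]       # unit_id -> sorted spike times (s)
    seed: int
    duration: float                     # s, total session span

    def spike_table(self) -> pd.DataFrame:
        """Long-format (unit_id, spike_time_s) table for CSV export."""
        frames = [pd.DataFrame({"unit_id": uid, "spike_time_s": st})
                  for uid, st in sorted(self.spikes.items())]
        if not frames:
            return pd.DataFrame(columns=["unit_id", "spike_time_s"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Trial table
# ---------------------------------------------------------------------------

def _balanced_condition_sequence(n_trials: int, rng: np.random.Generator,
                                 max_location_run: int = 3) -> np.ndarray:
    """Random order of the four (difficulty, location) types, balanced, with
    no location appearing more than ``max_location_run`` times in a row.

    Sequential sampling proportional to remaining type counts, masking any
    type whose location would extend the current run past the limit; the rare
    dead end at the tail restarts the draw.
    """
    types = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    per_type = n_trials // 4
    for _ in range(10_000):
        remaining = np.full(4, per_type, dtype=float)
        seq: list[tuple[int, int]] = []
        run_loc, run_len = 0, 0
        ok = True
        for _i in range(n_trials):
            weights = remaining.copy()
            if run_len >= max_location_run:
                for k, (_d, loc) in enumerate(types):
                    if loc == run_loc:
                        weights[k] = 0.0
            total = weights.sum()
            if total <= 0:
                ok = False
                break
            k = rng.choice(4, p=weights / total)
            remaining[k] -= 1
            d, loc = types[k]
            seq.append((d, loc))
            if loc == run_loc:
                run_len += 1
            else:
                run_loc, run_len = loc, 1
        if ok:
            return np.array(seq, dtype=int)
    raise RuntimeError("could not draw a constrained condition sequence")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float,
               hi: float, size: int) -> np.ndarray:
    """Truncated-normal draws by resampling out-of-range values."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate mean outside truncation bounds")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_trials(n_trials: int = 56,
                    rt_params: dict[int, tuple[float, float]] | None = None,
                    iti: float = DEFAULT_ITI,
                    accuracy: dict[int, float] | None = None,
                    drink_rt: tuple[float, float] = DEFAULT_DRINK_RT,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a balanced trial table for one session.

    Parameters
    ----------
    n_trials
        Total trial count; must be divisible by 4 so the four
        difficulty x location types appear equally often.
    rt_params
        ``{difficulty_code: (mean, sd)}`` of the reaction time to touch in
        seconds, truncated to [0.5, 15] s (slower trials are excluded from
        analysis upstream, so they are never generated).
    iti
        Inter-trial interval preceding each initiation, seconds.  The default
        leaves a full 7-s baseline window before every trial.
    accuracy
        ``{difficulty_code: P(correct)}``.
    drink_rt
        (mean, sd) of the touch-to-reward retrieval time on correct trials.

    Returns
    -------
    pandas.DataFrame
        Columns ``trial_id, t_init, t_touch, t_reward, difficulty, location,
        correct``; ``t_reward`` is NaN on incorrect trials.
    """
    if n_trials <= 0 or n_trials % 4 != 0:
        raise ValueError("n_trials must be a positive multiple of 4")
    rt_params = dict(DEFAULT_RT_PARAMS if rt_params is None else rt_params)
    accuracy = dict(DEFAULT_ACCURACY if accuracy is None else accuracy)
    for code in (-1, 1):
        mean, sd = rt_params[code]
        if mean <= 0 or sd < 0:
            raise ValueError("reaction-time mean must be positive, sd non-negative")
    if iti <= 0:
        raise ValueError("iti must be positive")

    rng = np.random.default_rng(seed)
    conds = _balanced_condition_sequence(n_trials, rng)
    difficulty, location = conds[:, 0], conds[:, 1]

    rts = np.empty(n_trials)
    for code in (-1, 1):
        mask = difficulty == code
        mean, sd = rt_params[code]
        rts[mask] = _truncnorm(rng, mean, sd, RT_TRUNC_LO, RT_TRUNC_HI,
                               int(mask.sum()))
    correct = rng.random(n_trials) < np.where(difficulty == -1,
                                              accuracy[-1], accuracy[1])
    drink = _truncnorm(rng, drink_rt[0], drink_rt[1], 0.2, 10.0, n_trials)

    t_init = np.empty(n_trials)
    t_touch = np.empty(n_trials)
    t_reward = np.full(n_trials, np.nan)
    clock = 0.0
    for i in range(n_trials):
        t_init[i] = clock + iti
        t_touch[i] = t_init[i] + rts[i]
        if correct[i]:
            t_reward[i] = t_touch[i] + drink[i]
            clock = t_reward[i]
        else:
            clock = t_touch[i] + TIMEOUT_DUR

    return pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "t_init": t_init,
        "t_touch": t_touch,
        "t_reward": t_reward,
        "difficulty": difficulty,
        "location": location,
        "correct": correct,
    })


def session_duration(trials: pd.DataFrame, tail: float = DEFAULT_ITI) -> float:
    """Session span: last event plus one trailing inter-trial interval."""
    last = np.nanmax(trials[["t_touch", "t_reward"]].to_numpy())
    return float(last + tail)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _kernel_align_times(unit: UnitSpec, trials: pd.DataFrame) -> np.ndarray:
    """Alignment-event times of the trials matching the unit's preference."""
    k = unit.kernel
    if k.variable == "none":
        return np.empty(0)
    match = trials[k.variable].to_numpy() == k.preferred_code
    return trials.loc[match, k.align].to_numpy(dtype=float)


def rate_function(unit: UnitSpec, trials: pd.DataFrame):
    """Return ``lam(t)``, the unit's instantaneous rate in Hz, vectorized.

    Baseline everywhere plus one Gaussian bump per matching trial, centred
    ``peak_latency`` after that trial's alignment event; floored at 0 so a
    suppressive (negative-amplitude) kernel cannot drive the rate negative.
    """
    k = unit.kernel
    centers = np.sort(_kernel_align_times(unit, trials) + k.peak_latency)

    # bumps from different trials are separated by at least the ITI; when
    # they are well separated only the nearest bump contributes, otherwise
    # fall back to the exact (slower) sum over all bumps
    if centers.size > 1 and (np.diff(centers) < 10 * k.width_sd).any():
        return _dense_rate_function(unit, trials)

    def lam(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rate = np.full(t.shape, unit.baseline_rate)
        if centers.size and k.amplitude != 0:
            idx = np.searchsorted(centers, t)
            left = np.clip(idx - 1, 0, centers.size - 1)
            right = np.clip(idx, 0, centers.size - 1)
            d = np.minimum(np.abs(t - centers[left]),
                           np.abs(t - centers[right]))
            near = d < 5 * k.width_sd
            rate[near] += k.amplitude * np.exp(
                -d[near] ** 2 / (2 * k.width_sd ** 2))
        return np.maximum(rate, 0.0)

    return lam


def _dense_rate_function(unit: UnitSpec, trials: pd.DataFrame):
    """Fallback exact rate: sum over every bump (O(trials) per call)."""
    k = unit.kernel
    centers = _kernel_align_times(unit, trials) + k.peak_latency

    def lam(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rate = np.full(t.shape, unit.baseline_rate)
        for c in centers:
            rate += k.amplitude * np.exp(-(t - c) ** 2 / (2 * k.width_sd ** 2))
        return np.maximum(rate, 0.0)

    return lam


def generate_unit_spikes(unit: UnitSpec, trials: pd.DataFrame,
                         seed: int = 0,
                         duration: float | None = None) -> np.ndarray:
    """Sample one unit's spike train by Poisson thinning.

    Candidates are drawn as a homogeneous Poisson process at the rate
    envelope ``baseline + max(amplitude, 0)`` and kept with probability
    ``lam(t) / lam_max``, so the realized process is exactly an inhomogeneous
    Poisson process with the unit's rate function.

    Returns sorted spike times in seconds.
    """
    if trials.empty:
        raise ValueError("trials table is empty")
    if unit.baseline_rate < 0:
        raise ValueError("baseline rate must be non-negative")
    T = session_duration(trials) if duration is None else float(duration)
    lam_max = unit.baseline_rate + max(unit.kernel.amplitude, 0.0)
    if lam_max == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, n_cand))
    keep = rng.random(n_cand) < rate_function(unit, trials)(cand) / lam_max
    return cand[keep]


def generate_session(n_units: int = 20,
                     n_trials: int = 56,
                     units: list[UnitSpec] | None = None,
                     seed: int = 0,
                     **trial_kwargs) -> SyntheticSession:
    """Generate a complete session: trials plus spike trains for each unit.

    If ``units`` is omitted, ``n_units`` untuned units are created with the
    default RS/FS mix (one FS per ten units, mirroring the ~10% FS fraction
    typical of cortical recordings).
    """
    ss = np.random.SeedSequence(seed)
    trial_seed, unit_seed0 = ss.spawn(2)
    trials = generate_trials(n_trials=n_trials,
                             seed=int(trial_seed.generate_state(1)[0] % 2**31),
                             **trial_kwargs)
    if units is None:
        units = [UnitSpec(unit_id=i,
                          cell_type="FS" if i % 10 == 9 else "RS",
                          baseline_rate=DEFAULT_BASELINE["FS" if i % 10 == 9 else "RS"],
                          peak_to_trough_ms=DEFAULT_PEAK_TO_TROUGH[
                              "FS" if i % 10 == 9 else "RS"])
                 for i in range(n_units)]
    dur = session_duration(trials)
    spike_seeds = unit_seed0.generate_state(len(units))
    spikes = {u.unit_id: generate_unit_spikes(u, trials,
                                              seed=int(s % 2**31),
                                              duration=dur)
              for u, s in zip(units, spike_seeds)}
    return SyntheticSession(trials=trials, units=list(units), spikes=spikes,
                            seed=seed, duration=dur)


# ---------------------------------------------------------------------------
# Raw broadband trace
# ---------------------------------------------------------------------------

def make_waveform_template(peak_to_trough_ms: float,
                           sampling_rate: float = 10_000.0,
                           amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular waveform: negative trough then positive peak.

    The trough sits at the template reference sample and the positive peak
    ``peak_to_trough_ms`` later, so downstream width measurements recover the
    requested duration.  Amplitude scales the trough depth (volts).
    """
    if peak_to_trough_ms <= 0:
        raise ValueError("peak_to_trough_ms must be positive")
    ptt = peak_to_trough_ms / 1000.0
    sd_neg = 0.15 * ptt + 0.04e-3
    sd_pos = 0.35 * ptt + 0.05e-3
    t = np.arange(-0.5e-3, ptt + 1.0e-3, 1.0 / sampling_rate)
    w = (-amplitude * np.exp(-t ** 2 / (2 * sd_neg ** 2))
         + 0.45 * amplitude * np.exp(-(t - ptt) ** 2 / (2 * sd_pos ** 2)))
    return w


def generate_raw_trace(session: SyntheticSession,
                       noise_sd: float = 0.05,
                       sampling_rate: float = 10_000.0,
                       seed: int = 0):
    """Superpose each unit's waveform template on white noise.

    Returns ``(trace, ground_truth)`` where ``ground_truth`` maps unit_id to
    the spike times actually embedded (those fitting inside the trace).
    """
    if sampling_rate < 10_000.0:
        raise ValueError("sampling_rate must be at least 10 kHz")
    n = int(np.ceil(session.duration * sampling_rate)) + 1
    rng = np.random.default_rng(seed)
    trace = (rng.normal(0.0, noise_sd, n) if noise_sd > 0
             else np.zeros(n))
    deadtime_samples = int(round(2e-3 * sampling_rate))
    truth: dict[int, np.ndarray] = {}
    for unit in session.units:
        w = make_waveform_template(unit.peak_to_trough_ms, sampling_rate,
                                   unit.waveform_amplitude)
        if w.size > 3 * deadtime_samples:
            warnings.warn("waveform template long relative to the detection "
                          "deadtime; overlapping events may merge")
        trough = int(np.argmin(w))
        kept = []
        for st in session.spikes[unit.unit_id]:
            i0 = int(round(st * sampling_rate)) - trough
            if i0 < 0 or i0 + w.size > n:
                continue
            trace[i0:i0 + w.size] += w
            kept.append((i0 + trough) / sampling_rate)
        truth[unit.unit_id] = np.asarray(kept)
    return trace, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, float_format="%.6f")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["correct"] = df["correct"].astype(bool)
    return df


def write_spikes_csv(session_or_table, path) -> None:
    table = (session_or_table.spike_table()
             if isinstance(session_or_table, SyntheticSession)
             else session_or_table)
    table.to_csv(path, index=False, float_format="%.6f")


def read_spikes_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {int(uid): np.sort(g["spike_time_s"].to_numpy(dtype=float))
            for uid, g in df.groupby("unit_id")}


def write_trace_h5(trace: np.ndarray, sampling_rate: float, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=trace)
        d.attrs["sampling_rate"] = sampling_rate


def read_trace_h5(path) -> tuple[np.ndarray, float]:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["trace"]
        return d[()], float(d.attrs["sampling_rate"])
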