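"""Event-aligned spike binning and baseline z-normalization (PETHs).

Per-trial spike counts are taken in fixed-width bins (200 ms default)
relative to an alignment event (trial initiation or target touch).  Each
unit's counts are z-scored against its inter-trial-interval baseline: the
7 s immediately preceding trial initiation is cut into the same 200-ms bins,
the mean and SD of those bin counts are computed per trial and averaged
across trials to a session-level baseline for the unit, and every analysis
bin is transformed as (count - baseline_mean) / baseline_sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASELINE_DURATION = 7.0   # s of ITI preceding initiation


@dataclass(frozen=True)
class BinSpec:
    """Analysis window and bin width relative to the alignment event."""

    window: tuple[float, float] = (-2.0, 3.0)
    binwidth: float = 0.2
    alignment: str = "t_touch"   # 't_touch' | 't_init'

    def __post_init__(self) -> None:
        start, end = self.window
        if start >= end:
            raise ValueError("window start must precede end")
        if self.binwidth <= 0:
            raise ValueError("binwidth must be positive")
        n = (end - start) / self.binwidth
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window length must be a multiple of binwidth")

    @property
    def n_bins(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.binwidth))

    @property
    def edges(self) -> np.ndarray:
        return self.window[0] + self.binwidth * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window[0] + self.binwidth * (np.arange(self.n_bins) + 0.5)


@dataclass
class BaselineStats:
    """Session-level baseline bin statistics for one unit (count units)."""

    mean: float                 # mean count per baseline bin
    sd: float                   # SD of baseline bin counts
    per_trial_mean: np.ndarray
    per_trial_sd: np.ndarray
    included: np.ndarray        # trials with a full baseline window
    binwidth: float = 0.2

    @property
    def rate_hz(self) -> float:
        return self.mean / self.binwidth


@dataclass
class ZScoredPETH:
    """Trials x bins matrix of baseline-normalized firing (z units)."""

    values: np.ndarray
    bin_centers: np.ndarray
    unit_id: int | None = None
    alignment: str = "t_touch"
    trial_ids: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def bin_spikes(spike_times: np.ndarray, event_times: np.ndarray,
               spec: BinSpec = BinSpec()) -> np.ndarray:
    """Count spikes in half-open bins [left, right) around each event.

    Returns a (trials, bins) integer matrix; a spike exactly on a bin's left
    edge is counted in that bin.  Overlapping trial windows are allowed (a
    spike may contribute to more than one trial) but flagged with a warning.
    """
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    events = np.asarray(event_times, dtype=float)
    span = spec.window[1] - spec.window[0]
    if events.size > 1 and (np.diff(np.sort(events)) < span).any():
        warnings.warn("trial windows overlap; spikes may be counted in "
                      "more than one trial")
    abs_edges = events[:, None] + spec.edges[None, :]
    idx = np.searchsorted(spikes, abs_edges, side="left")
    return np.diff(idx, axis=1)


def baseline_stats(spike_times: np.ndarray, trials: pd.DataFrame,
                   binwidth: float = 0.2,
                   baseline_duration: float = BASELINE_DURATION
                   ) -> BaselineStats:
    """Baseline bin statistics from the pre-initiation inter-trial interval.

    For each trial the ``baseline_duration`` seconds ending at ``t_init``
    are cut into ``binwidth`` bins; trials whose baseline window would reach
    into the previous trial (before its touch/reward) are flagged and
    excluded from the session average.
    """
    n_bins = int(round(baseline_duration / binwidth))
    t_init = trials["t_init"].to_numpy(dtype=float)

    prev_end = np.full(t_init.size, -np.inf)
    if t_init.size > 1:
        last_event = np.nanmax(
            trials[["t_touch", "t_reward"]].to_numpy(dtype=float), axis=1)
        prev_end[1:] = last_event[:-1]
    included = (t_init - prev_end) >= baseline_duration - 1e-9
    if not included.all():
        warnings.warn(f"{int((~included).sum())} trial(s) lack a full "
                      f"{baseline_duration:g}-s baseline window; excluded "
                      "from the baseline average")

    spec = BinSpec(window=(-baseline_duration, 0.0), binwidth=binwidth,
                   alignment="t_init")
    counts = bin_spikes(spike_times, t_init, spec)
    per_mean = counts.mean(axis=1)
    per_sd = counts.std(axis=1, ddof=0)
    if not included.any():
        raise ValueError("no trial has a full baseline window")
    mean = float(per_mean[included].mean())
    sd = float(per_sd[included].mean())
    assert counts.shape[1] == n_bins
    return BaselineStats(mean=mean, sd=sd, per_trial_mean=per_mean,
                         per_trial_sd=per_sd, included=included,
                         binwidth=binwidth)


def pooled_baseline_sd(baselines: list[BaselineStats]) -> float:
    """Fallback SD for silent units: mean baseline SD across all units."""
    sds = np.array([b.sd for b in baselines], dtype=float)
    return float(sds.mean())


def zscore_peth(counts: np.ndarray, baseline: BaselineStats,
                spec: BinSpec = BinSpec(), unit_id: int | None = None,
                fallback_sd: float | None = None,
                trial_ids: np.ndarray | None = None) -> ZScoredPETH:
    """z = (count - baseline_mean) / baseline_sd, elementwise.

    A unit whose own baseline SD is zero (silent or perfectly regular in the
    baseline) uses ``fallback_sd`` — typically the SD pooled across all
    units' baselines — with a logged substitution.
    """
    sd = baseline.sd
    if sd == 0:
        if fallback_sd is None or fallback_sd <= 0:
            raise ValueError("baseline SD is zero and no positive fallback "
                             "SD was provided")
        warnings.warn("baseline SD is zero; substituting the pooled SD "
                      f"{fallback_sd:g}")
        sd = fallback_sd
    values = (np.asarray(counts, dtype=float) - baseline.mean) / sd
    return ZScoredPETH(values=values, bin_centers=spec.bin_centers,
                       unit_id=unit_id, alignment=spec.alignment,
                       trial_ids=trial_ids)


def unit_zscored_peth(spike_times: np.ndarray, trials: pd.DataFrame,
                      spec: BinSpec = BinSpec(), unit_id: int | None = None,
                      correct_only: bool = True,
                      fallback_sd: float | None = None) -> ZScoredPETH:
    """Convenience end-to-end PETH for one unit.

    Baseline statistics always use every trial with a full baseline window;
    the analysis matrix is restricted to correct trials when
    ``correct_only`` (the default, matching the convention of analysing
    correct trials only).
    """
    base = baseline_stats(spike_times, trials, binwidth=spec.binwidth)
    use = trials[trials["correct"]] if correct_only else trials
    events = use[spec.alignment].to_numpy(dtype=float)
    counts = bin_spikes(spike_times, events, spec)
    return zscore_peth(counts, base, spec=spec, unit_id=unit_id,
                       fallback_sd=fallback_sd,
                       trial_ids=use["trial_id"].to_numpy())
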