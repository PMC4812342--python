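"""Sliding-window population decoding of task variables with an SVM.

Per-unit firing rates are computed in a 400-ms window sliding in 100-ms
steps across the analysis window centered on target touch.  Decoding runs
per bin with a linear-kernel support vector machine and leave-one-out
cross-validation, either within a session or on pseudo-simultaneous
populations pooled across sessions (20 randomly sampled trials per
condition per session, 15 iterations).  Chance level comes from a shuffle
control (labels permuted before decoding) and per-bin significance from
Bonferroni-corrected paired t-tests between the test and shuffle accuracy
series across replicates (sessions or iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC


@dataclass
class FeatureMatrix:
    """Per-bin trials x units firing-rate features."""

    rates: np.ndarray        # (bins, trials, units), Hz
    bin_centers: np.ndarray  # s relative to the alignment event
    labels: np.ndarray       # (trials,) +/-1 codes of the decoded variable

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]


def sliding_fr(spikes_by_unit: dict[int, np.ndarray], event_times: np.ndarray,
               labels: np.ndarray, window: tuple[float, float] = (-1.0, 1.0),
               win_len: float = 0.4, step: float = 0.1) -> FeatureMatrix:
    """Firing-rate features in a sliding window around each event.

    ``rates[b, i, u]`` is unit u's spike count in
    ``[center_b - win_len/2, center_b + win_len/2)`` on trial i, divided by
    ``win_len``.  Window centers run from ``window[0]`` to ``window[1]``
    inclusive in ``step`` increments.
    """
    if win_len < step:
        raise ValueError("win_len must be at least the step size")
    lo, hi = window
    if hi - lo < win_len - 1e-9:
        raise ValueError("analysis window shorter than the sliding window")
    centers = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    events = np.asarray(event_times, dtype=float)
    labels = np.asarray(labels)
    if labels.size != events.size:
        raise ValueError("one label per event required")
    unit_ids = sorted(spikes_by_unit)
    rates = np.empty((centers.size, events.size, len(unit_ids)))
    half = win_len / 2.0
    for u, uid in enumerate(unit_ids):
        sp = np.sort(np.asarray(spikes_by_unit[uid], dtype=float))
        left = events[None, :] + centers[:, None] - half
        counts = (np.searchsorted(sp, left + win_len, side="left")
                  - np.searchsorted(sp, left, side="left"))
        rates[:, :, u] = counts / win_len
    return FeatureMatrix(rates=rates, bin_centers=centers, labels=labels)


def _make_svm(C: float = 1.0, kernel: str = "linear") -> SVC:
    return SVC(C=C, kernel=kernel)


def loo_decode(rates: np.ndarray, labels: np.ndarray, C: float = 1.0,
               kernel: str = "linear", standardize: bool = False,
               balance_training: bool = True, seed: int = 0) -> np.ndarray:
    """Leave-one-out decoding accuracy per bin.

    For each bin and held-out trial, a fresh classifier is trained on every
    other trial and predicts the held-out label; accuracy is the fraction of
    correct predictions.  With ``balance_training`` (default) one random
    trial of the opposite class is also dropped from each training fold so
    the fold stays class-balanced: plain leave-one-out leaves the held-out
    trial's class underrepresented by one, which biases chance-level
    (shuffle-control) accuracy below 50% by roughly 1/(2 x trials).  Raw
    rates are used by default; ``standardize`` z-scores each unit's
    features within the training fold.
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    n_bins, n_trials, _ = rates.shape
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("decoding requires two classes")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 trials per class for leave-one-out")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_bins)
    for b in range(n_bins):
        Xb = rates[b]
        correct = 0
        for i in range(n_trials):
            train = np.flatnonzero(np.arange(n_trials) != i)
            if balance_training:
                opposite = train[labels[train] != labels[i]]
                if opposite.size > (labels[train] == labels[i]).sum():
                    train = train[train != rng.choice(opposite)]
            Xtr, Xte = Xb[train], Xb[i:i + 1]
            if standardize:
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
            clf = _make_svm(C=C, kernel=kernel)
            clf.fit(Xtr, labels[train])
            correct += int(clf.predict(Xte)[0] == labels[i])
        acc[b] = correct / n_trials
    return acc


def loo_decode_session(features: FeatureMatrix, shuffle: bool = False,
                       seed: int = 0, **kwargs) -> np.ndarray:
    """Per-session leave-one-out accuracy series (optionally label-shuffled)."""
    labels = features.labels
    if shuffle:
        labels = np.random.default_rng(seed).permutation(labels)
    return loo_decode(features.rates, labels, **kwargs)


def pooled_pseudo_decode(session_features: list[FeatureMatrix],
                         n_per_cond: int = 20, n_iter: int = 15,
                         seed: int = 0, shuffle: bool = False,
                         **kwargs) -> np.ndarray:
    """Pseudo-simultaneous decoding of populations pooled across sessions.

    Each iteration samples ``n_per_cond`` trials per condition level from
    every session, concatenates unit features across sessions into
    pseudo-trials — trials of one condition occupy the first half of the
    matrix, the other condition the second half — and runs leave-one-out
    decoding.  Sessions lacking enough trials of either level are dropped
    with a warning.  Returns an (n_iter, bins) accuracy array; the shuffle
    control permutes the pseudo-trial labels before decoding.
    """
    rng = np.random.default_rng(seed)
    usable = []
    for s, f in enumerate(session_features):
        counts = {c: int((f.labels == c).sum()) for c in (-1, +1)}
        if min(counts.values()) >= n_per_cond:
            usable.append(f)
        else:
            warnings.warn(f"session {s} has too few trials per condition "
                          f"({counts}); dropped from pooling")
    if not usable:
        raise ValueError("no session has enough trials per condition")
    grids = [f.bin_centers for f in usable]
    if any(g.shape != grids[0].shape or not np.allclose(g, grids[0])
           for g in grids):
        raise ValueError("sessions have mismatched bin grids")
    n_bins = usable[0].n_bins
    labels = np.concatenate([np.full(n_per_cond, -1), np.full(n_per_cond, +1)])
    acc = np.empty((n_iter, n_bins))
    for it in range(n_iter):
        blocks = []
        for f in usable:
            cols = []
            for c in (-1, +1):
                idx = np.flatnonzero(f.labels == c)
                pick = rng.choice(idx, size=n_per_cond, replace=False)
                cols.append(f.rates[:, pick, :])
            blocks.append(np.concatenate(cols, axis=1))
        pseudo = np.concatenate(blocks, axis=2)   # (bins, 2*n_per_cond, units)
        lab = rng.permutation(labels) if shuffle else labels
        acc[it] = loo_decode(pseudo, lab, **kwargs)
    return acc


@dataclass
class DecodingResult:
    """Test vs shuffle accuracy series with per-bin significance."""

    bin_centers: np.ndarray
    test: np.ndarray       # (replicates, bins)
    shuffle: np.ndarray    # (replicates, bins)
    significant: np.ndarray
    p_corrected: np.ndarray

    @property
    def mean_test(self) -> np.ndarray:
        return self.test.mean(axis=0)

    @property
    def mean_shuffle(self) -> np.ndarray:
        return self.shuffle.mean(axis=0)

    def ci95(self, which: str = "test") -> tuple[np.ndarray, np.ndarray]:
        """Normal-approximation 95% CI of the mean across replicates."""
        a = self.test if which == "test" else self.shuffle
        m = a.mean(axis=0)
        sem = a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])
        return m - 1.96 * sem, m + 1.96 * sem


def decode_significance(test: np.ndarray, shuffle: np.ndarray,
                        alpha: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin Bonferroni-corrected paired t-tests of test vs shuffle.

    ``test`` and ``shuffle`` are (replicates, bins) with replicates paired
    (same session or iteration).  Returns (flags, corrected p).
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    shuffle = np.atleast_2d(np.asarray(shuffle, dtype=float))
    if test.shape != shuffle.shape:
        raise ValueError("test and shuffle series must have the same shape")
    if test.shape[0] < 2:
        raise ValueError("need >= 2 paired replicates")
    n_bins = test.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_rel(test, shuffle, axis=0)
    p = np.where(np.isnan(p), 1.0, p)           # identical series: no evidence
    p_corr = np.minimum(p * n_bins, 1.0)
    return p_corr < alpha, p_corr


def decoding_result(bin_centers: np.ndarray, test: np.ndarray,
                    shuffle: np.ndarray, alpha: float = 0.05) -> DecodingResult:
    flags, p_corr = decode_significance(test, shuffle, alpha)
    return DecodingResult(bin_centers=np.asarray(bin_centers),
                          test=np.atleast_2d(test),
                          shuffle=np.atleast_2d(shuffle),
                          significant=flags, p_corrected=p_corr)
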