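"""Bin-wise linear-model encoding analysis with a shuffle run-length null.

For each unit, the z-scored firing rate across trials is regressed, one
analysis bin at a time, on +/-1-coded task variables (difficulty: easy=-1
hard=+1; location: left=-1 right=+1; optionally their interaction):

    r(i, t) = b0(t) + bD(t)*Difficulty_i + bL(t)*Location_i [+ bDL(t)*D*L] + e

The per-bin coefficient series traces when and how strongly the unit
discriminates conditions; its sign gives the preferred condition.  Per
variable and bin, significance uses the partial F statistic (the squared t
of that coefficient, df 1 and n-k).  Because isolated significant bins arise
by chance, a unit is called "preferring" only when its p < alpha bins form a
contiguous run longer than a shuffle-calibrated threshold: condition labels
are permuted (100 shuffles per unit), run lengths of consecutive significant
bins pooled across shuffles and variables, and the nearest-rank 95th
percentile of the pooled run lengths taken as the threshold.  Under the
standard task design this threshold is 1 bin, i.e. at least 2 contiguous
significant bins are required for preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .peth import ZScoredPETH

MAIN_VARIABLES = ("difficulty", "location")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def design_matrix(trials: pd.DataFrame, with_interaction: bool = False,
                  correct_only: bool = True
                  ) -> tuple[np.ndarray, list[str]]:
    """Build the trials x predictors matrix from a trial table.

    Columns: intercept, difficulty (+/-1), location (+/-1), and optionally
    the difficulty x location interaction.  Requires exact +/-1 coding and
    at least two trials per level of each variable.
    """
    use = trials[trials["correct"]] if correct_only else trials
    cols = [np.ones(len(use))]
    names = ["intercept"]
    for var in MAIN_VARIABLES:
        x = use[var].to_numpy(dtype=float)
        if not np.isin(x, (-1.0, 1.0)).all():
            raise ValueError(f"{var} codes must be exactly -1/+1")
        if min((x == -1).sum(), (x == 1).sum()) < 2:
            raise ValueError(f"need >= 2 trials per {var} level")
        cols.append(x)
        names.append(var)
    if with_interaction:
        cols.append(cols[1] * cols[2])
        names.append("interaction")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


@dataclass
class CoefficientSeries:
    """Per-bin OLS results for one unit: the preference time-series."""

    beta: np.ndarray          # (predictors, bins)
    F: np.ndarray             # (predictors, bins) partial F = t^2
    p: np.ndarray             # (predictors, bins)
    names: list[str]
    bin_centers: np.ndarray
    dof: int
    unit_id: int | None = None

    def var(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (unit_id, variable, bin_center_s, beta, F, p)."""
        rows = []
        for k, name in enumerate(self.names):
            for b, c in enumerate(self.bin_centers):
                rows.append((self.unit_id, name, c, self.beta[k, b],
                             self.F[k, b], self.p[k, b]))
        return pd.DataFrame(rows, columns=["unit_id", "variable",
                                           "bin_center_s", "beta", "F", "p"])


def _ols_series(Y: np.ndarray, X: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized per-bin OLS of Y (trials x bins) on X (trials x k).

    Returns (beta, F, p, dof) with beta (k, bins); F is the squared t of
    each coefficient, referred to F(1, n-k).
    """
    n, k = X.shape
    if n <= k:
        raise ValueError("more predictors than trials")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                      # (k, bins)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof       # (bins,)
    var_beta = np.diag(XtX_inv)[:, None] * sigma2[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(var_beta > 0, beta ** 2 / var_beta, 0.0)
    p = stats.f.sf(F, 1, dof)
    return beta, F, p, dof


def fit_binwise_glm(zpeth: ZScoredPETH, X: np.ndarray, names: list[str],
                    unit_id: int | None = None) -> CoefficientSeries:
    """Fit the per-bin linear model of z-scored firing on the task design."""
    Y = np.asarray(zpeth.values, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"design has {X.shape[0]} rows but PETH has "
                         f"{Y.shape[0]} trials")
    beta, F, p, dof = _ols_series(Y, X)
    return CoefficientSeries(beta=beta, F=F, p=p, names=list(names),
                             bin_centers=np.asarray(zpeth.bin_centers),
                             dof=dof, unit_id=unit_id)


# ---------------------------------------------------------------------------
# Contiguous-bin significance
# ---------------------------------------------------------------------------

def contiguous_runs(p_series: np.ndarray, alpha: float = 0.05
                    ) -> list[tuple[int, int]]:
    """Maximal runs of consecutive bins with p < alpha, as (start, length)."""
    sig = np.asarray(p_series) < alpha
    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, sig.size - start))
    return runs


@dataclass
class ShuffleNull:
    """Pooled run-length null distribution from label shuffles."""

    run_lengths: np.ndarray     # every contiguous-run length observed
    threshold: int              # nearest-rank 95th percentile (0 if empty)
    n_shuffles: int
    alpha: float


def _nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: smallest v with CDF(v) >= q/100."""
    v = np.sort(np.asarray(values))
    rank = int(np.ceil(q / 100.0 * v.size)) - 1
    return float(v[max(rank, 0)])


def shuffle_null(zpeth: ZScoredPETH, X: np.ndarray, names: list[str],
                 n_shuffles: int = 100, alpha: float = 0.05,
                 seed: int = 0,
                 variables: tuple[str, ...] = MAIN_VARIABLES) -> ShuffleNull:
    """Run-length null by joint permutation of condition labels.

    Each shuffle permutes the non-intercept design rows jointly across
    trials (breaking the trial-label link while preserving the balance of
    the four trial types), refits the per-bin model, and records the lengths
    of every maximal run of significant bins for each task variable.  The
    threshold is the nearest-rank 95th percentile of the pooled lengths
    (defined as 0 when no run occurs).
    """
    Y = np.asarray(zpeth.values, dtype=float)
    n = Y.shape[0]
    if n != X.shape[0]:
        raise ValueError("design/PETH row mismatch")
    var_idx = [names.index(v) for v in variables]
    for j in var_idx:
        if np.unique(X[:, j]).size < 2:
            raise ValueError("degenerate design: a shuffled variable has a "
                             "single level")
    rng = np.random.default_rng(seed)
    lengths: list[int] = []
    Xs = X.copy()
    cond_cols = [j for j in range(X.shape[1]) if names[j] != "intercept"]
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        Xs[:, cond_cols] = X[np.ix_(perm, cond_cols)]
        _, _, p, _ = _ols_series(Y, Xs)
        for j in var_idx:
            lengths.extend(length for _s, length in contiguous_runs(p[j], alpha))
    pooled = np.asarray(lengths, dtype=int)
    threshold = int(_nearest_rank(pooled, 95.0)) if pooled.size else 0
    return ShuffleNull(run_lengths=pooled, threshold=threshold,
                       n_shuffles=n_shuffles, alpha=alpha)


def pooled_threshold(nulls: list[ShuffleNull]) -> int:
    """Threshold from run lengths pooled across many units' nulls."""
    pooled = np.concatenate([n.run_lengths for n in nulls]) if nulls else np.empty(0)
    return int(_nearest_rank(pooled, 95.0)) if pooled.size else 0


# ---------------------------------------------------------------------------
# Preference classification
# ---------------------------------------------------------------------------

@dataclass
class PreferenceCall:
    """Preference verdict for one unit and task variable."""

    unit_id: int | None
    variable: str
    significant: bool
    runs: list[tuple[int, int]] = field(default_factory=list)
    preferred_code: int | None = None   # sign of the coefficient at its peak
    peak_time: float | None = None
    peak_value: float | None = None
    peak_bin: int | None = None


def classify_preference(series: CoefficientSeries, null: ShuffleNull,
                        alpha: float = 0.05,
                        variables: tuple[str, ...] | None = None
                        ) -> dict[str, PreferenceCall]:
    """Call preference per task variable using the contiguous-bin criterion.

    A variable is significant when some run of consecutively significant
    bins is strictly longer than the null threshold (i.e. length >=
    threshold + 1).  The preference peak is the bin with the largest
    absolute coefficient inside the qualifying runs; ties break toward the
    earlier bin, and the preferred condition is the sign of the coefficient
    there.
    """
    if variables is None:
        variables = tuple(n for n in series.names if n != "intercept")
    need = null.threshold + 1
    calls: dict[str, PreferenceCall] = {}
    for var in variables:
        j = series.var(var)
        runs = contiguous_runs(series.p[j], alpha)
        qual = [(s, ln) for s, ln in runs if ln >= need]
        call = PreferenceCall(unit_id=series.unit_id, variable=var,
                              significant=bool(qual), runs=runs)
        if qual:
            bins = np.concatenate([np.arange(s, s + ln) for s, ln in qual])
            peak_bin = int(bins[np.argmax(np.abs(series.beta[j, bins]))])
            call.peak_bin = peak_bin
            call.peak_time = float(series.bin_centers[peak_bin])
            call.peak_value = float(series.beta[j, peak_bin])
            call.preferred_code = int(np.sign(call.peak_value)) or +1
        calls[var] = call
    return calls


def preference_label(calls: dict[str, PreferenceCall]) -> str:
    """'difficulty' / 'location' / 'both' / 'none' for one unit."""
    d = calls.get("difficulty") and calls["difficulty"].significant
    loc = calls.get("location") and calls["location"].significant
    if d and loc:
        return "both"
    if d:
        return "difficulty"
    if loc:
        return "location"
    return "none"


def calls_to_frame(all_calls: list[dict[str, PreferenceCall]]) -> pd.DataFrame:
    rows = []
    for calls in all_calls:
        for var, c in calls.items():
            rows.append((c.unit_id, var, c.significant, c.preferred_code,
                         c.peak_time, c.peak_value,
                         max((ln for _s, ln in c.runs), default=0)))
    return pd.DataFrame(rows, columns=["unit_id", "variable", "significant",
                                       "preferred_code", "peak_time",
                                       "peak_value", "max_run"])
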