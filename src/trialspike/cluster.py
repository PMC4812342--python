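"""Ward clustering of preference-peak latencies into temporal families.

Units with significant preference are grouped by (cell type, task variable,
sign of the coefficient peak); within each group the 1-D peak times are
clustered agglomeratively with Ward's criterion, and the dendrogram is cut
at 95% of its full height to delimit cluster families.  Peak times — rather
than whole coefficient time-series — carry the signal because preference is
transient: the brief peak epoch is the discriminative feature, and whole-
series distances would be dominated by the long uninformative remainder of
the trial.  Each family is summarized by its member-averaged coefficient
series and condition-split PETHs, with epoch firing-rate contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .glm import CoefficientSeries, PreferenceCall
from .peth import ZScoredPETH


@dataclass(frozen=True)
class PeakRecord:
    unit_id: int
    cell_type: str
    variable: str
    sign: int            # +1 / -1 sign of the coefficient peak
    peak_time: float


@dataclass
class ClusterFamily:
    family_id: int
    unit_ids: list[int]
    peak_time_range: tuple[float, float]
    mean_coefficients: np.ndarray | None = None   # (bins,)
    mean_peth: dict[int, np.ndarray] = field(default_factory=dict)
    bin_centers: np.ndarray | None = None
    epoch_tests: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.unit_ids)


def collect_peaks(calls_by_unit: dict[int, dict[str, PreferenceCall]],
                  cell_types: dict[int, str],
                  variable: str,
                  restrict_cell_type: str | None = "RS"
                  ) -> dict[int, list[PeakRecord]]:
    """Build peak records for significant units, grouped by peak sign.

    Clustering defaults to RS units only; FS counts are typically too low
    for a stable dendrogram.  Returns ``{sign: [PeakRecord, ...]}``.
    """
    groups: dict[int, list[PeakRecord]] = {+1: [], -1: []}
    for uid, calls in calls_by_unit.items():
        call = calls.get(variable)
        if call is None or not call.significant:
            continue
        ct = cell_types[uid]
        if restrict_cell_type is not None and ct != restrict_cell_type:
            continue
        rec = PeakRecord(unit_id=uid, cell_type=ct, variable=variable,
                         sign=call.preferred_code, peak_time=call.peak_time)
        groups[rec.sign].append(rec)
    return groups


def ward_cluster(peak_times: np.ndarray) -> np.ndarray:
    """Ward linkage over 1-D peak times; merge heights are non-decreasing."""
    x = np.asarray(peak_times, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2:
        warnings.warn("singleton group: trivial one-leaf tree")
        return np.empty((0, 4))
    return linkage(x, method="ward")


def cut_tree_families(Z: np.ndarray, peaks: list[PeakRecord] | np.ndarray,
                      fraction: float = 0.95) -> list[ClusterFamily]:
    """Cut the dendrogram at ``fraction`` of its full height.

    Families are the connected components strictly below the cut: leaves
    whose cophenetic distance is below ``fraction * max_merge_height`` fall
    in the same family.  ``fraction`` must lie in (0, 1].
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    times = (np.asarray([p.peak_time for p in peaks])
             if peaks and isinstance(peaks[0], PeakRecord)
             else np.asarray(peaks, dtype=float))
    ids = ([p.unit_id for p in peaks]
           if peaks and isinstance(peaks[0], PeakRecord)
           else list(range(times.size)))
    if Z.shape[0] == 0:
        return [ClusterFamily(family_id=0, unit_ids=list(ids),
                              peak_time_range=(float(times.min()),
                                               float(times.max())))]
    cut = fraction * Z[:, 2].max()
    labels = fcluster(Z, t=cut, criterion="distance")
    families = []
    for fid in np.unique(labels):
        mask = labels == fid
        members = [ids[i] for i in np.flatnonzero(mask)]
        t = times[mask]
        families.append(ClusterFamily(family_id=int(fid) - 1,
                                      unit_ids=members,
                                      peak_time_range=(float(t.min()),
                                                       float(t.max()))))
    families.sort(key=lambda f: f.peak_time_range[0])
    for new_id, fam in enumerate(families):
        fam.family_id = new_id
    return families


#: Default epoch contrasts mirroring the behavioural phases around touch.
DEFAULT_EPOCHS = {"stimulus_viewing": (-2.0, -0.5),
                  "reward_acquisition": (0.5, 2.5)}


def summarize_family(family: ClusterFamily,
                     series_by_unit: dict[int, CoefficientSeries],
                     zpeth_by_unit: dict[int, ZScoredPETH],
                     condition_by_unit: dict[int, np.ndarray],
                     variable: str,
                     epochs: dict[str, tuple[float, float]] | None = None
                     ) -> ClusterFamily:
    """Attach member-averaged series, condition PETHs, and epoch tests.

    ``condition_by_unit`` maps unit_id to the +/-1 code of each PETH trial
    for the clustered variable.  Epoch tests are paired t-tests across the
    family's units of the epoch-mean z difference between condition levels.
    """
    if epochs is None:
        epochs = DEFAULT_EPOCHS
    grids = [series_by_unit[u].bin_centers for u in family.unit_ids]
    if any(g.shape != grids[0].shape or not np.allclose(g, grids[0])
           for g in grids):
        raise ValueError("member units have mismatched bin grids")
    centers = grids[0]

    coef = np.stack([series_by_unit[u].beta[series_by_unit[u].var(variable)]
                     for u in family.unit_ids])
    family.mean_coefficients = coef.mean(axis=0)
    family.bin_centers = centers

    per_unit_cond_mean: dict[int, np.ndarray] = {}
    for level in (-1, +1):
        rows = []
        for u in family.unit_ids:
            z = zpeth_by_unit[u]
            mask = condition_by_unit[u] == level
            rows.append(z.values[mask].mean(axis=0))
        per_unit_cond_mean[level] = np.stack(rows)
        family.mean_peth[level] = per_unit_cond_mean[level].mean(axis=0)

    family.epoch_tests = {}
    for name, (lo, hi) in epochs.items():
        sel = (centers >= lo) & (centers < hi)
        if not sel.any():
            raise ValueError(f"epoch {name} outside the analysis window")
        a = per_unit_cond_mean[+1][:, sel].mean(axis=1)
        b = per_unit_cond_mean[-1][:, sel].mean(axis=1)
        if len(family.unit_ids) >= 2:
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = np.nan, np.nan
        family.epoch_tests[name] = (float(t), float(p))
    return family


def families_to_frame(families: list[ClusterFamily]) -> pd.DataFrame:
    rows = [(f.family_id, uid) for f in families for uid in f.unit_ids]
    return pd.DataFrame(rows, columns=["family_id", "unit_id"])


def linkage_to_nested(Z: np.ndarray, n_leaves: int):
    """Serialize a linkage tree as nested lists of leaf indices."""
    nodes: dict[int, object] = {i: i for i in range(n_leaves)}
    for i, (a, b, _h, _n) in enumerate(Z):
        nodes[n_leaves + i] = [nodes.pop(int(a)), nodes.pop(int(b))]
    remaining = list(nodes.values())
    return remaining[0] if len(remaining) == 1 else remaining
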