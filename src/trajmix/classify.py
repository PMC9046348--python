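"""Baseline neurocognitive status: SuperAger (SA), cognitively normal (CN),
cognitively impaired (CI).

SA requires youthful global performance (peak-age global T >= 40, i.e.
within 1 SD of the 25-year-old normative mean) with no isolated domain
impairment on chronological-age norms (every domain chronological T >= 40).
Non-SA participants are split by the global deficit score (GDS): each
domain's chronological T maps to 0-5 deficit points and a mean of >= 0.5
across domains denotes impairment.  Both the deficit mapping and the 0.5
cutoff follow the deficit-score literature and are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: deficit points by descending T bin: [40, inf) -> 0, [35, 40) -> 1,
#: [30, 35) -> 2, [25, 30) -> 3, [20, 25) -> 4, (-inf, 20) -> 5.
DEFICIT_BINS = (40.0, 35.0, 30.0, 25.0, 20.0)
GDS_IMPAIRMENT_CUTOFF = 0.5
SA_T_CUTOFF = 40.0

LABELS = ("SA", "CN", "CI")


class ClassificationError(ValueError):
    pass


@dataclass
class BaselineStatus:
    label: str
    peak_global_T: float
    domain_chronological_Ts: tuple
    gds: float


def deficit_score(T, bins=DEFICIT_BINS):
    """Map a chronological-age T-score to deficit points (0 = no deficit).

    The lower bound of each bin is closed: T = 40 earns 0 points.
    """
    t = np.asarray(T, dtype=float)
    if np.any(~np.isfinite(t)):
        raise ClassificationError("deficit_score requires finite T")
    points = np.zeros_like(t, dtype=int)
    for score, lo in enumerate(bins):
        points = np.where(t < lo, score + 1, points)
    return points if points.ndim else int(points)


def global_deficit_score(domain_Ts, bins=DEFICIT_BINS) -> float:
    """Mean deficit points over the available (non-NaN) domains."""
    arr = np.asarray(domain_Ts, dtype=float)
    avail = arr[~np.isnan(arr)]
    if avail.size == 0:
        raise ClassificationError("no domain scores available")
    return float(np.mean(deficit_score(avail, bins)))


def classify_baseline(
    peak_global_T: float,
    domain_chronological_Ts,
    sa_cutoff: float = SA_T_CUTOFF,
    gds_cutoff: float = GDS_IMPAIRMENT_CUTOFF,
    bins=DEFICIT_BINS,
) -> BaselineStatus:
    """Assign exactly one of SA / CN / CI at baseline.

    SA iff the peak-age global T clears ``sa_cutoff`` and no domain
    chronological T falls below it; otherwise CI iff the global deficit
    score reaches ``gds_cutoff``, else CN.
    """
    if peak_global_T is None or not np.isfinite(peak_global_T):
        raise ClassificationError("peak_global_T is required")
    doms = np.asarray(domain_chronological_Ts, dtype=float)
    avail = doms[~np.isnan(doms)]
    if avail.size == 0:
        raise ClassificationError("at least one domain score is required")
    gds = float(np.mean(deficit_score(avail, bins)))
    if peak_global_T >= sa_cutoff and np.all(avail >= sa_cutoff):
        label = "SA"
    elif gds >= gds_cutoff:
        label = "CI"
    else:
        label = "CN"
    return BaselineStatus(label, float(peak_global_T), tuple(doms), gds)


def crosstab_status_by_class(statuses, classes):
    """Contingency table of baseline status by latent class, with chi-square.

    Returns (counts, row_pct, col_pct, chi2, p).  Degenerate tables (a single
    status or class level) yield chi2 = p = NaN with a warning rather than a
    crash.
    """
    statuses = list(statuses)
    classes = list(classes)
    if len(statuses) == 0:
        raise ClassificationError("empty input")
    if len(statuses) != len(classes):
        raise ClassificationError("statuses and classes must align")
    labels = [s.label if isinstance(s, BaselineStatus) else s for s in statuses]
    order = [l for l in LABELS if l in set(labels)] + sorted(
        set(labels) - set(LABELS)
    )
    counts = pd.crosstab(
        pd.Categorical(labels, categories=order),
        pd.Series(classes, name="class"),
        rownames=["status"],
    )
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100
    if min(counts.shape) < 2:
        warnings.warn(
            "degenerate contingency table (single status or class level); "
            "chi-square undefined"
        )
        return counts, row_pct, col_pct, float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy())
    return counts, row_pct, col_pct, float(chi2), float(p)
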