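"""Tumor-vs-normal differential flux testing and Z-score fluxome normalization.

All group comparisons use the two-sided Mann–Whitney U test with a raw
p < 0.001 significance cutoff and no multiplicity correction; direction is
read from the median difference.  Z-score profiles standardize each cancer
sample's module fluxes against the matched normal-control distribution.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InputError

SIGNIFICANCE_CUTOFF = 1e-3
EXACT_MAX_N = 20


class MannWhitneyResult(NamedTuple):
    U: float
    p_two_sided: float


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test; U is reported for the first sample.

    Uses the exact permutation null when the pooled size is at most 20 and
    there are no ties, otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both input vectors must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def differential_flux(
    flux: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "tumor",
    group_b: str = "normal",
    alpha: float = SIGNIFICANCE_CUTOFF,
) -> pd.DataFrame:
    """Per-column two-group differential table on a sample x feature matrix.

    Works identically for module fluxes and for balance-profile columns
    (abundance-change surrogates).  One row per column with group medians,
    the U statistic, the two-sided p-value, a significance flag at raw
    ``p < alpha``, and the direction of change in ``group_a`` relative to
    ``group_b``.
    """
    labels = labels.reindex(flux.index)
    in_a = (labels == group_a).to_numpy()
    in_b = (labels == group_b).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise InputError(f"both groups {group_a!r} and {group_b!r} must be non-empty")
    rows = []
    for col in flux.columns:
        a = flux.loc[in_a, col].to_numpy(dtype=float)
        b = flux.loc[in_b, col].to_numpy(dtype=float)
        u, p = mann_whitney_u(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        direction = "increase" if med_a > med_b else ("decrease" if med_a < med_b else "none")
        rows.append((col, med_a, med_b, u, p, p < alpha, direction))
    return pd.DataFrame(
        rows,
        columns=["feature", f"median_{group_a}", f"median_{group_b}", "U", "p",
                 "significant", "direction"],
    ).set_index("feature")


def summarize_across_types(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count, per feature, in how many cancer types it changed significantly.

    ``results`` maps a cancer-type tag to a :func:`differential_flux` table;
    all tables must share the same feature set.  Returns per-feature counts
    of types with a significant increase and a significant decrease, plus
    the number of types analyzed.
    """
    if not results:
        raise InputError("need at least one differential table")
    tables = list(results.values())
    features = tables[0].index
    for tag, tab in results.items():
        if not features.equals(tab.index):
            raise AlignmentError(f"table {tag!r} has a different feature set")
    inc = sum((t["significant"] & (t["direction"] == "increase")).astype(int) for t in tables)
    dec = sum((t["significant"] & (t["direction"] == "decrease")).astype(int) for t in tables)
    return pd.DataFrame(
        {"n_types": len(tables), "increased_in": inc, "decreased_in": dec}, index=features
    )


def flux_zscore(flux_cancer: pd.DataFrame, flux_normal: pd.DataFrame) -> pd.DataFrame:
    """Z-score each cancer sample's fluxes against the normal-control distribution.

    ``z = (flux - mean_normal) / sd_normal`` per module, with the n-1
    (sample) standard deviation.  Modules whose normal controls are
    constant get z = 0 with a warning.  Requires at least two normal
    controls.
    """
    if list(flux_cancer.columns) != list(flux_normal.columns):
        flux_normal = flux_normal.reindex(columns=flux_cancer.columns)
        if flux_normal.isna().any().any():
            raise AlignmentError("cancer and normal flux matrices have different modules")
    if flux_normal.shape[0] < 2:
        raise InputError("need at least 2 normal controls to compute Z-scores")
    mean = flux_normal.mean(axis=0)
    sd = flux_normal.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"constant normal controls for {list(sd.index[degenerate])}; z set to 0",
            stacklevel=2,
        )
    z = (flux_cancer - mean) / sd.replace(0.0, np.nan)
    return z.fillna(0.0) if degenerate.any() else z
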