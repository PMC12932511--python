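"""Paired EZ-vs-NEZ testing with false-discovery-rate control.

Per sample (patient x state epoch), nodal metrics are aggregated over EZ
nodes and over NEZ nodes; the two aggregates form one pair.  Pairs are
compared with the two-sided Wilcoxon signed-rank test (exact null
enumeration for up to 25 informative pairs, normal approximation with
continuity correction above; zero differences dropped).  Families of
tests are corrected with the Benjamini-Hochberg step-up procedure —
all 28 band x metric tests of one modality/state table form one family,
and the 21 band x density state-comparison tests form another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import FEATURE_COLUMNS

__all__ = [
    "WilcoxonResult",
    "aggregate_pairs",
    "paired_wilcoxon",
    "bh_adjust",
    "stat_table",
    "stat_table_wide",
    "density_state_comparison",
]

EXACT_MAX_N = 25


@dataclass
class WilcoxonResult:
    p: float
    statistic: float  # W+ (rank sum of positive differences)
    direction: int  # sign of the median paired difference
    n_informative: int
    flag: Optional[str] = None  # 'too_few_pairs' | 'all_zero' when undefined


def aggregate_pairs(
    feature_table: pd.DataFrame,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
    aggregator: str = "mean",
    sample_keys: Sequence[str] = ("patient_id",),
) -> pd.DataFrame:
    """Collapse nodal features to one (EZ, NEZ) pair per sample.

    Returns a frame indexed by the sample keys with hierarchical columns
    ``(feature, 'ez' | 'nez')``.  Samples missing either class raise.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    df = feature_table.copy()
    df["_class"] = np.where(df["ez_label"].astype(bool), "ez", "nez")
    grouped = df.groupby([*sample_keys, "_class"], observed=True)[list(feature_cols)]
    agg = grouped.mean() if aggregator == "mean" else grouped.median()
    wide = agg.unstack("_class")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"samples missing an EZ or NEZ class: {missing}")
    wide.columns = pd.MultiIndex.from_tuples(
        [(feat, cls) for feat, cls in wide.columns], names=["feature", "class"]
    )
    return wide.sort_index(axis=1)


def _exact_two_sided_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank p by enumerating the 2^n sign-assignment null.

    Tied magnitudes get average (mid-)ranks; doubling makes all ranks
    integral so the null distribution of W+ is built by convolution.
    Returns (p, W+).
    """
    ranks = sps.rankdata(np.abs(diffs))
    r2 = np.rint(2 * ranks).astype(int)
    w2 = int(r2[diffs > 0].sum())
    total_sum = int(r2.sum())
    counts = np.zeros(total_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total_sum + 1 - r]
        counts = counts + shifted
    cdf = np.cumsum(counts)
    total = counts.sum()
    lo, hi = min(w2, total_sum - w2), max(w2, total_sum - w2)
    p = (cdf[lo] + (total - (cdf[hi - 1] if hi > 0 else 0.0))) / total
    return min(1.0, float(p)), w2 / 2.0


def paired_wilcoxon(ez: np.ndarray, nez: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired aggregates.

    Differences are ``ez - nez``; a negative direction therefore means
    NEZ > EZ.  Zero differences are dropped (Wilcoxon's convention).
    Fewer than 5 informative pairs yields an undefined, flagged result.
    """
    ez = np.asarray(ez, dtype=float)
    nez = np.asarray(nez, dtype=float)
    if ez.shape != nez.shape:
        raise ValueError("paired samples must have equal length")
    if not (np.all(np.isfinite(ez)) and np.all(np.isfinite(nez))):
        raise ValueError("paired aggregates must be finite")
    d = ez - nez
    direction = int(np.sign(np.median(d)))
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return WilcoxonResult(float("nan"), 0.0, 0, 0, flag="all_zero")
    if n < 5:
        return WilcoxonResult(float("nan"), 0.0, direction, n, flag="too_few_pairs")
    if n <= EXACT_MAX_N:
        p, w = _exact_two_sided_p(nz)
    else:
        res = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                           method="approx", alternative="two-sided")
        # scipy reports min(W+, W-); recover W+ for the report
        ranks = sps.rankdata(np.abs(nz))
        w = float(ranks[nz > 0].sum())
        p = float(res.pvalue)
    return WilcoxonResult(p, w, direction, n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stat_table(paired: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon + BH over every feature of a paired-sample table.

    ``paired`` is the output of :func:`aggregate_pairs`.  All features in
    the table form one BH family; undefined tests are excluded from the
    family and keep a NaN adjusted p.
    """
    features = paired.columns.get_level_values("feature").unique()
    rows = []
    for feat in features:
        res = paired_wilcoxon(paired[(feat, "ez")].to_numpy(),
                              paired[(feat, "nez")].to_numpy())
        rows.append({"feature": feat, "raw_p": res.p, "statistic": res.statistic,
                     "direction": res.direction, "n": res.n_informative,
                     "flag": res.flag})
    out = pd.DataFrame(rows).set_index("feature")
    defined = out["raw_p"].notna()
    out["adj_p"] = np.nan
    if defined.any():
        out.loc[defined, "adj_p"] = bh_adjust(out.loc[defined, "raw_p"].to_numpy())
    return out


def stat_table_wide(table: pd.DataFrame, value: str = "adj_p") -> pd.DataFrame:
    """Pivot a feature-wise stat table to rows = metric, columns = band."""
    out = table.reset_index()
    parts = out["feature"].str.rsplit("_", n=1, expand=True)
    out["band"], out["metric"] = parts[0], parts[1]
    wide = out.pivot(index="metric", columns="band", values=value)
    cols = [b for b in ("full", "delta", "theta", "alpha", "beta", "gamma", "hf")
            if b in wide.columns]
    return wide[cols]


def density_state_comparison(density_table: pd.DataFrame) -> pd.DataFrame:
    """Paired ictal-vs-interictal tests of the sub-network densities.

    ``density_table`` needs columns ``patient_id, state, band, d_ez,
    d_nez, d_cross`` with both states present for every patient.  One BH
    family spans all band x density tests.  Directions are the sign of
    the median (ictal - interictal) difference.
    """
    measures = ("d_ez", "d_nez", "d_cross")
    rows = []
    for band in density_table["band"].unique():
        sub = density_table[density_table["band"] == band]
        if set(sub.groupby("patient_id")["state"].nunique()) != {2}:
            raise ValueError(f"unmatched samples across states in band {band!r}")
        wide = sub.pivot(index="patient_id", columns="state", values=list(measures))
        for m in measures:
            x = wide[(m, "ictal")].to_numpy()
            y = wide[(m, "interictal")].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)  # undefined block densities drop out
            res = paired_wilcoxon(x[ok], y[ok])
            rows.append({"band": band, "measure": m, "raw_p": res.p,
                         "direction": res.direction, "n": res.n_informative,
                         "flag": res.flag})
    out = pd.DataFrame(rows)
    defined = out["raw_p"].notna()
    out["adj_p"] = np.nan
    if defined.any():
        out.loc[defined, "adj_p"] = bh_adjust(out.loc[defined, "raw_p"].to_numpy())
    return out
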