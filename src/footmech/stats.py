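"""Paired nonparametric comparison of bare vs shod measures.

Sample sizes in loaded-foot studies are far too small to establish
normality, so bare/shod differences are tested with the Wilcoxon
signed-rank test (two-sided, alpha = 0.05).  Zero differences are dropped
(Wilcoxon's convention) and tied magnitudes receive average ranks; the
exact null distribution is used for small effective samples, the normal
approximation with continuity correction above.  No multiple-testing
correction is applied; p-values are reported raw.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedSample", "WilcoxonResult", "wilcoxon_signed_rank", "paired_comparison_table"]

EXACT_N_MAX = 25


@dataclass
class PairedSample:
    """Matched (bare, shod) value pairs over common keys."""

    bare: np.ndarray
    shod: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.bare, dtype=float)
        s = np.asarray(self.shod, dtype=float)
        if b.shape != s.shape or b.ndim != 1 or len(b) < 1:
            raise ValueError("bare and shod must be equal-length 1D arrays, n >= 1")
        self.bare, self.shod = b, s

    @property
    def differences(self) -> np.ndarray:
        return self.shod - self.bare


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    median_difference: float
    defined: bool = True  # False when every difference is zero


def wilcoxon_signed_rank(pairs: PairedSample) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on shod - bare differences.

    Returns the signed-rank statistic (smaller of the rank sums), the
    two-sided p-value, the effective n after dropping zeros, and the
    median difference.
    """
    d = pairs.differences
    nz = d[d != 0]
    median = float(np.median(d))
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; statistic undefined")
        return WilcoxonResult(np.nan, 1.0, 0, median, defined=False)
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), len(nz), median)


def paired_comparison_table(
    measures: pd.DataFrame,
    metric_type: str,
    alpha: float = 0.05,
    group_by_foot: bool = False,
) -> pd.DataFrame:
    """Per-entity Wilcoxon tests between footwear levels of a measure table.

    ``measures`` is the long-form table from :func:`footmech.biomech.measure_table`
    (columns config_id, footwear, metric_type, entity, frame_bone, value).
    Pairs are matched on (config_id, frame_bone) within each entity; with
    ``group_by_foot`` a ``foot`` column joins the pairing key and one row is
    emitted per (foot, entity).  Entities without overlapping pairs are
    flagged, never dropped.  The summary fraction of significant entities is
    stored in ``df.attrs['significant_fraction']``.
    """
    sub = measures[measures.metric_type == metric_type]
    if sub.empty:
        raise ValueError(f"no rows with metric_type {metric_type!r}")
    if not {"bare", "shod"} <= set(sub.footwear.unique()):
        raise ValueError("measures must contain both bare and shod observations")

    keys = ["config_id", "frame_bone"]
    group_cols = ["entity"]
    if group_by_foot:
        if "foot" not in sub.columns:
            raise ValueError("group_by_foot requires a 'foot' column")
        keys = ["config_id", "frame_bone"]
        group_cols = ["foot", "entity"]

    rows = []
    for gkey, g in sub.groupby(group_cols):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        bare = g[g.footwear == "bare"].set_index(keys)["value"]
        shod = g[g.footwear == "shod"].set_index(keys)["value"]
        common = bare.index.intersection(shod.index)
        row = dict(zip(group_cols, gkey))
        if len(common) == 0:
            row.update({"n": 0, "statistic": np.nan, "p_value": np.nan,
                        "median_difference": np.nan, "significant": False,
                        "flagged": True})
        else:
            res = wilcoxon_signed_rank(PairedSample(
                bare.loc[common].to_numpy(), shod.loc[common].to_numpy(), metric_type))
            row.update({"n": len(common), "statistic": res.statistic,
                        "p_value": res.p_value,
                        "median_difference": res.median_difference,
                        "significant": bool(res.defined and res.p_value < alpha),
                        "flagged": False})
        rows.append(row)

    out = pd.DataFrame(rows)
    tested = out[out.n > 0]
    out.attrs["significant_fraction"] = (
        float(tested.significant.mean()) if len(tested) else np.nan)
    return out
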