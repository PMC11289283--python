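"""Group comparisons across brain regions with adaptive FDR control.

Per-region two-group comparisons (multiple unpaired t-tests, each region one
row replicate) corrected with the two-stage step-up false-discovery-rate
procedure of Benjamini, Krieger and Yekutieli (BKY), plus percent-change
summaries.  Regions are flagged significant at adjusted q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats


def group_compare(
    table: pd.DataFrame,
    group_a: str = "young",
    group_b: str = "aged",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided unpaired t-test per region.

    ``table`` is long-form with columns ``region, group, value`` (an optional
    ``animal`` column is carried through).  The default is the pooled-variance
    t-test; ``welch=True`` drops the equal-variance assumption.  Missing
    values are excluded per region (complete case within region) and the
    retained sample sizes are reported.  A region where both groups have zero
    variance and equal means gets t = 0, p = 1 and a ``degenerate`` flag.

    Returns a frame with per-region means, SDs, percent change
    (100 x (B - A) / A), t and p.
    """
    required = {"region", "group", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    rows = []
    for region, grp in table.groupby("region", sort=False):
        a = grp.loc[grp["group"] == group_a, "value"].dropna().to_numpy(dtype=float)
        b = grp.loc[grp["group"] == group_b, "value"].dropna().to_numpy(dtype=float)
        n_missing = int(grp["value"].isna().sum())
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"region {region!r}: need >= 2 values per group")
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = sstats.ttest_ind(b, a, equal_var=not welch)
        rows.append(
            {
                "region": region,
                "n_a": len(a),
                "n_b": len(b),
                "n_missing": n_missing,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "percent_change": 100.0 * (b.mean() - a.mean()) / a.mean()
                if a.mean() != 0
                else np.nan,
                "t": float(t),
                "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def bky_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive step-up FDR (Benjamini-Krieger-Yekutieli 2006).

    Stage 1 runs Benjamini-Hochberg at level alpha' = alpha / (1 + alpha) and
    uses the rejection count r1 to estimate the number of true nulls
    m0 = m - r1; stage 2 reruns the step-up with the adapted level
    alpha' * m / m0.  Returned q-values are the stage-2 adjusted p-values
    (monotone in p); a hypothesis is rejected exactly when q <= alpha.
    Because m0 < m inflates the per-test level, q can fall below the raw p.

    Returns
    -------
    (reject, q_values)
        Boolean discovery flags and q-values, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)

    def bh_adjust(pv: np.ndarray, m_eff: float) -> np.ndarray:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m_eff / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    q1 = bh_adjust(p, m)
    r1 = int(np.sum(q1 <= alpha1))
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.minimum(q1 * (1.0 + alpha), 1.0)
    if r1 == m:
        # every hypothesis rejected at stage 1; q from the stage-1 step-up
        return np.ones(m, dtype=bool), np.minimum(q1 * (1.0 + alpha), 1.0)
    m0 = m - r1
    # stage 2: BH at alpha1 with m0 in place of m; q scaled so q <= alpha
    # reproduces the stage-2 rejection rule p_(i) <= i * alpha1 / m0
    q2 = bh_adjust(p, m0) * (1.0 + alpha)
    q2 = np.minimum(q2, 1.0)
    return q2 <= alpha, q2


def compare_regions(
    table: pd.DataFrame,
    group_a: str = "young",
    group_b: str = "aged",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Full per-region analysis: t-tests, BKY q-values, significance flags."""
    res = group_compare(table, group_a=group_a, group_b=group_b, welch=welch)
    reject, q = bky_fdr(res["p"].to_numpy(), alpha=alpha)
    res["q"] = q
    res["significant"] = reject
    return res


def percent_change_table(
    table: pd.DataFrame,
    group_a: str = "young",
    group_b: str = "aged",
    band: float = 10.0,
) -> pd.DataFrame:
    """Mean-based percent change per region with a within-±band indicator
    (default ±10%, the reference band drawn around the identity line in
    young-vs-aged scatter plots)."""
    res = group_compare(table, group_a=group_a, group_b=group_b)
    out = res[["region", "mean_a", "mean_b", "percent_change"]].copy()
    out["within_band"] = out["percent_change"].abs() <= band
    return out
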