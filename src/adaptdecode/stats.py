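"""Group-level statistics across penetrations.

Penetrations are the unit of replication: every statistical comparison is a
within-subject (repeated-measures) design with the penetration as the
blocking factor.  Provided are one- and two-way repeated-measures ANOVA
(uncorrected degrees of freedom by default, optional Greenhouse-Geisser
correction for one-way designs), Bonferroni-adjusted pairwise post-hoc
comparisons using the pooled within-subject error term, and the Wilcoxon
matched-pairs signed-rank test (exact for small n, normal approximation
with continuity correction otherwise, zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "WilcoxonResult",
    "rm_anova",
    "greenhouse_geisser_epsilon",
    "bonferroni_adjust",
    "bonferroni_posthoc",
    "wilcoxon_matched_pairs",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _to_long(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Wide (subjects x levels) to long format; columns may be a 2-level
    MultiIndex for two-way designs."""
    m = matrix.copy()
    if m.isna().any().any():
        raise ValueError("unbalanced design: missing cells are not supported")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 subjects (penetrations)")
    m.index.name = "subject"
    if isinstance(m.columns, pd.MultiIndex):
        factors = [n or f"factor{i+1}" for i, n in enumerate(m.columns.names)]
        long = m.stack(list(range(m.columns.nlevels)), future_stack=True)
        long = long.rename("value").reset_index()
        long.columns = ["subject", *factors, "value"]
    else:
        factors = [m.columns.name or "factor1"]
        long = m.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["subject", factors[0], "value"]
    return long, factors


def rm_anova(
    matrix: pd.DataFrame,
    greenhouse_geisser: bool = False,
) -> pd.DataFrame:
    """Repeated-measures ANOVA with penetration as the blocking factor.

    Parameters
    ----------
    matrix : wide DataFrame, rows = penetrations.  Plain columns give a
        one-way design; a two-level column MultiIndex gives a two-way
        design with interaction.
    greenhouse_geisser : apply the Greenhouse-Geisser sphericity correction
        (one-way designs only).  Off by default: reported degrees of
        freedom are then the uncorrected ``(k-1, (k-1)(n-1))``.

    Returns
    -------
    DataFrame with one row per effect: effect, F, df1, df2, p
    (plus eps, p_gg when corrected).  A zero-variance effect is reported as
    F = 0 with p = 1.
    """
    long, factors = _to_long(matrix)
    if greenhouse_geisser and len(factors) > 1:
        raise NotImplementedError(
            "Greenhouse-Geisser correction implemented for one-way designs only"
        )
    table = AnovaRM(long, "value", "subject", within=factors).fit().anova_table
    out = pd.DataFrame(
        {
            "effect": table.index,
            "F": table["F Value"].to_numpy(),
            "df1": table["Num DF"].to_numpy(),
            "df2": table["Den DF"].to_numpy(),
            "p": table["Pr > F"].to_numpy(),
        }
    ).reset_index(drop=True)
    # a zero-variance effect (all marginal cell means equal) is reported as
    # F = 0, p = 1; the raw 0/0 computation yields meaningless values
    scale = max(float(np.var(long["value"])), 1.0)
    for i, effect in enumerate(out["effect"]):
        involved = effect.split(":")
        cell_means = long.groupby(involved, observed=True)["value"].mean()
        if float(np.var(cell_means)) < 1e-12 * scale or not np.isfinite(
            out.loc[i, "F"]
        ):
            out.loc[i, "F"] = 0.0
            out.loc[i, "p"] = 1.0
    if greenhouse_geisser:
        eps = greenhouse_geisser_epsilon(matrix)
        out["eps"] = eps
        out["p_gg"] = sps.f.sf(out["F"], out["df1"] * eps, out["df2"] * eps)
    return out


def greenhouse_geisser_epsilon(matrix: pd.DataFrame) -> float:
    """Box's epsilon estimate from the sample covariance of the levels."""
    x = matrix.to_numpy(dtype=float)
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    # double-centered covariance
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s_dc) ** 2
    den = (k - 1) * np.sum(s_dc**2)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# post-hoc comparisons
# ---------------------------------------------------------------------------

def bonferroni_adjust(p: float | np.ndarray, n_comparisons: int) -> np.ndarray:
    """Multiply p by the number of comparisons, capped at 1."""
    return np.minimum(np.asarray(p, dtype=float) * n_comparisons, 1.0)


def bonferroni_posthoc(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise level comparisons with the pooled within-subject error term.

    For levels i, j: ``t = (mean_i - mean_j) / sqrt(2 MS_error / n)`` with
    the error mean square and degrees of freedom of the one-way
    repeated-measures ANOVA; two-sided p-values are Bonferroni-multiplied by
    the number of comparisons and capped at 1.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("unbalanced design")
    levels = list(matrix.columns)
    if pairs is None:
        pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise ValueError(f"pair ({a!r}, {b!r}) references an absent level")
    n, k = x.shape
    grand = x.mean()
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    df_err = (n - 1) * (k - 1)
    ms_err = np.sum(resid**2) / df_err
    rows = []
    means = dict(zip(levels, x.mean(axis=0)))
    for a, b in pairs:
        if ms_err == 0:
            t, p_raw = 0.0, 1.0
        else:
            t = (means[a] - means[b]) / np.sqrt(2.0 * ms_err / n)
            p_raw = 2.0 * sps.t.sf(abs(t), df_err)
        rows.append((a, b, t, p_raw, float(bonferroni_adjust(p_raw, len(pairs)))))
    return pd.DataFrame(
        rows, columns=["level_1", "level_2", "t", "p_raw", "p_adj"]
    )


# ---------------------------------------------------------------------------
# Wilcoxon matched pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p: float
    n_used: int
    all_zero: bool = False
    method: str = "exact"


def wilcoxon_matched_pairs(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired observations.

    Zero differences are dropped (Wilcoxon's original treatment).  The
    exact null distribution is used for n <= ``exact_max_n`` without rank
    ties; otherwise the normal approximation with continuity correction.
    If every difference is zero the test is degenerate and p = 1 is
    reported with a flag.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, all_zero=True, method="degenerate")
    if d.size < 5:
        raise ValueError(
            "need at least 5 non-zero differences for the signed-rank test"
        )
    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(ranks).size < ranks.size
    if d.size <= exact_max_n and not has_ties:
        method = "exact"
        res = sps.wilcoxon(d, alternative=alternative, method="exact")
    else:
        method = "approx"
        res = sps.wilcoxon(
            d, alternative=alternative, method="approx", correction=True
        )
    return WilcoxonResult(
        float(res.statistic), float(res.pvalue), int(d.size), method=method
    )
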