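"""Group screening statistics: Mann-Whitney U, Benjamini-Hochberg FDR,
chi-square proportions, and the feature screen over band powers + ratios.

All feature screens are two-sided; the BH family is the full set of
features tested within one (FFT parameterization x reference)
configuration — 10 lobar band powers plus 65 ratios = 75 tests — re-run per
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupComparisonResult",
    "mann_whitney_u",
    "bh_adjust",
    "chi_square_proportion",
    "screen_features",
    "demographics_table",
]


@dataclass
class GroupComparisonResult:
    feature: str
    U: float
    p: float
    p_adj: float
    direction: str  # 'FTD>CTL' | 'FTD<CTL'
    n_ftd: int
    n_ctl: int
    degenerate: bool = False


def mann_whitney_u(x, y, use_continuity: bool = True) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x > y (plus half-ties). The p-value is exact
    (network enumeration) for combined n <= 20 without ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    A fully degenerate comparison (all values identical) returns
    (n_x*n_y/2, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    adjusted p_(i) = min over k >= i of m * p_(k) / k, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def chi_square_proportion(a_events: int, a_n: int, b_events: int, b_n: int
                          ) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) comparing two
    proportions; returns (chi2, p). A zero-margin table gives (0, 1)."""
    if min(a_events, b_events) < 0 or a_events > a_n or b_events > b_n:
        raise ValueError("need 0 <= events <= n for both groups")
    table = np.array(
        [[a_events, a_n - a_events], [b_events, b_n - b_events]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = sstats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def screen_features(features: pd.DataFrame, groups: pd.Series,
                    positive: str = "FTD", negative: str = "CTL"
                    ) -> pd.DataFrame:
    """Mann-Whitney screen of every feature column with BH correction.

    ``features`` is a subjects x features table (typically the concatenated
    band-power and ratio tables); ``groups`` maps subject to group label.
    Missing cells are dropped per feature (counts recorded). Returns a
    DataFrame sorted by adjusted p with columns feature, U, p, p_adj,
    direction, n_ftd, n_ctl, degenerate.
    """
    groups = groups.reindex(features.index)
    if groups.isna().any():
        missing = features.index[groups.isna()].tolist()
        raise ValueError(f"no group label for subjects: {missing}")
    pos_idx = groups == positive
    neg_idx = groups == negative
    if pos_idx.sum() < 2 or neg_idx.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    gt = f"{positive}>{negative}"
    lt = f"{positive}<{negative}"
    vals = features.to_numpy(dtype=float)
    X = vals[pos_idx.to_numpy()]
    Y = vals[neg_idx.to_numpy()]
    clean = np.isfinite(vals).all(axis=0) & (
        np.ptp(vals, axis=0) > 0
    ) & np.array([X.shape[0] + Y.shape[0] > 20 for _ in features.columns])
    rows = []
    if clean.any():
        # vectorized asymptotic path (the large-sample regime)
        res = sstats.mannwhitneyu(
            X[:, clean], Y[:, clean], alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=0,
        )
        med_x = np.median(X[:, clean], axis=0)
        med_y = np.median(Y[:, clean], axis=0)
        for j, feat in enumerate(features.columns[clean]):
            rows.append(
                (feat, float(res.statistic[j]), float(res.pvalue[j]),
                 gt if med_x[j] >= med_y[j] else lt,
                 X.shape[0], Y.shape[0], False)
            )
    for feat in features.columns[~clean]:
        col = features[feat]
        x = col[pos_idx].dropna().to_numpy()
        y = col[neg_idx].dropna().to_numpy()
        degenerate = False
        if x.size < 1 or y.size < 1 or np.ptp(np.r_[x, y]) == 0:
            u, p = x.size * y.size / 2.0, 1.0
            degenerate = True
        else:
            u, p = mann_whitney_u(x, y)
        direction = gt if np.median(x) >= np.median(y) else lt
        rows.append((feat, u, p, direction, x.size, y.size, degenerate))
    out = pd.DataFrame(
        rows,
        columns=["feature", "U", "p", "direction", "n_ftd", "n_ctl", "degenerate"],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out[
        ["feature", "U", "p", "p_adj", "direction", "n_ftd", "n_ctl", "degenerate"]
    ]
    return out.sort_values("p_adj", kind="mergesort").reset_index(drop=True)


def screen_records(screen: pd.DataFrame) -> list[GroupComparisonResult]:
    """View a screen table as typed per-feature comparison records."""
    return [
        GroupComparisonResult(
            feature=row["feature"], U=float(row["U"]), p=float(row["p"]),
            p_adj=float(row["p_adj"]), direction=row["direction"],
            n_ftd=int(row["n_ftd"]), n_ctl=int(row["n_ctl"]),
            degenerate=bool(row["degenerate"]),
        )
        for _, row in screen.iterrows()
    ]


def demographics_table(subjects) -> pd.DataFrame:
    """Group comparison of age (rank-sum), sex (chi-square) and MMSE
    (rank-sum), mirroring the clinicodemographic summary table."""
    df = pd.DataFrame(
        {
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "mmse": [s.mmse if s.mmse is not None else np.nan for s in subjects],
        }
    )
    ftd = df[df.group == "FTD"]
    ctl = df[df.group == "CTL"]
    rows = []
    for var in ("mmse", "age"):
        x = ftd[var].dropna().to_numpy()
        y = ctl[var].dropna().to_numpy()
        _, p = mann_whitney_u(x, y)
        rows.append(
            (var.upper() if var == "mmse" else "Age",
             f"{x.mean():.2f} ({x.std(ddof=1) if x.size > 1 else 0:.2f})",
             f"{y.mean():.2f} ({y.std(ddof=1) if y.size > 1 else 0:.2f})",
             p)
        )
    f_ftd = int((ftd.sex == "F").sum())
    f_ctl = int((ctl.sex == "F").sum())
    _, p_sex = chi_square_proportion(f_ftd, len(ftd), f_ctl, len(ctl))
    rows.append(
        ("Sex", f"{f_ftd / len(ftd):.2f}", f"{f_ctl / len(ctl):.2f}", p_sex)
    )
    return pd.DataFrame(rows, columns=["variable", "FTD", "CTL", "p"])


def plot_screen(screen: pd.DataFrame, ax=None, tiers=(0.05, 0.01)):
    """Bar chart of -log10 adjusted p per feature with significance rules."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 4))
    vals = -np.log10(np.maximum(screen["p_adj"].to_numpy(), 1e-300))
    ax.bar(np.arange(len(screen)), vals, color="steelblue")
    for tier, color in zip(tiers, ("green", "red")):
        ax.axhline(-math.log10(tier), color=color, ls="--", lw=1,
                   label=f"p = {tier}")
    ax.set_xticks(np.arange(len(screen)))
    ax.set_xticklabels(screen["feature"], rotation=90, fontsize=5)
    ax.set_ylabel(r"$-\log_{10}\,p_{\mathrm{adj}}$")
    ax.legend()
    return ax
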