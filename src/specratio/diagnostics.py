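"""Diagnostic-accuracy statistics for a single continuous marker.

Covers the full evaluation suite applied to each candidate power ratio:
empirical ROC analysis with DeLong variance and the paired DeLong test,
precision-recall curves with the nonlinear (TP/FP-space) interpolation and a
logit-scale confidence interval for their area, Youden-index optimal
cutoffs with stratified bootstrap intervals, prevalence-standardized
predictive values, Clopper-Pearson intervals for sensitivity/specificity,
and the Hanley-McNeil sample-size calculation for a target ROC AUC.

Conventions: the positive class is the patient group; markers are
auto-oriented so that AUC >= 0.5 and the recorded orientation determines
whether the cutoff rule reads "> c" or "<= c".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "PRResult",
    "CutoffReport",
    "BootstrapConfig",
    "roc_auc_delong",
    "delong_paired_test",
    "pr_curve",
    "pr_auc_logit_ci",
    "youden_cutoff",
    "bootstrap_cutoff_ci",
    "exact_binomial_ci",
    "auc_sample_size",
    "ppv_npv",
]


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


@dataclass
class BootstrapConfig:
    """Stratified percentile bootstrap settings (defaults: 5000 draws, seed 978)."""

    iterations: int = 5000
    seed: int = 978
    method: str = "percentile"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.unstable = self.iterations < 100


@dataclass
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    orientation: str  # 'greater-is-positive' | 'less-is-positive'
    curve: np.ndarray  # (n_points, 2) columns (fpr, tpr)
    n_pos: int
    n_neg: int


@dataclass
class PRResult:
    auc: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (n_points, 2) columns (recall, precision)
    n_pos: int
    n_neg: int
    degenerate: bool = False


@dataclass
class CutoffReport:
    """Youden-optimal operating point with prevalence-standardized PPV/NPV.

    Rates are percentages; ``youden_j`` is a fraction. ``direction`` is
    '>' (score above cutoff calls positive) or '<=' (below-or-equal calls
    positive).
    """

    cutoff: float
    direction: str
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: float
    npv: float
    prevalence: float = 0.5
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None
    cutoff_ci: tuple[float, float] | None = None
    youden_ci: tuple[float, float] | None = None
    n_pos: int = 0
    n_neg: int = 0


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def roc_curve_points(scores, labels) -> np.ndarray:
    """Empirical ROC polygon from (0,0) to (1,1), scores oriented
    greater-is-positive."""
    scores, labels = _validate_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / labels.sum()]
    fpr = np.r_[0.0, fp / (1 - labels).sum()]
    return np.column_stack([fpr, tpr])


def roc_auc_delong(scores, labels, orient: bool = True) -> ROCResult:
    """Empirical ROC AUC with DeLong standard error and Wald 95% CI.

    With ``orient=True`` (default) the marker is flipped if needed so that
    AUC >= 0.5; the applied orientation is recorded.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    auc_raw, _, _ = _structural_components(pos, neg)
    orientation = "greater-is-positive"
    if orient and auc_raw < 0.5:
        orientation = "less-is-positive"
        scores = -scores
        pos, neg = -pos, -neg
    auc, v10, v01 = _structural_components(pos, neg)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    half = 1.959963984540054 * se
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(
        auc=float(auc),
        se=float(se),
        ci95=ci,
        orientation=orientation,
        curve=roc_curve_points(scores, labels),
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for equality of two correlated ROC AUCs.

    Both markers must be measured on the same subjects (same label vector).
    Returns (z, p). A zero-variance difference (e.g. identical or rank-
    equivalent markers) gives z = 0, p = 1.
    """
    a, labels = _validate_scores_labels(scores_a, labels)
    b, labels2 = _validate_scores_labels(scores_b, labels)
    if a.shape != b.shape:
        raise ValueError("paired markers must have the same length")
    pos_mask = labels == 1
    auc_a, v10_a, v01_a = _structural_components(a[pos_mask], a[~pos_mask])
    auc_b, v10_b, v01_b = _structural_components(b[pos_mask], b[~pos_mask])
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    v10 = np.vstack([v10_a, v10_b])
    v01 = np.vstack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (math.copysign(np.inf, diff), 0.0)
    z = diff / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------

def _pr_vertices(scores, labels):
    """Achievable (TP, FP) counts at decreasing score thresholds, starting
    from (0, 0)."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    fp = np.cumsum(1 - y)[distinct].astype(float)
    return np.r_[0.0, tp], np.r_[0.0, fp]


def _segment_area(tp_a, fp_a, tp_b, fp_b, n_pos) -> float:
    """Exact integral of precision d(recall) along one interpolated segment.

    Between achievable points, TP/FP interpolate linearly in count space
    (the nonlinear PR-space path): precision(u) = u / (alpha u + gamma) with
    alpha = 1 + s, gamma = fp_a - s * tp_a, s the local FP/TP slope.
    """
    dtp = tp_b - tp_a
    if dtp <= 0:
        return 0.0
    s = (fp_b - fp_a) / dtp
    alpha = 1.0 + s
    gamma = fp_a - s * tp_a
    if abs(gamma) < 1e-12:
        # constant precision along the segment
        return (1.0 / alpha) * dtp / n_pos
    # integral of u/(alpha u + gamma) du from tp_a to tp_b
    upper = alpha * tp_b + gamma
    lower = alpha * tp_a + gamma
    val = dtp / alpha - (gamma / alpha**2) * math.log(upper / lower)
    return val / n_pos


def pr_curve(scores, labels, n_grid: int = 200) -> PRResult:
    """Precision-recall curve with nonlinear interpolation and exact area.

    The area integrates precision over recall along the path induced by
    linear interpolation in (TP, FP) space between achievable points
    (closed form per segment). ``curve`` holds the interpolated polyline on
    a fine recall grid for plotting.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    tp, fp = _pr_vertices(scores, labels)
    area = 0.0
    for i in range(len(tp) - 1):
        area += _segment_area(tp[i], fp[i], tp[i + 1], fp[i + 1], n_pos)
    # plotting polyline: subdivide each segment in TP space
    pts = []
    for i in range(len(tp) - 1):
        dtp = tp[i + 1] - tp[i]
        if dtp <= 0:
            continue
        u = np.linspace(tp[i], tp[i + 1], max(2, int(n_grid * dtp / n_pos)))
        s = (fp[i + 1] - fp[i]) / dtp
        f = fp[i] + s * (u - tp[i])
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(u + f > 0, u / (u + f), 1.0)
        pts.append(np.column_stack([u / n_pos, prec]))
    curve = np.vstack(pts) if pts else np.zeros((0, 2))
    auc = float(area)
    ci, degenerate = pr_auc_logit_ci(auc, n_pos, len(labels) - n_pos)
    return PRResult(
        auc=auc, ci95=ci, curve=curve, n_pos=n_pos, n_neg=len(labels) - n_pos,
        degenerate=degenerate,
    )


def pr_auc_logit_ci(pr_auc: float, n_pos: int, n_neg: int,
                    level: float = 0.95) -> tuple[tuple[float, float], bool]:
    """Logit-scale confidence interval for a PR AUC.

    Standard binomial-style error on the logit scale with the number of
    positives as the effective sample size: se(logit A) =
    1 / sqrt(n_pos * A * (1 - A)). Returns ((lo, hi), degenerate_flag);
    a PR AUC of exactly 0 or 1 yields the degenerate point interval.
    """
    if not (0 <= pr_auc <= 1):
        raise ValueError("pr_auc must lie in [0, 1]")
    if pr_auc in (0.0, 1.0):
        return (pr_auc, pr_auc), True
    z = stats.norm.ppf(0.5 + level / 2)
    eta = math.log(pr_auc / (1 - pr_auc))
    tau = 1.0 / math.sqrt(n_pos * pr_auc * (1 - pr_auc))
    lo = 1 / (1 + math.exp(-(eta - z * tau)))
    hi = 1 / (1 + math.exp(-(eta + z * tau)))
    return (lo, hi), False


# ---------------------------------------------------------------------------
# Youden cutoff / predictive values
# ---------------------------------------------------------------------------

def ppv_npv(sens: float, spec: float, prevalence: float = 0.5
            ) -> tuple[float, float]:
    """Predictive values (fractions) at a standardized prevalence."""
    se, sp, pi = sens, spec, prevalence
    denom_p = se * pi + (1 - sp) * (1 - pi)
    denom_n = sp * (1 - pi) + (1 - se) * pi
    ppv = se * pi / denom_p if denom_p > 0 else np.nan
    npv = sp * (1 - pi) / denom_n if denom_n > 0 else np.nan
    return ppv, npv


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) binomial confidence interval for k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    res = stats.binomtest(int(k), int(n)).proportion_ci(
        confidence_level=level, method="exact"
    )
    return float(res.low), float(res.high)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus outer sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    span = max(u[-1] - u[0], 1.0)
    return np.r_[u[0] - span, mids, u[-1] + span]


def _sens_spec_at(pos, neg, cutoff, direction):
    if direction == ">":
        sens = float(np.mean(pos > cutoff))
        spec = float(np.mean(neg <= cutoff))
    else:
        sens = float(np.mean(pos <= cutoff))
        spec = float(np.mean(neg > cutoff))
    return sens, spec


def _best_youden(pos, neg, direction):
    """Maximize J over candidate cutoffs; ties broken toward higher
    specificity (then the lower cutoff for determinism)."""
    cands = _candidate_cutoffs(np.concatenate([pos, neg]))
    best = None
    for c in cands:
        sens, spec = _sens_spec_at(pos, neg, c, direction)
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -c if direction == ">" else c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    _, cutoff, sens, spec, j = best
    return cutoff, sens, spec, j


def youden_cutoff(scores, labels, prevalence: float = 0.5,
                  direction: str | None = None) -> CutoffReport:
    """Youden-index optimal cutoff with exact binomial CIs on sens/spec.

    The direction ('>' or '<=') defaults to the orientation making
    AUC >= 0.5. PPV/NPV are computed at the configured prevalence; their
    CIs propagate the Clopper-Pearson sensitivity/specificity limits
    through the predictive-value formulas (both are monotone increasing in
    sensitivity and specificity).
    """
    scores, labels = _validate_scores_labels(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if direction is None:
        auc = roc_auc_delong(scores, labels, orient=False).auc
        direction = ">" if auc >= 0.5 else "<="
    cutoff, sens, spec, j = _best_youden(pos, neg, direction)
    m, n = len(pos), len(neg)
    sens_ci = exact_binomial_ci(round(sens * m), m)
    spec_ci = exact_binomial_ci(round(spec * n), n)
    ppv, npv = ppv_npv(sens, spec, prevalence)
    ppv_lo, npv_lo = ppv_npv(sens_ci[0], spec_ci[0], prevalence)
    ppv_hi, npv_hi = ppv_npv(sens_ci[1], spec_ci[1], prevalence)
    return CutoffReport(
        cutoff=float(cutoff),
        direction=direction,
        sensitivity=100 * sens,
        specificity=100 * spec,
        youden_j=j,
        ppv=100 * ppv,
        npv=100 * npv,
        prevalence=prevalence,
        sensitivity_ci=(100 * sens_ci[0], 100 * sens_ci[1]),
        specificity_ci=(100 * spec_ci[0], 100 * spec_ci[1]),
        ppv_ci=(100 * ppv_lo, 100 * ppv_hi),
        npv_ci=(100 * npv_lo, 100 * npv_hi),
        n_pos=m,
        n_neg=n,
    )


def bootstrap_cutoff_ci(scores, labels, config: BootstrapConfig | None = None,
                        direction: str | None = None,
                        level: float = 0.95):
    """Stratified percentile bootstrap CIs for the Youden cutoff and max J.

    Resamples within each class, recomputes the optimal cutoff per draw
    (direction held fixed at the full-sample orientation), and returns
    ``(cutoff_ci, youden_ci)`` percentile intervals. Deterministic under the
    configured seed. The computation is vectorized over bootstrap draws via
    class-wise multinomial resampling.
    """
    config = config or BootstrapConfig()
    scores, labels = _validate_scores_labels(scores, labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    if direction is None:
        auc = roc_auc_delong(scores, labels, orient=False).auc
        direction = ">" if auc >= 0.5 else "<="
    rng = np.random.default_rng(config.seed)
    B = config.iterations
    m, n = len(pos), len(neg)
    cands = _candidate_cutoffs(np.concatenate([pos, neg]))  # (T,)
    if direction == ">":
        ind_pos = pos[:, None] > cands[None, :]  # (m, T)
        ind_neg = neg[:, None] <= cands[None, :]
    else:
        ind_pos = pos[:, None] <= cands[None, :]
        ind_neg = neg[:, None] > cands[None, :]
    w_pos = rng.multinomial(m, np.full(m, 1 / m), size=B).astype(float)
    w_neg = rng.multinomial(n, np.full(n, 1 / n), size=B).astype(float)
    sens = (w_pos @ ind_pos) / m  # (B, T)
    spec = (w_neg @ ind_neg) / n
    jmat = sens + spec - 1.0
    # per draw: max J, ties toward higher specificity; specificity is
    # monotone in the cutoff (increasing for '>', decreasing for '<='),
    # so scanning candidates in the corresponding order and taking the
    # first maximum realizes the tie-break exactly
    order = np.arange(len(cands))[::-1] if direction == ">" else np.arange(len(cands))
    jo = jmat[:, order]
    best = np.argmax(np.round(jo, 12), axis=1)
    j_star = jo[np.arange(B), best]
    cut_star = cands[order][best]
    alpha = 1 - level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    cutoff_ci = tuple(np.percentile(cut_star, qs))
    youden_ci = tuple(np.percentile(j_star, qs))
    return cutoff_ci, youden_ci


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auc_sample_size(alpha: float = 0.01, power: float = 0.8,
                    auc_alt: float = 0.8, auc_null: float = 0.5,
                    ratio: float = 1.0, n_max: int = 100000) -> int:
    """Smallest per-group n detecting ``auc_alt`` against ``auc_null``.

    Uses Hanley-McNeil AUC standard errors under the null and the
    alternative with a two-sided type-1 error: the smallest n (positives;
    negatives = ceil(ratio * n)) such that

        z_{alpha/2} * SE0(n) + z_{beta} * SE1(n) <= auc_alt - auc_null.
    """
    if not (0.5 <= auc_null < auc_alt < 1):
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    delta = auc_alt - auc_null
    for n in range(2, n_max + 1):
        n_neg = math.ceil(ratio * n)
        se0 = math.sqrt(_hanley_mcneil_var(auc_null, n, n_neg))
        se1 = math.sqrt(_hanley_mcneil_var(auc_alt, n, n_neg))
        if z_a * se0 + z_b * se1 <= delta:
            return n
    raise RuntimeError("no feasible sample size below n_max")
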