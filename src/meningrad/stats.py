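"""Univariate screening statistics for the grade analysis.

Binary (semantic) features are screened with Fisher's exact test and the
conditional-maximum-likelihood odds ratio; continuous (radiomic) features
with the rank AUC and Noether's asymptotic test of AUC = 0.5.  All p-values
are Benjamini–Hochberg adjusted within each analysis family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

SEMANTIC_FEATURES = (
    "intratumoral_heterogeneity",
    "multifocality",
    "midline_shift",
    "sinus_invasion",
    "necrosis_hemorrhage",
    "mass_effect",
    "cystic_component",
    "bone_invasion",
    "hyperostosis",
    "spiculation",
)


@dataclass
class UnivariateResult:
    feature: str
    estimate: float  # OR or AUC
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float = float("nan")
    flag: str = ""


def auc_rank(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Positives are label == 1 (high grade).  Computed from midranks so ties
    contribute one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def noether_test(scores, labels) -> tuple[float, float]:
    """Noether's asymptotic test of H0: AUC = 0.5.

    Returns (auc, two-sided p).  The null variance of the AUC is the
    tie-corrected Mann–Whitney variance divided by (n1 n0)^2; without ties
    it reduces to (n1 + n0 + 1) / (12 n1 n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc = auc_rank(scores, labels)
    n = n1 + n0
    _, t = np.unique(scores, return_counts=True)
    tie_term = float((t**3 - t).sum())
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        warnings.warn("all scores tied: Noether variance is zero, p = 1", stacklevel=2)
        return auc, 1.0
    z = (auc - 0.5) / math.sqrt(var_u / (n1 * n0) ** 2)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc, float(min(p, 1.0))


def auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float]:
    """Hanley–McNeil normal-approximation CI for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    a = auc_rank(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    zq = sps.norm.ppf(1 - alpha / 2)
    return max(0.0, a - zq * se), min(1.0, a + zq * se)


def fisher_or(table) -> tuple[float, tuple[float, float], float]:
    """Conditional-MLE odds ratio, exact 95% CI, and Fisher two-sided p.

    The OR is the conditional maximum-likelihood estimate under the
    noncentral hypergeometric model; the CI comes from exact test inversion.
    A zero margin makes the OR undefined (nan) with p = 1.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), (float("nan"), float("nan")), 1.0
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), (float(ci.low), float(ci.high)), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Screens


def _crosstab(flags: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2x2 table: rows feature absent/present, cols low/high grade."""
    t = np.zeros((2, 2), dtype=np.int64)
    for f in (0, 1):
        for g in (0, 1):
            t[f, g] = int(np.sum((flags == f) & (labels == g)))
    return t[::-1, ::-1]  # present/high first so OR > 1 means co-occurrence


def semantic_screen(semantic: pd.DataFrame, labels) -> pd.DataFrame:
    """Fisher OR screen of each binary semantic feature against grade.

    Returns a tidy frame (feature, odds_ratio, ci_low, ci_high, p_raw,
    p_adjusted, flag) with BH adjustment across the screened family.
    """
    labels = np.asarray(labels).astype(int)
    rows = []
    for col in semantic.columns:
        flags = np.asarray(semantic[col]).astype(int)
        if len(np.unique(flags)) < 2:
            rows.append(UnivariateResult(col, float("nan"), float("nan"), float("nan"), 1.0, flag="constant"))
            continue
        orr, (lo, hi), p = fisher_or(_crosstab(flags, labels))
        flag = "infinite_or" if np.isinf(orr) else ""
        rows.append(UnivariateResult(col, orr, lo, hi, p, flag=flag))
    padj = bh_adjust([r.p_raw for r in rows])
    for r, pa in zip(rows, padj):
        r.p_adjusted = float(pa)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "odds_ratio": [r.estimate for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "flag": [r.flag for r in rows],
        }
    )


def radiomic_screen(features: pd.DataFrame, labels) -> pd.DataFrame:
    """AUC + Noether screen of each continuous feature against grade.

    AUCs are oriented with high grade as the positive class, so AUC > 0.5
    means higher values predict high grade.  BH adjustment across the family.
    """
    labels = np.asarray(labels).astype(int)
    rows = []
    for col in features.columns:
        x = np.asarray(features[col], dtype=float)
        if np.unique(x).size < 2:
            rows.append(UnivariateResult(col, 0.5, 0.5, 0.5, 1.0, flag="constant"))
            continue
        auc, p = noether_test(x, labels)
        lo, hi = auc_ci(x, labels)
        rows.append(UnivariateResult(col, auc, lo, hi, p))
    padj = bh_adjust([r.p_raw for r in rows])
    for r, pa in zip(rows, padj):
        r.p_adjusted = float(pa)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "auc": [r.estimate for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "flag": [r.flag for r in rows],
        }
    )


def association_map(radiomic: pd.DataFrame, semantic: pd.DataFrame) -> pd.DataFrame:
    """Semantic x radiomic association matrix.

    Cell (s, r) holds the AUC of radiomic feature r predicting semantic flag
    s, its Noether p, and the BH-adjusted p across all cells.  Long format:
    one row per (semantic, radiomic) pair.
    """
    if len(radiomic) != len(semantic):
        raise ValueError("radiomic and semantic tables must be patient-aligned")
    rows = []
    for s in semantic.columns:
        lab = np.asarray(semantic[s]).astype(int)
        degenerate = np.unique(lab).size < 2
        for r in radiomic.columns:
            if degenerate:
                rows.append((s, r, float("nan"), 1.0, "constant_semantic"))
                continue
            x = np.asarray(radiomic[r], dtype=float)
            auc, p = noether_test(x, lab)
            rows.append((s, r, auc, p, ""))
    df = pd.DataFrame(rows, columns=["semantic", "radiomic", "auc", "p_raw", "flag"])
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def atypia_screen(
    cohort: pd.DataFrame,
    semantic_cols=SEMANTIC_FEATURES,
    radiomic: pd.DataFrame | None = None,
    grade_col: str = "grade_high",
    atypia_col: str = "atypia",
) -> dict[str, pd.DataFrame]:
    """Atypia sub-analysis: re-run both screens on grade-I patients only,
    with presence of any atypical histologic feature as the label.
    """
    low = cohort[cohort[grade_col] == 0]
    labels = low[atypia_col].astype(int).to_numpy()
    if min(int(labels.sum()), int((1 - labels).sum())) < 10:
        warnings.warn("atypia subset has < 10 patients in a class", stacklevel=2)
    out: dict[str, pd.DataFrame] = {}
    sem_cols = [c for c in semantic_cols if c in cohort.columns]
    out["semantic"] = semantic_screen(low[sem_cols], labels)
    if radiomic is not None:
        out["radiomic"] = radiomic_screen(radiomic.loc[low.index], labels)
    return out
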