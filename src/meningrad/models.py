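"""Multivariate grade classification: temporal split, training-set feature
selection, six random-forest models, validation metrics, and bootstrap model
comparison.

Model vocabulary (feature-set composition):

* ``clinical``     — age, gender, radiation-induced status, tumor volume,
  maximum axial diameter
* ``location``     — 5-level tumor location (one-hot)
* ``semantic``     — the 10 binary semantic flags
* ``radiomic``     — the selected radiomic panel
* ``radiographic`` — location + semantic + radiomic
* ``combined``     — everything above

The split is temporal (earlier surgeries train, later validate); radiomic
feature selection and hyperparameter tuning see training rows only, audited
through the :class:`SplitPlan`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .stats import SEMANTIC_FEATURES, auc_ci, auc_rank, noether_test

MODEL_NAMES = ("clinical", "location", "semantic", "radiomic", "radiographic", "combined")

CLINICAL_FEATURES = ("age", "gender_male", "radiation_induced", "Volume", "Maximum Axial Diameter")
LOCATION_LEVELS = (
    "midline_skull_base",
    "lateral_skull_base",
    "midline_convexity",
    "lateral_convexity",
    "other",
)


@dataclass
class SplitPlan:
    """Temporal train/validation partition with an access audit trail."""

    train_ids: list
    validation_ids: list
    cutoff_date: object
    accessed_ids: list = field(default_factory=list)

    def audit(self, ids) -> None:
        """Record ids touched pre-validation; refuse any validation id."""
        ids = list(ids)
        leaked = set(ids) & set(self.validation_ids)
        if leaked:
            raise ValueError(f"validation patients accessed during training: {sorted(leaked)[:5]}")
        self.accessed_ids.extend(ids)


@dataclass
class ModelResult:
    name: str
    auc: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    p_vs_random: float


def temporal_split(cohort: pd.DataFrame, train_fraction: float = 0.75,
                   date_col: str = "surgery_date", id_col: str = "patient_id") -> SplitPlan:
    """Assign the earliest ``floor(n * fraction)`` surgeries to training.

    Date ties are broken by patient id, so the plan is invariant to the
    input row order.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if cohort[date_col].isna().any():
        raise ValueError("every patient needs a surgery date for a temporal split")
    ordered = cohort.sort_values([date_col, id_col], kind="mergesort")
    n_train = int(np.floor(len(ordered) * train_fraction))
    train = ordered.iloc[:n_train]
    val = ordered.iloc[n_train:]
    return SplitPlan(
        train_ids=train[id_col].tolist(),
        validation_ids=val[id_col].tolist(),
        cutoff_date=train[date_col].max() if n_train else None,
    )


def select_radiomic_features(
    features: pd.DataFrame,
    plan: SplitPlan,
    k: int = 15,
    corr_threshold: float = 0.90,
) -> list[str]:
    """Variance/correlation feature selection on training rows only.

    Columns are considered in decreasing variance order; a column is dropped
    when its |Spearman rho| with an already-kept column exceeds the
    threshold (the higher-variance member survives).  The top-k survivors by
    variance are returned.  Variances are computed on the raw (pre-
    standardized) training values.
    """
    train = features.loc[[i for i in features.index if i in set(plan.train_ids)]]
    plan.audit(train.index)
    variances = train.var(ddof=1)
    order = variances.sort_values(ascending=False).index.tolist()
    kept: list[str] = []
    for col in order:
        ok = True
        for other in kept:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(train[col], train[other]).statistic
            if np.isfinite(rho) and abs(rho) > corr_threshold:
                ok = False
                break
        if ok:
            kept.append(col)
    if k > len(kept):
        warnings.warn(f"only {len(kept)} features survive correlation pruning (k={k})", stacklevel=2)
        return kept
    return kept[:k]


_MTRY_GRID_FRACTIONS = ("sqrt", 0.33, 0.5)
N_TREES = 500
N_TREES_TUNING = 60  # smaller forests in the inner CV keep tuning cheap


def _mtry_grid(n_features: int) -> list[int]:
    vals = []
    for g in _MTRY_GRID_FRACTIONS:
        m = int(np.ceil(np.sqrt(n_features))) if g == "sqrt" else int(np.ceil(g * n_features))
        vals.append(min(max(m, 1), n_features))
    return sorted(set(vals))


def train_model(X: pd.DataFrame, y, seed: int) -> RandomForestClassifier:
    """Random forest with the per-split predictor count (mtry) tuned by
    nested cross-validation: inner 5-fold stratified CV repeated 3 times,
    scored by AUC; the winning mtry is refit on the full training set with
    500 trees.  Fully seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    grid = _mtry_grid(X.shape[1])
    best_mtry, best_score = grid[0], -np.inf
    if len(grid) > 1:
        cv = RepeatedStratifiedKFold(n_splits=5, n_repeats=3, random_state=seed)
        folds = list(cv.split(X, y))
        for mtry in grid:
            scores = []
            for fi, (tr, te) in enumerate(folds):
                if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                    continue
                clf = RandomForestClassifier(
                    n_estimators=N_TREES_TUNING, max_features=mtry,
                    random_state=seed + 1000 + fi, n_jobs=1,
                )
                clf.fit(X[tr], y[tr])
                scores.append(auc_rank(clf.predict_proba(X[te])[:, 1], y[te]))
            if scores and np.mean(scores) > best_score:
                best_score, best_mtry = float(np.mean(scores)), mtry
    final = RandomForestClassifier(
        n_estimators=N_TREES, max_features=best_mtry, random_state=seed, n_jobs=1
    )
    final.fit(X, y)
    return final


def evaluate_model(model, X_val: pd.DataFrame, y_val, name: str = "model") -> ModelResult:
    """Validation AUC (rank-based) with Noether p against chance, plus
    sensitivity/specificity at the 0.5 class-probability threshold (high
    grade positive; probability exactly 0.5 counts as a positive call).
    """
    y_val = np.asarray(y_val).astype(int)
    if np.unique(y_val).size < 2:
        raise ValueError("validation data must contain both classes")
    prob = model.predict_proba(np.asarray(X_val, dtype=float))[:, 1]
    auc, p = noether_test(prob, y_val)
    lo, hi = auc_ci(prob, y_val)
    pred = (prob >= 0.5).astype(int)
    sens = float(np.sum((pred == 1) & (y_val == 1)) / np.sum(y_val == 1))
    spec = float(np.sum((pred == 0) & (y_val == 0)) / np.sum(y_val == 0))
    return ModelResult(name, float(auc), sens, spec, float(lo), float(hi), float(p))


def bootstrap_compare(prob_a, prob_b, y_val, n_boot: int = 1000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for AUC(A) != AUC(B) on shared validation
    patients.  Patients are resampled with replacement; single-class
    resamples are skipped.  p = 2 min(P(delta <= 0), P(delta >= 0)), capped at 1.
    """
    prob_a = np.asarray(prob_a, dtype=float)
    prob_b = np.asarray(prob_b, dtype=float)
    y_val = np.asarray(y_val).astype(int)
    if not (len(prob_a) == len(prob_b) == len(y_val)):
        raise ValueError("both models must be evaluated on the same validation patients")
    rng = np.random.default_rng(seed)
    deltas = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(y_val), size=len(y_val))
        yb = y_val[idx]
        if np.unique(yb).size < 2:
            skipped += 1
            continue
        deltas.append(auc_rank(prob_a[idx], yb) - auc_rank(prob_b[idx], yb))
    if skipped:
        warnings.warn(f"{skipped} single-class bootstrap resamples skipped", stacklevel=2)
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        return 1.0
    # add-one smoothed tails: a one-sided tail never drops below 1/(B+1)
    n_eff = deltas.size
    p = 2.0 * min(
        (np.sum(deltas <= 0) + 1) / (n_eff + 1),
        (np.sum(deltas >= 0) + 1) / (n_eff + 1),
    )
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Model-suite assembly


def model_feature_columns(name: str, radiomic_panel: list[str]) -> list[str]:
    """Feature columns composing each named model."""
    location = [f"location_{lv}" for lv in LOCATION_LEVELS]
    semantic = list(SEMANTIC_FEATURES)
    table = {
        "clinical": list(CLINICAL_FEATURES),
        "location": location,
        "semantic": semantic,
        "radiomic": list(radiomic_panel),
        "radiographic": location + semantic + list(radiomic_panel),
        "combined": list(CLINICAL_FEATURES) + location + semantic + list(radiomic_panel),
    }
    if name not in table:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return table[name]


def design_matrix(cohort: pd.DataFrame, radiomic: pd.DataFrame) -> pd.DataFrame:
    """Join cohort covariates (with one-hot location) and radiomic features."""
    df = cohort.copy()
    if "location" in df.columns:
        for lv in LOCATION_LEVELS:
            df[f"location_{lv}"] = (df["location"] == lv).astype(int)
    return df.join(radiomic, how="inner")


def run_model_suite(
    cohort: pd.DataFrame,
    radiomic: pd.DataFrame,
    models=MODEL_NAMES,
    seed: int = 0,
    train_fraction: float = 0.75,
    k: int = 15,
    corr_threshold: float = 0.90,
    label_col: str = "grade_high",
    n_boot: int = 1000,
) -> dict:
    """End-to-end multivariate analysis on a patient-indexed cohort.

    Temporal split -> training-only radiomic selection -> one tuned random
    forest per requested model -> validation metrics -> pairwise bootstrap
    comparisons.  Returns results table, per-model validation probabilities,
    the split plan, and the selected radiomic panel.
    """
    plan = temporal_split(cohort.rename_axis("patient_id").reset_index(), train_fraction)
    # size features (Volume, Maximum Axial Diameter) belong to the clinical
    # model; the radiomic panel is selected from the remaining feature space
    candidates = radiomic.drop(columns=[c for c in CLINICAL_FEATURES if c in radiomic.columns])
    panel = select_radiomic_features(candidates, plan, k=k, corr_threshold=corr_threshold)
    X = design_matrix(cohort, radiomic)
    y = cohort[label_col].astype(int)
    train_idx = [i for i in X.index if i in set(plan.train_ids)]
    val_idx = [i for i in X.index if i in set(plan.validation_ids)]

    results, probs = [], {}
    for mi, name in enumerate(models):
        cols = model_feature_columns(name, panel)
        plan.audit(train_idx)
        clf = train_model(X.loc[train_idx, cols], y.loc[train_idx], seed=seed + 17 * mi)
        res = evaluate_model(clf, X.loc[val_idx, cols], y.loc[val_idx], name=name)
        results.append(res)
        probs[name] = clf.predict_proba(np.asarray(X.loc[val_idx, cols], dtype=float))[:, 1]

    comparisons = []
    names = list(models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = bootstrap_compare(
                probs[names[i]], probs[names[j]], y.loc[val_idx], n_boot=n_boot, seed=seed + 9001
            )
            comparisons.append((names[i], names[j], p))

    results_df = pd.DataFrame(
        {
            "model": [r.name for r in results],
            "auc": [r.auc for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_vs_random": [r.p_vs_random for r in results],
        }
    )
    return {
        "results": results_df,
        "probabilities": probs,
        "plan": plan,
        "selected_panel": panel,
        "comparisons": pd.DataFrame(comparisons, columns=["model_a", "model_b", "p_value"]),
        "validation_labels": y.loc[val_idx],
    }
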