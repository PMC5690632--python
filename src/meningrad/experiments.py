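"""Seeded simulation studies validating the analysis pipeline.

Each study draws phantom cohorts under stated conditions (the defaults are
the study conditions: n = 175 patients, 41% high-grade prevalence,
odds-ratio-calibrated semantic effects) and measures an operating
characteristic of the pipeline: false-discovery control under the null,
power to recover injected effects, monotone feature response to phantom
traits, and the ordering of the classification models.  Replicate-level
studies use the fast tabular simulator; the paired-phantom study renders
and extracts real volumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .features import extract_panel
from .imaging import preprocess
from .models import (
    design_matrix,
    evaluate_model,
    model_feature_columns,
    run_model_suite,
    train_model,
)
from .phantom import CohortSpec, EffectConfig, PhantomSpec, make_phantom, simulate_cohort_tables
from .stats import SEMANTIC_FEATURES, radiomic_screen, semantic_screen


def random_discretized_volume(rng, max_side: int = 6, max_ng: int = 4):
    """Random tiny level grid (level 0 = background) for oracle comparisons."""
    from .features import DiscretizedVolume

    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    ng = int(rng.integers(2, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if mask.sum() < 2:
        mask.flat[:2] = True
    levels[~mask] = 0
    return DiscretizedVolume(
        levels=levels, ng=ng, bin_edges=np.arange(ng + 1, dtype=float), mask=levels > 0
    )


def texture_oracle_study(n_volumes: int = 200, seed: int = 0) -> float:
    """Max |fast implementation - naive enumeration| over the eight texture
    features on random tiny volumes (<= 6^3 voxels, Ng <= 4)."""
    from .features import glcm_features, glrlm_features, glszm_features
    from .reference import glcm_oracle, glrlm_oracle, glszm_oracle

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_volumes):
        disc = random_discretized_volume(rng)
        got = {**glcm_features(disc), **glrlm_features(disc), **glszm_features(disc)}
        want = {
            **glcm_oracle(disc.levels, disc.ng),
            **glrlm_oracle(disc.levels, disc.ng),
            **glszm_oracle(disc.levels, disc.ng),
        }
        assert len(got) == 8 and got.keys() == want.keys()
        # normalize by magnitude for large-valued features (HILAE grows as N^2)
        for k in want:
            scale = max(1.0, abs(want[k]))
            max_err = max(max_err, abs(got[k] - want[k]) / scale)
    return max_err


def fisher_oracle_study(max_margin: int = 12, n_ci_checks: int = 200, seed: int = 0) -> dict:
    """Compare fisher_or with exhaustive hypergeometric enumeration on every
    2x2 table with both row margins <= max_margin; CI bounds are verified to
    invert the exact tails on a seeded subsample of informative tables."""
    from .reference import cmle_or_oracle, exact_tail_prob, fisher_p_oracle
    from .stats import fisher_or

    rng = np.random.default_rng(seed)
    p_err = or_err = 0.0
    ci_err = 0.0
    informative = []
    for r1 in range(max_margin + 1):
        for a in range(r1 + 1):
            for r2 in range(max_margin + 1):
                for c in range(r2 + 1):
                    t = [[a, r1 - a], [c, r2 - c]]
                    tt = np.asarray(t)
                    if (tt.sum(axis=0) == 0).any() or (tt.sum(axis=1) == 0).any():
                        continue
                    orr, (lo, hi), p = fisher_or(t)
                    p_err = max(p_err, abs(p - fisher_p_oracle(t)))
                    want = cmle_or_oracle(t)
                    if np.isfinite(want) and want > 0 and np.isfinite(orr):
                        or_err = max(or_err, abs(orr - want) / max(want, 1.0))
                    else:
                        assert orr == want or (np.isinf(orr) and np.isinf(want))
                    if np.isfinite(lo) and lo > 0 and np.isfinite(hi):
                        informative.append((t, lo, hi))
    idx = rng.choice(len(informative), size=min(n_ci_checks, len(informative)), replace=False)
    for i in idx:
        t, lo, hi = informative[i]
        ci_err = max(ci_err, abs(exact_tail_prob(t, lo, upper=True) - 0.025))
        ci_err = max(ci_err, abs(exact_tail_prob(t, hi, upper=False) - 0.025))
    return {"p_max_err": p_err, "or_max_rel_err": or_err, "ci_tail_max_err": ci_err}


def auc_oracle_study(n_samples: int = 1000, seed: int = 0) -> float:
    """Max |rank AUC - pair-counting AUC| over random small labelled samples
    (with ties induced by value rounding)."""
    from .reference import auc_pair_oracle
    from .stats import auc_rank

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_samples):
        n = int(rng.integers(4, 25))
        scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        max_err = max(max_err, abs(auc_rank(scores, labels) - auc_pair_oracle(scores, labels)))
    return max_err


def bh_oracle_study(n_vectors: int = 200, seed: int = 0) -> float:
    """Max elementwise |bh_adjust - step-up definition| on random p-vectors."""
    from .reference import bh_oracle
    from .stats import bh_adjust

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        max_err = max(max_err, float(np.max(np.abs(bh_adjust(p) - bh_oracle(p)))))
    return max_err


def fdr_null_probe(n_replicates: int = 200, n: int = 100, seed: int = 0) -> dict[str, float]:
    """Fraction of adjusted-significant calls per screen under the null.

    Cohorts are drawn with every grade contrast zeroed, so any adjusted
    p < 0.05 is a false discovery; BH control implies each rate stays at or
    below 0.05 up to binomial error.
    """
    sem_calls = sem_tests = rad_calls = rad_tests = 0
    for r in range(n_replicates):
        spec = CohortSpec(
            n_patients=n, effects=EffectConfig.null(), seed=seed * 100_003 + r
        )
        cohort, radiomic = simulate_cohort_tables(spec)
        labels = cohort["grade_high"]
        sem = semantic_screen(cohort[list(SEMANTIC_FEATURES)], labels)
        rad = radiomic_screen(radiomic, labels)
        sem_calls += int((sem["p_adjusted"] < 0.05).sum())
        sem_tests += len(sem)
        rad_calls += int((rad["p_adjusted"] < 0.05).sum())
        rad_tests += len(rad)
    return {
        "semantic_rate": sem_calls / sem_tests,
        "radiomic_rate": rad_calls / rad_tests,
        "n_replicates": n_replicates,
    }


def semantic_recovery_study(n_replicates: int = 20, seed: int = 0) -> dict[str, float]:
    """Fraction of replicates in which the semantic screen recovers the
    heterogeneity and necrosis/hemorrhage effects (OR > 1, adjusted p < 0.05)
    at the study conditions (n = 175, prevalence 0.41, calibrated ORs)."""
    hits = {"intratumoral_heterogeneity": 0, "necrosis_hemorrhage": 0}
    for r in range(n_replicates):
        spec = CohortSpec(seed=seed * 100_003 + r)
        cohort, _ = simulate_cohort_tables(spec)
        sem = semantic_screen(cohort[list(SEMANTIC_FEATURES)], cohort["grade_high"])
        sem = sem.set_index("feature")
        for feat in hits:
            row = sem.loc[feat]
            if row["odds_ratio"] > 1 and row["p_adjusted"] < 0.05:
                hits[feat] += 1
    return {feat: count / n_replicates for feat, count in hits.items()}


def paired_phantom_study(n_pairs: int = 8, seed: int = 0) -> dict[str, float]:
    """Monotone feature response on rendered phantom pairs.

    For each seed, two phantoms differing only in one trait are rendered and
    extracted; reports the fraction of pairs where the matched feature moves
    the expected way (necrosis_fraction up => LILAE up; irregularity up =>
    spherical disproportion up).  LILAE runs through the standard
    preprocessing pipeline; spherical disproportion is measured on the
    native-resolution mask, since shape is a property of the segmentation
    and the 3 mm lattice under-resolves the surface perturbation.
    """
    from .features import shape_features

    def texture_of(spec: PhantomSpec, pair_seed: int, name: str) -> float:
        img, mask = make_phantom(spec, seed=pair_seed)
        pimg, pmask = preprocess(img, mask)
        return extract_panel(pimg, pmask, panel=(name,))[name]

    def sd_of(spec: PhantomSpec, pair_seed: int) -> float:
        _, mask = make_phantom(spec, seed=pair_seed)
        return shape_features(mask)["Spherical Disproportion"]

    lilae_up = sd_up = 0
    for r in range(n_pairs):
        s = seed * 7919 + r
        base = PhantomSpec(heterogeneity=0.1)
        necro = dataclasses.replace(base, necrosis_fraction=0.3)
        name = "Low Intensity Large Area Emp."
        if texture_of(necro, s, name) > texture_of(base, s, name):
            lilae_up += 1
        smooth = PhantomSpec(irregularity=0.0, heterogeneity=0.1)
        rough = dataclasses.replace(smooth, irregularity=0.4)
        if sd_of(rough, s) > sd_of(smooth, s):
            sd_up += 1
    return {
        "lilae_increase_fraction": lilae_up / n_pairs,
        "sd_increase_fraction": sd_up / n_pairs,
        "n_pairs": n_pairs,
    }


MODEL_STUDY_MODELS = ("clinical", "semantic", "radiomic", "radiographic")


def model_ordering_study(
    n_cohorts: int = 20, seed: int = 0, models=MODEL_STUDY_MODELS
) -> pd.DataFrame:
    """Validation AUC of each model plus a permuted-label control, one row
    per seeded phantom cohort at the study conditions."""
    rows = []
    for r in range(n_cohorts):
        rep_seed = seed * 100_003 + r
        spec = CohortSpec(seed=rep_seed)
        cohort, radiomic = simulate_cohort_tables(spec)
        suite = run_model_suite(cohort, radiomic, models=models, seed=rep_seed, n_boot=0)
        row = dict(zip(suite["results"]["model"], suite["results"]["auc"]))

        # permuted-label control: shuffle grade, retrain the radiographic model
        rng = np.random.default_rng(rep_seed + 1)
        y_perm = pd.Series(
            rng.permutation(cohort["grade_high"].to_numpy()), index=cohort.index
        )
        plan = suite["plan"]
        X = design_matrix(cohort, radiomic)
        cols = model_feature_columns("radiographic", suite["selected_panel"])
        tr = [i for i in X.index if i in set(plan.train_ids)]
        va = [i for i in X.index if i in set(plan.validation_ids)]
        clf = train_model(X.loc[tr, cols], y_perm.loc[tr], seed=rep_seed + 2)
        row["permuted"] = evaluate_model(clf, X.loc[va, cols], y_perm.loc[va]).auc
        rows.append(row)
    return pd.DataFrame(rows)
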