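"""Permutation-test inference for classifier performance, per PC and per species.

The null hypothesis is that age class carries no information about a PC's
scores: labels are randomly permuted, the identical cross-validated
evaluation is re-run (including hyperparameter re-tuning when the classifier
was tuned — freezing them would leak information and be anti-conservative;
``fast_perm=True`` freezes them anyway for speed), and the p-value is the
add-one estimator ``(1 + #{null >= observed}) / (B + 1)``, which can never
be exactly zero.

The per-(species, PC) table mirrors the conventional reporting layout:
accuracy, AUC, permutation p, effect direction (A < I when infants score
higher), and a significance band.  Raw p-values are reported (no familywise
correction), with a Benjamini-Hochberg column added for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from facemorph.classify import (
    TUNED_KINDS,
    ClassifierSpec,
    evaluate,
    tune_hyperparameters,
)
from facemorph.tps_io import SpecimenMetadata

BANDS = [(0.005, "p<.005"), (0.01, "p<.01"), (0.05, "p<.05"), (0.10, "p<.10")]


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int
    statistic: str = "accuracy"


@dataclass
class AgeClassTable:
    """Long-format per-(group, PC) discrimination table."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def significance_band(p: float) -> str:
    for cut, label in BANDS:
        if p < cut:
            return label
    return "ns"


def direction_of_effect(scores_1d: np.ndarray, labels: np.ndarray) -> str:
    """"A_lt_I" if adult mean score < infant mean, "I_lt_A" if greater, "none" on tie."""
    scores_1d = np.asarray(scores_1d, float)
    labels = np.asarray(labels)
    adult = scores_1d[labels == "adult"]
    infant = scores_1d[labels == "infant"]
    if adult.size == 0 or infant.size == 0:
        raise ValueError("both age classes must be present")
    if adult.mean() < infant.mean():
        return "A_lt_I"
    if adult.mean() > infant.mean():
        return "I_lt_A"
    return "none"


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    folds: int = 4,
    statistic: str = "accuracy",
    fast_perm: bool = False,
    standardize: bool = True,
    cv_seed: int = 0,
    grid_min_exp: int = -10,
    grid_max_exp: int = 10,
) -> PermutationResult:
    """Permutation test of classifier performance against label shuffling.

    ``statistic`` is "accuracy" (default) or "auc".  When ``spec`` is a tuned
    kind and ``fast_perm`` is False, hyperparameters are re-tuned inside each
    permutation; otherwise the given spec is frozen.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if statistic not in ("accuracy", "auc"):
        raise ValueError(f"unknown statistic {statistic!r}")
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    rng = _as_rng(seed)
    retune = (spec.kind in TUNED_KINDS) and not fast_perm

    def _stat(lab: np.ndarray) -> float:
        use_spec = spec
        if retune:
            use_spec = tune_hyperparameters(
                features, lab, spec.kind, seed=cv_seed, folds=folds,
                grid_min_exp=grid_min_exp, grid_max_exp=grid_max_exp,
                standardize=standardize,
            )
        res = evaluate(features, lab, use_spec, folds=folds, seed=cv_seed,
                       standardize=standardize)
        return res.accuracy if statistic == "accuracy" else res.auc

    observed = _stat(labels)
    null = np.empty(B)
    for b in range(B):
        null[b] = _stat(rng.permutation(labels))
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    seed_int = seed if isinstance(seed, int) else -1
    return PermutationResult(
        observed_stat=observed, null_stats=null, p_value=float(p), B=B,
        seed=seed_int, statistic=statistic,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def per_pc_analysis(
    scores: np.ndarray,
    metadata: list[SpecimenMetadata],
    spec: ClassifierSpec,
    pcs: tuple[int, ...] = tuple(range(1, 12)),
    B: int = 1000,
    seed: int = 0,
    folds: int = 4,
    statistic: str = "accuracy",
    fast_perm: bool = False,
    standardize: bool = True,
) -> AgeClassTable:
    """Single-PC age discrimination, pooled and per species.

    ``pcs`` are 1-based PC numbers (PC 1 = first column of ``scores``, the
    printed convention).  Per-species rows use only that species' specimens
    but the PC scores from the pooled decomposition.  Each row gets its own
    reproducible permutation stream spawned from ``seed``.
    """
    scores = np.asarray(scores, float)
    species = np.array([m.species for m in metadata])
    ages = np.array([m.age_class for m in metadata])
    groups = ["pooled"] + sorted(set(species))
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(groups) * len(pcs)))
    rows = []
    for group in groups:
        mask = np.ones(len(metadata), bool) if group == "pooled" else species == group
        for pc in pcs:
            child = next(streams)
            feat = scores[mask, pc - 1]
            lab = ages[mask]
            n_adult = int(np.sum(lab == "adult"))
            n_infant = int(np.sum(lab == "infant"))
            if min(n_adult, n_infant) < 2:
                rows.append(
                    dict(group=group, pc=pc, n=int(mask.sum()), accuracy=np.nan,
                         auc=np.nan, p_value=np.nan, direction="none",
                         significance_band="insufficient-n")
                )
                continue
            res = evaluate(feat, lab, spec, folds=min(folds, n_adult, n_infant),
                           seed=0, standardize=standardize)
            perm = permutation_test(
                feat, lab, spec, B=B, seed=np.random.default_rng(child),
                folds=min(folds, n_adult, n_infant), statistic=statistic,
                fast_perm=fast_perm, standardize=standardize,
            )
            rows.append(
                dict(group=group, pc=pc, n=int(mask.sum()), accuracy=res.accuracy,
                     auc=res.auc, p_value=perm.p_value,
                     direction=direction_of_effect(feat, lab),
                     significance_band=significance_band(perm.p_value))
            )
    df = pd.DataFrame(rows)
    valid = df["p_value"].notna()
    df["p_bh"] = np.nan
    if valid.any():
        df.loc[valid, "p_bh"] = _bh_adjust(df.loc[valid, "p_value"].to_numpy())
    return AgeClassTable(df)
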