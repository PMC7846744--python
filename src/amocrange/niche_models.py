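"""Suitability learners and validation metrics.

Three learners are shipped, mirroring a pragmatic ensemble for
presence/background niche modeling:

``MAXENT``
    An l1-regularized logistic model over a MaxEnt-style feature expansion
    (linear, quadratic, pairwise-product and hinge features with knots at
    training deciles).  This is the standard penalized-GLM realization of
    the MaxEnt density formulation for presence vs background data.
``BRT``
    Boosted regression trees: gradient-boosted classification trees with
    small shrinkage, interaction depth 3 and early stopping.
``CART``
    A single classification tree with cost-complexity pruning selected by
    internal cross-validation.

All learners consume the five bioclim variables, standardized per species
with statistics from the training split, and emit suitabilities in [0, 1].
Validation uses a rank-based (Mann-Whitney) AUC plus confusion-matrix
metrics (sensitivity, specificity, TSS, Cohen's kappa, omission rate) at a
stated binarization threshold; species x algorithm combinations whose mean
cross-run TSS is <= 0.4 are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.tree import DecisionTreeClassifier

from .binarization import compute_threshold
from .errors import FitError, MetricError, ParameterError

DEFAULT_TSS_MIN = 0.4
METRIC_COLUMNS = ("species_id", "algorithm", "run", "auc", "tss", "kappa", "omission")


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Equals the fraction of (presence, background) score pairs in which the
    presence scores higher, counting ties as one half.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise MetricError("roc_auc needs scores on both sides")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    omission: float


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Sensitivity, specificity, TSS, kappa and omission from counts.

    TSS = sensitivity + specificity - 1; kappa is the chance-corrected
    agreement (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginals; omission = fn / (tp + fn).
    """
    if min(tp, fn, tn, fp) < 0:
        raise MetricError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise MetricError("both classes must be represented (zero marginal)")
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        tss=sens + spec - 1.0,
        kappa=kappa,
        omission=fn / (tp + fn),
    )


# ---------------------------------------------------------------------------
# learners


@dataclass
class SuitabilityModel:
    """A fitted per-species, per-run suitability predictor.

    ``predict`` maps raw bioclim feature rows to suitabilities in [0, 1]
    and is pure: the standardization statistics and the fitted estimator
    are frozen at training time.
    """

    species_id: str
    algorithm: str
    run: int
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    estimator: object
    expand: Callable[[np.ndarray], np.ndarray] | None = None
    n_train: int = 0
    seed: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (np.asarray(features, dtype=float) - self.feat_mean) / self.feat_sd
        if self.expand is not None:
            x = self.expand(x)
        p = self.estimator.predict_proba(x)[:, 1]
        return np.clip(p, 0.0, 1.0)


def _maxent_expansion(knots: list[np.ndarray]) -> Callable[[np.ndarray], np.ndarray]:
    """Linear + quadratic + product + hinge feature map on standardized inputs."""

    def expand(x: np.ndarray) -> np.ndarray:
        cols = [x, x**2]
        nv = x.shape[1]
        prods = [x[:, i] * x[:, j] for i in range(nv) for j in range(i + 1, nv)]
        cols.append(np.column_stack(prods))
        hinges = [
            np.maximum(0.0, x[:, v, None] - knots[v][None, :]) for v in range(nv)
        ]
        cols.extend(hinges)
        return np.concatenate(cols, axis=1)

    return expand


def _fit_maxent(x: np.ndarray, y: np.ndarray, hp: dict, seed: int):
    deciles = np.arange(1, 10) / 10.0
    knots = [np.unique(np.quantile(x[:, v], deciles)) for v in range(x.shape[1])]
    expand = _maxent_expansion(knots)
    est = LogisticRegression(
        l1_ratio=1.0,  # pure l1 penalty
        C=hp.get("C", 1.0),
        solver="liblinear",
        max_iter=hp.get("max_iter", 300),
        random_state=seed,
    )
    est.fit(expand(x), y)
    return est, expand


def _fit_brt(x: np.ndarray, y: np.ndarray, hp: dict, seed: int):
    est = GradientBoostingClassifier(
        learning_rate=hp.get("shrinkage", 0.01),
        max_depth=hp.get("depth", 3),
        n_estimators=hp.get("max_trees", 400),
        subsample=hp.get("subsample", 0.8),
        validation_fraction=0.2,
        n_iter_no_change=hp.get("patience", 15),
        tol=1e-4,
        random_state=seed,
    )
    est.fit(x, y)
    return est, None


def _fit_cart(x: np.ndarray, y: np.ndarray, hp: dict, seed: int):
    base = DecisionTreeClassifier(
        min_samples_leaf=hp.get("min_samples_leaf", 5), random_state=seed
    )
    path = base.cost_complexity_pruning_path(x, y)
    alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
    if len(alphas) > 8:  # subsample the pruning path for speed
        alphas = alphas[np.linspace(0, len(alphas) - 1, 8).round().astype(int)]
    best_alpha, best_score = 0.0, -np.inf
    rng = np.random.default_rng(seed)
    folds = rng.integers(0, 3, size=len(y))
    for alpha in alphas:
        scores = []
        for k in range(3):
            tr, te = folds != k, folds == k
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            t = DecisionTreeClassifier(
                min_samples_leaf=hp.get("min_samples_leaf", 5),
                ccp_alpha=alpha,
                random_state=seed,
            ).fit(x[tr], y[tr])
            p = t.predict_proba(x[te])[:, 1]
            scores.append(roc_auc(p[y[te] == 1], p[y[te] == 0]))
        if scores and np.mean(scores) > best_score:
            best_score, best_alpha = float(np.mean(scores)), float(alpha)
    est = DecisionTreeClassifier(
        min_samples_leaf=hp.get("min_samples_leaf", 5),
        ccp_alpha=best_alpha,
        random_state=seed,
    ).fit(x, y)
    return est, None


ALGORITHM_REGISTRY: dict[str, Callable] = {
    "MAXENT": _fit_maxent,
    "BRT": _fit_brt,
    "CART": _fit_cart,
}
DEFAULT_ALGORITHMS = ("MAXENT", "BRT", "CART")


def fit_suitability(
    algorithm: str,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
    species_id: str = "",
    run: int = 0,
) -> SuitabilityModel:
    """Fit one learner on raw bioclim features and binary labels.

    Labels are 1 for presence, 0 for pseudoabsence.  Features are
    standardized internally with training-set statistics, which the
    returned model reuses at prediction time.
    """
    if algorithm not in ALGORITHM_REGISTRY:
        raise ParameterError(
            f"unknown algorithm {algorithm!r}; registered: {sorted(ALGORITHM_REGISTRY)}"
        )
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ParameterError("features must be (n, p) aligned with labels")
    if len(np.unique(y)) < 2:
        raise FitError(f"{species_id or 'training set'}: single-class training set")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mean) / sd
    est, expand = ALGORITHM_REGISTRY[algorithm](xs, y, hyperparams or {}, seed)
    return SuitabilityModel(
        species_id=species_id,
        algorithm=algorithm,
        run=run,
        feat_mean=mean,
        feat_sd=sd,
        estimator=est,
        expand=expand,
        n_train=len(y),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate_model(
    model: SuitabilityModel,
    test_presence_features: np.ndarray,
    test_background_features: np.ndarray,
    train_presence_features: np.ndarray,
    train_background_features: np.ndarray,
    criterion: str = "P10TP",
) -> dict:
    """Held-out metrics for one fitted model.

    AUC is threshold-free; confusion metrics are computed on the validation
    split at the same threshold criterion used for downstream binarization
    (default the 10th-percentile training presence).
    """
    sp = model.predict(test_presence_features)
    sb = model.predict(test_background_features)
    train_p = model.predict(train_presence_features)
    train_b = model.predict(train_background_features)
    thr = compute_threshold(
        train_p,
        scores=np.concatenate([train_p, train_b]),
        labels=np.concatenate(
            [np.ones(len(train_p), dtype=int), np.zeros(len(train_b), dtype=int)]
        ),
        criterion=criterion,
    )
    tp = int((sp >= thr.value).sum())
    fn = int((sp < thr.value).sum())
    fp = int((sb >= thr.value).sum())
    tn = int((sb < thr.value).sum())
    cm = confusion_metrics(tp, fn, tn, fp)
    return {
        "species_id": model.species_id,
        "algorithm": model.algorithm,
        "run": model.run,
        "auc": roc_auc(sp, sb),
        "tss": cm.tss,
        "kappa": cm.kappa,
        "omission": cm.omission,
        "threshold": thr.value,
    }


def sample_screening_species(
    records: Sequence, per_realm: int = 15, seed: int = 0
) -> list:
    """Random screening sample: up to ``per_realm`` species per realm.

    Used to pick the species on which every registered learner is tried
    before settling on the retained algorithm set.
    """
    rng = np.random.default_rng(seed)
    by_realm: dict[str, list] = {}
    for r in records:
        by_realm.setdefault(r.realm, []).append(r)
    sample = []
    for realm in sorted(by_realm):
        grp = by_realm[realm]
        take = min(per_realm, len(grp))
        sample.extend(grp[i] for i in rng.choice(len(grp), size=take, replace=False))
    return sample


def screen_algorithms(
    fit_eval_rows: Sequence[dict] | pd.DataFrame,
) -> pd.DataFrame:
    """Tabulate mean validation metrics per algorithm, best TSS first.

    Input rows are per species x algorithm x run metric dicts (as produced
    by :func:`evaluate_model`) for a screening sample — by default 15
    random species per realm fitted with every registered learner.  The
    table reports the evidence; choosing which algorithms to retain is the
    caller's decision.
    """
    df = pd.DataFrame(fit_eval_rows)
    if df.empty:
        raise ParameterError("no screening results to tabulate")
    table = (
        df.groupby("algorithm", as_index=False)[["auc", "tss", "kappa", "omission"]]
        .mean()
        .sort_values("tss", ascending=False)
        .reset_index(drop=True)
    )
    table["n_fits"] = df.groupby("algorithm").size().reindex(table["algorithm"]).values
    return table


def exclude_poor_models(
    results: pd.DataFrame, tss_min: float = DEFAULT_TSS_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species x algorithm combinations with mean cross-run TSS <= tss_min.

    Returns (retained rows, exclusion log).  The boundary is inclusive:
    a mean TSS exactly equal to ``tss_min`` is excluded.
    """
    if "tss" not in results.columns:
        raise ParameterError("results must carry a 'tss' column")
    mean_tss = results.groupby(["species_id", "algorithm"])["tss"].mean()
    poor = mean_tss[mean_tss <= tss_min]
    log = poor.rename("mean_tss").reset_index()
    log["reason"] = "tss"
    key = results.set_index(["species_id", "algorithm"]).index
    retained = results[~key.isin(poor.index)].reset_index(drop=True)
    return retained, log
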