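"""Presence-background single-species SDM in the MaxEnt model family.

The model is an L1-penalized Bernoulli (logistic) regression over MaxEnt-style
feature expansions of the predictors — linear (L), quadratic (Q), hinge (H),
product (P) and threshold (T) classes — which is the established equivalence
between MaxEnt and penalized logistic regression on presence-background data.
It is *not* a reimplementation of the sequential-update MaxEnt program: the
optimization is a deterministic penalized likelihood fit, which keeps the
pipeline reproducible and oracle-checkable while staying in the same model
family.

The regularization multiplier ``m`` scales an L1 penalty of ``m / sqrt(n)``
per coefficient on the mean log-likelihood (mirroring MaxEnt's default
1/sqrt(n) regularization scaling); the intercept is never penalized, so a
fully shrunk model predicts the training base rate.

Variable importance is permutation-based: the drop in training gain (model
log-likelihood above the constant base-rate model) when a predictor's column
is permuted, averaged over permutations and normalized to sum to 100%.  This
differs from the MaxEnt program's path-dependent gain accounting but shares
its normalization and is directly checkable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

DEFAULT_MULTIPLIERS = (0.25, 0.50, 1.0, 1.50, 2.0, 4.0, 6.0)
DEFAULT_CLASS_COMBOS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")
DEFAULT_REPLICATES = 100

_VALID_CLASSES = set("LQHPT")


class SDMError(ValueError):
    """Raised for invalid SDM configurations or failed fits."""


@dataclass
class FeatureSpec:
    """Feature classes, knot count and regularization multiplier."""

    classes: str = "LQH"
    knots: int = 10
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.classes = "".join(dict.fromkeys(self.classes.upper()))
        if not self.classes or set(self.classes) - _VALID_CLASSES:
            raise SDMError(
                f"classes must be a non-empty subset of LQHPT, got "
                f"{self.classes!r}")
        if self.multiplier <= 0:
            raise SDMError("regularization multiplier must be positive")
        if self.knots < 1:
            raise SDMError("knot count must be >= 1")


@dataclass
class MaxentFeatures:
    """Deterministic L/Q/H/P/T feature expansion with quantile knots.

    Knots are placed at ``knots`` equally spaced interior quantiles of the
    training data and frozen, so the same transform applies to new sites and
    prediction grids.  Q/H/T features of constant predictors are dropped with
    a warning (they would be constant or zero).
    """

    spec: FeatureSpec
    knot_values: dict[str, np.ndarray] = field(default_factory=dict)
    predictors: list[str] = field(default_factory=list)

    def fit(self, X: pd.DataFrame) -> "MaxentFeatures":
        self.predictors = list(X.columns)
        qs = np.arange(1, self.spec.knots + 1) / (self.spec.knots + 1)
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                if set(self.spec.classes) & set("QHT"):
                    log.warning("predictor %r is constant; dropping its "
                                "Q/H/T features", col)
                self.knot_values[col] = np.array([])
            else:
                self.knot_values[col] = np.unique(np.quantile(x, qs))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for name in self.predictors:
            x = X[name].to_numpy(dtype=float)
            knots = self.knot_values[name]
            constant = knots.size == 0
            if "L" in self.spec.classes:
                cols[f"L({name})"] = x
            if "Q" in self.spec.classes and not constant:
                cols[f"Q({name})"] = x ** 2
            if "H" in self.spec.classes and not constant:
                for k in knots:
                    cols[f"H({name},{k:.6g})"] = np.maximum(0.0, x - k)
            if "T" in self.spec.classes and not constant:
                for k in knots:
                    cols[f"T({name},{k:.6g})"] = (x > k).astype(float)
        if "P" in self.spec.classes:
            for a, b in combinations(self.predictors, 2):
                cols[f"P({a}*{b})"] = (X[a].to_numpy(dtype=float)
                                       * X[b].to_numpy(dtype=float))
        return pd.DataFrame(cols, index=X.index)


def build_features(X: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Expand a (standardized) design matrix into MaxEnt-style features."""
    return MaxentFeatures(spec).fit(X).transform(X)


@dataclass
class SDMModel:
    """A fitted penalized presence-background model.

    ``predict`` expects predictors on the same (standardized) scale the model
    was fitted on; ``standardization`` carries the per-predictor (mean, sd)
    constants needed to put raw grids on that scale.
    """

    features: MaxentFeatures
    weights: pd.Series
    intercept: float
    multiplier: float
    standardization: dict[str, tuple[float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        F = self.features.transform(X)
        w = self.weights.reindex(F.columns).fillna(0.0).to_numpy()
        return self.intercept + F.to_numpy() @ w

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of presence at each row of ``X``."""
        eta = np.clip(self.decision(X), -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))

    def n_active(self) -> int:
        return int((self.weights.abs() > 1e-10).sum())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": "sdm",
            "classes": self.features.spec.classes,
            "knots": self.features.spec.knots,
            "multiplier": self.multiplier,
            "predictors": self.features.predictors,
            "knot_values": {k: v.tolist()
                            for k, v in self.features.knot_values.items()},
            "weights": {k: float(v) for k, v in self.weights.items()},
            "intercept": self.intercept,
            "standardization": (None if self.standardization is None else
                                {k: list(v)
                                 for k, v in self.standardization.items()}),
            "metadata": self.metadata,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SDMModel":
        d = json.loads(Path(path).read_text())
        spec = FeatureSpec(classes=d["classes"], knots=d["knots"],
                           multiplier=d["multiplier"])
        feats = MaxentFeatures(
            spec,
            knot_values={k: np.asarray(v)
                         for k, v in d["knot_values"].items()},
            predictors=list(d["predictors"]))
        std = d.get("standardization")
        return cls(features=feats,
                   weights=pd.Series(d["weights"], dtype=float),
                   intercept=float(d["intercept"]),
                   multiplier=float(d["multiplier"]),
                   standardization=(None if std is None else
                                    {k: (v[0], v[1])
                                     for k, v in std.items()}),
                   metadata=d.get("metadata", {}))


def _l1_logistic(F: np.ndarray, y: np.ndarray, multiplier: float,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float]:
    """L1-penalized logistic fit; penalty multiplier/sqrt(n) per coefficient
    on the mean log-likelihood.  Intercept unpenalized (saga solver)."""
    n = len(y)
    lam = multiplier / np.sqrt(n)        # per-coefficient penalty, mean loss
    C = 1.0 / (n * lam)                  # sklearn's sum-loss parametrization
    # liblinear technically penalizes the (scaled) intercept too; with the
    # large intercept_scaling that cost is negligible and the Newton polish
    # below solves the exact unpenalized-intercept score equation anyway
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                             intercept_scaling=100.0,
                             max_iter=max_iter, tol=tol, random_state=0)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            clf.fit(F, y)
        except ConvergenceWarning as exc:
            raise SDMError(
                f"penalized fit did not converge in {max_iter} iterations "
                f"(multiplier={multiplier}, n={n}): {exc}") from exc
    coefs = clf.coef_[0]
    # The intercept is unpenalized, so at the optimum it solves the Bernoulli
    # score equation given the coefficients.  Solve that 1-D equation by
    # Newton: a no-op at a converged solution, and it repairs the
    # vanishing-gradient regime of the solver at very large multipliers
    # (tiny C), where the fitted intercept would otherwise be arbitrary.
    eta_w = F @ coefs
    intercept = float(clf.intercept_[0])
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(eta_w + intercept)))
        step = np.sum(y - p) / max(np.sum(p * (1 - p)), 1e-12)
        intercept += step
        if abs(step) < 1e-12:
            break
    return coefs, intercept


def fit_penalized(features: pd.DataFrame, y: np.ndarray, multiplier: float,
                  feature_set: MaxentFeatures | None = None,
                  standardization: dict | None = None,
                  max_iter: int = 20_000, tol: float = 1e-4) -> SDMModel:
    """Fit the penalized Bernoulli model on a pre-built feature matrix."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SDMError("both presence and background classes are required")
    if multiplier <= 0:
        raise SDMError("multiplier must be positive")
    coefs, intercept = _l1_logistic(features.to_numpy(dtype=float), y,
                                    multiplier, max_iter, tol)
    if not np.all(np.isfinite(coefs)) or not np.isfinite(intercept):
        raise SDMError("fit produced non-finite weights")
    if feature_set is None:
        # identity transform over the given columns (L-features of them)
        spec = FeatureSpec(classes="L", multiplier=multiplier)
        feature_set = MaxentFeatures(
            spec, knot_values={c: np.array([]) for c in features.columns},
            predictors=list(features.columns))
        weights = pd.Series(coefs, index=[f"L({c})" for c in features.columns])
    else:
        weights = pd.Series(coefs, index=features.columns)
    return SDMModel(features=feature_set, weights=weights,
                    intercept=intercept, multiplier=multiplier,
                    standardization=standardization)


def fit_sdm(X: pd.DataFrame, y: np.ndarray, spec: FeatureSpec,
            standardization: dict | None = None) -> SDMModel:
    """Build features from (standardized) predictors and fit the model."""
    feats = MaxentFeatures(spec).fit(X)
    F = feats.transform(X)
    model = fit_penalized(F, y, spec.multiplier, feature_set=feats,
                          standardization=standardization)
    return model


def _mean_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def predictive_deviance(p: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli deviance, -2 x mean log-likelihood."""
    return -2.0 * _mean_loglik(p, y)


def tune(X: pd.DataFrame, y: np.ndarray,
         multipliers=DEFAULT_MULTIPLIERS,
         class_combos=DEFAULT_CLASS_COMBOS,
         folds: int = 5, seed: int = 0) -> FeatureSpec:
    """Grid search over multipliers x feature-class combos.

    Selects the spec minimizing mean cross-validated predictive deviance;
    ties go to the earlier grid entry.  The full grid is attached to the
    returned spec as ``cv_results_`` and logged.
    """
    multipliers = list(multipliers)
    class_combos = list(class_combos)
    if not multipliers or not class_combos:
        raise SDMError("tuning grid must be non-empty")
    if folds < 2:
        raise SDMError("folds must be >= 2")
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    best: tuple[float, FeatureSpec] | None = None
    for combo in class_combos:
        for m in multipliers:
            spec = FeatureSpec(classes=combo, multiplier=m)
            devs = []
            for train, test in splits:
                feats = MaxentFeatures(spec).fit(X.iloc[train])
                model = fit_penalized(feats.transform(X.iloc[train]),
                                      y[train], m, feature_set=feats)
                devs.append(predictive_deviance(model.predict(X.iloc[test]),
                                                y[test]))
            mean_dev = float(np.mean(devs))
            rows.append({"classes": combo, "multiplier": m,
                         "cv_deviance": mean_dev})
            if best is None or mean_dev < best[0]:
                best = (mean_dev, spec)
    results = pd.DataFrame(rows)
    log.info("tuning grid results:\n%s", results.to_string(index=False))
    spec = best[1]
    spec.cv_results_ = results  # type: ignore[attr-defined]
    return spec


def percent_contribution(model: SDMModel, X: pd.DataFrame, y: np.ndarray,
                         permutations: int = 5, seed: int = 0) -> pd.Series:
    """Permutation importance per predictor, normalized to sum to 100."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    base_ll = _mean_loglik(model.predict(X), y)
    drops = pd.Series(0.0, index=list(X.columns))
    for col in X.columns:
        total = 0.0
        for _ in range(permutations):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            total += base_ll - _mean_loglik(model.predict(Xp), y)
        drops[col] = max(0.0, total / permutations)
    if drops.sum() <= 0:
        # no predictor moves the gain (e.g. fully shrunk model): split evenly
        return pd.Series(100.0 / len(drops), index=drops.index)
    return 100.0 * drops / drops.sum()


@dataclass
class EliminationResult:
    retained: list[str]
    path: list[dict]


def backward_eliminate(X: pd.DataFrame, y: np.ndarray,
                       contrib_threshold: float = 1.0,
                       corr_threshold: float = 0.75,
                       spec: FeatureSpec | None = None,
                       permutations: int = 3,
                       seed: int = 0) -> EliminationResult:
    """Stepwise backward elimination of predictors.

    Repeatedly refits, then (a) among pairs with Pearson ``|r| >=
    corr_threshold`` drops the lower-contribution member, else (b) drops the
    lowest-contribution predictor with contribution ``<= contrib_threshold``
    percent.  Stops when no rule fires; raises if everything would be dropped.
    """
    if X.shape[1] < 1:
        raise SDMError("need at least one predictor")
    spec = spec or FeatureSpec(classes="LQ")
    cols = list(X.columns)
    path: list[dict] = []
    while True:
        model = fit_sdm(X[cols], np.asarray(y), spec)
        contrib = percent_contribution(model, X[cols], y,
                                       permutations=permutations, seed=seed)
        drop: str | None = None
        reason = ""
        if len(cols) > 1:
            corr = X[cols].corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            pairs = [(a, b) for a in cols for b in cols
                     if a < b and corr.loc[a, b] >= corr_threshold]
            if pairs:
                a, b = max(pairs, key=lambda p: corr.loc[p[0], p[1]])
                drop = a if contrib[a] <= contrib[b] else b
                reason = f"|r|={corr.loc[a, b]:.3f} with " + \
                    (b if drop == a else a)
        if drop is None:
            weak = contrib[contrib <= contrib_threshold]
            if len(weak):
                drop = weak.idxmin()
                reason = f"contribution {contrib[drop]:.2f}% <= " \
                         f"{contrib_threshold}%"
        if drop is None:
            break
        if len(cols) == 1:
            raise SDMError(
                "backward elimination would drop every predictor; relax "
                "contrib_threshold or corr_threshold")
        cols.remove(drop)
        path.append({"dropped": drop, "reason": reason,
                     "remaining": list(cols)})
        log.info("backward elimination: dropped %r (%s)", drop, reason)
    return EliminationResult(retained=cols, path=path)


@dataclass
class SDMEnsemble:
    """Replicate-averaged SDM: mean prediction over resampled refits."""

    members: list[SDMModel]
    spec: FeatureSpec
    replicate_auc: np.ndarray
    replicate_threshold: np.ndarray
    standardization: dict | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.mean([m.predict(X) for m in self.members], axis=0)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.replicate_auc))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.replicate_auc, ddof=1)) \
            if len(self.replicate_auc) > 1 else 0.0

    @property
    def threshold_mean(self) -> float:
        return float(np.mean(self.replicate_threshold))


def fit_replicates(X: pd.DataFrame, y: np.ndarray, spec: FeatureSpec,
                   n_replicates: int = DEFAULT_REPLICATES, seed: int = 0,
                   holdout_fraction: float = 0.2,
                   standardization: dict | None = None) -> SDMEnsemble:
    """Fit ``n_replicates`` resampled models and average their predictions.

    Each replicate holds out a seeded random ``holdout_fraction`` of the data
    (cross-validation-style error estimation), fits on the remainder, and
    records held-out AUC and the held-out maximum sensitivity-plus-specificity
    threshold, enabling mean +/- sd reporting across replicates.
    """
    from .evaluate import max_sens_spec_threshold  # local to avoid cycle

    if n_replicates < 1:
        raise SDMError("n_replicates must be >= 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    members, aucs, thresholds = [], [], []
    n = len(y)
    n_hold = max(1, int(round(holdout_fraction * n)))
    for _ in range(n_replicates):
        for _attempt in range(20):
            perm = rng.permutation(n)
            hold, train = perm[:n_hold], perm[n_hold:]
            if (len(np.unique(y[train])) == 2
                    and len(np.unique(y[hold])) == 2):
                break
        else:
            raise SDMError("could not draw a replicate split with both "
                           "classes on each side")
        model = fit_sdm(X.iloc[train], y[train], spec,
                        standardization=standardization)
        p_hold = model.predict(X.iloc[hold])
        aucs.append(roc_auc_score(y[hold], p_hold))
        thresholds.append(max_sens_spec_threshold(p_hold, y[hold]))
        members.append(model)
    if n_replicates == 1:
        # single replicate: refit on the full data, matching a plain fit
        members = [fit_sdm(X, y, spec, standardization=standardization)]
    return SDMEnsemble(members=members, spec=spec,
                       replicate_auc=np.asarray(aucs),
                       replicate_threshold=np.asarray(thresholds),
                       standardization=standardization)
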