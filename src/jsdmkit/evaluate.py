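"""Model discrimination, thresholding and the SDM-vs-JSDM comparison.

Evaluation follows standard presence-background practice: the "negatives" of
the ROC analysis are the background pseudo-absence sites (there are no true
absences).  Discrimination is AUC — the probability that a random presence
site outscores a random background site, ties counted half.  The operating
threshold is the maximum sensitivity-plus-specificity rule over observed
score values.  Threshold-dependent performance is reported as sensitivity
(percentage of occurrence records falling inside the thresholded predicted
range) at several evaluation cell sizes, where a coarse cell counts as
predicted-present iff any fine cell within it is predicted-present (an
optional mean-aggregation rule is provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .predict import ProbabilitySurface
from .tables import OccurrenceSet, SiteTable

log = logging.getLogger(__name__)

DEFAULT_CELL_SIZES = (0.004, 0.01, 0.02, 0.03, 0.05)
DEFAULT_FOLDS = 5
DEFAULT_TRAIN_FRACTION = 0.6


class EvaluationError(ValueError):
    """Raised for undefined evaluation requests (e.g. one-class input)."""


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise EvaluationError(
            "both presence and background labels are required")


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties half).

    Equivalent to the Mann-Whitney rank statistic and to the area under the
    trapezoidal ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def max_sens_spec_threshold(scores, labels) -> float:
    """Threshold (among observed scores) maximizing sensitivity + specificity.

    Prediction rule: positive iff ``score >= threshold``.  Ties in the
    objective are broken toward the lowest qualifying threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    candidates = np.unique(scores)
    # sens(t) = P(pos >= t), spec(t) = P(neg < t); counted via searchsorted
    # and divided once, so values are bit-identical to direct proportions
    sens = (len(pos) - np.searchsorted(pos, candidates, side="left")) \
        / len(pos)
    spec = np.searchsorted(neg, candidates, side="left") / len(neg)
    objective = sens + spec
    best = np.flatnonzero(objective == objective.max())[0]
    return float(candidates[best])


def sensitivity_at_resolution(surface: ProbabilitySurface,
                              occ: OccurrenceSet, threshold: float,
                              cell_size: float,
                              rule: str = "any") -> float:
    """Sensitivity (%) of the thresholded surface at an evaluation cell size.

    The surface is aggregated onto a coarse lattice anchored at the surface
    origin.  Under ``rule="any"`` (default) a coarse cell is predicted
    present iff any unmasked fine cell inside it meets the threshold; under
    ``rule="mean"`` iff the mean fine-cell probability does.  Sensitivity is
    100 x (occurrences in predicted-present coarse cells) / (occurrences).
    """
    if cell_size < surface.cell_size:
        raise EvaluationError(
            f"evaluation cell size {cell_size} is finer than the surface "
            f"resolution {surface.cell_size}")
    if len(occ) == 0:
        raise EvaluationError("no occurrence records to evaluate")
    lon, lat = occ.lon, occ.lat
    if (lon.min() < surface.west or lon.max() > surface.east
            or lat.min() < surface.south or lat.max() > surface.north):
        raise EvaluationError("occurrences fall outside the surface extent")

    rows, cols = np.nonzero(surface.mask)
    lons, lats = surface.cell_centers()
    ci = np.floor((surface.north - lats[rows]) / cell_size).astype(int)
    cj = np.floor((lons[cols] - surface.west) / cell_size).astype(int)
    ncj = int(np.ceil((surface.east - surface.west) / cell_size))
    flat = ci * ncj + cj
    probs = surface.values[rows, cols]
    present_cells: set[int]
    if rule == "any":
        hit = probs >= threshold
        present_cells = set(flat[hit].tolist())
    elif rule == "mean":
        df = pd.DataFrame({"cell": flat, "p": probs})
        means = df.groupby("cell")["p"].mean()
        present_cells = set(means[means >= threshold].index.tolist())
    else:
        raise EvaluationError(f"unknown aggregation rule {rule!r}")

    oi = np.floor((surface.north - lat) / cell_size).astype(int)
    oj = np.floor((lon - surface.west) / cell_size).astype(int)
    # records on the outer east/north edge belong to the last cell
    oi = np.clip(oi, 0, None)
    oj = np.clip(oj, 0, None)
    ocell = oi * ncj + oj
    inside = np.fromiter((c in present_cells for c in ocell), dtype=bool,
                         count=len(ocell))
    return 100.0 * inside.sum() / len(ocell)


@dataclass
class EvalReport:
    """Evaluation summary for one model on one site table."""

    model_id: str
    auc: float
    auc_sd: float | None = None
    threshold: float = float("nan")
    sensitivity_by_cell_size: dict[float, float] = field(default_factory=dict)
    cv_auc: list[float] = field(default_factory=list)
    cv_sensitivity: list[float] = field(default_factory=list)
    cv_threshold: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    data_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise EvaluationError("AUC must lie in [0, 1]")
        for s in self.sensitivity_by_cell_size.values():
            if not (0.0 <= s <= 100.0):
                raise EvaluationError("sensitivity must lie in [0, 100]")

    @property
    def cv_auc_mean(self) -> float:
        return float(np.mean(self.cv_auc)) if self.cv_auc else float("nan")

    @property
    def cv_sensitivity_mean(self) -> float:
        return float(np.mean(self.cv_sensitivity)) \
            if self.cv_sensitivity else float("nan")

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id, "auc": self.auc, "auc_sd": self.auc_sd,
            "threshold": self.threshold,
            "sensitivity_by_cell_size": {str(k): v for k, v in
                                         self.sensitivity_by_cell_size.items()},
            "cv_auc": self.cv_auc, "cv_sensitivity": self.cv_sensitivity,
            "cv_threshold": self.cv_threshold,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_sensitivity_mean": self.cv_sensitivity_mean,
            "config": self.config, "data_fingerprint": self.data_fingerprint,
        }


def _split_indices(n: int, train_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def cross_validate(sites: SiteTable, model_kind: str,
                   folds: int = DEFAULT_FOLDS,
                   train_fraction: float = DEFAULT_TRAIN_FRACTION,
                   seed: int = 0, sdm_spec=None, jsdm_spec=None,
                   max_redraws: int = 20) -> EvalReport:
    """Repeated seeded train/validate splits (default 5 splits at 60/40).

    Each split fits the requested model on the training part and scores the
    held-out part: AUC, the maximum sensitivity-plus-specificity threshold
    derived from the *training* scores, and held-out sensitivity at that
    threshold.  Splits that lose an entire response class are redrawn (logged,
    up to ``max_redraws``).
    """
    if model_kind not in ("sdm", "jsdm"):
        raise EvaluationError(f"unknown model kind {model_kind!r}")
    if folds < 1:
        raise EvaluationError("folds must be >= 1")
    if not (0.0 < train_fraction < 1.0):
        raise EvaluationError("train_fraction must lie in (0, 1)")
    from . import jsdm as jsdm_mod
    from . import sdm as sdm_mod

    rng = np.random.default_rng(seed)
    n = sites.n_sites
    y_focal = sites.Y[sites.focal].to_numpy()
    cv_auc, cv_sens, cv_thr = [], [], []
    for fold in range(folds):
        for attempt in range(max_redraws):
            train, test = _split_indices(n, train_fraction, rng)
            cols = (sites.Y.to_numpy() if model_kind == "jsdm"
                    else y_focal[:, None])
            ok = all(len(np.unique(cols[part][:, j])) == 2
                     for part in (train, test)
                     for j in range(cols.shape[1]))
            if ok:
                break
            log.warning("fold %d: redrawing split (a class was lost, "
                        "attempt %d)", fold, attempt + 1)
        else:
            raise EvaluationError(
                "could not draw a split keeping both classes for every "
                "species")
        tr, te = sites.subset(train), sites.subset(test)
        if model_kind == "sdm":
            spec = sdm_spec or sdm_mod.FeatureSpec(classes="LQ")
            model = sdm_mod.fit_sdm(tr.X, tr.Y[tr.focal].to_numpy(), spec)
            s_train = model.predict(tr.X)
            s_test = model.predict(te.X)
        else:
            spec = jsdm_spec or jsdm_mod.desk_preset(seed=seed + fold)
            post = jsdm_mod.fit_jsdm(tr, spec)
            s_train = post.site_probability(tr.X, tr.focal)
            s_test = post.site_probability(te.X, te.focal)
        thr = max_sens_spec_threshold(s_train, tr.Y[tr.focal].to_numpy())
        y_te = te.Y[te.focal].to_numpy()
        cv_auc.append(auc(s_test, y_te))
        pres = y_te == 1
        cv_sens.append(100.0 * np.mean(s_test[pres] >= thr))
        cv_thr.append(thr)
    return EvalReport(
        model_id=model_kind,
        auc=float(np.mean(cv_auc)),
        threshold=float(np.mean(cv_thr)),
        cv_auc=cv_auc, cv_sensitivity=cv_sens, cv_threshold=cv_thr,
        config={"folds": folds, "train_fraction": train_fraction,
                "seed": seed},
        data_fingerprint=sites.fingerprint(),
    )


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Side-by-side comparison table (models as columns).

    Rows: AUC (with sd where available), the selected threshold, and
    sensitivity per evaluation cell size.  All reports must have been
    computed on the same evaluation data; no winner is declared.
    """
    if len(reports) < 2:
        raise EvaluationError("need at least two reports to compare")
    prints = {r.data_fingerprint for r in reports}
    if len(prints) != 1:
        raise EvaluationError(
            "reports were computed on different evaluation data")
    cell_sizes = sorted({cs for r in reports
                         for cs in r.sensitivity_by_cell_size})
    rows = {}
    rows["AUC"] = {r.model_id: r.auc for r in reports}
    rows["AUC sd"] = {r.model_id: r.auc_sd for r in reports}
    rows["Max sens+spec threshold"] = {r.model_id: r.threshold
                                       for r in reports}
    for cs in cell_sizes:
        rows[f"Sensitivity @ {cs:g}"] = {
            r.model_id: r.sensitivity_by_cell_size.get(cs)
            for r in reports}
    return pd.DataFrame(rows).T
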