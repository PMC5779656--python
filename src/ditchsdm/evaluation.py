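"""Cross-validated model evaluation and residual mapping.

The evaluation design follows standard presence/absence SDM practice:
stratified k-fold cross-validation (default k = 4) with a floor of more than
10 presences per fold, rank-based AUC as the threshold-independent score,
max-kappa thresholding of the held-out scores, confusion-matrix metrics
(PPV, NPV, overall accuracy, kappa), a spatial sorting bias diagnostic per
split, and per-pixel false-positive / false-negative ratio maps compiled
across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid
from .models import GlmFit, MaxentConfig, MaxentFit, fit_glm, fit_maxent, predict
from .network import Cell, CovariateTable, DitchGraph, OccurrenceSet
from .spatial_stats import spatial_sorting_bias

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "kfold_split",
    "auc",
    "auc_band",
    "max_kappa_threshold",
    "confusion_metrics",
    "cross_validate",
    "residual_maps",
    "species_frequency",
]


@dataclass
class FoldAssignment:
    """Seeded stratified fold partition of an occurrence set."""

    k: int
    seed: int
    fold_of: dict[Cell, int]
    presence_counts: list[int]
    absence_counts: list[int]

    def fold_cells(self, fold: int, occ: OccurrenceSet) -> tuple[list[Cell], list[Cell]]:
        """(test cells, train cells) for one fold."""
        test = [c for c in occ.cells if self.fold_of[c] == fold]
        train = [c for c in occ.cells if self.fold_of[c] != fold]
        return test, train


def kfold_split(
    occurrences: OccurrenceSet,
    k: int = 4,
    seed: int = 0,
    min_presence: int = 10,
    max_redraws: int = 100,
) -> FoldAssignment:
    """Random class-stratified partition into k folds.

    Every fold must hold more than ``min_presence`` presences (so both
    learning and validation samples stay above the floor); the draw is
    repeated up to ``max_redraws`` times, then an explicit error is raised.
    """
    rng = np.random.default_rng(seed)
    pres, abs_ = list(occurrences.presences), list(occurrences.absences)
    if len(pres) <= k * min_presence:
        raise ValueError(
            f"{len(pres)} presences cannot give > {min_presence} per fold with k={k}"
        )
    for _ in range(max_redraws):
        fold_of: dict[Cell, int] = {}
        for cells in (pres, abs_):
            order = list(cells)
            rng.shuffle(order)
            for i, cell in enumerate(order):
                fold_of[cell] = i % k
        p_counts = [sum(1 for c in pres if fold_of[c] == f) for f in range(k)]
        a_counts = [sum(1 for c in abs_ if fold_of[c] == f) for f in range(k)]
        if all(p > min_presence for p in p_counts):
            return FoldAssignment(
                k=k, seed=seed, fold_of=fold_of,
                presence_counts=p_counts, absence_counts=a_counts,
            )
    raise ValueError(
        f"could not satisfy the > {min_presence} presence floor per fold "
        f"after {max_redraws} draws"
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)  # midranks
    r_pos = float(ranks[labels == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_band(value: float) -> str:
    """Conventional interpretation band for an AUC value."""
    if value <= 0.5:
        return "no better than random"
    if value <= 0.7:
        return "low"
    if value <= 0.9:
        return "good"
    return "excellent"


def max_kappa_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Score threshold maximizing Cohen's kappa.

    Candidates are the midpoints between consecutive sorted unique scores;
    scores >= threshold predict presence. Ties resolve to the smallest
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("max-kappa threshold needs both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_k = float(candidates[0]), -np.inf
    for t in candidates:
        pred = (scores >= t).astype(int)
        kappa = _cohen_kappa(pred, labels)
        if kappa > best_k + 1e-12:
            best_t, best_k = float(t), float(kappa)
    return best_t, best_k


def _cohen_kappa(pred: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    po = float(np.mean(pred == labels))
    p_yes = pred.sum() / n * labels.sum() / n
    p_no = (1 - pred.sum() / n) * (1 - labels.sum() / n)
    pe = p_yes + p_no
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """PPV, NPV, overall accuracy and kappa from binary predictions.

    Undefined ratios (no predicted positives/negatives) are returned as nan
    -- flagged, never silently zeroed.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("length mismatch between predictions and labels")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    n = len(labels)
    return {
        "PPV": tp / (tp + fp) if tp + fp > 0 else np.nan,
        "NPV": tn / (tn + fn) if tn + fn > 0 else np.nan,
        "OA": (tp + tn) / n,
        "kappa": _cohen_kappa(predictions, labels),
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
    }


@dataclass
class FoldResult:
    fold: int
    auc: float
    threshold: float
    kappa: float
    ppv: float
    npv: float
    oa: float
    ssb: float
    failed: bool = False
    test_cells: list[Cell] = field(default_factory=list)
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None


@dataclass
class EvaluationReport:
    """Per-fold and aggregated cross-validation metrics for one species/model."""

    species: str
    model: str
    folds: list[FoldResult]

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.folds if not f.failed])

    def mean(self, attr: str) -> float:
        vals = self._values(attr)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else np.nan

    def sd(self, attr: str) -> float:
        vals = self._values(attr)
        vals = vals[np.isfinite(vals)]
        return float(vals.std(ddof=1)) if len(vals) > 1 else np.nan

    @property
    def mean_auc(self) -> float:
        return self.mean("auc")

    @property
    def band(self) -> str:
        return auc_band(self.mean_auc)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric, attr in [("AUC", "auc"), ("PPV", "ppv"), ("NPV", "npv"),
                             ("OA", "oa"), ("kappa", "kappa"), ("ssb", "ssb")]:
            rows.append({"species": self.species, "model": self.model, "metric": metric,
                         "mean": self.mean(attr), "sd": self.sd(attr)})
        return pd.DataFrame(rows)


def cross_validate(
    occurrences: OccurrenceSet,
    table: CovariateTable,
    folds: FoldAssignment,
    model: str = "glm",
    graph: DitchGraph | None = None,
    maxent_config: MaxentConfig | None = None,
    threshold_on: str = "test",
) -> EvaluationReport:
    """k-fold cross-validation of one model for one species.

    Per fold: fit on the other k-1 folds, score the held-out cells, compute
    AUC, pick the max-kappa threshold on the held-out scores (or on training
    scores with ``threshold_on='train'`` for leakage-sensitivity checks) and
    derive the confusion metrics at it. SSB is computed per split when a
    graph is supplied. A fold whose fit fails is marked failed and excluded
    from the aggregation with a warning.
    """
    if not table.rescaled:
        raise ValueError("cross_validate expects rescaled covariates")
    if threshold_on not in ("test", "train"):
        raise ValueError("threshold_on must be 'test' or 'train'")
    names = table.covariates
    results: list[FoldResult] = []
    pres_set = set(occurrences.presences)
    for f in range(folds.k):
        test_cells, train_cells = folds.fold_cells(f, occurrences)
        y_train = np.array([1 if c in pres_set else 0 for c in train_cells])
        y_test = np.array([1 if c in pres_set else 0 for c in test_cells])
        try:
            X_train = table.rows_for(train_cells)
            X_test = table.rows_for(test_cells)
            if model == "glm":
                fit = fit_glm(X_train[names], y_train, names=names)
            elif model == "maxent":
                train_pres = [c for c in train_cells if c in pres_set]
                fit = fit_maxent(train_pres, X_train, train_cells,
                                 config=maxent_config, variables=names)
            else:
                raise ValueError(f"unknown model {model!r}")
            scores = predict(fit, X_test)
            fold_auc = auc(scores, y_test)
            if threshold_on == "test":
                thr, kap = max_kappa_threshold(scores, y_test)
            else:
                train_scores = predict(fit, X_train)
                thr, _ = max_kappa_threshold(train_scores, y_train)
                kap = _cohen_kappa((scores >= thr).astype(int), y_test)
            cm = confusion_metrics((scores >= thr).astype(int), y_test)
            ssb = np.nan
            if graph is not None:
                train_occ = OccurrenceSet(
                    species=occurrences.species,
                    presences=tuple(c for c in train_cells if c in pres_set),
                    absences=tuple(c for c in train_cells if c not in pres_set),
                )
                test_occ = OccurrenceSet(
                    species=occurrences.species,
                    presences=tuple(c for c in test_cells if c in pres_set),
                    absences=tuple(c for c in test_cells if c not in pres_set),
                )
                ssb = spatial_sorting_bias(train_occ, test_occ, graph).ssb
            results.append(FoldResult(
                fold=f, auc=fold_auc, threshold=thr, kappa=cm["kappa"],
                ppv=cm["PPV"], npv=cm["NPV"], oa=cm["OA"], ssb=ssb,
                test_cells=test_cells, test_scores=scores, test_labels=y_test,
            ))
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"fold {f} failed ({err}); aggregating remaining folds",
                          stacklevel=2)
            results.append(FoldResult(
                fold=f, auc=np.nan, threshold=np.nan, kappa=np.nan,
                ppv=np.nan, npv=np.nan, oa=np.nan, ssb=np.nan, failed=True,
            ))
    return EvaluationReport(species=occurrences.species, model=model, folds=results)


def residual_maps(
    reports: list[EvaluationReport], template: Grid
) -> tuple[Grid, Grid]:
    """Per-pixel false-positive and false-negative ratio maps across species.

    For each pixel evaluated for at least one species: FP map value = number
    of species falsely predicted present there / total number of species (FN
    analogous). Pixels never evaluated are nan.
    """
    if not reports:
        raise ValueError("no evaluation reports")
    n_species = len(reports)
    fp = np.zeros(template.shape)
    fn = np.zeros(template.shape)
    seen = np.zeros(template.shape, dtype=bool)
    for rep in reports:
        for fold in rep.folds:
            if fold.failed or fold.test_scores is None:
                continue
            pred = (fold.test_scores >= fold.threshold).astype(int)
            for cell, p, obs in zip(fold.test_cells, pred, fold.test_labels):
                seen[cell] = True
                if p == 1 and obs == 0:
                    fp[cell] += 1
                elif p == 0 and obs == 1:
                    fn[cell] += 1
    if not seen.any():
        raise ValueError("no overlapping evaluated pixels")
    fp /= n_species
    fn /= n_species
    fp[~seen] = np.nan
    fn[~seen] = np.nan
    return template.like(fp), template.like(fn)


def species_frequency(n_presence: int, n_absence: int) -> float:
    """Frequency (%) of presence rasters, to one decimal."""
    total = n_presence + n_absence
    if total <= 0:
        raise ValueError("no rasters at all")
    return round(100.0 * n_presence / total, 1)
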