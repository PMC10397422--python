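"""Evaluation protocol: negative sampling, cross-validation, metrics.

Known interactions are positives; negatives are drawn uniformly from
drug-target pairs absent from the network (1:1 balanced by default, 1:10
for the imbalanced protocol). Performance is measured under stratified
10-fold cross-validation with AUC, AUPR and F1 at a 0.5 cutoff. Two
diagnostics quantify representation quality: MAD (mean average cosine
distance between node embeddings — lower means more over-smoothed) and the
mean per-vector interquartile range of pair features. A paired Wilcoxon
signed-rank test compares per-round metrics between models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .hbin import Hbin, build_hbin
from .predictor import GbdtConfig, GBDTPairClassifier, make_pair_features
from .smoothing import NdlsConfig, smooth_all

__all__ = [
    "SamplingPlan",
    "FoldPlan",
    "MetricReport",
    "sample_negatives",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "mad",
    "iqr_dispersion",
    "paired_wilcoxon",
]


@dataclass
class SamplingPlan:
    """Negative-sampling settings: negatives per positive, and the seed."""

    ratio: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("sampling ratio must be >= 1")


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int
    assignment: np.ndarray = field(repr=False)
    seed: int = 0


@dataclass
class MetricReport:
    auc: float
    aupr: float
    f1: float
    precision: float
    recall: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def sample_negatives(hbin: Hbin, plan: SamplingPlan) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of non-interacting pairs.

    Pairs are returned as global (drug_index, target_index) tuples, never
    overlapping the known edge set. If the requested count exceeds the
    number of non-edges the whole universe is returned with a warning.
    """
    n_d, n_t = hbin.catalog.n_drugs, hbin.catalog.n_targets
    flat_edges = {
        (i, j - n_d) for i, j in hbin.edges
    }  # local target indices for flattening
    universe_size = n_d * n_t - len(flat_edges)
    if universe_size == 0:
        warnings.warn("no non-interacting pairs exist; returning empty set")
        return []
    requested = plan.ratio * hbin.n_edges
    mask = np.ones(n_d * n_t, dtype=bool)
    for i, j in flat_edges:
        mask[i * n_t + j] = False
    candidates = np.flatnonzero(mask)
    rng = np.random.default_rng(plan.seed)
    if requested >= candidates.size:
        if requested > candidates.size:
            warnings.warn(
                f"requested {requested} negatives but only {candidates.size} "
                "non-edges exist; returning all of them"
            )
        chosen = candidates
    else:
        chosen = rng.choice(candidates, size=requested, replace=False)
    return [(int(c // n_t), int(n_d + c % n_t)) for c in sorted(chosen)]


def make_folds(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Partition labelled pairs into folds of (near-)equal size.

    Stratified by label by default, so each fold keeps the global
    positive:negative ratio.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n_folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    if n_folds > n:
        raise ValueError(f"{n_folds} folds requested for {n} pairs")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, cutoff: float = 0.5
) -> MetricReport:
    """AUC, AUPR and threshold metrics at the cutoff (strict '>').

    F1 is the harmonic mean of precision and recall, with the 0/0 -> 0
    convention. Single-class label vectors leave AUC/AUPR undefined (NaN).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if np.unique(labels).size < 2:
        auc = aupr = float("nan")
        warnings.warn("single-class labels: AUC/AUPR undefined")
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    calls = scores > cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    # 2PR/(P+R) computed as 2TP/(2TP+FP+FN): identical algebraically,
    # exact in floating point; 0/0 -> 0 convention.
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricReport(
        auc=auc, aupr=aupr, f1=f1, precision=precision, recall=recall,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _without_edges(hbin: Hbin, removed: set[tuple[int, int]]) -> Hbin:
    """Copy of the network with the given global-index edges removed."""
    catalog = hbin.catalog
    keep = [e for e in hbin.edges if e not in removed]
    interactions = [
        (catalog.node_id(i), catalog.node_id(j)) for i, j in keep
    ]
    return build_hbin(list(catalog.drug_ids), list(catalog.target_ids), interactions)


def cross_validate(
    hbin: Hbin,
    C: np.ndarray,
    sampling: SamplingPlan | None = None,
    n_folds: int = 10,
    gbdt: GbdtConfig | None = None,
    ndls: NdlsConfig | None = None,
    r: float = 0.5,
    mask_test_edges: bool = True,
    cutoff: float = 0.5,
    fold_seed: int = 0,
    shuffle_labels: bool = False,
) -> dict:
    """K-fold cross-validated DTI prediction on one network.

    Positives are the known edges; negatives are sampled per ``sampling``.
    With mask_test_edges=True (default) each fold's positive test edges are
    removed from the adjacency before smoothing, so the embeddings carry no
    trace of the held-out labels; False reproduces the simpler full-graph
    protocol. ``shuffle_labels`` permutes labels for a null control.

    Returns {"folds": [MetricReport...], "mean": {...}} dictionaries.
    """
    sampling = sampling or SamplingPlan()
    gbdt = gbdt or GbdtConfig()
    ndls = ndls or NdlsConfig()
    positives = sorted(hbin.edges)
    negatives = sample_negatives(hbin, sampling)
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    if shuffle_labels:
        rng = np.random.default_rng(sampling.seed + 1)
        labels = rng.permutation(labels)
    plan = make_folds(labels, n_folds=n_folds, seed=fold_seed)

    n_drugs = hbin.catalog.n_drugs
    fold_reports: list[MetricReport] = []
    cached_emb = None
    for fold in range(plan.n_folds):
        test_mask = plan.assignment == fold
        if mask_test_edges:
            held_out = {
                pairs[i]
                for i in np.flatnonzero(test_mask)
                if labels[i] == 1 and pairs[i] in hbin.edges
            }
            graph = _without_edges(hbin, held_out)
            emb, _ = smooth_all(graph, C, ndls, r=r)
        else:
            if cached_emb is None:
                cached_emb, _ = smooth_all(hbin, C, ndls, r=r)
            emb = cached_emb
        h = make_pair_features(emb.X, pairs, n_drugs)
        clf = GBDTPairClassifier(
            n_trees=gbdt.n_trees,
            learning_rate=gbdt.learning_rate,
            max_depth=gbdt.max_depth,
            seed=gbdt.seed,
        )
        clf.fit(h[~test_mask], labels[~test_mask])
        scores = clf.score_pairs(h[test_mask])
        fold_reports.append(compute_metrics(labels[test_mask], scores, cutoff))

    mean = {
        key: float(np.mean([getattr(rep, key) for rep in fold_reports]))
        for key in ("auc", "aupr", "f1", "precision", "recall")
    }
    return {"folds": fold_reports, "mean": mean}


def mad(X: np.ndarray) -> float:
    """Mean average cosine distance between node embedding rows, in [0, 1]
    for non-negative embeddings.

    Zero rows carry no direction and are excluded (with a warning). Lower
    values mean the representation has collapsed (over-smoothing); higher
    values mean more discriminative rows.
    """
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    usable = norms > 0
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} zero rows from MAD")
    X = X[usable]
    if X.shape[0] < 2:
        raise ValueError("MAD needs at least 2 nonzero rows")
    unit = X / np.linalg.norm(X, axis=1, keepdims=True)
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - cos
    n = dist.shape[0]
    np.fill_diagonal(dist, 0.0)
    per_node = dist.sum(axis=1) / (n - 1)
    return float(per_node.mean())


def iqr_dispersion(h: np.ndarray):
    """Interquartile range of a vector's elements (linear-interpolation
    quartiles); for a stack of vectors, (mean, std) of per-vector IQRs."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim == 1:
        if h.size < 4:
            raise ValueError("IQR needs at least 4 elements")
        q1, q3 = np.percentile(h, [25, 75])
        return float(q3 - q1)
    if h.shape[1] < 4:
        raise ValueError("IQR needs at least 4 elements per vector")
    q1 = np.percentile(h, 25, axis=1)
    q3 = np.percentile(h, 75, axis=1)
    iqrs = q3 - q1
    return float(iqrs.mean()), float(iqrs.std())


def paired_wilcoxon(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Significance convention: p < 0.05. All-zero difference vectors leave
    the statistic undefined; NaN is returned with a warning.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired rounds")
    if np.all(a == b):
        warnings.warn("all paired differences are zero: test undefined")
        return float("nan")
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
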