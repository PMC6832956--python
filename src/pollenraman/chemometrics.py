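"""Chemometric identification stack.

Growth-habit screening uses hierarchical cluster analysis (HCA) on per-taxon
mean spectra of the fingerprint region: Minkowski distance with exponent 5,
average linkage, dendrogram fidelity measured by the cophenetic correlation
coefficient, and a flat cut into four groups.  Taxonomy within each growth
habit uses PCA (nine components by default) followed by a one-vs-one
Gaussian-kernel SVM ensemble with error-correcting-output-code decoding,
ten-fold stratified cross-validation on the training scores, a held-out
confusion matrix with per-class sensitivity and positive predictive value,
and a Barnes-Hut t-SNE embedding of the training scores for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ClassificationError
from .preprocess import RegionConfig, crop_matrix
from .spectrum import SpectralDataset


# ---------------------------------------------------------------------------
# distances and hierarchical clustering


def minkowski_distance(x: np.ndarray, y: np.ndarray, p: float = 5.0) -> float:
    """(sum |x_i - y_i|^p)^(1/p); a metric for p >= 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("minkowski_distance requires equal-length inputs")
    if p < 1:
        raise ValueError("p must be >= 1 for a metric")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


@dataclass
class HCAConfig:
    """Clustering settings for growth-habit screening."""

    exponent: float = 5.0
    linkage: str = "average"
    n_clusters: int = 4

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("Minkowski exponent must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class Dendrogram:
    """Agglomeration result: linkage matrix, labels, cophenetic statistics."""

    linkage_matrix: np.ndarray      # scipy (n-1, 4) format
    labels: list[str]
    cophenetic_coefficient: float
    cophenetic_distances: np.ndarray  # condensed form
    original_distances: np.ndarray    # condensed form

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hca(mean_spectra: np.ndarray, labels: Sequence[str], config: HCAConfig | None = None) -> Dendrogram:
    """Average-linkage agglomeration over the Minkowski distance matrix.

    The cophenetic correlation coefficient is the Pearson correlation
    between original pairwise distances and the heights at which pairs first
    merge; it is 1 exactly when the input distances are ultrametric.
    """
    config = config or HCAConfig()
    X = np.atleast_2d(np.asarray(mean_spectra, dtype=float))
    if X.shape[0] < 2:
        raise ClassificationError("HCA needs at least 2 items")
    if len(labels) != X.shape[0]:
        raise ValueError("one label per spectrum is required")
    dists = pdist(X, metric="minkowski", p=config.exponent)
    Z = hierarchy.linkage(dists, method=config.linkage)
    if X.shape[0] == 2:
        # a single pair: the cophenetic distance equals the original exactly
        coph_coeff, coph_dists = 1.0, dists.copy()
    else:
        coph_coeff, coph_dists = hierarchy.cophenet(Z, dists)
    return Dendrogram(
        linkage_matrix=Z,
        labels=list(labels),
        cophenetic_coefficient=float(coph_coeff),
        cophenetic_distances=coph_dists,
        original_distances=dists,
    )


def cut_and_map(
    dendrogram: Dendrogram,
    n_clusters: int,
    true_groups: Sequence[str],
) -> tuple[list[str], "ConfusionMatrix"]:
    """Cut the tree into flat clusters and score them against known groups.

    Each flat cluster is mapped to the majority true group among its members
    (ties resolve to the lexicographically first group), giving a predicted
    group per item and a confusion matrix of true vs mapped groups.
    """
    n = len(dendrogram.labels)
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters must be between 1 and the item count")
    if len(true_groups) != n:
        raise ValueError("one true group per item is required")
    flat = hierarchy.fcluster(dendrogram.linkage_matrix, t=n_clusters, criterion="maxclust")
    true_arr = np.asarray(true_groups)
    mapping: dict[int, str] = {}
    for cluster_id in np.unique(flat):
        members = true_arr[flat == cluster_id]
        groups, counts = np.unique(members, return_counts=True)  # sorted lexicographically
        mapping[int(cluster_id)] = str(groups[np.argmax(counts)])  # first max wins ties
    predicted = [mapping[int(c)] for c in flat]
    return predicted, ConfusionMatrix.from_predictions(list(true_groups), predicted)


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass
class ConfusionMatrix:
    """Class-by-class counts; rows are actual classes, columns predictions."""

    labels: list[str]
    counts: np.ndarray

    @classmethod
    def from_predictions(
        cls, y_true: Sequence, y_pred: Sequence, labels: Sequence | None = None
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        labels = [str(l) for l in labels]
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[str(t)], index[str(p)]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def sensitivity(self) -> dict[str, float]:
        """Per-class recall: diagonal over row sum (nan for absent classes)."""
        rows = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(rows > 0, np.diag(self.counts) / rows, np.nan)
        return dict(zip(self.labels, (float(v) for v in vals)))

    @property
    def positive_predictive_value(self) -> dict[str, float]:
        """Per-class precision: diagonal over column sum (nan if never predicted)."""
        cols = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cols > 0, np.diag(self.counts) / cols, np.nan)
        return dict(zip(self.labels, (float(v) for v in vals)))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Mean spectrum plus ordered orthonormal loadings."""

    mean: np.ndarray
    loadings: np.ndarray            # (n_components, n_channels)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


def pca_fit(X: np.ndarray, n_components: int = 9) -> PCAModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        raise ClassificationError(
            f"n_components={n_components} exceeds min(n_samples-1, n_channels)={limit}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    return PCAModel(
        mean=model.mean_,
        loadings=model.components_,
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def pca_transform(X: np.ndarray, model: PCAModel) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.mean) @ model.loadings.T


# ---------------------------------------------------------------------------
# one-vs-one Gaussian-kernel SVM with ECOC decoding


@dataclass
class TrainConfig:
    """Training-set design: samples per class reserved for modelling, fold
    count for cross-validation, and the RNG seed."""

    n_train_scores: int = 100
    n_folds: int = 10
    seed: int = 0
    strict: bool = False  # error (rather than use-all-and-warn) on small classes

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_train_scores < self.n_folds:
            raise ValueError("n_train_scores must be >= n_folds")


@dataclass
class SVMModel:
    """k(k-1)/2 one-vs-one binary Gaussian-kernel learners over class pairs."""

    classes: list[str]
    learners: dict[tuple[int, int], SVC]
    train_indices: np.ndarray
    test_indices: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    sigma = float(np.median(d))
    return 1.0 / (2.0 * sigma**2)


def _fit_ovo(
    X: np.ndarray, y_idx: np.ndarray, n_classes: int, kernel_scale: float | None
) -> dict[tuple[int, int], SVC]:
    learners: dict[tuple[int, int], SVC] = {}
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            mask = (y_idx == i) | (y_idx == j)
            Xp, yp = X[mask], y_idx[mask]
            if kernel_scale is not None:
                gamma = 1.0 / (2.0 * kernel_scale**2)
            else:
                gamma = _median_heuristic_gamma(Xp)
            clf = SVC(C=1.0, kernel="rbf", gamma=gamma)
            clf.fit(Xp, yp)
            learners[(i, j)] = clf
    return learners


def _decode_ovo(
    learners: dict[tuple[int, int], SVC], X: np.ndarray, n_classes: int
) -> np.ndarray:
    """ECOC minimum-distance decoding of the one-vs-one vote pattern.

    For the one-vs-one code matrix, minimizing Hamming distance to a class
    codeword is equivalent to maximizing its pairwise votes; ties break to
    the lowest class index.
    """
    votes = np.zeros((X.shape[0], n_classes), dtype=int)
    for (i, j), clf in learners.items():
        pred = clf.predict(X)
        votes[np.arange(X.shape[0]), pred.astype(int)] += 1
    return np.argmax(votes, axis=1)


def train_svm(
    scores: np.ndarray,
    labels: Sequence[str],
    kernel_scale: float | None = None,
    config: TrainConfig | None = None,
) -> SVMModel:
    """Draw the training design and fit the one-vs-one SVM ensemble.

    Per class, ``config.n_train_scores`` samples are drawn without
    replacement (seeded); the remainder becomes the held-out test set.  A
    class smaller than the training quota either raises (strict mode) or
    contributes all its samples with a logged warning.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray([str(l) for l in labels])
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ClassificationError("need at least 2 classes to train")
    rng = np.random.default_rng(config.seed)
    train_idx: list[int] = []
    warnings: list[str] = []
    for lab in classes:
        members = np.flatnonzero(y == lab)
        if members.size < config.n_train_scores:
            if config.strict:
                raise ClassificationError(
                    f"class {lab!r} has {members.size} samples; "
                    f"{config.n_train_scores} required in strict mode"
                )
            warnings.append(
                f"class {lab!r}: only {members.size} samples, using all for training"
            )
            chosen = members
        else:
            chosen = rng.choice(members, size=config.n_train_scores, replace=False)
        train_idx.extend(int(i) for i in chosen)
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.setdiff1d(np.arange(y.size), train_idx)

    class_index = {lab: i for i, lab in enumerate(classes)}
    y_idx = np.asarray([class_index[l] for l in y])
    learners = _fit_ovo(X[train_idx], y_idx[train_idx], len(classes), kernel_scale)
    return SVMModel(
        classes=classes,
        learners=learners,
        train_indices=train_idx,
        test_indices=test_idx,
        warnings=warnings,
    )


def svm_predict(model: SVMModel, scores: np.ndarray) -> list[str]:
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    decoded = _decode_ovo(model.learners, X, len(model.classes))
    return [model.classes[i] for i in decoded]


def cross_validate(
    scores: np.ndarray,
    labels: Sequence[str],
    config: TrainConfig | None = None,
    kernel_scale: float | None = None,
) -> float:
    """Mean held-out misclassification over stratified k folds.

    Folds are label-stratified with sizes differing by at most one; each
    fold is held out once against an ensemble trained on the rest.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray([str(l) for l in labels])
    if X.shape[0] < config.n_folds:
        raise ClassificationError("fewer samples than folds")
    classes = sorted(np.unique(y).tolist())
    class_index = {lab: i for i, lab in enumerate(classes)}
    y_idx = np.asarray([class_index[l] for l in y])
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    rates = []
    for fit_rows, held_rows in skf.split(X, y_idx):
        learners = _fit_ovo(X[fit_rows], y_idx[fit_rows], len(classes), kernel_scale)
        pred = _decode_ovo(learners, X[held_rows], len(classes))
        rates.append(float(np.mean(pred != y_idx[held_rows])))
    return float(np.mean(rates))


def predict_and_score(
    model: SVMModel, test_scores: np.ndarray, test_labels: Sequence[str]
) -> ConfusionMatrix:
    """Held-out evaluation: confusion matrix with sensitivity / PPV."""
    y = [str(l) for l in test_labels]
    unseen = set(y) - set(model.classes)
    if unseen:
        raise ClassificationError(f"test labels never seen in training: {sorted(unseen)}")
    pred = svm_predict(model, test_scores)
    return ConfusionMatrix.from_predictions(y, pred, labels=model.classes)


# ---------------------------------------------------------------------------
# t-SNE visualization


@dataclass
class EmbeddingResult:
    """2-D Barnes-Hut t-SNE of training scores, with per-class medians."""

    coordinates: np.ndarray
    labels: list[str]
    class_medians: dict[str, np.ndarray]
    perplexity: float
    seed: int


def tsne_embed(
    scores: np.ndarray,
    labels: Sequence[str],
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """Barnes-Hut t-SNE (approximation angle 0.5) of the training scores.

    Visualization only — the embedding never feeds classification.  The
    per-class median (component-wise) summarizes each class's cloud.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] < 3:
        raise ClassificationError("t-SNE needs at least 3 points")
    if perplexity >= X.shape[0]:
        raise ClassificationError(
            f"perplexity {perplexity} must be below the point count {X.shape[0]}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="barnes_hut",
        angle=0.5,
        init="pca",
        random_state=seed,
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(X)
    labs = [str(l) for l in labels]
    medians = {
        lab: np.median(coords[np.asarray(labs) == lab], axis=0)
        for lab in sorted(set(labs))
    }
    return EmbeddingResult(
        coordinates=coords,
        labels=labs,
        class_medians=medians,
        perplexity=float(perplexity),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-habit taxonomy pipeline


@dataclass
class TaxonomyResult:
    habit: str
    genera: list[str]
    pca: PCAModel
    svm: SVMModel
    cv_misclassification: float
    confusion: ConfusionMatrix
    embedding: EmbeddingResult | None
    cumulative_variance: float


def run_taxonomy(
    dataset: SpectralDataset,
    habit: str,
    regions: RegionConfig | None = None,
    train_config: TrainConfig | None = None,
    n_components: int = 9,
    kernel_scale: float | None = None,
    perplexity: float = 30.0,
    embed: bool = True,
) -> TaxonomyResult:
    """Genus identification within one growth habit.

    Spectra are cropped to the concatenated fingerprint and high-wavenumber
    regions, reduced by PCA, split into a seeded training design and a
    held-out test set, cross-validated on the training scores, scored on the
    test set, and embedded with t-SNE for visualization.
    """
    regions = regions or RegionConfig()
    train_config = train_config or TrainConfig()
    dataset.require_columns("growth_habit", "genus")
    mask = (dataset.manifest["growth_habit"] == habit).to_numpy()
    if not mask.any():
        raise ClassificationError(f"growth habit {habit!r} not present in the dataset")
    subset = dataset.subset(mask)
    genera = sorted(subset.manifest["genus"].unique().tolist())
    if len(genera) < 2:
        raise ClassificationError(
            f"habit {habit!r} contains a single genus; classification is degenerate"
        )

    _, fp = crop_matrix(subset.axis, subset.intensities, regions.fingerprint)
    _, hw = crop_matrix(subset.axis, subset.intensities, regions.high_wavenumber)
    X = np.hstack([fp, hw])
    labels = subset.manifest["genus"].tolist()

    pca = pca_fit(X, n_components=n_components)
    scores = pca_transform(X, pca)
    svm = train_svm(scores, labels, kernel_scale=kernel_scale, config=train_config)

    train_scores = scores[svm.train_indices]
    train_labels = [labels[i] for i in svm.train_indices]
    cv_rate = cross_validate(train_scores, train_labels, config=train_config, kernel_scale=kernel_scale)
    confusion = predict_and_score(
        svm, scores[svm.test_indices], [labels[i] for i in svm.test_indices]
    )

    embedding = None
    if embed:
        feasible = min(perplexity, (len(svm.train_indices) - 1) / 3.0)
        embedding = tsne_embed(
            train_scores, train_labels, perplexity=max(feasible, 2.0), seed=train_config.seed
        )
    return TaxonomyResult(
        habit=habit,
        genera=genera,
        pca=pca,
        svm=svm,
        cv_misclassification=cv_rate,
        confusion=confusion,
        embedding=embedding,
        cumulative_variance=pca.cumulative_variance,
    )
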