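"""Supervised guilt-by-association network scorer.

The scorer follows the GenePlexus recipe: encode every gene of a weighted
PPI network as a feature row of a *representation matrix* — the normalized
adjacency matrix, the random-walk-with-restart (RWR) influence matrix, or a
spectral node embedding — then train an L2-regularized logistic regression
that separates a validated disease-gene set (positives) from the rest of the
genome (negatives, after excluding gene sets functionally similar to the
positives), and read off each gene's fitted probability of class membership
as its association score.

The influence matrix is the RWR kernel ``alpha * (I - (1 - alpha) * W)^-1``
of the column-stochastic transition ``W`` built from the normalized edge
confidences; column ``j`` is the stationary visiting distribution of walks
restarting at node ``j``, so its entries are non-negative and sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .network_io import AnnotationCorpus, PPINetwork, SeedSet, ValidationError

logger = logging.getLogger("netscreen")

__all__ = [
    "RepresentationMatrix",
    "TrainingSets",
    "GeneScoreTable",
    "ScorerConfig",
    "build_representation",
    "select_negatives",
    "train_and_score",
    "score_gene_set",
    "cross_validate",
]

Mode = Literal["adjacency", "influence", "embedding"]


@dataclass
class RepresentationMatrix:
    """Per-gene feature rows derived from the network.

    Rows follow the network node order. ``mode`` records which encoding was
    built; ``params`` keeps the knobs that shaped it (restart probability
    ``alpha`` for the influence kernel, dimension ``d`` for the embedding).
    """

    genes: list[str]
    features: np.ndarray
    mode: Mode
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.genes):
            raise ValidationError("feature row count does not match gene count")


@dataclass
class TrainingSets:
    """Disjoint partition of the network nodes into training classes.

    ``positives`` are the mapped seeds, ``excluded`` are genes left out of
    both classes because they belong to annotation terms similar to the
    seed set, and ``negatives`` is everything else.
    """

    positives: set[str]
    negatives: set[str]
    excluded: set[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives or self.positives & self.excluded or self.negatives & self.excluded:
            raise ValidationError("training classes are not pairwise disjoint")


@dataclass
class GeneScoreTable:
    """Gene -> association probability in [0, 1], plus training metadata."""

    probabilities: dict[str, float]
    mode: Mode = "influence"
    regularization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability for {g!r} is {p}, outside [0, 1]")

    def __getitem__(self, gene: str) -> float:
        return self.probabilities[gene]

    def array(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.probabilities[g] for g in genes])


@dataclass
class ScorerConfig:
    """Settings that fully determine one scoring run (given the network)."""

    mode: Mode = "influence"
    alpha: float = 0.85
    d: int = 32
    lam: float = 1.0
    jaccard_max: float = 0.1
    seed: int = 0


# ---------------------------------------------------------------------------
# representation matrices
# ---------------------------------------------------------------------------

def _weighted_adjacency(network: PPINetwork) -> np.ndarray:
    """Dense normalized adjacency: entry (i, j) = score(i, j)/1000, zero diagonal."""
    n = network.n_nodes
    a = np.zeros((n, n))
    idx = network.node_index
    for (u, v), s in network.edges.items():
        w = s / 1000.0
        i, j = idx[u], idx[v]
        a[i, j] = w
        a[j, i] = w
    return a


def _column_stochastic(a: np.ndarray) -> np.ndarray:
    """Column-normalize; a column with no mass becomes a self-transition."""
    w = a.copy()
    colsum = w.sum(axis=0)
    isolated = colsum == 0
    w[:, ~isolated] /= colsum[~isolated]
    if isolated.any():
        for j in np.flatnonzero(isolated):
            w[j, j] = 1.0
    return w


def influence_matrix(a: np.ndarray, alpha: float) -> np.ndarray:
    """RWR kernel alpha * (I - (1 - alpha) W)^-1 with W column-stochastic.

    Columns are probability distributions (non-negative, sum to one): column
    j is where a walker restarting at j spends its time.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"restart probability alpha must be in (0, 1), got {alpha}")
    n = a.shape[0]
    w = _column_stochastic(a)
    return alpha * np.linalg.inv(np.eye(n) - (1.0 - alpha) * w)


def spectral_embedding(a: np.ndarray, d: int) -> np.ndarray:
    """Deterministic d-dimensional spectral coordinates of the weighted adjacency.

    Uses the d eigenpairs of largest eigenvalue magnitude, each eigenvector
    scaled by sqrt(|eigenvalue|); the sign of each vector is fixed so that its
    first nonzero entry is positive, making the result reproducible.
    """
    n = a.shape[0]
    if d >= n:
        raise ValidationError(f"embedding dimension d={d} must be < node count {n}")
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(-np.abs(vals))[:d]
    emb = np.empty((n, d))
    for col, k in enumerate(order):
        v = vecs[:, k]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        emb[:, col] = v * np.sqrt(abs(vals[k]))
    return emb


def build_representation(
    network: PPINetwork,
    mode: Mode = "influence",
    alpha: float = 0.85,
    d: int = 32,
    seed: int = 0,
) -> RepresentationMatrix:
    """Build the per-gene feature matrix for one of the three encodings.

    ``adjacency`` is the normalized weighted adjacency itself; ``influence``
    is the RWR kernel at restart probability ``alpha``; ``embedding`` is a
    deterministic ``d``-dimensional spectral embedding. ``seed`` is recorded
    for provenance — all three constructions are deterministic.
    """
    if mode in ("influence", "embedding") and (network.n_nodes < 2 or network.n_edges < 1):
        raise ValidationError(f"{mode} mode needs >= 2 nodes and >= 1 edge")
    a = _weighted_adjacency(network)
    if mode == "adjacency":
        features = a
        params = {}
    elif mode == "influence":
        features = influence_matrix(a, alpha)
        params = {"alpha": alpha}
    elif mode == "embedding":
        features = spectral_embedding(a, d)
        params = {"d": d, "seed": seed}
    else:
        raise ValidationError(f"unknown representation mode {mode!r}")
    return RepresentationMatrix(genes=list(network.nodes), features=features, mode=mode, params=params)


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def select_negatives(
    network: PPINetwork,
    positives: SeedSet,
    corpus: AnnotationCorpus | None = None,
    jaccard_max: float = 0.1,
) -> TrainingSets:
    """Partition network nodes into positives / negatives / excluded.

    Genes belonging to any annotation term whose Jaccard similarity with the
    positive set exceeds ``jaccard_max`` are excluded from the negative
    class (they are plausibly disease-related, so using them as negatives
    would poison the classifier). Everything else outside the positives is a
    negative.
    """
    pos = set(positives.mapped) if isinstance(positives, SeedSet) else set(positives)
    missing = pos - set(network.node_index)
    if missing:
        raise ValidationError(f"positives not in network: {sorted(missing)[:5]}")
    similar: set[str] = set()
    if corpus is not None:
        for term, members in corpus.terms.items():
            if _jaccard(members, pos) > jaccard_max:
                similar |= members
    excluded = (similar - pos) & set(network.node_index)
    negatives = set(network.node_index) - pos - excluded
    if not negatives:
        raise ValidationError("no negative genes remain after exclusion")
    return TrainingSets(positives=pos, negatives=negatives, excluded=excluded)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    """Column-standardize over genes; constant columns are dropped."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        # every feature constant: no signal, keep a single zero column
        return np.zeros((x.shape[0], 1))
    return (x[:, keep] - mu[keep]) / sd[keep]


def train_and_score(
    rep: RepresentationMatrix,
    sets: TrainingSets,
    lam: float = 1.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> GeneScoreTable:
    """Fit seeds-vs-negatives L2 logistic regression; score every gene.

    The intercept is unpenalized and classes receive inverse-frequency
    sample weights, so a handful of seeds is not swamped by thousands of
    negatives. The fitted probability is returned for *every* network gene,
    including the positives and the excluded genes.
    """
    if lam <= 0:
        raise ValidationError(f"regularization strength lam must be > 0, got {lam}")
    if not sets.positives or not sets.negatives:
        raise ValidationError("both training classes must be non-empty")
    feats = rep.features
    if rep.mode == "influence":
        # drop the self-visit mass: the kernel diagonal is a near-one-hot
        # identity feature per gene, which lets the classifier memorize the
        # training partition instead of learning network proximity
        feats = feats.copy()
        np.fill_diagonal(feats, 0.0)
    x = _standardize(feats)
    index = {g: i for i, g in enumerate(rep.genes)}
    train_idx = np.array([index[g] for g in sets.positives] + [index[g] for g in sets.negatives])
    y = np.array([1] * len(sets.positives) + [0] * len(sets.negatives))
    clf = LogisticRegression(
        C=1.0 / lam,
        class_weight="balanced",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    clf.fit(x[train_idx], y)
    if clf.n_iter_[0] >= max_iter:
        raise ValidationError(f"logistic solver failed to converge (lam={lam}, max_iter={max_iter})")
    probs = clf.predict_proba(x)[:, 1]
    return GeneScoreTable(
        probabilities={g: float(p) for g, p in zip(rep.genes, probs)},
        mode=rep.mode,
        regularization=lam,
        seed=seed,
    )


def score_gene_set(
    rep: RepresentationMatrix,
    network: PPINetwork,
    seed_genes: set[str] | SeedSet,
    corpus: AnnotationCorpus | None,
    cfg: ScorerConfig,
) -> GeneScoreTable:
    """Full scoring pass for one positive set: negatives -> fit -> probabilities."""
    pos = seed_genes.mapped if isinstance(seed_genes, SeedSet) else set(seed_genes)
    seeds = SeedSet(label="_set", mapped=set(pos))
    sets = select_negatives(network, seeds, corpus, jaccard_max=cfg.jaccard_max)
    return train_and_score(rep, sets, lam=cfg.lam, seed=cfg.seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    rep: RepresentationMatrix,
    sets: TrainingSets,
    lam: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """k-fold CV over the positives; negatives are shared across folds.

    Each fold's held-out positives are ranked against all negatives using the
    model trained on the remaining positives; ranking quality is the
    area under the ROC curve. Returns per-fold and mean AUROC.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    positives = sorted(sets.positives)
    if len(positives) < k:
        raise ValidationError(f"need at least k={k} positives, have {len(positives)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, k)
    index = {g: i for i, g in enumerate(rep.genes)}
    neg_idx = np.array([index[g] for g in sorted(sets.negatives)])
    aurocs = []
    for fold in folds:
        held = {positives[i] for i in fold}
        train_pos = set(positives) - held
        fold_sets = TrainingSets(positives=train_pos, negatives=sets.negatives, excluded=sets.excluded | held)
        table = train_and_score(rep, fold_sets, lam=lam, seed=seed)
        held_idx = np.array([index[g] for g in sorted(held)])
        scores = np.array([table.probabilities[rep.genes[i]] for i in np.concatenate([held_idx, neg_idx])])
        labels = np.concatenate([np.ones(len(held_idx)), np.zeros(len(neg_idx))])
        aurocs.append(float(roc_auc_score(labels, scores)))
    return {"fold_auroc": aurocs, "mean_auroc": float(np.mean(aurocs)), "k": k}
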