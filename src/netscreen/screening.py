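"""The three screening tests that distill classifier scores into a gene list.

A guilt-by-association scorer run on a PPI network assigns every gene a
probability of belonging to the disease set, but some genes score highly for
purely topological reasons (hubs, central positions) regardless of which
seeds are chosen. Three successive screens remove such artefacts:

1. **Permutation test** — re-run the scorer on R random seed sets of the
   same size; a gene's empirical p-value is the fraction of random runs in
   which its probability meets or exceeds the observed one. Genes with
   p < 0.05 survive.
2. **Interaction test** — the maximum interaction score MIS(g) is the
   largest normalized STRING confidence Q(g, g') = score/1000 between g and
   any validated gene g'. Genes with MIS >= 0.9 (highest-confidence
   interactions) survive.
3. **Enrichment test** — each gene g gets a vector V_g of enrichment
   scores ES(g, F) = -log10 P(X >= m), the upper hypergeometric tail for the
   overlap m between g's network neighbours (n of them) and the M genes
   annotated by term F in a universe of N genes. The maximum enrichment
   score MES(g) is the largest cosine similarity between V_g and any
   validated gene's vector; genes with MES >= 0.95 survive.

The survivors of all three screens form the final inferred-gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .netscore import (
    GeneScoreTable,
    RepresentationMatrix,
    ScorerConfig,
    score_gene_set,
)
from .network_io import (
    AnnotationCorpus,
    PPINetwork,
    SeedSet,
    ValidationError,
)

logger = logging.getLogger("netscreen")

__all__ = [
    "AnnotationCorpus",
    "ESVector",
    "PermutationResult",
    "ScreenScores",
    "run_permutation_test",
    "compute_mis",
    "compute_es_vector",
    "cosine_similarity",
    "compute_mes",
    "apply_cascade",
]

# a permutation run scores the network once per random set; refuse jobs whose
# R * n_nodes product would grind for hours
DEFAULT_SCORING_BUDGET = 20_000_000

STAGE_NONE = "none"
STAGE_PERMUTATION = "permutation"
STAGE_INTERACTION = "interaction"
STAGE_ENRICHMENT = "enrichment"


@dataclass
class ESVector:
    """Per-gene enrichment-score vector V_g over the annotation terms.

    Entries are ES(g, F) >= 0; a term whose hypergeometric tail equals one
    contributes exactly zero, and a gene with no network neighbours has the
    all-zero vector.
    """

    gene: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        for term, v in self.scores.items():
            if v < 0:
                raise ValidationError(f"ES({self.gene!r}, {term!r}) = {v} is negative")

    def as_array(self, term_order: Sequence[str]) -> np.ndarray:
        return np.array([self.scores.get(t, 0.0) for t in term_order])


@dataclass
class PermutationResult:
    """Empirical permutation p-values for every non-seed gene.

    For gene g, ``null_counts[g]`` is the number of the R random-seed runs
    whose probability for g met or exceeded the observed probability, and
    p = null_count / R exactly.
    """

    observed: dict[str, float]
    null_counts: dict[str, int]
    n_random_sets: int
    add_one_smoothing: bool = False

    def p_value(self, gene: str) -> float:
        n, r = self.null_counts[gene], self.n_random_sets
        if self.add_one_smoothing:
            return (n + 1) / (r + 1)
        return n / r

    @property
    def p_values(self) -> dict[str, float]:
        return {g: self.p_value(g) for g in self.null_counts}


@dataclass
class ScreenScores:
    """Per-candidate outcome of the three-stage cascade.

    ``stage_removed`` is ``"none"`` exactly when the gene survived all three
    screens; MIS/MES are NaN for genes removed before the corresponding
    screen was reached.
    """

    p_value: dict[str, float]
    mis: dict[str, float]
    mes: dict[str, float]
    stage_removed: dict[str, str]
    thresholds: dict[str, float] = field(default_factory=dict)

    def survivors(self, stage: str = STAGE_NONE) -> set[str]:
        """Genes alive after the given stage (default: the final list)."""
        order = [STAGE_PERMUTATION, STAGE_INTERACTION, STAGE_ENRICHMENT, STAGE_NONE]
        if stage == STAGE_NONE:
            return {g for g, s in self.stage_removed.items() if s == STAGE_NONE}
        cut = order.index(stage)
        return {
            g
            for g, s in self.stage_removed.items()
            if s == STAGE_NONE or order.index(s) > cut
        }

    @property
    def final(self) -> set[str]:
        return self.survivors(STAGE_NONE)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def run_permutation_test(
    network: PPINetwork,
    rep: RepresentationMatrix,
    seeds: SeedSet,
    corpus: AnnotationCorpus | None,
    cfg: ScorerConfig,
    n_random_sets: int = 1000,
    rng_seed: int = 0,
    exclude_seeds_from_null: bool = False,
    max_budget: int = DEFAULT_SCORING_BUDGET,
    observed: GeneScoreTable | None = None,
) -> PermutationResult:
    """Empirical p-values from R random seed sets of matched size.

    Each random set contains ``|seeds.mapped|`` distinct nodes sampled
    uniformly from the network (by default seeds are eligible to be drawn —
    set ``exclude_seeds_from_null`` to remove them from the pool). The
    scorer is re-run with the identical configuration once per set, and for
    every non-seed gene the p-value is the fraction of random runs whose
    probability for that gene is >= its observed probability.
    """
    if n_random_sets < 1:
        raise ValidationError(f"need at least 1 random set, got {n_random_sets}")
    k = len(seeds.mapped)
    if k >= network.n_nodes:
        raise ValidationError("seed set must be smaller than the network")
    if n_random_sets * network.n_nodes > max_budget:
        raise ValidationError(
            f"permutation budget {n_random_sets} sets x {network.n_nodes} nodes exceeds "
            f"{max_budget}; reduce the number of random sets"
        )
    if observed is None:
        observed = score_gene_set(rep, network, seeds, corpus, cfg)
    pool = [g for g in network.nodes if not (exclude_seeds_from_null and g in seeds.mapped)]
    rng = np.random.default_rng(rng_seed)

    candidates = [g for g in network.nodes if g not in seeds.mapped]
    obs = np.array([observed.probabilities[g] for g in candidates])
    counts = np.zeros(len(candidates), dtype=int)
    for _ in range(n_random_sets):
        random_set = set(rng.choice(len(pool), size=k, replace=False))
        random_genes = {pool[i] for i in random_set}
        null_table = score_gene_set(rep, network, random_genes, corpus, cfg)
        null = np.array([null_table.probabilities[g] for g in candidates])
        counts += null >= obs
    logger.info("permutation test: %d random sets, %d candidate genes", n_random_sets, len(candidates))
    return PermutationResult(
        observed={g: float(p) for g, p in zip(candidates, obs)},
        null_counts={g: int(c) for g, c in zip(candidates, counts)},
        n_random_sets=n_random_sets,
    )


# ---------------------------------------------------------------------------
# interaction test
# ---------------------------------------------------------------------------

def compute_mis(gene: str, seeds: SeedSet, network: PPINetwork) -> float:
    """Maximum normalized confidence between ``gene`` and any validated gene.

    MIS(g) = max over seeds g' of score(g, g')/1000; 0.0 when no edge links
    the gene to any seed.
    """
    if gene not in network:
        raise ValidationError(f"gene {gene!r} not in network")
    nbrs = network.neighbors(gene)
    best = 0
    for g in seeds.mapped:
        s = nbrs.get(g, 0)
        if s > best:
            best = s
    return best / 1000.0


# ---------------------------------------------------------------------------
# enrichment test
# ---------------------------------------------------------------------------

def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper tail P(X >= m) for X ~ Hypergeometric(N, M, n)."""
    if m > min(M, n):
        raise ValidationError(f"m={m} exceeds min(M={M}, n={n}): inconsistent inputs")
    if m <= 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def compute_es_vector(
    gene: str,
    network: PPINetwork,
    corpus: AnnotationCorpus,
    min_score: int = 1,
) -> ESVector:
    """Enrichment-score vector of a gene's network neighbourhood.

    For each term F with M annotated genes in a universe of N: n is the
    number of network neighbours of ``gene`` (edges with score >=
    ``min_score``; the gene itself is never counted), m the number of those
    neighbours annotated by F, and ES = -log10 of the upper hypergeometric
    tail P(X >= m). A gene with no neighbours gets the all-zero vector.
    """
    if gene not in network:
        raise ValidationError(f"gene {gene!r} not in network")
    N = corpus.universe_size
    nbrs = set(network.neighbors(gene, min_score=min_score))
    nbrs.discard(gene)
    n = len(nbrs)
    scores: dict[str, float] = {}
    for term, members in corpus.terms.items():
        M = len(members)
        if max(M, n) > N:
            raise ValidationError(f"universe_size N={N} smaller than M={M} or n={n} for term {term!r}")
        if n == 0:
            scores[term] = 0.0
            continue
        m = len(nbrs & members)
        tail = hypergeom_tail(N, M, n, m)
        # clamp: tails can round to 0 at double precision for extreme overlaps
        scores[term] = -np.log10(max(tail, 1e-300))
    return ESVector(gene=gene, scores=scores)


def cosine_similarity(v: ESVector, w: ESVector) -> float:
    """Cosine of the angle between two ES vectors; 0.0 if either is all-zero.

    Vectors are aligned on the union of their term universes (missing terms
    count as zero). For non-negative ES entries the result lies in [0, 1].
    """
    terms = sorted(set(v.scores) | set(w.scores))
    a = v.as_array(terms)
    b = w.as_array(terms)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def compute_mes(gene_vector: ESVector, seed_vectors: Sequence[ESVector]) -> float:
    """Maximum cosine similarity between a gene's ES vector and any seed's."""
    if not seed_vectors:
        raise ValidationError("seed_vectors must be non-empty")
    return max(cosine_similarity(gene_vector, sv) for sv in seed_vectors)


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def apply_cascade(
    candidates: Iterable[str],
    perm: PermutationResult,
    network: PPINetwork,
    seeds: SeedSet,
    corpus: AnnotationCorpus,
    p_cut: float = 0.05,
    mis_cut: float = 0.9,
    mes_cut: float = 0.95,
    neighbor_min_score: int = 1,
) -> ScreenScores:
    """Run the three screens in order and record where each candidate fell.

    Stage 1 keeps p < ``p_cut`` (strict, matching "p-values under this
    threshold"); stage 2 keeps MIS >= ``mis_cut``; stage 3 keeps
    MES >= ``mes_cut``. MIS is computed for every stage-1 survivor and MES
    for every stage-2 survivor; genes never reaching a screen carry NaN for
    its score. Survivor sets are nested by construction.
    """
    for name, cut in (("p_cut", p_cut), ("mis_cut", mis_cut), ("mes_cut", mes_cut)):
        if not 0.0 <= cut <= 1.0:
            raise ValidationError(f"{name}={cut} outside [0, 1]")
    candidates = list(dict.fromkeys(candidates))
    overlap = set(candidates) & seeds.mapped
    if overlap:
        raise ValidationError(f"candidates overlap the seed set: {sorted(overlap)[:5]}")

    p_value: dict[str, float] = {}
    mis: dict[str, float] = {}
    mes: dict[str, float] = {}
    stage_removed: dict[str, str] = {}

    # stage 1: permutation
    stage1: list[str] = []
    for g in candidates:
        p = perm.p_value(g)
        p_value[g] = p
        mis[g] = float("nan")
        mes[g] = float("nan")
        if p < p_cut:
            stage1.append(g)
        else:
            stage_removed[g] = STAGE_PERMUTATION

    # stage 2: interaction
    stage2: list[str] = []
    for g in stage1:
        mis[g] = compute_mis(g, seeds, network)
        if mis[g] >= mis_cut:
            stage2.append(g)
        else:
            stage_removed[g] = STAGE_INTERACTION

    # stage 3: enrichment (seed ES vectors shared across candidates)
    seed_vectors = [
        compute_es_vector(g, network, corpus, min_score=neighbor_min_score)
        for g in sorted(seeds.mapped)
    ]
    for g in stage2:
        vg = compute_es_vector(g, network, corpus, min_score=neighbor_min_score)
        mes[g] = compute_mes(vg, seed_vectors)
        if mes[g] >= mes_cut:
            stage_removed[g] = STAGE_NONE
        else:
            stage_removed[g] = STAGE_ENRICHMENT

    logger.info(
        "cascade: %d candidates -> %d (p<%g) -> %d (MIS>=%g) -> %d (MES>=%g)",
        len(candidates), len(stage1), p_cut, len(stage2), mis_cut,
        sum(1 for s in stage_removed.values() if s == STAGE_NONE), mes_cut,
    )
    return ScreenScores(
        p_value=p_value,
        mis=mis,
        mes=mes,
        stage_removed=stage_removed,
        thresholds={"p_cut": p_cut, "mis_cut": mis_cut, "mes_cut": mes_cut},
    )
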