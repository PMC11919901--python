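"""Synthetic benchmark generator with a planted disease module.

Real inputs to the screen — a STRING protein-links file, curated
disease-gene lists, GO/KEGG annotation — all require downloads. This module
generates stand-ins carrying the statistical structure the analysis relies
on, so the whole pipeline can run and be validated offline:

* an Erdős–Rényi background graph whose edges carry mid-range confidence
  scores, with a planted module whose members are connected more densely and
  at near-maximal confidence (the "true" disease genes);
* an annotation corpus in which a configurable fraction of terms are
  enriched for the planted module, mimicking disease-relevant GO terms;
* a random split of the planted module into revealed seeds (the validated
  genes handed to the scorer) and held-out genes (the discoveries a good
  screen should recover).

By default the module and background score distributions are disjoint
(850-999 vs 150-700), so interaction-screen behaviour is fully controllable
in tests. Everything is deterministic under the master seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network_io import (
    AnnotationCorpus,
    PPINetwork,
    ValidationError,
    write_gmt,
    write_string_edges,
)

logger = logging.getLogger("netscreen")

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_network",
    "generate_background_network",
    "generate_annotations",
    "split_seeds",
    "generate_benchmark",
    "write_fixture",
]


@dataclass
class SyntheticConfig:
    """Knobs of the planted-module benchmark.

    Defaults produce a 200-node network with a 30-gene module wired at edge
    probability 0.5 against a 0.02 background — dense and high-confidence
    enough for guilt-by-association to have signal, sparse enough to run in
    seconds.
    """

    n_nodes: int = 200
    q_bg: float = 0.02
    m_mod: int = 30
    q_mod: float = 0.5
    bg_score_range: tuple[int, int] = (150, 700)
    mod_score_range: tuple[int, int] = (850, 999)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    enriched_fraction: float = 0.3
    enriched_module_weight: float = 0.7  # fraction of an enriched term drawn from the module
    seed_fraction: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.m_mod > self.n_nodes:
            raise ValidationError("module size m_mod exceeds n_nodes")
        if not (0.0 < self.q_bg <= 1.0 and 0.0 < self.q_mod <= 1.0):
            raise ValidationError("edge probabilities must be in (0, 1]")
        if self.q_mod <= self.q_bg:
            raise ValidationError("planted module must be denser than background (q_mod > q_bg)")
        for lo, hi in (self.bg_score_range, self.mod_score_range):
            if not (1 <= lo <= hi <= 999):
                raise ValidationError("score ranges must lie within [1, 999]")
        if self.term_size_range[1] > self.n_nodes:
            raise ValidationError("term size exceeds n_nodes")


@dataclass
class SyntheticTruth:
    """Ground truth of one benchmark instance."""

    planted: set[str]
    seeds: set[str] = field(default_factory=set)
    heldout: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.seeds | self.heldout:
            if (self.seeds | self.heldout) != self.planted or (self.seeds & self.heldout):
                raise ValidationError("seeds and heldout must partition the planted set")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(cfg: SyntheticConfig, _attempt: int = 0) -> tuple[PPINetwork, set[str]]:
    """Erdős–Rényi background with a planted high-confidence module.

    Returns the network and the planted gene set. If more than 20% of the
    planted genes come out isolated (an unusable instance for propagation),
    the instance is regenerated from a shifted stream with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 1, _attempt]))
    names = [_node_name(i) for i in range(cfg.n_nodes)]
    planted_idx = rng.choice(cfg.n_nodes, size=cfg.m_mod, replace=False)
    planted = {names[i] for i in planted_idx}
    in_mod = np.zeros(cfg.n_nodes, dtype=bool)
    in_mod[planted_idx] = True

    edges: dict[tuple[str, str], int] = {}
    iu, ju = np.triu_indices(cfg.n_nodes, k=1)
    both_mod = in_mod[iu] & in_mod[ju]
    p = np.where(both_mod, cfg.q_mod, cfg.q_bg)
    keep = rng.random(iu.size) < p
    bg_lo, bg_hi = cfg.bg_score_range
    mod_lo, mod_hi = cfg.mod_score_range
    scores = np.where(
        both_mod,
        rng.integers(mod_lo, mod_hi + 1, size=iu.size),
        rng.integers(bg_lo, bg_hi + 1, size=iu.size),
    )
    for i, j, s in zip(iu[keep], ju[keep], scores[keep]):
        a, b = names[i], names[j]
        edges[(a, b) if a <= b else (b, a)] = int(s)

    nodes = sorted({g for pair in edges for g in pair})
    net = PPINetwork(nodes=nodes, edges=edges)
    isolated = [g for g in planted if g not in net]
    if len(isolated) > 0.2 * cfg.m_mod:
        warnings.warn(
            f"{len(isolated)}/{cfg.m_mod} planted genes isolated; regenerating", stacklevel=2
        )
        return generate_network(cfg, _attempt=_attempt + 1)
    # keep isolated planted genes out of the truth set: they carry no signal
    planted &= set(net.node_index)
    logger.info("synthetic network: %d nodes, %d edges, %d planted", net.n_nodes, net.n_edges, len(planted))
    return net, planted


def generate_background_network(
    n_nodes: int = 300,
    q: float = 0.04,
    score_range: tuple[int, int] = (150, 700),
    seed: int = 0,
) -> PPINetwork:
    """Homogeneous Erdős–Rényi network with no planted structure.

    The null instrument for calibration checks: every gene is statistically
    exchangeable, so empirical p-values from random seed sets should be
    uniform. A planted module would instead move coherently with each random
    draw and is deliberately absent here.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    names = [_node_name(i) for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(iu.size) < q
    lo, hi = score_range
    scores = rng.integers(lo, hi + 1, size=iu.size)
    edges = {}
    for i, j, s in zip(iu[keep], ju[keep], scores[keep]):
        edges[(names[i], names[j])] = int(s)
    nodes = sorted({g for pair in edges for g in pair})
    return PPINetwork(nodes=nodes, edges=edges)


def generate_annotations(cfg: SyntheticConfig, network: PPINetwork, planted: set[str]) -> AnnotationCorpus:
    """Annotation corpus with module-enriched and uniform background terms.

    A fraction ``enriched_fraction`` of the terms draw the majority
    (``enriched_module_weight``) of their members from the planted module;
    the rest sample members uniformly. ``universe_size`` is the network node
    count, matching how the enrichment screen is run against a network.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 2]))
    nodes = list(network.nodes)
    planted_list = sorted(planted)
    background = [g for g in nodes if g not in planted]
    n_enriched = int(round(cfg.enriched_fraction * cfg.n_terms))
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    lo, hi = cfg.term_size_range
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(nodes))
        if t < n_enriched:
            n_from_mod = min(int(round(cfg.enriched_module_weight * size)), len(planted_list))
            mod_part = rng.choice(len(planted_list), size=n_from_mod, replace=False)
            n_bg = min(size - n_from_mod, len(background))
            bg_part = rng.choice(len(background), size=n_bg, replace=False)
            members = {planted_list[i] for i in mod_part} | {background[i] for i in bg_part}
            name, desc = f"TERM_ENR_{t:03d}", "module-enriched synthetic term"
        else:
            pick = rng.choice(len(nodes), size=size, replace=False)
            members = {nodes[i] for i in pick}
            name, desc = f"TERM_BG_{t:03d}", "background synthetic term"
        terms[name] = members
        descriptions[name] = desc
    return AnnotationCorpus(terms=terms, universe_size=network.n_nodes, descriptions=descriptions)


def split_seeds(planted: set[str], fraction: float, seed: int) -> SyntheticTruth:
    """Uniformly split the planted module into revealed seeds and held-out genes.

    ``|seeds| = round(fraction * |planted|)`` clamped to [1, |planted| - 1],
    so both sides are always non-empty.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    if len(planted) < 2:
        raise ValidationError("need at least 2 planted genes to split")
    rng = np.random.default_rng(seed)
    ordered = sorted(planted)
    k = int(round(fraction * len(ordered)))
    k = max(1, min(k, len(ordered) - 1))
    idx = rng.choice(len(ordered), size=k, replace=False)
    seeds = {ordered[i] for i in idx}
    return SyntheticTruth(planted=set(planted), seeds=seeds, heldout=set(planted) - seeds)


def generate_benchmark(cfg: SyntheticConfig) -> tuple[PPINetwork, AnnotationCorpus, SyntheticTruth]:
    """One deterministic benchmark instance: network + annotations + seed split."""
    net, planted = generate_network(cfg)
    corpus = generate_annotations(cfg, net, planted)
    split_stream = int(np.random.SeedSequence([cfg.master_seed, 3]).generate_state(1)[0] % (2**31))
    truth = split_seeds(planted, cfg.seed_fraction, seed=split_stream)
    return net, corpus, truth


def write_fixture(cfg: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Emit a benchmark instance in the same file formats the pipeline reads.

    Writes ``network.txt`` (3-column edge list), ``seeds_synthetic.txt``
    (one ID per line), ``annotations.gmt`` and ``truth_heldout.txt``;
    returns the paths. Doubles as living documentation of the input formats.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, corpus, truth = generate_benchmark(cfg)
    paths = {
        "network": out / "network.txt",
        "seeds": out / "seeds_synthetic.txt",
        "annotations": out / "annotations.gmt",
        "heldout": out / "truth_heldout.txt",
    }
    write_string_edges(net, paths["network"])
    paths["seeds"].write_text("\n".join(sorted(truth.seeds)) + "\n")
    write_gmt(corpus, paths["annotations"])
    paths["heldout"].write_text("\n".join(sorted(truth.heldout)) + "\n")
    return paths
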