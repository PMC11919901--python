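"""End-to-end orchestration: seeds -> scorer -> three screens -> report.

Each disease label is screened independently against the shared network:
parse inputs, map its seed list, score every gene, run the permutation test,
apply the interaction and enrichment screens, and write per-stage tables
plus a run manifest that suffices to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .netscore import ScorerConfig, build_representation, score_gene_set
from .network_io import (
    AnnotationCorpus,
    PPINetwork,
    SeedSet,
    ValidationError,
    map_seed_genes,
    parse_string_edges,
    read_gmt,
    read_seed_list,
    write_score_table,
)
from .screening import (
    PermutationResult,
    ScreenScores,
    apply_cascade,
    run_permutation_test,
)

logger = logging.getLogger("netscreen")

__all__ = ["PipelineConfig", "LabelReport", "ScreenReport", "run_screen", "screen_label", "connection_report", "load_config"]


@dataclass
class PipelineConfig:
    """Flat configuration of one screening run (YAML key: value on disk)."""

    network_path: str
    seed_paths: dict[str, str]  # disease label -> seed-list path
    corpus_path: str
    out_dir: str = "netscreen_out"
    mode: str = "influence"
    alpha: float = 0.85
    d: int = 32
    lam: float = 1.0
    jaccard_max: float = 0.1
    min_score: int = 1
    n_random_sets: int = 1000
    p_cut: float = 0.05
    mis_cut: float = 0.9
    mes_cut: float = 0.95
    conf_cut: float = 0.9
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cut", "mis_cut", "mes_cut", "conf_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_random_sets < 1:
            raise ValidationError("n_random_sets must be >= 1")

    def scorer_config(self, seed: int) -> ScorerConfig:
        return ScorerConfig(
            mode=self.mode, alpha=self.alpha, d=self.d,
            lam=self.lam, jaccard_max=self.jaccard_max, seed=seed,
        )


def load_config(path) -> PipelineConfig:
    """Read a flat YAML mapping into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed_paths" not in raw or not isinstance(raw["seed_paths"], dict):
        raise ValidationError("config must provide seed_paths: {label: path} mapping")
    return PipelineConfig(**raw)


@dataclass
class LabelReport:
    """Screen outcome for one disease label."""

    label: str
    seeds: SeedSet
    stage_counts: dict[str, int]
    permutation: PermutationResult
    scores: ScreenScores
    final_genes: list[str]
    connection_counts: dict[str, int]


@dataclass
class ScreenReport:
    """Full-run report: one LabelReport per disease label, plus provenance."""

    labels: dict[str, LabelReport]
    config: PipelineConfig
    out_dir: Path = field(default=Path("."))


def _derive_seed(master_seed: int, *tags: int) -> int:
    """Named substream of the master seed, kept below 2**31."""
    return int(np.random.SeedSequence([master_seed, *tags]).generate_state(1)[0] % (2**31))


def _label_tag(label: str) -> int:
    """Stable integer tag for a disease label (process-independent)."""
    return zlib.crc32(label.encode("utf-8")) % (2**16)


def screen_label(
    label: str,
    seed_ids: list[str],
    network: PPINetwork,
    corpus: AnnotationCorpus,
    cfg: PipelineConfig,
) -> LabelReport:
    """Screen one disease label: map -> score -> permutation -> cascade."""
    seeds = map_seed_genes(seed_ids, network, label)
    scorer_cfg = cfg.scorer_config(seed=_derive_seed(cfg.master_seed, _label_tag(label), 1))
    rep = build_representation(network, mode=cfg.mode, alpha=cfg.alpha, d=cfg.d, seed=scorer_cfg.seed)
    observed = score_gene_set(rep, network, seeds, corpus, scorer_cfg)
    perm = run_permutation_test(
        network, rep, seeds, corpus, scorer_cfg,
        n_random_sets=cfg.n_random_sets,
        rng_seed=_derive_seed(cfg.master_seed, _label_tag(label), 2),
        observed=observed,
    )
    candidates = [g for g in network.nodes if g not in seeds.mapped]
    scores = apply_cascade(
        candidates, perm, network, seeds, corpus,
        p_cut=cfg.p_cut, mis_cut=cfg.mis_cut, mes_cut=cfg.mes_cut,
    )
    final = sorted(scores.final)
    stage_counts = {
        "candidates": len(candidates),
        "permutation": len(scores.survivors("permutation")),
        "interaction": len(scores.survivors("interaction")),
        "final": len(final),
    }
    conn = connection_report(set(final), seeds, network, conf_cut=cfg.conf_cut)
    logger.info("[%s] stage survivors: %s", label, stage_counts)
    return LabelReport(
        label=label, seeds=seeds, stage_counts=stage_counts, permutation=perm,
        scores=scores, final_genes=final, connection_counts=conn,
    )


def run_screen(cfg: PipelineConfig) -> ScreenReport:
    """Execute the full pipeline for every disease label in the config.

    Writes, per label, the permutation table, the full screen table, the
    final gene list and the connection report, plus a run manifest echoing
    the configuration, the master seed and the package version.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network = parse_string_edges(cfg.network_path, min_score=cfg.min_score)
    corpus = read_gmt(cfg.corpus_path, universe_size=network.n_nodes)
    labels: dict[str, LabelReport] = {}
    for label in sorted(cfg.seed_paths):
        try:
            seed_ids = read_seed_list(cfg.seed_paths[label])
            report = screen_label(label, seed_ids, network, corpus, cfg)
        except Exception as exc:
            raise ValidationError(f"screen failed for label {label!r}: {exc}") from exc
        labels[label] = report
        _write_label_outputs(report, out)
    _write_manifest(cfg, out)
    return ScreenReport(labels=labels, config=cfg, out_dir=out)


def _write_label_outputs(report: LabelReport, out: Path) -> None:
    tag = report.label.replace(" ", "_")
    s = report.scores
    perm = report.permutation
    perm_rows = [
        (g, {
            "observed": perm.observed[g],
            "null_count": float(perm.null_counts[g]),
            "p_value": perm.p_value(g),
        })
        for g in sorted(perm.observed)
    ]
    write_score_table(perm_rows, out / f"{tag}.permutation.tsv")
    screen_rows = [
        (g, {"p_value": s.p_value[g], "mis": s.mis[g], "mes": s.mes[g], "stage_removed": s.stage_removed[g]})
        for g in sorted(s.p_value)
    ]
    write_score_table(screen_rows, out / f"{tag}.screen.tsv")
    conn_rows = [(g, {"seed_connections": float(c)}) for g, c in sorted(report.connection_counts.items())]
    write_score_table(conn_rows, out / f"{tag}.connections.tsv")
    (out / f"{tag}.final_genes.txt").write_text("\n".join(report.final_genes) + ("\n" if report.final_genes else ""))
    (out / f"{tag}.seed_mapping.txt").write_text(
        f"label\t{report.label}\nmapped\t{len(report.seeds.mapped)}\nunmapped\t{len(report.seeds.unmapped)}\n"
    )


def _write_manifest(cfg: PipelineConfig, out: Path) -> None:
    manifest = {
        "netscreen_version": __version__,
        "master_seed": cfg.master_seed,
        "config": {k: (dict(v) if isinstance(v, dict) else v) for k, v in vars(cfg).items()},
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


# ---------------------------------------------------------------------------
# connection report
# ---------------------------------------------------------------------------

def connection_report(
    inferred: set[str],
    seeds: SeedSet,
    network: PPINetwork,
    conf_cut: float = 0.9,
) -> dict[str, int]:
    """Count each inferred gene's seed neighbours at confidence >= ``conf_cut``.

    Counting uses the same normalized score Q = score/1000 as the
    interaction screen; the return maps gene -> number of validated genes it
    touches at or above the cut.
    """
    if not 0.0 <= conf_cut <= 1.0:
        raise ValidationError(f"conf_cut={conf_cut} outside [0, 1]")
    overlap = inferred & seeds.mapped
    if overlap:
        raise ValidationError(f"inferred genes overlap seeds: {sorted(overlap)[:5]}")
    counts: dict[str, int] = {}
    for g in inferred:
        nbrs = network.neighbors(g)
        counts[g] = sum(1 for s0 in seeds.mapped if nbrs.get(s0, 0) / 1000.0 >= conf_cut)
    return counts
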