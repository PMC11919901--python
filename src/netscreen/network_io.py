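"""Readers, writers and core containers for STRING-style PPI data.

The on-disk formats handled here are the ones a protein-interaction screen
actually consumes in practice:

* a protein-links edge list — three whitespace-separated columns
  ``protein_a protein_b combined_score`` with the combined confidence score an
  integer in 1-999, optionally gzip-compressed and optionally headed;
* seed-gene lists, one identifier per line;
* GMT gene-set files (term, description, members...) standing in for GO/KEGG
  annotation;
* tab-separated score tables for results.

Identifiers are opaque strings compared exactly (STRING ships Ensembl protein
IDs verbatim); no translation layer is attempted.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

logger = logging.getLogger("netscreen")

__all__ = [
    "NetscreenError",
    "ParseError",
    "ValidationError",
    "NoUsableSeedsError",
    "PPINetwork",
    "SeedSet",
    "AnnotationCorpus",
    "parse_string_edges",
    "write_string_edges",
    "map_seed_genes",
    "read_seed_list",
    "read_gmt",
    "write_gmt",
    "write_score_table",
    "read_score_table",
]

SCORE_MAX = 999  # STRING combined scores live in 1..999


class NetscreenError(Exception):
    """Base class for errors raised by this package."""


class ParseError(NetscreenError):
    """A malformed input file; the message names the offending line."""


class ValidationError(NetscreenError):
    """Input violated a documented invariant (score range, thresholds...)."""


class NoUsableSeedsError(NetscreenError):
    """None of the supplied seed identifiers map to the network."""


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered node pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PPINetwork:
    """An undirected, weighted protein-protein interaction network.

    Nodes are protein identifier strings; each edge carries the raw integer
    combined score (1-999). Edges are stored once under a canonical unordered
    pair, so queries in either orientation see the same score. The normalized
    confidence Q(g, g') = score / 1000 used by the interaction screen is
    exposed via :meth:`q`.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], int]
    node_index: dict[str, int] = field(default_factory=dict)
    _adjacency: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {g: i for i, g in enumerate(self.nodes)}
        if not self._adjacency:
            adj: dict[str, dict[str, int]] = {g: {} for g in self.nodes}
            for (a, b), s in self.edges.items():
                adj[a][b] = s
                adj[b][a] = s
            self._adjacency = adj
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for (a, b), s in self.edges.items():
            if not 1 <= s <= SCORE_MAX:
                raise ValidationError(f"edge ({a},{b}) score {s} outside 1..{SCORE_MAX}")
            if a == b:
                raise ValidationError(f"self-loop on node {a}")
            if a not in self.node_index or b not in self.node_index:
                raise ValidationError(f"edge ({a},{b}) references a node not in the node list")

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.node_index

    def score(self, a: str, b: str) -> int:
        """Raw combined score of edge (a, b) in either orientation; 0 if absent."""
        return self.edges.get(_pair(a, b), 0)

    def q(self, a: str, b: str) -> float:
        """Normalized confidence score/1000 in (0, 1]; 0.0 when no edge."""
        return self.score(a, b) / 1000.0

    def neighbors(self, gene: str, min_score: int = 1) -> dict[str, int]:
        """Mapping neighbour -> raw score, restricted to score >= min_score."""
        nbrs = self._adjacency.get(gene)
        if nbrs is None:
            raise ValidationError(f"gene {gene!r} not in network")
        if min_score <= 1:
            return dict(nbrs)
        return {g: s for g, s in nbrs.items() if s >= min_score}

    def degree(self, gene: str) -> int:
        return len(self._adjacency.get(gene, ()))


@dataclass
class SeedSet:
    """Disease-labelled validated genes mapped onto a network.

    ``mapped`` holds the identifiers found among the network nodes;
    ``unmapped`` preserves, in input order, the identifiers that were not,
    since mapping losses are expected and worth reporting.
    """

    label: str
    mapped: set[str]
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mapped & set(self.unmapped):
            raise ValidationError("mapped and unmapped seed sets overlap")


@dataclass
class AnnotationCorpus:
    """Term -> gene-set mapping used by the enrichment screen.

    ``universe_size`` is N, the total number of genes considered when
    computing hypergeometric tails; it defaults to the size of the union of
    all terms at load time and is normally overridden with the network node
    count by the pipeline.
    """

    terms: dict[str, set[str]]
    universe_size: int
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for term, members in self.terms.items():
            if not members:
                raise ValidationError(f"annotation term {term!r} has no members")
            union |= members
        if self.universe_size < len(union):
            raise ValidationError(
                f"universe_size {self.universe_size} smaller than annotated-gene union {len(union)}"
            )

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)


# ---------------------------------------------------------------------------
# edge-list parsing
# ---------------------------------------------------------------------------

def _open_text(source) -> TextIO:
    """Open a path (gzip-transparent) or pass through a text stream."""
    if hasattr(source, "read"):
        return source
    path = Path(source)
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def parse_string_edges(source, min_score: int = 1) -> PPINetwork:
    """Parse a STRING-style protein-links edge list into a :class:`PPINetwork`.

    Parameters
    ----------
    source:
        Path to a text (optionally gzipped) file, or an open text stream, of
        lines ``protein_a protein_b score``. A single header line whose third
        field is not an integer is skipped.
    min_score:
        Keep only edges with raw combined score >= ``min_score`` (default 1,
        i.e. every score above zero, matching the usual construction).

    Duplicate and reversed pairs collapse to one undirected edge keeping the
    maximum score; self-loop rows are dropped with a warning. Nodes are
    induced by the retained edges, so isolated identifiers never occur.
    """
    if min_score < 1:
        raise ValidationError(f"min_score must be >= 1, got {min_score}")
    edges: dict[tuple[str, str], int] = {}
    n_self = 0
    fh = _open_text(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected 3 whitespace-separated columns, got {len(fields)}")
            a, b, raw_score = fields[0], fields[1], fields[2]
            try:
                s = int(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"line {lineno}: score {raw_score!r} is not an integer") from None
            if s < 0 or s > SCORE_MAX:
                raise ValidationError(f"line {lineno}: score {s} outside 0..{SCORE_MAX}")
            if a == b:
                n_self += 1
                continue
            if s < min_score:
                continue
            key = _pair(a, b)
            prev = edges.get(key)
            if prev is None or s > prev:
                edges[key] = s
    finally:
        if fh is not source:
            fh.close()
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop row(s)", stacklevel=2)
    nodes = sorted({g for pair in edges for g in pair})
    net = PPINetwork(nodes=nodes, edges=edges)
    logger.info("parsed network: %d nodes, %d edges (min_score=%d)", net.n_nodes, net.n_edges, min_score)
    return net


def write_string_edges(network: PPINetwork, destination) -> None:
    """Write a network back to the 3-column protein-links format (round-trips)."""
    own = not hasattr(destination, "write")
    fh = Path(destination).open("w") if own else destination
    try:
        fh.write("protein1 protein2 combined_score\n")
        for (a, b) in sorted(network.edges):
            fh.write(f"{a} {b} {network.edges[(a, b)]}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# seed lists
# ---------------------------------------------------------------------------

def read_seed_list(source) -> list[str]:
    """Read a one-identifier-per-line seed list (blank lines and # comments skipped)."""
    fh = _open_text(source)
    try:
        return [ln.strip() for ln in fh if ln.strip() and not ln.strip().startswith("#")]
    finally:
        if fh is not source:
            fh.close()


def map_seed_genes(ids: Sequence[str], network: PPINetwork, label: str) -> SeedSet:
    """Map validated-gene identifiers onto the network nodes.

    Duplicates are removed; identifiers absent from the network are kept in
    ``unmapped`` in input order. Raises :class:`NoUsableSeedsError` when no
    identifier maps, since downstream scoring needs at least one positive.
    """
    if not ids:
        raise ValidationError("empty seed identifier list")
    seen: set[str] = set()
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in ids:
        if g in seen:
            continue
        seen.add(g)
        if g in network:
            mapped.add(g)
        else:
            unmapped.append(g)
    if not mapped:
        raise NoUsableSeedsError(f"no usable seeds for {label!r}: none of {len(seen)} identifiers map to the network")
    logger.info("seed mapping [%s]: %d mapped, %d unmapped", label, len(mapped), len(unmapped))
    return SeedSet(label=label, mapped=mapped, unmapped=unmapped)


# ---------------------------------------------------------------------------
# GMT annotation files
# ---------------------------------------------------------------------------

def read_gmt(source, universe_size: int | None = None) -> AnnotationCorpus:
    """Read a GMT file (tab-separated: term, description, members...).

    ``universe_size`` defaults to the size of the union of all member sets;
    callers screening against a network normally pass the node count instead.
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    fh = _open_text(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: GMT rows need term, description and >=1 member")
            term, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if not members:
                raise ParseError(f"line {lineno}: term {term!r} has no members")
            terms[term] = set(members)
            descriptions[term] = desc
    finally:
        if fh is not source:
            fh.close()
    if universe_size is None:
        universe_size = len(set().union(*terms.values())) if terms else 0
    return AnnotationCorpus(terms=terms, universe_size=universe_size, descriptions=descriptions)


def write_gmt(corpus: AnnotationCorpus, destination) -> None:
    own = not hasattr(destination, "write")
    fh = Path(destination).open("w") if own else destination
    try:
        for term, members in corpus.terms.items():
            desc = corpus.descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

def write_score_table(rows: Iterable[tuple[str, Mapping[str, float]]], destination) -> None:
    """Write (gene, named numeric fields) rows as a headered TSV.

    All rows must share the same field names; floats are rendered with
    twelve significant digits so the table round-trips through
    :func:`read_score_table` to within 1e-9.
    """
    rows = list(rows)
    own = not hasattr(destination, "write")
    fh = Path(destination).open("w") if own else destination
    try:
        names: list[str] | None = None
        for gene, fields in rows:
            if names is None:
                names = list(fields)
                fh.write("\t".join(["gene", *names]) + "\n")
            elif list(fields) != names:
                raise ValidationError(f"row for {gene!r} has field names {list(fields)}, expected {names}")
            rendered = []
            for name in names:
                v = fields[name]
                if isinstance(v, float) and not (isinstance(v, bool)):
                    rendered.append("nan" if math.isnan(v) else f"{v:.12g}")
                else:
                    rendered.append(str(v))
            fh.write("\t".join([gene, *rendered]) + "\n")
        if names is None:
            fh.write("gene\n")
    finally:
        if own:
            fh.close()


def read_score_table(source) -> pd.DataFrame:
    """Read a TSV written by :func:`write_score_table`, indexed by gene."""
    df = pd.read_csv(source, sep="\t", dtype={"gene": str})
    return df.set_index("gene")
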