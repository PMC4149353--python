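"""Readers and writers for the pipeline's external representations.

Everything the pipeline touches on disk is plain text: GMT gene-set
collections (Broad dialect), directed edge lists with effect/mechanism
annotations, node-role tables, expression matrices and flat gene lists —
all TSV with a fixed column order and ``.`` as the decimal separator so
outputs are diffable. Readers validate vocabulary and report offending
line numbers; every reader/writer pair round-trips (a file written by the
canonical writer reads back to an identical object and re-writes
byte-identically).

Gene identifiers are opaque, case-sensitive strings with no whitespace;
no symbol-to-Entrez mapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted edge-effect vocabulary.
EFFECTS = ("activation", "inhibition", "unspecified")
#: Accepted edge-mechanism vocabulary.
MECHANISMS = ("transcription-regulation", "binding", "other")
#: Accepted node roles (pathway-topology context).
ROLES = ("ligand", "receptor", "transducer", "transcription-factor", "other")


def _check_gene(symbol: str) -> str:
    if not symbol or any(c.isspace() for c in symbol):
        raise ValueError(f"invalid gene identifier {symbol!r}: "
                         "must be a non-empty token without whitespace")
    return symbol


@dataclass(frozen=True)
class EdgeRecord:
    """A directed molecular interaction annotated with its biological
    effect (activation / inhibition / unspecified) and mechanism."""

    source: str
    target: str
    effect: str = "unspecified"
    mechanism: str = "other"

    def __post_init__(self) -> None:
        _check_gene(self.source)
        _check_gene(self.target)
        if self.effect not in EFFECTS:
            raise ValueError(
                f"unknown effect {self.effect!r}; accepted: {', '.join(EFFECTS)}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; "
                f"accepted: {', '.join(MECHANISMS)}")

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    @property
    def key(self) -> tuple[str, str, str]:
        # uniqueness is on (source, target, mechanism)
        return (self.source, self.target, self.mechanism)


@dataclass(frozen=True)
class NodeRoleRecord:
    """Pathway role of a gene plus whether it is detectable in whole blood."""

    gene: str
    role: str = "other"
    blood_expressed: bool = False

    def __post_init__(self) -> None:
        _check_gene(self.gene)
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r}; accepted: {', '.join(ROLES)}")


class GeneSet(NamedTuple):
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets plus the universe they live in.

    The default universe is the union of all member genes (the total gene
    content of the ontology); an explicit universe may be supplied to
    override it, e.g. with the measured genes of a platform.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    explicit_universe: frozenset[str] | None = None

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate set name {name!r}")
        mem = frozenset(_check_gene(m) for m in members)
        if not mem:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, description, mem)

    @property
    def universe(self) -> frozenset[str]:
        if self.explicit_universe is not None:
            return self.explicit_universe
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return frozenset(out)

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return (self.sets == other.sets
                and self.universe == other.universe)


@dataclass
class ExpressionMatrix:
    """A normalized genes x samples table with a sample -> group design.

    Values are assumed to be on the log2 scale throughout the pipeline.
    Any number of groups is accepted at load time; the two-group contract
    is enforced by the testing stage.
    """

    values: pd.DataFrame  # genes as rows, samples as columns
    design: dict[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        for g in self.values.index:
            _check_gene(str(g))

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def groups(self) -> list[str]:
        """Group labels in sorted order."""
        return sorted({self.design[s] for s in self.samples})

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.samples if self.design[s] == label]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path,
             universe_path: str | Path | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members...

    The universe defaults to the union of all members; ``universe_path``
    (one gene per line) overrides it.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}")
            name, desc, *members = fields
            if name in coll.sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            coll.add(name, desc, members)
    if universe_path is not None:
        coll.explicit_universe = frozenset(read_gene_list(universe_path))
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Canonical GMT writer: insertion order of sets, members sorted."""
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["source", "target", "effect", "mechanism"]


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    """Read a directed edge list TSV (source, target, effect, mechanism).

    Duplicate (source, target, mechanism) rows are collapsed, keeping the
    first occurrence, with a logged warning. Unknown effect or mechanism
    tokens are rejected with the accepted vocabulary in the message.
    """
    records: dict[tuple[str, str, str], EdgeRecord] = {}
    n_dup = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise ValueError(
                f"{path}: expected header {_EDGE_HEADER}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, "
                                 f"got {len(fields)}")
            try:
                rec = EdgeRecord(*fields)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rec.key in records:
                n_dup += 1
                if records[rec.key].effect != rec.effect:
                    logger.warning("%s:%d: duplicate edge %s with conflicting "
                                   "effect; keeping first", path, lineno, rec.key)
                continue
            if rec.is_self_loop:
                logger.warning("%s:%d: self-loop on %s", path, lineno, rec.source)
            records[rec.key] = rec
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return list(records.values())


def write_edge_list(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.effect}\t{e.mechanism}\n")


# ---------------------------------------------------------------------------
# Node roles
# ---------------------------------------------------------------------------

_ROLE_HEADER = ["gene", "role", "blood_expressed"]


def read_roles(path: str | Path) -> dict[str, NodeRoleRecord]:
    roles: dict[str, NodeRoleRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ROLE_HEADER:
            raise ValueError(f"{path}: expected header {_ROLE_HEADER}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            gene, role, blood = line.split("\t")
            if blood not in ("true", "false"):
                raise ValueError(f"{path}:{lineno}: blood_expressed must be "
                                 "'true' or 'false'")
            if gene in roles:
                raise ValueError(f"{path}:{lineno}: duplicate role for {gene!r}")
            roles[gene] = NodeRoleRecord(gene, role, blood == "true")
    return roles


def write_roles(roles: Mapping[str, NodeRoleRecord] | Iterable[NodeRoleRecord],
                path: str | Path) -> None:
    if isinstance(roles, Mapping):
        roles = roles.values()
    with open(path, "w") as fh:
        fh.write("\t".join(_ROLE_HEADER) + "\n")
        for r in roles:
            fh.write(f"{r.gene}\t{r.role}\t{'true' if r.blood_expressed else 'false'}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path,
                    design: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene ids).

    Every sample column must appear in ``design``; non-numeric cells are
    reported with their (gene, sample) coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"{path}: samples missing from design: {missing}")
    try:
        values = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                cell = df.loc[gene, sample]
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at "
                        f"gene {gene!r}, sample {sample!r}") from None
        raise
    return ExpressionMatrix(values, {s: design[s] for s in df.columns})


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Full-precision canonical writer (values survive a round trip exactly)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for gene, row in matrix.values.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row)
                     + "\n")


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


def read_design(path: str | Path) -> dict[str, str]:
    design: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample", "group"]:
            raise ValueError(f"{path}: expected header ['sample', 'group']")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            sample, group = line.split("\t")
            design[sample] = group
    return design


# ---------------------------------------------------------------------------
# Pathway topologies
# ---------------------------------------------------------------------------

_TOPO_HEADER = ["pathway", "source", "target", "effect", "mechanism"]


def read_pathway_topologies(path: str | Path,
                            roles: Mapping[str, NodeRoleRecord] | None = None
                            ) -> "dict[str, object]":
    """Read per-pathway directed topologies from a 5-column TSV
    (pathway, source, target, effect, mechanism); node ``role``
    attributes are filled from ``roles`` (default ``other``)."""
    import networkx as nx

    roles = roles or {}
    topologies: dict[str, nx.DiGraph] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TOPO_HEADER:
            raise ValueError(f"{path}: expected header {_TOPO_HEADER}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            try:
                pathway, source, target, effect, mechanism = line.split("\t")
                rec = EdgeRecord(source, target, effect, mechanism)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            g = topologies.setdefault(pathway, nx.DiGraph())
            g.add_edge(rec.source, rec.target, effect=rec.effect,
                       mechanism=rec.mechanism)
    for g in topologies.values():
        for v in g.nodes:
            g.nodes[v]["role"] = roles[v].role if v in roles else "other"
    return topologies


def write_pathway_topologies(topologies: "Mapping[str, object]",
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TOPO_HEADER) + "\n")
        for name in topologies:
            g = topologies[name]
            for u, v, d in g.edges(data=True):
                fh.write(f"{name}\t{u}\t{v}\t{d.get('effect', 'unspecified')}\t"
                         f"{d.get('mechanism', 'other')}\n")


# ---------------------------------------------------------------------------
# Flat gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line (or the first column of a TSV); order preserved,
    duplicates collapsed keeping first occurrence."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            token = raw.rstrip("\n").split("\t")[0].strip()
            if not token:
                continue
            _check_gene(token)
            if token not in seen:
                seen.add(token)
                out.append(token)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
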