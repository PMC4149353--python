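"""Ten-criterion key-gene scoring and blood-biomarker panel building.

Each gene receives one point per satisfied evidence criterion: it is
(1) differentially expressed, (2) an expression regulator, (3)/(4)
annotated with an enriched GO biological-process / molecular-function
term, (5)-(7) present on an enriched pathway map / process network /
toxicity network, (8) present on a key pathway, (9) present on the
reconstructed causal network, (10) expressed in whole blood. Totals
range 0-10; high scorers expressed in blood are biomarker candidates.
An evidence source that is unavailable in a given configuration scores
0 for its flag (logged once), so totals are comparable only within one
configuration.

The panel builder takes the top ``k_up`` up-regulated and ``k_down``
down-regulated blood-expressed candidates (defaults 25 + 25) ranked by
(total score desc, |log2fc| desc, gene id asc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

FLAG_NAMES = (
    "is_deg",
    "is_regulator",
    "in_enriched_go_process",
    "in_enriched_go_function",
    "on_enriched_pathway",
    "on_enriched_process_network",
    "on_enriched_toxicity_network",
    "on_key_pathway",
    "on_causal_network",
    "blood_expressed",
)


@dataclass(frozen=True)
class EvidenceFlags:
    """The ten binary evidence criteria of the key-gene score."""

    is_deg: bool = False
    is_regulator: bool = False
    in_enriched_go_process: bool = False
    in_enriched_go_function: bool = False
    on_enriched_pathway: bool = False
    on_enriched_process_network: bool = False
    on_enriched_toxicity_network: bool = False
    on_key_pathway: bool = False
    on_causal_network: bool = False
    blood_expressed: bool = False

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(bool(getattr(self, f.name)) for f in fields(self))


def score_gene(flags: EvidenceFlags) -> int:
    """Total key-gene score: the number of satisfied criteria (0..10)."""
    return sum(flags.as_tuple())


@dataclass(frozen=True)
class KeyGeneScore:
    gene: str
    flags: EvidenceFlags
    total: int
    direction: str = "none"  # up | down | none
    log2fc: float = 0.0


@dataclass
class EvidenceSources:
    """Upstream pipeline artifacts reduced to gene sets, one per criterion.

    ``None`` marks an evidence source that is unavailable in this
    configuration; its flag is False for every gene.
    """

    deg_genes: frozenset[str] | None = None
    regulator_genes: frozenset[str] | None = None
    enriched_go_process_genes: frozenset[str] | None = None
    enriched_go_function_genes: frozenset[str] | None = None
    enriched_pathway_genes: frozenset[str] | None = None
    enriched_process_network_genes: frozenset[str] | None = None
    enriched_toxicity_network_genes: frozenset[str] | None = None
    key_pathway_genes: frozenset[str] | None = None
    causal_network_genes: frozenset[str] | None = None
    blood_genes: frozenset[str] | None = None

    _SOURCE_BY_FLAG = {
        "is_deg": "deg_genes",
        "is_regulator": "regulator_genes",
        "in_enriched_go_process": "enriched_go_process_genes",
        "in_enriched_go_function": "enriched_go_function_genes",
        "on_enriched_pathway": "enriched_pathway_genes",
        "on_enriched_process_network": "enriched_process_network_genes",
        "on_enriched_toxicity_network": "enriched_toxicity_network_genes",
        "on_key_pathway": "key_pathway_genes",
        "on_causal_network": "causal_network_genes",
        "blood_expressed": "blood_genes",
    }

    def log_unavailable(self) -> None:
        missing = [f for f, s in self._SOURCE_BY_FLAG.items()
                   if getattr(self, s) is None]
        if missing:
            logger.info("evidence source(s) unavailable (flags score 0): %s",
                        ", ".join(missing))


def collect_evidence(gene: str, sources: EvidenceSources) -> EvidenceFlags:
    """Derive the ten flags for one gene purely from upstream artifacts."""
    values = {}
    for flag, source in EvidenceSources._SOURCE_BY_FLAG.items():
        pool = getattr(sources, source)
        values[flag] = (gene in pool) if pool is not None else False
    return EvidenceFlags(**values)


def score_genes(genes: Iterable[str],
                sources: EvidenceSources,
                directions: dict[str, str] | None = None,
                log2fcs: dict[str, float] | None = None) -> list[KeyGeneScore]:
    """Score a list of genes, attaching direction and log2 fold change
    when known (needed for panel building)."""
    sources.log_unavailable()
    directions = directions or {}
    log2fcs = log2fcs or {}
    out = []
    for gene in genes:
        flags = collect_evidence(gene, sources)
        out.append(KeyGeneScore(gene, flags, score_gene(flags),
                                directions.get(gene, "none"),
                                float(log2fcs.get(gene, 0.0))))
    return out


@dataclass(frozen=True)
class Panel:
    up: tuple[str, ...]
    down: tuple[str, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def build_panel(scores: Sequence[KeyGeneScore],
                k_up: int = 25, k_down: int = 25) -> Panel:
    """Select the biomarker panel from scored candidates.

    Only blood-expressed genes with a known direction are eligible. When
    fewer candidates exist than requested, the panel is short (warning).
    Output is invariant to input ordering.
    """
    def top(direction: str, k: int) -> tuple[str, ...]:
        cand = [s for s in scores
                if s.flags.blood_expressed and s.direction == direction]
        cand.sort(key=lambda s: (-s.total, -abs(s.log2fc), s.gene))
        if len(cand) < k:
            logger.warning("only %d eligible %s-regulated candidate(s) for a "
                           "panel slot of %d", len(cand), direction, k)
        return tuple(s.gene for s in cand[:k])

    return Panel(top("up", k_up), top("down", k_down))
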