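"""End-to-end focused analysis: DEGs → regulators → enrichment ×3 →
key pathways → causal network → key-gene scores → biomarker panel."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import biomarkers, causal, diffexp, enrichment, regulators
from .biomarkers import EvidenceSources, KeyGeneScore, Panel
from .causal import CausalNetwork, KeyPathway, PathwayMap
from .diffexp import DEGList, GeneScoreRecord
from .enrichment import EnrichmentResult
from .io import ExpressionMatrix, GeneSetCollection
from .regulators import InteractionNetwork, RegulatorResult


@dataclass
class FocusedAnalysisResult:
    records: list[GeneScoreRecord]
    degs: DEGList
    regulator_results: list[RegulatorResult]
    regulator_genes: list[str]
    enrich_deg: list[EnrichmentResult]
    enrich_reg: list[EnrichmentResult]
    enrich_combo: list[EnrichmentResult]
    key_pathways: list[KeyPathway]
    causal_network: CausalNetwork
    scores: list[KeyGeneScore] = field(default_factory=list)
    panel: Panel = Panel((), ())


def run_focused_analysis(expression: ExpressionMatrix,
                         network: InteractionNetwork,
                         collection: GeneSetCollection,
                         pathway_maps: Sequence[PathwayMap],
                         blood_genes: Iterable[str] | None = None,
                         *,
                         fc_cut: float = diffexp.DEFAULT_FC_CUT,
                         p_cut: float | None = None,
                         alpha: float = 0.05,
                         regulator_direction: str = "out",
                         universe: Iterable[str] | None = None,
                         min_stretch: int = causal.DEFAULT_MIN_STRETCH,
                         max_gap: int = causal.DEFAULT_MAX_GAP,
                         k_up: int = 25,
                         k_down: int = 25) -> FocusedAnalysisResult:
    """Run the whole focused analysis on in-memory artifacts.

    ``alpha`` gates regulator calls (BH FDR), enrichment calls (raw p)
    and the key-pathway synergy comparison. ``universe`` overrides the
    collection's default enrichment universe.
    """
    records = diffexp.moderated_t(expression)
    degs = diffexp.call_degs(records, fc_cut, p_cut)
    deg_set = degs.genes

    reg_results = regulators.direct_regulators(network, deg_set,
                                               regulator_direction)
    reg_genes = regulators.significant_regulators(reg_results, alpha)
    reg_set = frozenset(reg_genes)

    e_deg = enrichment.enrich(deg_set, collection, universe)
    e_reg = enrichment.enrich(reg_set, collection, universe)
    e_combo = enrichment.enrich(deg_set | reg_set, collection, universe)

    keys = causal.identify_key_pathways(e_deg, e_reg, e_combo, alpha)
    net = causal.reconstruct_causal_network(keys, pathway_maps, deg_set,
                                            reg_set, min_stretch, max_gap)

    key_names = {k.name for k in keys if k.is_key}
    key_genes: set[str] = set()
    for name in key_names:
        key_genes |= collection[name].members
    sources = EvidenceSources(
        deg_genes=deg_set,
        regulator_genes=reg_set,
        enriched_pathway_genes=enrichment.genes_on_enriched_sets(
            e_deg, collection, alpha),
        key_pathway_genes=frozenset(key_genes),
        causal_network_genes=net.genes,
        blood_genes=frozenset(blood_genes) if blood_genes is not None else None,
    )
    directions = {r.gene: degs.direction_of(r.gene) for r in records}
    log2fcs = {r.gene: r.log2fc for r in records}
    scores = biomarkers.score_genes([r.gene for r in records], sources,
                                    directions, log2fcs)
    panel = biomarkers.build_panel(scores, k_up, k_down)

    return FocusedAnalysisResult(records, degs, reg_results, reg_genes,
                                 e_deg, e_reg, e_combo, keys, net,
                                 scores, panel)
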