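# Methods

This note records the statistical models behind each pipeline stage,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Differential expression

The two-group test is an empirical-Bayes moderated t. Per gene, the
pooled within-group variance s²_g has d_g = n₁ + n₂ − 2 degrees of
freedom. Under the hierarchical model s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g
with 1/σ²_g ~ χ²_{d₀}/(d₀s₀²), the marginal of log s²_g is a shifted
log-F whose mean and variance are digamma/trigamma expressions in
(d₀, s₀²). We fit both by the method of moments on log s²_g, inverting
the trigamma identity with a Newton iteration; when the observed
log-variance dispersion is no larger than expected from χ² sampling
alone, d₀ = ∞ and all genes share s₀². The moderated statistic uses the
posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and is referred
to t with d₀ + d_g df (normal when d₀ = ∞). Setting the prior df to 0
recovers the classical pooled t exactly — the test suite pins the
implementation to a directly coded pooled-t oracle at 1e-10 — and the
null simulation (2000 genes, zero effect) keeps the p < 0.05 fraction
within 0.05 ± 0.02.

Degenerate genes: zero variance with zero mean difference gives t = 0,
p = 1; zero variance with a nonzero difference is evaluated at the
machine-minimum variance floor and logged.

**DEG calling.** Transcript DEGs are called on linear fold change
strictly above `fc_cut` (default 1.2) with no p-value gate; protein
lists use the same fold-change rule plus p ≤ 0.05. Both thresholds are
explicit arguments — no hidden multiplicity correction is applied at
this stage, and any p gate for transcripts must be user-supplied.
Printed overlap percentages are rounded half-up to one decimal.

## Enrichment

One-sided hypergeometric upper tail (over-representation only);
depletion is out of scope. The universe N defaults to the total gene
content of the collection, overridable with an explicit universe (e.g.
the measured genes of a platform); query genes and set members are
restricted to the universe before counting, with dropped query genes
logged. BH FDR is computed per collection; significance calls default
to raw p ≤ 0.05 with the FDR column always emitted, since the method's
reported significance values are unadjusted. The implementation
(scipy's stable survival function) is verified exhaustively against
exact rational enumeration for every parameter combination with
N ≤ 12.

## Direct regulators (over-connectivity)

For each candidate node v: n = |neighbours(v)|, r = |neighbours(v) ∩
DEGs|, R = |DEGs \ {v}|, N = |nodes| − 1. Excluding the candidate from
its own universe prevents self-counting. By default only outgoing edges
count, on the view that causality flows along edge direction (a
regulator acts on its targets); `direction="undirected"` covers
binding-only networks. BH across all candidates; ties broken by
(p ascending, overlap descending, gene id ascending).

## Remote regulators (hidden nodes)

The condition-specific sub-network is the set of all shortest directed
paths between ordered DEG pairs; the background is the same over all
ordered node pairs. Every shortest path per pair is enumerated
implicitly (a per-source BFS DAG with a descendant-count accumulation,
O(V·(V+E)) total, no path materialised), and each path increments each
of its interior nodes once; endpoints never count. With K the total
number of DEG-pair shortest paths, M the total over all pairs, and
k_v / m_v the per-node interior counts, node v is scored by the
hypergeometric upper tail of k_v successes among its m_v traversals
drawn from M paths of which K are condition-specific. Each all-pairs
shortest path is thus the draw unit. This convention makes the
degenerate identity exact: when every node is a DEG, k_v = m_v and
K = M, so p ≡ 1. Nodes with m_v = 0 are excluded. A seeded permutation
null (resampling DEG-sized node sets, default 1000 draws) is available
for sensitivity analysis; the hypergeometric null is the default
because it is deterministic and fast. The traversal counter is pinned
exactly to a brute-force all-shortest-path enumerator on random
digraphs, together with the conservation identity
Σ_v k_v = Σ_paths (length − 1).

## Key pathways

Three enrichment runs over one collection — DEGs, regulators, and their
union (the "combination" list; the union is the only combination whose
enrichment is a single p-value per pathway) — are compared per pathway:
key iff p_combo < p_deg and p_combo < p_reg with all three ≤ α
(default 0.05; the gate is applied to raw p). Note the strict
inequality makes the rule vacuous when the regulator list is a subset
of the DEG list (the union adds nothing and p_combo = p_deg); this can
happen on unlucky runs when regulators are themselves noise-called
DEGs, and is reported honestly as "no key pathways" rather than
patched.

## Causal reconstruction

DEGs and regulators are both considered affected. On each key pathway's
topology, cascades are simple directed paths (cycles traversed at most
once) from an affected ligand or receptor to an affected transcription
factor, with at most `max_gap` unaffected interior nodes (default 0)
and a longest consecutive run of affected nodes ≥ `min_stretch`
(default 2) — the strictest reading of "consecutive stretches", both
exposed as parameters. Cascade edges are unioned across pathways with
per-edge and per-node provenance; affected members of annotated
functional-module groups (e.g. protein complexes) are attached as
module-group nodes with any topology edges among them. The network
never contains an edge absent from a source topology, and enlarging the
affected set can only grow the cascade set.

## Key-gene score and panel

Ten binary criteria summed to 0–10. Criteria that depend on ontologies
not supplied in a configuration (GO process/function, process networks,
toxicity networks) score 0 with a logged "unavailable" marker, so
totals are comparable only within one configuration. Panel ranking is
(total desc, |log2fc| desc, gene id asc) — the tie-break is a
determinism choice since only "high scores" is specified — with the top
25 per direction among blood-expressed, direction-called candidates;
shortfalls yield a short panel with a warning. Hand-curated panel
tailoring is not automated.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
dataset:

* **Network**: Barabási–Albert preferential attachment (m ≈
  edges/nodes), randomly oriented, 1000 genes / ~3000 edges by default
  — hub-like topology because regulator detection presumes hub drivers.
  Each planted regulator gains directed transcription-regulation edges
  to its 20 targets.
* **Cascades**: each planted regulator is the transcription factor of
  one causal pathway (ligand → receptor → transducer → TF, length 4 by
  default). The upstream chain genes are planted as up-regulated DEGs
  (signaling genes whose expression also shifts), so cascades are
  recoverable, while the TF itself changes only its targets —
  regulators are drivers, not necessarily DEGs. All planted TFs are
  members of every causal pathway (pathways share TFs), so the
  regulator-list enrichment is informative: a single-regulator overlap
  of a 30-gene set in a ~600-gene universe cannot reach p ≤ 0.05, and
  requiring it would make the synergy rule untestable at this scale.
* **Expression**: per-gene baselines ~ N(8, 1) on log2 scale; disease
  group shifted ±1 log2 unit on planted targets (half up, half down)
  and +1 on chain genes; i.i.d. N(0, 0.5) noise; 10 samples per group.
  These defaults give ~29% of genes past the FC-only 1.2 cutoff (the
  fold-change rule is deliberately permissive) while planted targets
  are called with probability ≈ 1.
* **Ontology**: 20 pathways of 30 genes — background sets sampled
  uniformly, planted enriched sets seeded with ≥ 60% planted DEGs, plus
  one causal pathway per regulator (chain + TFs + targets, padded with
  random genes). Blood expression is a 50% coin flip per gene.
* **Reproducibility**: one global seed derives fixed per-stage
  sub-seeds (network / expression / ontology channels), so stages can
  be regenerated independently and artifacts are byte-identical for a
  given (config, seed).

What it does **not** emulate: probe effects, batch structure,
count-distributed RNA-seq data, correlated co-expression modules,
scale-dependent variance trends, literature-curated ontology overlap
structure, or realistic blood-expression biology. Passing recovery
tests therefore show the algorithms detect the structures they were
designed for at realistic signal-to-noise — not that any particular
biological dataset would yield the same lists.

## Test problem sizes

Recovery suites use 50 seeds at the default conditions (direct
regulators top-5 and causal-cascade recovery; observed rates 50/50 and
48/50), 100 seeds at a 300-gene configuration for planted-pathway
enrichment ranking, and 50 runs of a 100-node construction for
hidden-node recovery — sizes chosen so the full suite runs in well
under a minute on one CPU while keeping Monte-Carlo margins wide.

## Known limitations

* The hidden-nodes null treats path draws as exchangeable and ignores
  path-length and degree structure; the permutation null is the
  recommended sensitivity check on small networks.
* Enrichment universes built from ontology unions make p-values
  ontology-dependent; supply an explicit measured-gene universe to
  compare across collections.
* `find_affected_cascades` enumerates simple paths and is meant for
  curated pathway topologies (tens of nodes), not whole interactomes.
* Moment-based prior fitting assumes a common d_g across genes
  (complete two-group designs without missing values).
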