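# keydriver

Topological key-driver and key-pathway analysis for two-group disease
omics data — transcriptomics or proteomics of affected versus control
tissue. The package is aimed at systems-biology analysts who have a
normalized expression matrix (or precomputed differential lists), a
directed molecular-interaction network and a pathway ontology, and who
want to go beyond descriptive DEG/enrichment overviews to a *focused
analysis*: which upstream regulators drive the observed changes, which
pathways carry both the changes and their drivers, what the causal
signaling structure looks like, and which genes make the best
blood-accessible biomarker candidates.

## The method

1. **Differential expression.** An empirical-Bayes moderated t-test:
   per-gene pooled variances s²_g (d_g df) are shrunk toward a prior
   (d₀, s₀²) fitted by a method of moments on log s²_g, giving
   s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and
   t̃_g = Δmean_g / (s̃_g √(1/n₁ + 1/n₂)) on d₀ + d_g df. DEGs are
   called when the linear fold change is strictly above 1.2 (protein
   lists additionally gate on p ≤ 0.05).
2. **Enrichment.** One-sided hypergeometric over-representation:
   p = Σ_{i≥r} C(R,i)·C(N−R,n−i)/C(N,n) for a query of R genes
   overlapping an n-gene set in r of N universe genes, with
   Benjamini–Hochberg FDR per collection.
3. **Expression regulators.** *Direct* regulators are nodes whose
   interaction partners are over-connected to DEGs (hypergeometric on
   the neighbourhood, candidate excluded from its own universe).
   *Remote* regulators ("hidden nodes") are nodes traversed by an
   unexpectedly high share of all shortest directed paths between DEG
   pairs, relative to their share of all shortest paths in the network.
4. **Key pathways.** A pathway is key when its enrichment p-value for
   the union of DEGs and regulators is lower than its p-values for
   either list alone (synergistic enrichment), all three significant.
5. **Causal networks.** Over key-pathway topologies, affected ligands or
   receptors (triggers) are connected through consecutive stretches of
   affected signal-transduction molecules to affected transcription
   factors; retained cascades are unioned with per-edge provenance.
6. **Key genes.** Each gene scores 0–10 over ten binary evidence
   criteria (DEG, regulator, enriched GO process/function, enriched
   pathway / process network / toxicity network, key pathway, causal
   network, blood expression). The biomarker panel takes the top 25
   up- and 25 down-regulated blood-expressed candidates.

A synthetic-data generator (`keydriver.simulate`) plants regulators,
fold changes, enriched pathways and ligand→receptor→transducer→TF
cascades with recorded ground truth, so the whole pipeline is testable
without any download. See `docs/methods.md` for modelling details and
limitations.

## Worked example

Run the whole pipeline on a simulated dataset with three planted
regulators, each driving 20 targets:

```sh
cat > run.yaml <<'YAML'
simulate:
  n_genes: 1000
  network_edges: 3000
  n_regulators: 3
  targets_per_regulator: 20
YAML
keydriver run-all --config run.yaml --out-dir results --seed 1
```

which prints

```
142 up / 146 down DEGs; 3 regulator(s); 3 key pathway(s); panel of 50
```

and writes per-stage artifacts into `results/`. The planted regulators
(recorded in `results/truth.json` as G0288, G0829, G0969) come out as
the top-ranked over-connected nodes:

```
$ head -4 results/regulators.tsv
gene    kind    r   n   R    N    p            fdr          rank
G0829   direct  23  23  288  999  1.97235e-13  1.97235e-10  1
G0288   direct  20  21  287  999  1.40223e-10  5.01631e-08  2
G0969   direct  20  21  288  999  1.50489e-10  5.01631e-08  3
```

Here r of the n interaction partners of each candidate are among the
R = 288 DEGs in the N = 999 other network genes — e.g. all 23 partners
of G0829, hence the vanishing p. The three planted causal pathways are
flagged key because the combined DEG-plus-regulator list is more
enriched than either list alone:

```
$ head -4 results/key_pathways.tsv
pathway    p_deg        p_reg        p_combo      is_key
CP_G0288   3.97269e-08  0.000224452  3.37417e-10  true
CP_G0829   3.97269e-08  0.000224452  3.37417e-10  true
CP_G0969   3.5246e-07   0.000224452  4.82712e-09  true
```

`results/causal.nodes.tsv` / `causal.edges.tsv` hold the reconstructed
trigger→cascade→TF network, `key_genes.tsv` the ten evidence flags and
0–10 totals per gene, and `panel.txt` the 50-gene (25 up, 25 down)
blood-expressed biomarker panel.

Individual stages are also exposed (`keydriver simulate / deg / overlap
/ enrich / regulators / keypathways / causal / keygenes`), and
everything is importable as a library (`keydriver.run_focused_analysis`).

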