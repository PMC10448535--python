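# herborgan

Target-organ localization for herbal compound targets.

Traditional pharmacology holds that an herb acts selectively on particular
organs (herbal channel tropism). `herborgan` operationalizes that question as
a reproducible bioinformatics pipeline: starting from a compound table with
ADME scores and multi-source compound→gene association tables, it selects
active compounds, aggregates and confidence-filters their gene targets, picks
*core targets* from a high-confidence protein–protein interaction (PPI)
network, and localizes the targets to organs by two complementary routes —
gene-set **enrichment/depletion** against a gene→organ catalog, and
**expression-atlas linking** of individual genes to the tissues where they
are overexpressed. The output is organ rankings and compound–gene–organ
networks in standard exchange formats (GraphML, SIF, TSV).

It is written for computational systems-biology / network-pharmacology
practitioners who have exported tables from the usual databases (TCMSP-style
compound tables, HIT/BATMAN-style target tables, STRING edge lists, organ
catalogs, BioGPS/HPA-style expression matrices) and want the downstream
analysis to be scripted, tested and deterministic instead of a chain of web
tools.

## The statistics at the core

**ADME screen.** Compounds pass if oral bioavailability OB ≥ 30 % and
drug-likeness DL ≥ 0.18 (both inclusive), after cross-database deduplication
by shared identifier (CID → InChIKey → CAS → normalized name).

**Confidence rules.** Letter-graded associations keep grades A/B/C; scored
associations keep score ≥ 30; sources without a stated rule pass unchanged.

**Core targets.** In the PPI graph restricted to edges with combined score
strictly > 0.9, a gene is a core target when

    deg(g) > 2 · mean degree

with the mean taken over the connected (non-isolated) nodes.

**Enrichment/depletion.** For a query list of n genes in a universe of N,
a term of K genes with k hits is scored by the hypergeometric distribution
X ~ Hypergeom(N, K, n):

* classical tails: p⁺ = P(X ≥ k), p⁻ = P(X ≤ k);
* EASE variant (conservative): p = P(X ≥ k − 1), with k = 0 ⇒ p = 1;
* mid-p variant: p⁺ = P(X > k) + ½·P(X = k) and the mirror lower tail,
  so that p⁺ + p⁻ = 1 exactly.

Fold is k / (n·K/N); direction is *enriched* when fold ≥ 1, *depleted*
otherwise. All tested hypotheses (every term, both directions when depletion
is tested) enter one Benjamini–Hochberg family.

**Expression linking.** A gene links to a tissue where its expression
strictly exceeds its own cross-tissue mean (above-mean rule) or,
equivalently on non-constant rows, where its row Z-score (ddof = 1) is
strictly positive. Two atlases merge into a consensus by per-cell maximum.
Each gene can be assigned to the organ group (e.g. CD33⁺ myeloid cells →
bone marrow) with its highest expression; organs are ranked by bipartite
degree (number of linked genes).

## Worked example

The package bundles the printed 17-row active-compound table and the
44-gene core-target group partition as plain-text data:

```python
import herborgan as hb
from herborgan import io_formats

records = hb.dedup_compounds(io_formats.bundled_compound_table())
active = hb.adme_filter(records)            # OB >= 30 %, DL >= 0.18
print(len(active))                          # 17  (all printed rows pass)
print([r.name for r in hb.cross_source_overlap(records)])
# ['Beta-sitosterol', 'Spinasterol', 'Β-ecdysterone']
```

Every input class can also be simulated with planted ground truth, and the
whole pipeline run from one config file:

```sh
herborgan simulate --what study --seed 1 --out study
herborgan run --config study/config.txt
```

which prints the run-report counts (abridged):

```json
{"compounds": {"active": 17, "deduplicated": 170, "input_rows": 196},
 "targets": {"per_source": {"BATMAN-TCM": 78, "HIT2.0": 312, "TCMSP": 207},
             "union": 448},
 "core": {"core_targets": 44, "network_nodes": 448, "mean_degree": 70.4018},
 "enrichment": {"tested": 150, "significant": 2,
                "significant_enriched": 1, "significant_depleted": 1},
 "linking": {"mean_rule_edges": 1409, "z_rule_edges": 786, "grouped_genes": 44}}
```

Reading the numbers: of 196 input rows, 170 distinct compounds remain after
deduplication and 17 pass the ADME screen; the three association sources
contribute 207/312/78 distinct confidence-filtered genes whose union is 448;
the score-filtered PPI network yields 44 core targets (here exactly the
generator's planted hubs); among 150 catalog terms exactly the planted
enriched and planted depleted organs are significant; and the 44 core genes
are linked to tissues and assigned to organ groups by both linking rules.
All artifacts (gene lists, degree tables, enrichment TSV, rankings, GraphML
networks, JSON report) land in `study/results/`.

## Layout

* `src/herborgan/io_formats.py` — dialect-explicit readers/writers (TSV,
  GMT, STRING-style edge lists, expression matrices, GraphML/SIF).
* `src/herborgan/compound_screen.py` — deduplication + ADME filter.
* `src/herborgan/target_aggregate.py` — confidence rules, target union.
* `src/herborgan/ppi_core.py` — score-filtered PPI graph, degree-rule core.
* `src/herborgan/organ_enrichment.py` — exact tests (classical/EASE/mid-p),
  BH adjustment, catalog scanning.
* `src/herborgan/expression_linking.py` — linking rules, Z-scores,
  consensus, organ-group assignment, degree ranking.
* `src/herborgan/network_pipeline.py` — role-typed networks, config,
  end-to-end orchestration.
* `src/herborgan/synthetic_data.py` — seeded generators with planted truth.
* `docs/methods.md` — models, assumptions, parameter choices, limitations.
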