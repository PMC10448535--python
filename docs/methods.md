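# Methods

This note documents the models and procedures `herborgan` implements, the
parameters that matter, the numerical conventions, what the synthetic-data
generators do and do not emulate, and the design choices made where the
underlying workflow left the design open.

## Pipeline model

The pipeline formalizes a common network-pharmacology workflow for locating
the organs an herb's targets act on:

1. **Compound screen.** Multi-database compound records are merged when they
   share any strong identifier (PubChem CID, then InChIKey, then CAS, then a
   normalized name). Name normalization case-folds, collapses whitespace and
   spells out Greek letters so that `β-ecdysterone` and `Β-ecdysterone`
   compare equal. The activity filter keeps OB ≥ 30 % and DL ≥ 0.18, both
   inclusive as typeset in the conventions it follows. When merged records
   disagree on OB/DL the maximum is kept: the filter asks whether *any*
   curated entry supports activity, and in practice a single database
   supplies these scores so conflicts are rare.
2. **Target aggregation.** Associations carry per-source confidence:
   letter grades (keep A/B/C) or a numeric score (keep ≥ 30, inclusive —
   the cutoff is read as a threshold, and the flag is overridable). Sources
   without a stated rule pass unchanged. The target set is the deduplicated
   union of surviving gene symbols; symbols are compared case-sensitively
   after trimming, with no alias resolution (symbol mapping is assumed done
   upstream).
3. **Core selection.** Edges with combined score strictly > 0.9 (0–1 scale;
   0–1000 exports are auto-detected and divided by 1000) form an undirected
   simple graph. Degree is the raw incident-edge count — unweighted, not
   normalized — because the selection rule "degree > 2 × mean" is only
   meaningful on the raw scale. The mean is computed after removing isolated
   nodes, matching the convention of analyzing the displayed connected
   network. The rule is strict: a node at exactly twice the mean is not a
   core target. Note that at multiplier 2 the core can never be the whole
   network (Σ deg = n · mean forbids deg > 2·mean everywhere).
4. **Organ enrichment/depletion.** See below.
5. **Expression linking.** See below.
6. **Networks.** Bipartite gene–tissue and tripartite compound–gene–organ
   graphs with role-typed nodes (edges only between adjacent roles) and
   degree attributes, exported to GraphML/SIF/TSV rather than rendered.

Enrichment runs by default on the full target union while expression linking
runs on the core set; this asymmetry mirrors the workflow the pipeline
formalizes (list-level statistics tolerate noise that per-gene expression
readouts do not) and both choices are overridable (`enrich_on`, `link_on`).

## Exact tests

For a query of n genes in a universe of N, a term with K genes and k hits,
with X ~ Hypergeom(N, K, n):

* `hypergeometric` / `fisher`: p⁺ = P(X ≥ k) (one-sided Fisher on the 2×2
  table), lower tail P(X ≤ k) for depletion.
* `ease`: p = P(X ≥ k − 1), k = 0 ⇒ 1. The one-gene discount makes single-hit
  terms never significant and is the conservative convention of annotation
  servers; plain Fisher remains available by flag.
* `midp`: p⁺ = P(X > k) + ½·P(X = k), p⁻ = P(X < k) + ½·P(X = k). This is
  the standard mid-p correction for discrete tests; the two directions sum
  to exactly 1, and the mid-p never exceeds the classical tail when
  P(X = k) > 0. It is the default, matching the convention of phenotype
  gene–organ catalogs ("mid-range correction"); classical tails are a flag
  away since the original tool's exact variant is not fully published.

Direction is decided by fold = k/(n·K/N): depleted iff fold < 1 and
depletion testing is enabled; a fold of exactly 1 is tested as enrichment
(and is never significant). Terms with K = 0 cannot occur (catalog terms
have ≥ 1 gene); k = 0 depletion is a legitimate test. Multiple testing uses
Benjamini–Hochberg (statsmodels) over one family containing every tested
hypothesis — all terms, both directions when depletion is on. The family
construction is a declared choice; the upstream tools report FDR without
specifying theirs. Query genes outside the universe are dropped from n with
a logged count; the universe defaults to the union of the catalog's gene
sets and can be overridden by an explicit universe file (the closest
reproducible analog of a server-side background).

## Expression linking

* Above-mean rule: link (g, t) iff x(g,t) > mean over the gene's tissues,
  strictly. Constant rows produce no links; a non-constant row always yields
  between 1 and T−1 links.
* Z-score rule: z = (x − row mean)/row sd with ddof = 1 (sample sd; the
  source workflow does not specify, flag-overridable to 0); link iff
  z > 0, strictly. Zero-sd rows are flagged, not divided. On non-constant
  rows the two rules are provably identical (z > 0 ⇔ x > mean, for any
  ddof); both exist because they are the interfaces the two atlas dialects
  (microarray intensity vs consensus nTPM) expose.
* Consensus of two sources: per-cell maximum (the nTPM convention), genes =
  intersection (a consensus is undefined for a gene absent from one
  source), tissues = union with single-source values carried.
* Organ-group assignment: a group's value is the max over its member
  tissues (consistent with the max-based consensus convention; the
  regrouping workflow never states its aggregate), the gene goes to the
  argmax group, ties break to the lexicographically smallest group name for
  determinism (tie count logged), all-zero genes stay unassigned.
* Organ ranking: tissues ordered by linked-gene count, descending, then
  name.

The bundled 15-tissue → 8-group map assigns hematopoietic cell types to
their organ of origin (CD33⁺/CD34⁺/B-lymphoblast → bone marrow;
CD14⁺/CD56⁺/whole blood → whole blood; dendritic/Raji/CD19⁺/CD4⁺ →
lymphoid tissue) and keeps solid tissues as singleton groups.

## I/O conventions

Readers are total on their writers' output (round-trip tested for edge
lists, GMT catalogs, expression matrices and GraphML). Score-scale detection
treats any score > 1 as marking a 0–1000 file; a file mixing 0–1 decimals
with integer-scale scores is rejected as a format error, and normalization
is idempotent. Self-loops are dropped with a logged count. Duplicate gene
rows in expression matrices collapse by per-tissue maximum (probe/row
collapsing is unstated upstream; max matches the "highest value"
convention used elsewhere in the pipeline). Empty cells are always NA.
All writers emit UTF-8 with LF endings.

## Synthetic data: what it emulates, and what it does not

Each generator is a pure function of its arguments including the seed, and
every planted item is recoverable by the corresponding pipeline stage at the
strong-signal defaults.

* `gen_compounds` (defaults n = 170, frac_active = 0.1): actives draw
  OB ~ U(30, 70), DL ~ U(0.18, 0.9); inactives fail at least one bound;
  15 % of compounds are duplicated under a second source label. The default
  yields exactly 17 actives — the scale of a typical single-herb screen.
* `gen_ppi` (defaults 200 genes, 3 hubs, hub_p = 0.8, spoke_p = 0.01):
  planted edges carry scores in {0.901, …, 0.999} and decoys ≤ 0.9, as exact
  multiples of 1/1000 so the 0–1000 integer export round-trips losslessly.
  Hub wiring at 0.8 against sparse spokes makes the degree rule recover the
  hubs; `hub_p ≤ spoke_p` is refused without `force` because recovery is
  then not guaranteed.
* `gen_catalog_and_list` (defaults 150 terms, universe 7,000, planted term
  100, list 50, signal 0.6, depleted term 1,500): non-planted term sizes
  draw U(100, 2000), anchored to the scale of real gene–organ catalogs
  (~150 terms carrying ~150,000 associations over ~7,000 genes, i.e. mean
  term size ≈ 1,000). Under this distribution the discrete hypergeometric
  test's achievable significance levels average a null rejection rate of
  about 3–4 % at α = 0.05 — conservative, as discrete exact tests are, but
  not degenerate. The depleted term must be large to be detectable from a
  50-gene list: a completely avoided term of size K has
  P(k = 0) ≈ exp(−nK/N), which crosses raw significance only near K ≈ 400
  and survives a 300-hypothesis BH family only for K well above 1,000;
  hence the 1,500 default. `signal_fraction=None` draws the list uniformly
  (the null condition).
* `gen_atlas` (defaults fold = 4, cv = 0.3): lognormal per-cell noise
  (σ = √ln(1+cv²)) around a per-gene baseline, with the planted group's
  tissues multiplied by `fold`; `fold = 1` is the chance-level condition
  (recovery ≈ group-size-weighted 1/8 under the default map). Pairs of
  re-noised copies share the planted truth for consensus tests.
* `gen_study` wires all of the above into one bundle sized like a real
  single-herb study (17 actives; source gene sets of 207/312/78 distinct
  genes constructed to union exactly to 448; 44 planted hubs; 84- and
  54-tissue atlases) plus a ready config and the truth as JSON.

The generators emulate the *statistical structure* the pipeline's rules act
on — marginal OB/DL distributions, hub-dominated degree profiles, planted
over/under-represented terms, multiplicative tissue-specific overexpression.
They do not emulate microarray probe structure, sequencing counts, realistic
PPI topology beyond hub planting, or gene-symbol noise; passing tests
therefore demonstrate correctness and statistical consistency of the rules,
not performance on any particular real database export.

## Numerical and procedural choices

* All threshold comparisons follow their stated direction exactly: OB/DL and
  association score inclusive (≥), PPI score and degree rule strict (>),
  linking rules strict (>).
* Simulation sizes in the test suite (200 null seeds, 100 recovery seeds,
  50 atlas seeds, exhaustive enumeration up to N = 12) were chosen as the
  smallest batches at which the binomial noise of the measured rates is well
  inside the asserted bands.
* Tie-breaks are deterministic everywhere (lexicographic for group argmax
  and result ordering; degree-then-name for core and ranking tables), and
  the run report is byte-stable for a fixed config and inputs.
* Degenerate inputs: empty networks and single-tissue atlases are usage
  errors; constant expression rows are flagged and excluded from Z-linking;
  records lacking OB/DL or confidence fields are excluded with logged
  counts rather than errors.
* The core subnetwork's internal degrees can differ from full-network
  degrees; `subnetwork` re-derives them so both tables can be reported,
  since the upstream convention is ambiguous.

## Known limitations

* Printed p-values from annotation servers depend on their proprietary
  annotation tables and are treated as context, not oracles; the bundled
  plain-text inputs are the printed compound table and group partition only.
* No identifier resolution (compound or gene aliases) beyond the stated
  normalization; one-to-many protein→gene mappings must be resolved
  upstream.
* The enrichment universe is catalog-derived unless a background file is
  supplied; results are sensitive to this choice, as with any
  over-representation analysis.
* Depletion of small terms is statistically undetectable from short lists
  (see the exp(−nK/N) bound above); the pipeline reports such terms as
  non-significant rather than warning per term.
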