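# Methods

This note documents the rules, statistics and modelling choices the
package implements, the synthetic data it validates them on, and the
numerical conventions that matter when reproducing results.

## Viral-contig triage

A candidate contig survives triage only if it passes every stage:

1. **Primary screen.** Detector score ≥ 0.5 (a deliberately relaxed
   sensitivity cutoff), and removal of contigs with < 50% estimated
   completeness or > 10% estimated contamination. The removal conditions
   are strict inequalities, so a contig sitting exactly at 50%
   completeness or 10% contamination survives. This boundary convention is
   applied literally throughout the package: every threshold keeps the
   printed inequality direction and inclusiveness.
2. **Tripartite criteria** on per-contig gene-annotation counts.
   Criterion 1: ≥ 5 genes with viral-protein-family (VPF) hits, < 20% of
   genes with KEGG Orthology annotations and ≤ 40% of genes covered by
   Pfam domains (cellular-organism signal caps). Criterion 2: VPF gene
   count ≥ Pfam gene count and VPF genes ≥ 60% of all genes. The two
   criteria are combined conjunctively by default; a documented
   `admission="any"` switch makes them alternative admission routes.
   Counts are of *genes* (one vote per gene), not of summed domain hits.
   Contigs with zero called genes fail with reason `no genes` rather than
   raising, so fragmentary inputs cannot abort a run.
3. **Clustering.** Contigs of length ≤ 5000 bp are dropped (the retention
   rule is strictly "> 5 kb"), survivors are sorted by descending length
   (ties broken lexicographically by contig id, for determinism), and each
   joins the first cluster whose representative it matches at ≥ 95%
   identity, else founds a new cluster; the representative is the longest
   member. Identity is defined as (L_short − d) / L_short where d is the
   edit distance of the shorter sequence aligned against its best window
   of the longer (infix alignment, both strands, computed exactly with
   edlib). The query role is fixed by (length, id) order, making the
   measure symmetric. A shared-15-mer prefilter skips hopeless pairs; for
   thresholds ≥ 95% this filter is exact, not heuristic, because d ≤
   0.05·L forces a mismatch-free run of ≥ L/(d+1) ≈ 20 bp by pigeonhole.

The length cut is applied before clustering (the source protocol binds
them into one step; cutting first is also the cheaper order and cannot
change the surviving set, only candidate membership of dropped fragments).

## Lifestyle classification

A retained contig is **lysogenic** when it carries at least one marker
annotation from the fixed lexicon {integrase, transposase, invertase,
recombinase, excisionase} or, under the default union merge, when an
external lifestyle predictor labels it lysogenic (the external tool is
treated as supplementary evidence — it can add detections, never veto
markers). All remaining contigs are **potential lytic** viruses: the
classification is a two-way partition. Classification is monotone in
evidence: adding marker rows can only move a contig lytic → lysogenic.

Per-sample lifestyle proportions default to abundance weighting (each
contig weighted by its RPKM share); count weighting (fraction of contigs
present in the sample) is provided because published proportion figures do
not always state the weighting. Samples with zero total abundance get
missing proportions.

## Virus–host linking

Three independent evidence channels, each a pure filter:

* **CRISPR spacers.** Each host spacer (≥ 20 nt, A/C/G/T) is scanned
  ungapped against every viral contig on both strands. A window of spacer
  length L qualifies when its Hamming distance d satisfies **both** printed
  thresholds: d ≤ 2 and identity (L−d)/L ≥ 95%. These two rules are
  mutually tense — for L < 40, two mismatches already violate 95%
  identity — so the conjunctive reading gives an effective budget of
  min(2, ⌊0.05·L⌋). A `rule="union"` switch applies either threshold
  alone for users who read the protocol disjunctively. Matching is
  substitution-only (no indels), which is how a "maximum of two single
  nucleotide polymorphisms" reads; at these lengths and identities the
  e-value cutoff of an alignment-tool search is subsumed by the
  identity/mismatch rule and is not recomputed.
* **tRNAs.** Same ungapped both-strand scan at identity ≥ 95% with no
  absolute mismatch cap.
* **Genomic homology.** Pre-computed tabular hits (12-column tabular
  dialect) filtered at identity ≥ 70%, query coverage ≥ 75%, e-value
  ≤ 1e-3, bit score ≥ 50 and alignment length ≥ 2500 bp, all inclusive.
  The computation *is* the filter; no alignment engine is embedded. Query
  coverage is (qend − qstart + 1)/query length when not supplied.

All link coordinates are 0-based half-open on the forward strand of the
virus. Every qualifying window is reported (positions matter for
inspection); the merge step deduplicates to unique (virus, host) pairs
with the set of supporting channels, is idempotent, and classifies each
virus as specialist (one host taxon at the chosen rank, or one host contig
without taxonomy) or generalist.

## AMG filtering and normalisation

AMG candidates carry an auxiliary score (1 = confidently metabolic and
virus-encoded … 5 = likely not auxiliary) and single-letter flags.
Retention requires score ∈ {1, 2, 3}, at least one metabolism flag
(M or F), and no flag from the disqualifying set {V, A, P, T, B}
(viral-function, attachment, peptidase, transposon, transposon-adjacent) —
the flag semantics of the annotation convention the scores follow; both
flag sets are configurable because published settings list only "-M and
-F". Two callers' outputs can be combined by union (default) or
intersection keyed on gene id. Retained genes are categorised by KEGG
level-2 pathway (explicit label, else a shipped static KO → category
table) and by CAZyme class parsed from the family-label prefix
(GH, GT, PL, CE, AA, CBM); genes with neither label count as
"unclassified". Per-gene abundances are Z-scored across treatments with
sample SD (n−1); constant rows map to all zeros, and fewer than two
treatments is an error.

## Community and microcosm statistics

* **RPKM**: count / (length/10³) / (mapped-total/10⁶). The conservation
  identity Σᵢ rpkmᵢ·(lengthᵢ/10³) = 10⁶·Σᵢcountᵢ/total is verified in
  tests.
* **Alpha diversity**: Shannon H = −Σ pᵢ ln pᵢ over non-zero proportions
  (natural log, the default of the standard ecology toolkit; the metric is
  unnamed in many protocols). Richness is also emitted. H is invariant to
  per-sample depth rescaling.
* **Bray–Curtis**: d(u,v) = 1 − 2·Σ min(uᵢ,vᵢ)/Σ(uᵢ+vᵢ), in [0,1],
  symmetric, zero diagonal; distances to an all-zero sample are 1 by
  convention, with a warning.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (M/2) with ranks over all M = n(n−1)/2 pairwise distances (average
  ranks on ties). R ∈ [−1, 1] and is invariant under strictly monotone
  transforms of the distances.
* **Mantel**: Spearman (default) correlation of the two upper triangles;
  the permutation reorders one matrix's samples. Because a sample
  reordering permutes the pair multiset bijectively, ranks are computed
  once and permuted with the matrix — an exact optimisation, not an
  approximation. Constant upper triangles yield a missing r.
* Both permutation tests use the add-one estimator
  p = (1 + #{R* ≥ R_obs}) / (1 + nperm), so p ∈ [1/(nperm+1), 1] and is
  never exactly zero; the tests are one-sided (greater), deterministic
  under an integer seed, and their type-I error is calibrated on
  exchangeable null data in the acceptance suite.
* **Co-occurrence networks**: all pairwise Spearman correlations over
  samples; Benjamini–Hochberg FDR across the full pairwise family of one
  network (the family is otherwise unspecified in common protocols);
  an edge requires |r| > 0.7 and q < 0.01, both strict as printed.
  Constant features are dropped with a warning.
* **Cumulative CO₂-C**: alkali traps integrate production over each
  sampling interval, so the cumulative value at day k is the prefix sum of
  interval amounts — no trapezoidal interpolation of instantaneous fluxes.
* **qCO₂** = cumulative CO₂-C / (MBC · duration), in
  mg CO₂-C mg⁻¹ MBC d⁻¹; MBC = 0 yields a missing value.
* **Group comparisons**: one-way ANOVA (F, p) with Duncan's multiple range
  test for compact letter displays — critical range for a span of r means
  is q(1−(1−α)^(r−1); r, df_error)·√(MSE/n_h) with the studentized-range
  distribution and harmonic-mean group size, with the usual protection
  rule (pairs inside a non-significant wider range are not separated).
  Degenerate all-equal zero-variance groups share one letter. Pairwise
  contrasts use Welch's t-test by default (pooled optional), since
  published group t-tests rarely state the variance assumption.

## Synthetic communities and what they do (not) show

The generator plants every decision the pipeline must make and records the
expected outcome in a truth table:

* contig feature rows that comfortably pass, fail exactly one rule, or sit
  exactly on each printed boundary (score 0.49/0.50, completeness
  49.9/50, contamination 10/10.1, KEGG 19.9%/20%, Pfam 40%/40.1%, VPF 4/5,
  VPF fraction 59%/60%, length 5000/5001);
* protospacers planted on either strand with exactly 0–3 substitutions at
  distinct interior positions (never the first or last base, so the match
  window is unambiguous), plus unplanted decoy spacers;
* tRNA insertions bracketing the 95% identity budget; homologous blocks
  copied between virus and host with controlled identity, coverage,
  e-value, bit-score and length failures;
* AMG candidates covering the full score × flag grid;
* per-sample relative abundances with Dirichlet group structure
  (`group_effect=0` gives exchangeable samples for null calibration;
  `abundance_mode="equal"` gives exact count-fraction recovery), and a
  35-day microcosm series (days 1, 3, 5, 7, 14, 21, 28, 35; virus-addition
  VS/NS × treatments × 3 replicates) with known cumulative CO₂-C and qCO₂.

Defaults mirror the study design the pipeline serves: 4 treatments × 3
replicates, planted lysogenic fraction 0.21, spacer mismatch plan
(0, 1, 2, 3). Sequences are uniform random A/C/G/T; the generator does not
emulate real genome composition, HMM score distributions, assembly
artefacts, amplification bias or read-level noise. Passing tests therefore
demonstrate that the *decision rules* are implemented exactly and
calibrated — not that the upstream detectors would behave identically on
real soil metagenomes.

All randomness flows from one integer seed through named sub-streams
(one per generated table), so identical configurations are byte-identical
and individual stages are reproducible in isolation.

## Numerical conventions and problem sizes

* Threshold comparisons follow printed inequality directions exactly;
  boundary behaviour is pinned by tests on both sides of every boundary.
* Z-scores and SDs use ddof = 1; normalisation tolerances 1e-12.
* Closed-form quantities (RPKM, Shannon, Bray–Curtis, CO₂, qCO₂) are
  checked to 1e-9 relative tolerance.
* Permutation-test calibration uses 500 null replicates at nperm = 199
  (in the test suite) against the binomial 95% acceptance band
  [0.032, 0.071] around α = 0.05; cross-checks against an independent
  reference implementation use 9999 permutations so that both Monte Carlo
  estimates are tight. Exhaustive-window spacer oracles run on compact
  communities (< 100 kb of viral sequence); triage oracle equivalence runs
  on 200 contigs. These sizes make the default suite complete in about a
  minute while exercising every rule and boundary.

## Known limitations

* Clustering identity uses edit distance of the best infix alignment; for
  sequences near 95% identity with many indels this slightly
  underestimates matches/columns identity relative to tools that count
  alignment columns. At the package's scale (near-duplicate detection)
  the two agree.
* The spacer/tRNA channels are substitution-only by design; a genuine
  protospacer containing an indel would be missed (as it would be under a
  strict reading of the SNP rule).
* Duncan's test is implemented for balanced and mildly unbalanced designs
  (harmonic-mean group size); strongly unbalanced designs should prefer
  the Tukey-style alternative of standard statistics packages.
* NMDS ordination, network layout and random-forest driver analyses are
  intentionally out of scope; distance matrices and edge lists are
  exported for external tools.
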