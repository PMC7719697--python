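# Methods notes

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the judgment calls made where the procedure was genuinely
open.

## Differential expression

Each dataset is a two-group (tumor/normal) comparison analyzed in
isolation. The significance engine is a per-gene Welch two-sample t-test —
on log2 intensities for microarray, on log2(CPM + 0.5) for counts — with
Benjamini-Hochberg correction across all genes of the dataset. This is a
deliberate simplification relative to moderated-statistics engines (limma,
DESeq2): the package's contribution is the threshold-and-consensus layer,
which consumes any DEG table with (gene, log2fc, p_adj, direction)
columns, so a stricter engine can be swapped in upstream without touching
anything downstream.

Conventions that matter and are fixed here:

* log2FC = tumor mean − normal mean; "over" ⇔ log2FC > 0.
* Significance is the conjunction |log2FC| ≥ 1 **and** adjusted p < 0.05
  (strict inequality on p). The fold-change gate is independent of the
  p gate: a gene at log2FC = 0.99 with astronomical significance is not a
  DEG.
* Genes with zero variance in both groups get p = 1 (not NaN) so they
  pass through BH harmlessly.
* CPM is computed before the pseudocount (log2(counts/libsize·1e6 + 0.5)),
  which makes log2FC exactly invariant to global library-size rescaling.
* QC exclusion: a sample flagged on ≥ ceil(k/2) of k metrics is removed —
  a tie at exactly half excludes.

## Frequency consensus

Per (gene, direction, technology) the unit of evidence is the *cancer
type*: a type counts once regardless of how many of its datasets contain
the DEG, which prevents well-sampled cancers from dominating. Defaults are
6 of 13 microarray types and 3 of 8 RNA-seq types. The cross-technology
consensus is the per-direction **intersection** of the two frequent sets
("shared by both"); a gene frequent as over in one technology and under in
the other is excluded from both directions and surfaced in a conflict
report rather than silently resolved. Jaccard screening defaults to
per-cancer unions of significant DEGs over all of that cancer's datasets;
restricting to frequent genes is a caller-side choice (pass those sets
instead). Two empty sets score 0 by convention (the index is undefined
there); the flag threshold is 0.15. The ML feature filter is conjunctive —
≥ 3 cancer types *and* ≥ 5 total hits — with a deterministic sort
(types desc, hits desc, name) so outputs are byte-reproducible.

## Network topology

First-shell expansion drops interactome edges with confidence < 0.400
(inclusive boundary, matching the usual "medium confidence (0.400)"
convention), then caps the shell at 200 interactors. The cap needs a
deterministic ranking, which an interactive database delegates to its own
scoring; here it is (number of seed neighbors, summed confidence to seeds,
lexicographic id). Seeds absent from the filtered interactome are reported
unconnected and labeled NA.

Centralities: degree is the incident-edge count; betweenness is exact
Brandes accumulation, unnormalized, endpoints excluded; eigenvector
centrality is power iteration on A + I (the identity shift leaves
eigenvectors unchanged but guarantees convergence on bipartite
components), tolerance 1e-10, at most 1000 iterations, L2-normalized
absolute scores. On disconnected graphs the uniform start converges to the
dominant component and other components score ≈ 0; an edgeless graph
scores 0 everywhere by convention. Non-convergence raises an error that
names the component structure.

Classification compares each node with the **mean** over all network
nodes (seeds and interactors alike, the whole-network behavior of
CentiScaPe-style scoring), with strict `>`; mean-vs-median and
strict-vs-inclusive are not fixed by the source procedure, so mean/strict
was adopted and is stated here. Only the relative position versus the mean
matters, which is why the betweenness normalization choice is neutral —
but it must be pinned, and is. A vertex-transitive graph (e.g. a cycle)
therefore yields NTR for every node. The HBS subnetwork is the induced
subgraph on all HBS-labeled nodes.

## Regulatory core

TAR-Net keeps every regulon edge whose target is a seed (consensus DEGs
and ML features both count as seeds; a `degs_only` flag restricts the
tally to DEGs). A TF that is itself a seed keeps both roles, and its own
incoming edges count toward other TFs' tallies. The core filter retains
TFs targeting ≥ 2 distinct seeds, then seeds still targeted by a retained
TF; a single cascade pass suffices because removing orphan seeds cannot
strip a retained TF below threshold (its qualifying targets are all
retained by construction) — an assertion guards this invariant. The
filter is idempotent and returns a subgraph of its input. Signaling-path
reconstruction (k-shortest-paths style) is out of scope; the ≥ 2-seed
rule is exposed as the standalone core-defining operation.

## Enrichment

The two-sided hypergeometric p is 2·min(upper tail, lower tail) capped at
1, with the point probability included in both tails; direction is
"enriched" iff the upper tail is strictly smaller. This doubling is the
simplest defensible two-sided construction for a discrete one-parameter
family and is what the package means by "two-sided" throughout.
Bonferroni multiplies by the number of tested terms.

The term filter applies, in fixed order: (1) keep Bonferroni p ≤ 1e-5;
(2) drop exact-name matches to a user-supplied generic-term blacklist;
(3) where both "positive regulation of X" and "negative regulation of X"
survive, keep the smaller p (ties keep the positive form); (4) drop
categories with < 3 surviving terms, judged artifacts. The 1e-5 reading —
*discard terms failing a 1e-5 level* — is a judgment call (the alternative
literal reading, discarding the most significant terms, inverts standard
practice); `strict_p` is configurable. Categories are user-supplied
metadata (the GMT description field), not inferred.

## Survival screening

Grouping contrasts expression extremes: strictly above the 75th percentile
(high) versus strictly below the 25th (low), middle half excluded, with
percentiles by linear interpolation between order statistics — the
convention is pinned because group membership depends on it. The phrase
"above the upper quartile … and those below" is ambiguous between this
extremes-only split and an exhaustive split at Q3; both are implemented
(`scheme="extremes"` default, `scheme="upper_quartile"` alternative).

KM is the product-limit estimator; the log-rank statistic is the standard
two-group observed-minus-expected form referred to chi-square with 1 df;
the Cox fit is univariate on the high-group indicator, HR = exp(β),
CI = exp(β ± 1.96·se). Tie handling is Efron (the lifelines
implementation); with continuous synthetic times ties do not occur, where
Efron and Breslow coincide. The risk flag is the conjunction
log-rank p < 0.05 and HR ≥ 1; protective genes (HR < 1) are never
flagged however significant. Per-gene failures (constant expression,
non-convergence) are reported with a status string, not dropped.

## Synthetic generators

All generators are pure functions of (parameters, seed).

* **Microarray**: per-gene baselines N(8, 2) in log2 units, observation
  noise N(0, sd) with sd = 1 by default; planted effects add to the tumor
  group in log2 units. Default study size 10 + 10.
* **RNA-seq**: negative binomial with variance μ + φμ², constant
  dispersion φ (default 0.1 in the panel) across genes, baseline means
  log-normal around 100; a planted effect of e multiplies the tumor mean
  by 2^e. The simplest count model sufficient to exercise threshold rules.
* **Panel**: 13 microarray and 8 RNA-seq cancer types, one dataset each,
  300 genes; 12 pan-over and 6 pan-under genes planted in every type of
  both technologies at ±3 log2 units (well above the fold gate, so
  consensus recovery measures the pipeline, not test power at the
  boundary), plus 10 private over-genes per type that give the Jaccard
  matrices shared-plus-private structure.
* **Interactome**: Erdős–Rényi background plus extra edges on planted
  hubs; confidences uniform on [0, 1]; no self-loops or parallel edges.
* **Survival**: standard-normal expression; exponential event times with
  the hazard multiplied by exp(β) for patients strictly above the
  empirical 75th percentile — the same indicator the screen reconstructs,
  which is what makes HR recovery well defined. Censoring is independent
  exponential with observed time = min(event, censor); the censor-rate
  parameter is the expected censored fraction among baseline patients.

What the generators do **not** emulate: probe-level microarray structure,
read-level RNA-seq, batch effects, inter-gene correlation, platform
differences within a technology, or covariate-dependent censoring.
Passing tests therefore demonstrate the pipeline's rules and estimators,
not robustness to those real-data complications; with planted effects of
3 log2 units, recovery rates near 100% say nothing about sensitivity to
marginal effect sizes (the monotone-sensitivity test covers the trend).

## Problem sizes

The packaged demo and the acceptance script run at desk scale: a 21-study
panel (300 genes, 10 + 10 samples), a 400-node interactome, 40 annotation
terms, and survival cohorts of 600 (demo) and 2,000 (parameter-recovery)
patients; null calibration averages 100–200 seeded re-simulations. These
sizes were chosen so the full suite completes in well under a minute per
heavy check while keeping every Monte-Carlo bound comfortably away from
its threshold.

## Known limitations

* The Welch/CPM engine understates what moderated-variance engines can do
  at n = 3–5 per group; with the default panel (n = 10) this is immaterial.
* Eigenvector scores on graphs with two exactly tied dominant components
  converge to a start-dependent mixture; real interactomes never tie
  exactly.
* The regulatory stage does not infer regulation direction from
  expression; modes come from the regulon table verbatim.
* The survival screen is univariate and unadjusted, by design; it mirrors
  expression-portal screening, not a clinical model.
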