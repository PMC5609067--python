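# Methods

## The network model

The degradation network is a curation scaffold, not a stoichiometric
model: reactions carry a compartment class (`extracellular`, `transport`,
`intracellular`), non-empty substrate/product compound sets, one or more
of the seven pathway tags (cellulose, xylan, xyloglucan, mannan,
mixed-linkage glucan, pectin, starch) and a gene set with OR semantics
(any listed product suffices). Flux-balance analysis is deliberately out
of scope, so stoichiometric coefficients are not stored.

Gene identifiers are normalized to `NCU` + zero-padded five digits;
symbols (`gh5-7`) are kept verbatim as annotations. A gene's compartment
role and pathway set are **derived** as the union over its reactions,
except that a `role` column in the gene table, when present, overrides the
derivation — curated sources typically assign one primary role per gene,
and the published 103/19/46 role partition (which sums exactly to the 168
genes) is reproduced only under that reading. Orphan reactions (no
associated gene, e.g. transport steps with unidentified transporters) are
warnings, never errors; dangling references and duplicate identifiers are
fatal.

## Evidence integration and the confidence score

Five heterogeneous evidence types are collapsed to one boolean flag each:

- **f — functional genomics**: database annotation matches the assigned
  function, AND the signal-peptide prediction pattern is role-consistent
  (SignalP or Phobius positive for extracellular proteins; both negative
  for transport and intracellular proteins), AND at least one localization
  predictor (WoLF PSORT / ProtComp) matches the role, with transport
  matched by a `membrane` call. Transport proteins are treated like
  intracellular ones for the signal-peptide clause, consistent with no
  transporter having a predicted signal peptide.
- **t — transcriptomics**: significant up-regulation versus the NoC
  control on at least one carbon source *relevant* to one of the gene's
  pathways. The pathway→condition relevance map (configurable) is
  cellulose→{Avicel, cellobiose}, xylan→{xylan}, mannan→{mannan},
  xyloglucan→{xyloglucan}, mixed-linkage glucan→{MLG},
  pectin→{pectin, orange peel powder}, starch→{starch}. For a
  multi-pathway gene any one relevant substrate suffices.
- **p — proteomics**: detected in a secretome or increased in abundance
  versus NoC, in any condition.
- **g — genetics**: any growth-deficient deletion-strain phenotype.
- **b — biochemistry**: direct characterization or a characterized
  ortholog/paralog in another filamentous fungus.

The confidence score is the weighted flag sum over the maximum:
weights (f, t, p, g, b) = (1, 2, 4, 8, 16), maximum 31. Because each
weight strictly exceeds the sum of all smaller ones, the 32 flag patterns
map bijectively onto numerators 0–31 and a stronger evidence class always
dominates every combination of weaker ones. Scores are exact `Fraction`s
internally and serialized with six decimals plus the integer numerator, so
equality tests are exact. The constructor rejects any weight vector
violating the dominance property.

Proteomics priority: a protein observed in a secretome whose assigned role
is not extracellular is re-annotated to extracellular and flagged with
provenance; the empirical observation outranks the in-silico localization.

## Regulon calling

A regulon is defined against two controls: membership requires adjusted
*p* < α (default 0.05) and at least `min_fold` induction (default 2,
inclusive, i.e. log₂FC ≥ 1) in **both** the test-vs-NoC and
test-vs-sucrose comparisons; down-regulons mirror the rule. Both
thresholds are enforced in both comparisons. Precomputed
differential-expression tables (with the external engine's adjusted p)
take precedence; when only raw p is present, Benjamini–Hochberg is applied
within the comparison.

The built-in fallback (for simulated data): fold changes from
condition-mean FPKM with a 1-FPKM pseudocount, a two-sided Welch *t*-test
on log₂(FPKM + 1) replicate values, BH across genes per comparison. It
requires ≥ 2 replicates and makes no attempt to reproduce an external
engine's p-values. With three replicates the Welch–Satterthwaite degrees
of freedom fall between 2 and 4, so the test is exact but conservative;
see Limitations.

Exclusive intersections assign every gene in a regulon union to its exact
membership pattern (UpSet semantics); the decomposition partitions the
union by construction, and a minimum-size filter is applied only to the
returned mapping. Unique fractions are plain set arithmetic,
`|target ∖ ∪others| / |target|`. Emitted gene lists are sorted.

## Log-space hypergeometric enrichment

The one-sided (upper-tail) hypergeometric test with an explicit universe
size — equivalent to one-sided Fisher's exact — evaluates
`P(X ≥ k) = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)`. Every term is computed as
a log-gamma expression and the sum is combined by log-sum-exp in natural
logs, converted to log₁₀ for reporting; the full suffix-tail profile over
k is produced in one vectorized reverse accumulation. The tail therefore
never underflows for any valid query with N up to 10⁶, and the reported
`log10 p` agrees with exact big-integer rational summation to better than
10⁻¹⁰ over the fully enumerated N ≤ 60 query space (a test oracle that is
independent of the implementation). Values at or below the support floor
(k ≤ max(0, n−(N−K))) are returned as exactly 0 (p = 1). The reported
`percent` is 100·k/n and `fold` is (k/n)/(K/N); significance defaults to
the p < 10⁻⁶ asterisk rule used for overlap displays.

## Transcriptome structure

The recipe follows the classic expression-clustering workflow: genes
below 10 FPKM in every condition are removed (threshold applied to
condition means, inclusive at the boundary); values are
log₂(x + 1)-transformed; each gene row is centered on its mean log — the
log of the geometric mean across conditions — and, by default, scaled to
unit Euclidean norm ("normalize genes" semantics; toggleable). Log base 2
and pseudocount 1 are package choices where the upstream convention is
unstated. Condition structure is summarized by the pairwise Pearson matrix
and an average-linkage tree on 1 − r, and by PCA variance fractions
(SVD of the column-centered condition × gene matrix). Gene clustering
uses average linkage on 1 − r between gene rows, cut by `maxclust`;
rows are sorted lexicographically by gene id before linkage so the merge
order and labelling are fully deterministic, and constant rows (undefined
correlation) are excluded with a warning. The default cluster count is 6,
matching the number of major expression clusters the network's genes form,
but is an ordinary parameter. Trees export to Newick with branch lengths
equal to height differences.

## TF targets and feed-forward loops

TF modules consume flat ChIP-derived target lists; peak coordinates,
distances and binding strengths are not modeled. Overlap significance
reuses the enrichment module with the network gene set as category.
A feed-forward loop requires the master TF to bind the intermediate TF's
own gene; each shared target of the two TFs (optionally restricted to the
network) yields one loop instance, with the intermediate's own gene
excluded to avoid self-loop artifacts.

## Synthetic data

Generators are pure functions of (config, seed) built on
`numpy.random.default_rng`; a bundle derives four sub-seeds from one base
seed via `SeedSequence` (kept below 2³¹).

- **Network**: one reaction per gene (so gene counts are exact and
  validation is clean by construction), compartments drawn at the curated
  proportions ≈ 50/17/33%, pathways from a configurable mixture.
- **Expression**: replicate FPKM = 2^(baseline + effect·planted + noise),
  baseline ~ N(5, 1.5²) per gene on the log₂ scale, noise ~ N(0, 0.3²)
  per replicate, three replicates, planted log₂ effect 3 applied to a 30%
  share of network genes per non-control condition; the NoC and sucrose
  controls are never induced, so planted genes are true two-control
  regulon members.
- **Evidence**: per-type Bernoulli flags at prevalences
  (0.86, 0.63, 0.40, 0.11, 0.67), mirroring the observed support fractions
  145/106/68/19/113 of 168, rendered down to sub-evidence columns that the
  scoring rules invert exactly (round-trip identity). Planted proteomic
  support for non-extracellular genes is rendered as increased abundance
  rather than secretome detection so the re-annotation rule stays inert on
  simulated data.
- **TF targets**: the number of network-drawn targets is sampled
  hypergeometrically with an effective category of
  round(overlap_fraction·N) genes — exactly null-calibrated when the
  fraction equals the network's genome share, planted enrichment when
  larger. The target count is clamped to the genome size for compact test
  configurations.

What the generator does **not** emulate: read-level sampling, gene-length
and library-size effects, count overdispersion, correlated co-regulation
beyond the planted block structure, and biological covariance between
evidence types. Passing recovery tests therefore demonstrate pipeline
correctness and statistical calibration under the stated model, not
performance on real RNA-seq.

## Problem sizes and numerical choices

The test suite runs the recovery experiments at the generator's default
genome of 2000 genes (50 seeds), the exact-oracle enumeration over the
complete N ≤ 60 query space, and the null calibrations at 200–2000 draws;
the acceptance script uses 25 seeds for recovery and a 9758-gene genome
for the simulated TF analysis. Correlation distance matrices are
symmetrized and clipped at 0 before linkage to absorb floating-point
noise; Welch p-values on identical replicate vectors (NaN) are mapped to
1; BH uses `statsmodels.multipletests(method="fdr_bh")`.

## Known limitations

- The exact Welch fallback is underpowered at three replicates relative
  to dispersion-sharing DE engines: with the default planted effect
  (log₂FC 3) and noise (sd 0.3), the raw-p distribution of planted genes
  straddles the BH step-up cut at genome scale, and pooled two-control
  recovery sensitivity is far below what a moderated test would achieve
  (the false-discovery proportion stays at 0). Users with real data
  should supply precomputed differential-expression tables, which always
  take precedence.
- Two published regulon percentages (mannan 29%, xyloglucan 43%) are not
  equal to 100·k/n under any universe consistent with the printed counts;
  the package reports 100·k/n throughout, matching the Avicel usage.
- Cluster membership for k clusters depends on the average-linkage tie
  order; determinism is guaranteed (sorted input, fixed algorithm), but
  alternative lexicographic tie-break conventions could label borderline
  merges differently.
- The curated network tables themselves are not bundled; published totals
  (202/168, 101/35/66, 103/19/46, regulon sizes, support counts) are
  reproduced exactly only when a transcription of those tables is
  supplied, as exercised with synthetic stand-ins carrying the same
  marginals in the test suite.
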