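# Methods

## Scope and model

`entryscreen` implements the statistics of a phage host-factor entry
screen and its companion analyses. Three experimental readouts are
modelled and analysed end to end:

1. **Tn-Seq/BarSeq enrichment.** A pooled library of barcoded transposon
   insertions is challenged with phage. Cells carrying an insertion that
   disrupts a gene the phage needs for infection survive; nearly everyone
   else dies, escaping only at a small rate ε. Barcode abundance is read
   out by amplicon sequencing before (no-phage control) and after
   selection.
2. **Pull-down spectral counts.** Proximity-labelling or crosslinking
   pull-downs are quantified as spectral counts per protein per sample;
   enrichment near a membrane-anchored bait is expressed as a pseudocounted
   log2 ratio of bait over control.
3. **Homolog family architecture.** A family of homologs of a
   membrane-anchored nuclease is dereplicated, aligned in reference
   coordinates, and summarized: per-position identity, region length
   distributions, transmembrane-segment categories, and greedy coverage of
   domain hits.

## Enrichment statistic

Counts in each condition are normalized as

    log2( (count / Σ_condition counts) × 10^6 + 1 )

with the +1 inside the logarithm (a zero count maps to exactly 0; the
value is *not* `log1p` of CPM times a scale). For each phage condition an
ordinary least-squares line with intercept is fit with the no-phage
condition as the independent variable. The intercept makes the
residual-sum-zero identity hold and is the default convention when only
"linear regression" is specified. Each barcode's residual is its log2
deviation from the no-selection expectation; residuals are averaged
(unweighted) per gene into enrichment scores. Intergenic barcodes are
counted but excluded from gene scores. Zero-count barcodes are retained
by default (they contribute a point near the origin); an optional
`min_total` filter exists but is off, since no low-count filter is part
of the method. Scores are descriptive ranks — no p-values or
multiple-testing machinery. Ties in the score ordering break
lexicographically by gene id so output is reproducible.

## Barcode extraction and counting

Reads are `pre_flank + barcode + post_flank`. The pre-flank may sit at
any offset; among placements whose combined pre-flank and post-anchor
(first ≤8 bases of the post-flank) substitutions fit the
`max_flank_mismatch` budget, the fewest-mismatch placement wins, ties to
the smallest offset. Counting is closed-pool: barcodes absent from the
characterized library are never added as rows. The default policy is
exact matching; `correct1` additionally assigns an observed barcode to a
known barcode iff exactly one known barcode is within Hamming distance 1
(ambiguous observations are discarded and reported). Per condition,
assigned + discarded + unextracted always equals total reads.

## Spectral-count ratios

Proteins with fewer than `min_count` (default 50) spectral counts in
every sample are excluded from ratio reporting; retained counts are never
altered and the filter is idempotent. The ratio is
`log2(a + pc) − log2(b + pc)`, computed as a difference of logarithms so
swapping numerator and denominator negates every value bitwise.
Pseudocount profiles: 1 for proximity-labelling tables (where only "a
pseudocount" is conventional), 0.5 for crosslinking tables; both are
plain parameters.

## Alignment, identity and dereplication

`pairwise_identity` uses a fixed-scoring global alignment: match +1,
mismatch 0, linear gap −1 per gap column. Among optimal-score alignments
the one with the most identical columns defines the result; given the
score and the match count, the gap and column counts are determined, so
identity (matches / columns) and coverage (residue-residue columns /
shorter length) are unique and the choice needs no traceback. The DP
folds the lexicographic (score, matches) objective into one integer.
Dereplication is greedy: sequences are scanned longest first (ties by id
ascending) and each joins the first representative met at identity ≥ 0.95
and coverage ≥ 0.90 (the conventional collapse thresholds), else starts a
new cluster. The scan order makes the output deterministic.

## Identity profile and regions

The per-position profile is **reference-match identity**: at each
reference position, the fraction of non-reference rows whose residue in
that alignment column equals the reference residue, with gaps counted as
mismatches. Consensus-based identity was considered and rejected — the
plot is numbered in reference coordinates, so the reference is the
natural comparator. A centred rolling mean (default window 5) is
truncated, not padded, at the ends, so the profile length equals the
reference length. Region lengths count a homolog's non-gap characters in
the alignment columns spanning the region's reference positions;
insertion columns after a region's last reference position attach to that
region (and pre-reference columns to the first region), so lengths over a
full tiling partition each homolog's residues exactly. Protein
coordinates are 1-based inclusive throughout; genome coordinates are
0-based half-open.

## Transmembrane segments and hit coverage

TM annotations are consumed as input tables (they normally come from an
external predictor); a desk-scale hydropathy predictor is included:
Kyte–Doolittle mean over a 19-residue window, threshold 1.6, with maximal
runs of above-threshold windows merged and each run's full span reported.
It is a simple sliding-window method, adequate for synthetic fixtures,
not a replacement for modern predictors on real proteins. Domain-hit
coverage keeps hits with p < 1e-5, then repeatedly takes the hit present
in the most remaining homologs (ties to the lexicographically smallest
name) and removes the homologs containing it; each homolog is counted
once. Clade grouping takes single-linkage components at identity > 0.90;
cross-clade pairs at ≥ 0.20 identity are reported and both clades flagged
non-conforming rather than merged, because the separation condition is a
validity check, not a clustering rule. A region-restricted identity mode
supports comparisons over a stated residue window.

## Synthetic data: what it emulates and what it does not

* **Library and selection.** Pre-selection clone abundances are
  log-normal (σ = `abundance_dispersion`, default 1.0) — the standard
  clone-skew model; insertion positions are uniform, and assignment to
  genes is purely positional (strand ignored). Selection is modelled as
  reweighting each barcode by its survival weight (1 in required genes, ε
  elsewhere) followed by a multinomial draw at the requested depth. This
  matches the effective statistics of plating, challenge and scraping;
  it ignores double infections, growth differences between survivors,
  and bottleneck drift, so passing recovery tests shows the statistic
  works under multinomial sampling noise, not under every real-library
  artefact.
* **Reads.** Substitution errors only, no indels — sufficient to
  exercise flank-anchored extraction; quality scores are placeholders.
* **Spectral counts.** Per-protein baselines are gamma-distributed
  across proteins (shape 2, a moderate spread) with Poisson counts;
  planted proteins multiply their bait-sample mean by the fold change.
  No peptide-level structure, shared peptides, or batch effects.
* **Homolog families.** Homologs derive from a random reference by
  per-region substitutions plus one N-terminal insertion or deletion (≤
  `nterm_length_jitter`, placed just after the first reference position
  so it lands inside the first region), giving a divergent variable-length
  N-terminal region and a conserved C-terminal domain. TM segments are
  placed within the first 70 residues with lengths in [10, 20]. The
  default simulation fractions for one and two TM segments are 0.59 and
  0.07, the category proportions characteristic of this protein family.
  The generator emits the exact induced alignment, so profile and
  region-length code is tested against truth, not against a heuristic
  aligner.

Every generator is a pure function of (seed, parameters); count-table
column sums equal requested depths exactly; truth tables suffice to
recompute all generated observables.

## Problem sizes and numerical choices

The standard screen scenario is 200 genes, 3,000 insertions, 2 required
genes, ε = 1e-3 and sequencing depth 1e6 per condition — a desk-scale
screen with per-gene barcode counts (~13) and signal-to-noise typical of
a real BarSeq experiment. Recovery is assessed over 20 seeds (required
genes top-2 in ≥19/20), with null calibration at ε = 1 (no |score|
beyond 5 score-SDs in ≥19/20). Regression uses `scipy.stats.linregress`;
a control column with zero variance (including underflow) is a hard
error. Normalization agrees with direct evaluation of the formula to
1e-12. Alignment oracles are exhaustive path enumeration (lengths ≤ 5)
and an independent memoized recursion (lengths ≤ 8).

## Known limitations

* The enrichment statistic assumes one shared control condition and
  unweighted gene averaging; replicate-aware or variance-stabilized
  variants are out of scope.
* The hydropathy TM predictor over-extends segments into flanking polar
  residues by up to ~6 positions (window overlap), so its spans cover
  rather than tightly delimit hydrophobic runs.
* Dereplication is greedy and scan-order defined, not a globally optimal
  clustering; representatives are below-threshold pairwise only in the
  scan order's sense.
* Essential genes cannot show enrichment in a transposon screen by
  construction; the simulator does not model essentiality.
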