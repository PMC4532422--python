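# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitohet`, and what the synthetic-data experiments do and do not show
about real data.

## Coordinates and reference model

All public coordinates are 1-based inclusive positions on the 16,569-bp
circular mitochondrial coordinate system (rCRS / NC_012920).  Positions ≤ 0 or
> 16,569 wrap modulo the genome length (`normalize_circular`); no 0-based
interval arithmetic appears in any interface.

The gene annotation ships as a fixture table (`src/mitohet/data/regions.tsv`)
and is the single source of truth for region lookups.  Standard rCRS gene
boundaries are edited into a strict partition: where the canonical annotation
overlaps (MT-ATP8/MT-ATP6, MT-ATP6/MT-CO3, MT-ND4L/MT-ND4, MT-TI/MT-TQ,
MT-TC/MT-TY), the overlap is assigned to the upstream feature and the
downstream protein gene keeps its true reading frame through a `frame` offset
column, so codon phase at position *p* is `(p − start + frame) mod 3` (and
`(end − p + frame) mod 3` on the light strand).  Intergenic spacers and the
light-strand replication origin are carried as control-class rows; a variant
inside a trimmed overlap is classified in the upstream gene's frame only.
Hypervariable segments HVS-I/II/III and their homopolymeric C-stretches are
sub-features of the control region used for labelling, not partition members.
The partition property (every position in exactly one region; relative region
lengths summing to 1) is enforced at load time and by tests.  The published
"fraction in the control region"-style statistics depend on the boundary
convention chosen here (control region = 16024–576 plus spacers); this is a
documented fixture choice, not an inferred one.

Coding effects use the vertebrate mitochondrial genetic code (NCBI table 2).
Codons truncated at a gene's 3′ end (incomplete stop codons) are padded with
`A`, mirroring transcript polyadenylation.  Single-base indels in protein
genes classify as frameshifts; other regions return their region class.

The real reference sequence is not bundled.  Every sequence-dependent test
runs on synthetic full-length genomes (`synthetic_genome`, random sequence at
mtDNA-like 44% GC, labelled synthetic); annotation-dependent behaviour needs
only the boundary fixture.  Users supply their own reference FASTA for real
data.

## Pileup

Only bases with PHRED base quality ≥ 30 and mapping quality ≥ 30 are counted
(both configurable).  N bases, deletions, reference skips and inserted bases
contribute nothing — the caller targets point substitutions only; length
heteroplasmy enters the cohort layer solely as externally supplied
annotations.  Both mates of overlapping read pairs are counted and duplicates
are not removed; both choices are deliberate defaults so counts are
reproducible from the BAM alone.  BAQ recalibration is off by default and
available as a flag (delegated to htslib); the artifact diagnostics are
defined with BAQ off.

## Dual-strand calling

Let f⁺ and f⁻ be an allele's count fractions on the two strands.  A site is
called when some allele other than the pooled major has min(f⁺, f⁻) ≥ t with
t = 0.01 by default ("at least" ⇒ closed bound).  Zero depth on either strand
yields an explicit `insufficient_coverage` no-call.  When several non-major
alleles pass, the reported minor is the most frequent pooled one, ties broken
toward the higher worst-strand fraction, then alphabetically (triallelic sites
are not expected in practice).

Two level conventions are carried on every call because published tables mix
them: `level_pct`, the pooled percentage of the most frequent non-reference
allele (a 87.02% value means the reference base is the 12.98% minor); and
`minor_pct = min(level, 100 − level)`, used for the low/high classification at
the 10% boundary (`low` iff minor < 10).  Internal arithmetic is full
precision; output TSVs round to two decimals.

## Artifact filters

The published artifact instances give examples rather than thresholds, so the
defaults are the instances' envelope and all are configurable:
recurrence in ≥ 8 samples at minor ≤ 5% (`phantom_context`, context window
9 bp, circular), strand-drop ratio ≤ 0.8 against the flanking median of 5
positions per side with the other strand ≥ 0.9 (`strand_drop`), satellite
correlation ≥ 0.9 over ≥ 3 anchor-positive samples (`correlated_neighbor`),
primer zone 2523–2667 and a 5-bp circular-edge margin.  `phantom_context` and
`strand_drop` exclude only low-level calls (minor ≤ 5%) — a genuine high-level
heteroplasmy at an artifact-prone position survives with the flag attached;
zone and satellite flags exclude outright.  Filtering partitions the input
(pass ∪ excluded = input) and is idempotent on the pass set.  Recurrence-based
flagging requires a cohort; single-sample runs can only apply strand-drop and
zone filters.

## Method agreement

Below-LOD measurements are substituted by LOD/√2 before summaries (10/1.414 =
7.07 at the default 10% Sanger LOD); LOD/2 is available as `rule="half"`
because the two conventions coexist in the literature (and, inconsistently, in
the source material for this pipeline — the explicit √2 arithmetic is taken as
authoritative).  The empirically observed 7% Sanger limit can be passed as
`lod=7`.  Limits of agreement use the fixed 1.96 normal quantile, not a
t-quantile, matching the d̄ ± 1.96·SD definition; `pct_within` counts pairs
inside the closed interval.  Zero-variance differences collapse the limits
onto the mean and flag the bias t-test as degenerate rather than emitting a
spurious p-value.  Correlation can be computed on substituted or
mutually-detected pairs — both are exposed since published correlation values
rarely state which was used.

## Cohort classification

Per-patient, per-variant records store one level per tissue class with two
distinct missingness marks: `n.a.` (tissue unavailable — excluded from all
denominators) and `n.d.` (sequenced but below the 1% threshold — treated as
absence for classification, never imputed as 0 in means).  A detected level is
heteroplasmic when its minor component is ≥ 1%.  Classification:

1. `germline_homoplasmic` — detected and homoplasmic in every observed tissue;
2. `germline_heteroplasmy` — detected in a benign-side tissue (margin, blood,
   benign node) and either also present in a cancerous tissue or detected in
   ≥ 2 benign-side tissues;
3. `somatic_shared` — absent from benign-side tissues, present in ≥ 2
   cancerous tissues;
4. `somatic_private` — otherwise.

Clause 2's "≥ 2 benign-side tissues" extension covers records whose cancerous
tissue was never sampled (e.g. a variant seen in margin and blood only), which
a strict benign-AND-cancer rule would mislabel as somatic.  Dysplasia is
grouped benign-side; second primaries count as cancerous.

Chi-square tests on 2×2 tables use **no** Yates continuity correction — the
uncorrected statistic is what reproduces published p-values on low/high level
tables; Fisher's exact test replaces it in the enrichment test when any
expected cell is below 5.  Level histograms use 1-percentage-point bins.  The
gene-region spectrum keeps each protein gene and each rRNA separate, pools
tRNAs, and pools control region plus spacers; length correlations are
restricted to protein genes by default.  Both groupings are configurable since
published correlation values do not state the exact grouping.

QC profile splitting assigns every homoplasmic variant to both profiles and a
heteroplasmy's major/minor alleles to the major/minor profile respectively, so
the union reconstructs the call set.

## Synthetic experiments

The mixture simulator draws per-strand depth Poisson(17,500) (≈ 35,000× total,
the study-scale coverage; 50/50 strand split), minor-haplotype counts
Binomial(depth, f) at the differing sites, and uniform miscalls at 5×10⁻⁴ per
base.  That error rate is a typical Illumina substitution-error figure after
Q30 filtering; it contributes ≈ +0.017 percentage points to a 1% minor
fraction (miscalls from the major allele land on the minor base at e/3),
visible but well inside the 3-standard-error acceptance band.  An optional
copy-number skew converts mixing fractions defined on total DNA into mtDNA
molecule fractions; the default 1.0 assumes equal mtDNA content per unit DNA.

The cohort simulator encodes the study conditions as defaults: 28 patients,
benign margin + primary tumor for everyone, blood/recurrence/metastasis at the
cohort's observed frequencies (4/28, 6/28, 5/28); ~3 germline low-level
heteroplasmies per patient (truncated lognormal, median ≈ 3.5%, floor 0.3% so
some germline variants sit below the detection limit and re-surface as
apparent somatic events after clonal expansion — the mimicry the cohort layer
is designed to expose); ~3 somatic mutations per tumor (truncated lognormal,
median 10%, floor 1.5%), carried into recurrences/metastases with probability
0.7 at a lognormal expansion multiplier centred on 2.8-ish factors (μ = ln
2.5, σ = 0.4, matching the observed 1.4–4.2 range); and two artifact positions
(72 and 414) injected in ~40% of samples at 1–2% with a 0.52 forward-depth
factor.  Measurement noise is binomial at the study coverage and the 1%
dual-strand rule is applied, so simulated call sets have realistic detection
dropout.  Truth labels reflect the realised placement.

What this does *not* model: read-level effects (alignment error, NUMT
contamination, context-dependent error spectra — artifacts are injected
explicitly rather than emerging from an error model), length heteroplasmy,
UV-like mutational signatures, and within-tissue subclonal structure.  Passing
recovery tests therefore demonstrates the correctness of the counting,
calling, filtering and classification logic under the stated sampling model,
not robustness to every failure mode of real libraries.

## Problem sizes and determinism

Every generator is deterministic under its seed (`numpy` Generator).  The test
suite and the acceptance script run whole-genome simulations (16,569 positions
× 2 strands) in milliseconds, so the validation uses full-scale coverage and
genome size; the mixture acceptance computation averages five replicate
mixtures of 27 sites, and the detection-rate check uses 20 seeded replicates.
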