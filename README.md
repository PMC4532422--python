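# mitohet

Strand-confirmed detection and quantification of low-level mitochondrial DNA
(mtDNA) heteroplasmy from high-coverage sequencing counts, with systematic-
artifact exclusion, Sanger-vs-NGS method-agreement statistics, and multi-tissue
tumor-cohort analysis of somatic versus germline heteroplasmy dynamics.

## The problem

Heteroplasmy — the coexistence of two mtDNA allele populations in one sample —
is a sensitive marker of clonal processes in tumors, but levels of interest sit
far below the ~10% detection limit of Sanger electropherograms. High-coverage
sequencing (~35,000 reads per base over the 16,569-bp circular genome) can
quantify mixtures down to 1%, provided systematic artifacts are controlled.
`mitohet` implements that workflow for researchers analysing paired
tumor/normal mtDNA profiles:

* **Pileup**: per-position, per-strand base counts from SAM/BAM or TSV, keeping
  only bases with PHRED ≥ 30 and mapping quality ≥ 30.
* **Calling**: a site is heteroplasmic when the same minor allele reaches the
  threshold *t* (default 1%) on the forward **and** the reverse strand
  separately:  call ⇔ min(f⁺, f⁻) ≥ t.  Each call carries the mutated-allele
  level L (% of the non-rCRS base, may exceed 50) and the minor component
  min(L, 100 − L) ≤ 50.
* **Artifact filters**: recurrent low-level positions sharing a sequence
  neighbourhood (phantom mutations), one-strand coverage drops, satellite
  positions correlated with an anchor artifact, primer-zone and circular-edge
  masking.
* **Method agreement**: below-LOD values substituted by LOD/√2 (10/1.414 =
  7.07), Bland–Altman limits of agreement d̄ ± 1.96·SD, one-sample t-test for
  fixed bias, Pearson correlation.
* **Cohort analysis**: germline/somatic classification of per-patient variant
  records across tissue classes, clonal-expansion trajectories, low/high-level
  (10% boundary) chi-square comparisons, gene-region mutation spectra, and
  major/minor contamination-QC profile splitting.
* **Synthetic data**: seeded generators for two-haplotype mixture dilutions
  (1+1 … 1+99) and multi-tissue cohorts with ground-truth labels.

## Worked example

Simulate the 1+99 mixture-dilution validation and call it at a lowered 0.8%
threshold:

```bash
mitohet simulate mixture --ratio 1:99 --coverage 35000 --seed 7 --out mix/
mitohet call --pileup mix/pileup.tsv --threshold 0.008 --sample mix --out mix/calls.tsv
```

which prints `27 heteroplasmy calls written to mix/calls.tsv`; the calls table
starts

```
sample  pos   ref major minor level_pct minor_pct minor_fwd_pct minor_rev_pct depth_fwd depth_rev filters
mix     88    C   C     G     0.97      0.97      0.92          1.01          17422     17603     PASS
mix     920   T   T     G     1.06      1.06      1.01          1.11          17563     17342     PASS
```

All 27 sites at which the two mixed haplotypes differ are recovered, each with
an estimated minor component scattered around the true 1% (binomial noise at
~35,000× is ±0.05 percentage points per site).  The same library calls work
from Python:

```python
import mitohet as mh

genome = mh.synthetic_genome(seed=7)
design = mh.make_haplotype_pair(genome, n_diff=27, seed=7, fraction_b=0.01)
print(mh.mixture_recovery(design)["mean_minor_pct"])  # ~1.0
```

For cohort work, `mitohet cohort --samples samples.tsv --out report/`
classifies every per-patient variant record as germline (homoplasmic or
heteroplasmic), shared somatic or private somatic, and writes per-tissue level
tables with explicit `n.a.` (tissue unavailable) / `n.d.` (below the 1%
threshold) marks.

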