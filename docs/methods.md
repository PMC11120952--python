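# Methods

This note documents the models and procedures implemented in `pavscape`,
the defaults chosen where the workflow leaves room, and the limits of what
the synthetic panel can demonstrate.

## Scope and data model

A PAV (presence/absence variation) is a deletion or insertion of at least
50 bp, represented on 1-based inclusive coordinates: a deletion spans
`[start, end]` with `end > start` and `SVLEN = -(end - start)`; an
insertion is anchored at one base (`end = start`) with a positive `SVLEN`.
Samples are fully inbred lines, so genotypes are binary presence/absence
(plus missing), not diploid dosages; MAF on samples and on alleles
coincide under this coding. Supported interchange formats are a VCF 4.2
dialect with symbolic `<DEL>`/`<INS>` alleles and `SVTYPE`/`END`/`SVLEN`
INFO keys, GFF3 gene models, tab-separated phenotype tables (replicate
columns `trait.repK` are averaged), and 0-based BED for region output.
Multi-allelic SV rows, breakend notation and SV types other than DEL/INS
are out of scope (foreign types are skipped and counted).

## Caller merging

Records from all callers are pooled (optionally PASS-only, the default)
and clustered by single linkage under the relation *same chromosome, same
SV type, |Δstart| ≤ D and |Δend| ≤ D*, with D = 1000 bp by default — a
conventional proximity threshold for short-read SV merging; the callers'
true concordance scale is not identifiable from the merged output, so D is
configurable. Components are found by a position-sorted sweep with
union-find (|Δstart| ≤ D is necessary for linkage, so only a bounded
window of predecessors needs checking); the result is provably identical
to all-pairs connected components and independent of input order, which
the test suite verifies against a networkx oracle. Single-linkage chains
can exceed D end to end; this matches common SV-merging tools and is
accepted.

Consensus coordinates are per-field medians of cluster members (even
cluster sizes: the midpoint, floored on half-integers, for exact
cross-platform reproducibility). Genotype union across members is
presence-dominant — present if any member calls present, else absent if
any calls absent, else missing — maximizing sensitivity, which is the
point of merging two callers in the first place. Caller-specific
re-genotyping workflows are not emulated; callers are black-box callset
producers.

Locus filters: keep a locus iff MAF ≥ 0.01 (inclusive) and missing
fraction < 0.40 (strict, per the printed "< 40%" convention). An
all-missing locus has undefined MAF and is removed.

## Landscape statistics

**Size spectrum.** Counts per half-open bin; default bins are log2-spaced
from 50 bp. The short-PAV share counts sizes in [50, 1000] bp.

**Context classes** (non-exclusive; a PAV carries every class it overlaps
by ≥ 1 bp): `flank_3kb` (± 3 kb of a gene, excluding any gene body),
`CDS`, `UTR`, `intron` (gaps between exons), `intergenic` (any base
outside all gene bodies and flanks). Exonic bases without a CDS/UTR
annotation count as coding, which also covers the exonless-gene fallback
(whole span = one exon). Insertions are classified as 1 bp breakpoints.
"Genic" means carrying any of the four non-intergenic classes.
Percentages are per-class carrier fractions and may sum above 100%.

**Hotspots.** Breakpoint = the PAV start coordinate, counted once in
every window containing it (1000 kb windows, 500 kb step, so most points
fall in two windows; a `--both-ends` notion was considered and rejected to
keep one count per PAV). Windows are ranked genome-wide (per-chromosome
ranking available); with n windows the cutoff is the k-th highest count,
k = ⌈0.10 n⌉; ties at the cutoff are all kept (determinism over arbitrary
dropping) but zero-count windows never qualify (prevents degenerate
all-hotspot output on sparse genomes). Overlapping or touching hotspot
windows on a chromosome merge into maximal regions.

## Association scan

The engine is a per-locus fixed-effects OLS fit
`trait ~ intercept + locus + PC1..PCk` (k = 3 by default), with a
two-sided p from the locus coefficient's t statistic. A multi-locus
iterative engine used in large panels is deliberately replaced by this
transparent single-locus model: it preserves the inferential structure
(PC correction for population structure plus permutation FWER control)
while being exactly testable — with no covariates and a binary locus the
scan reduces in closed form to the pooled two-sample t-test, which the
suite asserts to 1e-10. The scan is vectorized via Frisch–Waugh–Lovell:
phenotype and genotypes are residualized against an orthonormal basis of
the covariate design, and each locus is then a simple regression.

Missing genotypes are mean-imputed per locus before PCA and scanning;
loci monomorphic after imputation are flagged unusable. PCA is the SVD of
the column-centred matrix; component signs are fixed (largest-magnitude
loading positive) and variance proportions are eigenvalue shares summing
to 1.

**Permutation threshold.** For each of B permutations (default 1000) the
covariate-residualized phenotype is permuted across samples and the full
scan repeated (Freedman–Lane-style conditional permutation; raw-label
permutation available); the genome-wide maximum −log₁₀(p) is recorded,
and the threshold is the empirical (1 − α) quantile of the B maxima
(α = 0.05), using the type-1 order-statistic convention (with B = 1000,
the 950th order statistic). The max-statistic construction is the
standard FWER control; a pooled-quantile variant over all
locus × permutation p-values exists behind a flag because the source
description admits both readings, but it is not the default. Significance
is `−log₁₀(p) ≥ threshold` (ties included).

**Gene mapping.** A significant PAV maps to every gene whose span ± 3 kb
overlaps it — the same geometry used for the context classes.

## Haplotype comparison

Samples split into non-carriers (group 1, reference) and carriers
(group 2) at one PAV; samples with missing genotype or phenotype are
excluded. The trait contrast is a two-sided Welch t-test
(Welch–Satterthwaite df), matching the default two-sample behaviour of
the statistical environment such analyses are usually run in; the
pooled-variance Student variant is available. Both groups need ≥ 2
members. The null rejection rate is verified at 5% ± 2 points over 2,000
simulated replicates.

## Synthetic panel

The generator emulates the statistical structure of a resequenced panel
of 148 improved inbred cultivars; all defaults below are the package's
study conditions.

* **Genome**: 3 chromosomes × 10 Mb; 900 non-overlapping genes
  (2–8 kb, 1–5 exons, terminal UTRs where the flanking exons allow,
  CDS elsewhere) placed by Dirichlet-distributed gaps — a placement
  failure (genome too small) raises an explicit error.
* **PAV sizes**: truncated Pareto on [50 bp, 100 kb] with tail exponent
  0.42 — i.e. geometric decay across log-spaced bins, the qualitative
  shape of observed PAV size spectra — putting ≈ 74.6% of sizes in
  50–1000 bp. 97% of PAVs are deletions.
* **Positions**: uniform per base, except `enrichment_factor`-times
  denser inside planted hotspots; the default plants one 8× hotspot over
  20–30% of the last chromosome. An optional minimum same-chromosome
  start separation (off by default) makes distance-based merging
  information-preserving for recovery tests; it is infeasible inside
  dense hotspots and is not used there.
* **Population**: two subpopulations at a 109:39 split; each locus draws
  an independent presence frequency per subpopulation from U(0.05, 0.95),
  giving strong, PC-detectable structure. The real panel's frequency
  spectrum is unknown; this prior is a stand-in, not a calibrated model.
* **Callers**: two pseudo-callers share the truth; each drops whole loci
  at rate 0.05, jitters breakpoints with N(0, 30 bp) rounded and clamped
  (size floor preserved), tags 5% of records LowQual, and blanks 2% of
  genotypes. Disagreement between callers arises only from this noise,
  which isolates merge-logic testing from caller modelling.
* **Traits**: five quantitative traits on their natural scales
  (days to heading 96.8 d, plant height 91.3 cm, flag leaf length
  26.9 cm, flag leaf width 1.4 cm, panicle number 9.2). Latent score =
  Σ causal-effect × presence + subpopulation shift (0.5 SD) + N(0, 1)
  noise, centred and affine-mapped per trait; affine mapping changes no
  r², t or p statistic. Causal effects are back-computed from a target
  variance-explained fraction v (default: one random polymorphic locus
  per trait at v = 0.25): with total latent variance σ²_T = σ²_noise /
  (1 − Σv), β = √(v σ²_T / var(g)). In the noiseless limit this
  decomposition degenerates and a unit latent variance is used instead.
  Infeasible targets (monomorphic locus) raise an error.

Everything is a bit-deterministic function of the configuration seed
(stage-specific child generators, so stages are independently stable).

**What the panel does not emulate**: read-level error, sequencing depth,
linkage disequilibrium along chromosomes, multi-allelic loci,
genotype-calling asymmetries between deletions and insertions, and any
realistic gene-density or recombination landscape. Passing tests
demonstrate the correctness and calibration of the *algorithms* under
known structure — not that real-panel estimates would be unbiased.

## Problem sizes and numerical choices

Simulated scales are chosen so the full suite and the acceptance script
run in minutes on one core: the default end-to-end run uses 148 samples ×
2,000 true PAVs with 1,000 permutations per trait; distributional checks
use 10,000 PAVs; FWER calibration uses 200 replicates of 150 × 1,000 loci
with 200 permutations each; power checks use 50 seeds. p-values are
floored at 1e-300 before −log₁₀; quantiles are order statistics (lower
tie); consensus medians floor half-integers; cluster, region and output
orderings are fully specified so that repeated runs are byte-identical.

## Known limitations

* Inside dense hotspots, distinct true PAVs closer than the merge
  distance collapse into one locus; a causal PAV absorbed this way loses
  association power (observed in the worked example). This is a property
  of distance-based merging itself, not of the implementation.
* The single-locus engine does not model LD between PAVs (none is
  simulated) and estimates marginal, not conditional, effects.
* The permutation threshold is recomputed per trait; thresholds across
  correlated traits are not jointly controlled.
* Context percentages depend on the annotation's completeness; unanchored
  chromosomes classify as intergenic with a warning.
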