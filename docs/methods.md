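# Methods

## Splicing level

For each intron (junction) and sample the splicing level is
SPL = out / (out + in/2), where *out* counts uniquely mapping reads gapped
exactly across the intron and *in* counts reads covering the donor or the
acceptor boundary contiguously with at least 6 aligned nt on each side,
summed over the two sites. Dividing the splicing-in total by two averages
the retention evidence over the two splice sites, making the denominator
commensurate with the single per-junction excision count; under the
generative model below the plug-in SPL is then an unbiased estimate of the
per-sample splicing probability. Three deliberate conventions:

* **Missingness.** out = in = 0 yields a missing SPL, not zero — absence
  of coverage is not evidence of retention. Missing cells are excluded
  from medians and quantiles and count as "not above threshold" in
  prevalence rules (the prevalence denominator can optionally be restricted
  to observed samples).
* **Multimappers** are excluded from *out* by default
  (`include_multimappers` adds them).
* A read spanning **both** boundaries contributes 2 to *in* by default,
  once per site (`dedupe_spanning_reads` counts it once); a read spliced at
  a different junction still counts at a boundary its splice leaves intact.

## Region classification

GTF input (GENCODE dialect, exon/CDS/stop_codon features) is converted to
0-based half-open coordinates at parse time; UTRs are derived as
exon-minus-CDS split at the CDS boundaries, so explicit UTR features are
not required, and a missing stop codon is reconstructed from the CDS 3′
end with a warning. The stop codon is counted as CDS for exclusion
purposes. An intron is **3′ UTR-exclusive** when (a) it is fully contained
in the genomic span of at least one same-strand transcript's 3′ UTR and
(b) it overlaps zero CDS and zero 5′ UTR bases of any transcript. The
exclusion in (b) considers both strands by default because short-read
junction evidence is frequently strand-ambiguous; `stranded_exclusion`
restricts it to same-strand features. Containment (not mere overlap) in a
single transcript's 3′ UTR region is required; junction merging across
samples is by exact coordinates, with no boundary-wobble clustering.
Introns that touch a 3′ UTR without qualifying, or that mix region
classes, are labelled MIXED; introns overlapping nothing are NONCODING
(as are introns on chromosomes absent from the annotation, with a
warning, configurable to an error).

## Event-level rules

* **Discovery**: ≥ 2 junction reads and SPL > 10 % (both strict, in the
  same sample), on top of 3′ UTR exclusivity.
* **Common events**: SPL > 10 % in strictly more than half of the
  cohort's samples; the denominator includes missing samples
  (conservative).
* **Burden**: per sample, the number of 3′ UTR events over the number of
  junctions of any region class passing the same support rule; samples
  with fewer than 1,000 supported junctions are flagged as too shallow.
* **External support**: long-read (or annotation) support requires
  identical donor and acceptor coordinates on the same chromosome; strand
  is not compared, consistent with strand-ambiguous short-read junctions.

## Differential screen

Per event, tumour and normal SPLs (missing dropped) are compared with a
two-sided Mann–Whitney U test: exact enumeration when both groups have at
most 8 untied observations, otherwise the normal approximation with tie
and continuity corrections. Benjamini–Hochberg runs across the tested
events of one cohort; events with fewer than 3 observations per group are
reported untestable with NA p and excluded from the BH family size.
Significance additionally requires the tumour−normal and tumour−reference
median differences to agree in sign and at least one of them to exceed
0.05 in magnitude (strict). For matched designs of a few pairs, a
sign-flip permutation of paired differences (statistic: median paired
difference; exhaustive when 2^n ≤ n_perm, else seeded sampling) yields an
empirical per-event FDR — the mean null count of events at least as
extreme divided by the observed count, capped at 1. This permutation
construction is this package's explicit design for the small-cohort case.
Set overlaps use the upper-tail hypergeometric probability; the
RNA-binding-protein knockdown screen reuses the rank test per factor
against pooled controls.

## Over-/under-splicing calls

Quantiles use the nearest-rank method (the ceil(q·n)-th order statistic):
deterministic, interpolation-free, and well-defined for small normal
cohorts. The over cutoff is the **maximum** of the adjacent-normal and
reference-normal 90 % quantiles; the under cutoff defaults to the
**minimum** of the two 10 % quantiles — symmetric stringency, with a
`max` option since either reading is defensible. Comparisons at the
cutoffs are strict (a tumour equal to the cutoff is NEITHER). Calls are
made for the significantly dysregulated events by default
(`all_events` overrides). Under the null, a new sample exceeds the
nearest-rank q90 of n normals with probability 1 − ceil(0.9 n)/(n + 1),
about 0.10–0.12 at realistic n; the max-of-two rule pulls this slightly
below.

## Survival

Overall survival only. Univariate Cox proportional hazards with Efron tie
handling (lifelines); the covariate is the raw SPL in [0, 1], so the
hazard ratio is per full 0→1 change — no standardisation, keeping the HR
interpretable across events. Labels follow the raw Wald P < 0.05 rule
(UNFAVOURABLE when HR > 1, FAVOURABLE when HR < 1) with no multiplicity
adjustment, mirroring the screening convention for prognosis labels; a BH
column is emitted alongside for transparency. Guards: at least 20 samples
and 5 observed deaths, non-constant covariate, and non-convergence all
yield NS with a diagnostic flag rather than an estimate. Kaplan–Meier
half-splits send ties and the odd middle sample to the low group and use
the log-rank test; binary groupings (e.g. over-spliced vs rest) get both
a binary-covariate Cox fit and a log-rank p.

## Sequence features

Stop-codon distance is measured in mRNA (exonic) coordinates from the
first nt after the stop codon to the intron's 5′ splice site,
strand-aware; for events hosted by several transcripts the minimum is
reported (conservative for NMD). NMD is predicted when that distance
strictly exceeds 50 nt — the canonical last-exon-junction rule — so a
junction 11 nt downstream of the stop escapes it; the threshold is
configurable. Repeat overlap is the unioned fraction of intron bases
under RepeatMasker-style BED intervals, with an Alu flag when any
overlapping repeat name starts with "Alu".

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
per-event baselines p_e ~ Beta(2, 5) (right-skewed, mostly 0.1–0.5);
per-sample true levels Beta-distributed around the cohort target with
concentration 50 (SD ≈ 0.06 at p = 0.3, a plausible biological
between-sample spread); informative depth Poisson with mean 100 per event
per sample; out ~ Binomial(depth, p) and in = 2·(depth − out), the exact
inverse of the SPL formula's two-site convention. Defaults: 400 events,
70 % in 3′ UTRs with decoys in CDS, 5′ UTR and non-coding exons; 40
tumour / 40 normal / 40 reference samples; 5 % of events shifted +0.25 in
tumour median (targets clipped into [0.01, 0.95] with a warning);
survival exponential with log-hazard log(4) per unit mean-SPL over the
shifted events, uniformly censored. One locus reproduces the near-stop
geometry (5′ splice site 11 nt after the stop codon); remaining 3′ UTR
events draw stop distances from 5–400 nt and intron lengths 150–600 nt,
and about 30 % also appear as an annotated spliced isoform. Alu repeats
cover the middle half of half the 3′ UTR introns. All randomness flows
through one seeded generator; outputs are byte-stable per seed.

What the simulation does **not** model: expression covariance between
genes, strand-ambiguous or fuzzy junction boundaries, mappability and GC
biases, batch effects, non-proportional hazards, and isoform-level
competition between overlapping events. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its stated
assumptions, not robustness to those real-data artefacts.

## Problem sizes and numerics

The recovery and calibration checks run at 400 events × 120 samples
(power), 2,000 events × 90 samples (null FDR), 500 tumours × 3 seeds
(call calibration) and 300 patients × 50 seeds (Cox coverage) — sizes at
which the Monte-Carlo error of each assertion is small relative to its
tolerance while a full run stays interactive. Ties in rank tests fall
back to the corrected normal approximation; BH uses the standard step-up
with enforced monotonicity; quantile and threshold comparisons are strict
everywhere, so boundary values never flip a call; permutation FDRs and
the simulator derive all randomness from explicit seeds.

## Known limitations

Only GTF (not GFF3) annotation is supported; transcript assembly,
alternative-polyadenylation detection, isoform quantification,
covariate-adjusted survival and mixture-model dysregulation calls are out
of scope. The 50-nt rule is a proxy for NMD susceptibility, not a
mechanistic prediction, and Alu overlap is a descriptive feature, not an
inference about Staufen-mediated decay.
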