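# Methods

This note documents the models and procedures implemented in `sstrkit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Measurement model for Sanger SNP quantification

A bulk-population chromatogram over an edited locus is a mixture trace: at a
SNP position the wild-type and SNP channels carry peaks whose heights are,
to first order, proportional to the allele fractions — but scaled by a
position- and base-specific factor ("context multiplier") reflecting the
local sequence dependence of Sanger peak heights. The naive ratio
`H(snp)/(H(snp)+H(wt))` is therefore biased by the ratio of the two
multipliers.

The dual-control normalization removes this bias with two matched control
chromatograms sequenced over the same target: a pure wild-type (negative)
control and, per SNP, a pure-SNP (positive) control. Within each
chromatogram all heights are divided by the height of the anchor base (an
'A' at break-relative position −42, ten bases upstream of the most upstream
panel SNP), which cancels the chromatogram's overall amplitude. The sample's
relative wild-type peak is then divided by the negative control's, and its
relative SNP peak by the positive control's; because the controls share the
multipliers, the context factors cancel exactly, and

    editing = norm_snp / (norm_snp + norm_wt)

equals the allele fraction when the model holds. Assumptions: (i) the
controls are sequenced with the same primer/chemistry so multipliers are
shared; (ii) the anchor base is unedited and well resolved (zero or wrong
anchor base is an error, never silently rescaled); (iii) peak height is
linear in template fraction. Scale invariance (any one trace rescaled by a
constant leaves every estimate unchanged) holds by construction and is
asserted in tests.

The coordinate frame is 1-based over called trace positions; break-relative
coordinates are integers on the sense strand with 0 at the centre of the
staggered cut. Target location is ungapped with at most 2 mismatches (the
target is a fixed 75-nt sequence from the same locus; gaps are not
contemplated), and ambiguous placements are errors. For heavily edited
samples the target should be located on the negative control — base calls
at SNP positions can flip near 50% editing — and the shared placement
reused; the analysis drivers do this.

## Background noise model and SNP detection

Detection asks whether the SNP channel's percent signal exceeds background.
Background percent signals of non-consensus channels inside the analysis
window (default trace positions 200–400, chosen to calibrate the null
closely around the region of analysis; at least 50 positions required) are
modelled per base as zero-inflated gamma: a point mass at zero (empirical
fraction of exact zeros) plus a gamma fitted by maximum likelihood to the
nonzero values. A lognormal alternative is available both as a fitting
fallback and as a deliberately misspecified generator option. The detection
p-value is the null tail probability of the observed percent signal
(`p = (1 − π₀)·SF(obs)`, `p = 1` at zero signal), reported raw per SNP
(α = 0.05 by convention; multiplicity is the caller's concern). Reported
quality metrics: average percent signal over non-consensus channels in the
window; per-base model mu `(1 − π₀)·E[gamma]`; Filliben's probability-plot
correlation of the nonzero values against gamma quantiles at order-statistic
medians (ties at zero excluded; NaN below 3 points). Note that on an edited
sample the window contains genuine secondary peaks, which inflate the tail
of the fitted null and depress Filliben's correlation — a conservative
property inherited from fitting each chromatogram's own window.

## Editing symmetry

For a sense-strand ssODN, negative break-relative positions lie on the 5′
homology arm; for an antisense ssODN the arms swap. Position 0 sits on
neither arm: it is excluded from arm means but included in the ANOVA. The
position effect is tested by one-way ANOVA across panel positions over
biological replicates (positions with fewer than two replicates are dropped
with a warning); Tukey's HSD pairwise table is attached only when the ANOVA
is significant, mirroring conditional post-hoc reporting. The asymmetry
summary is mean(3′-arm)/mean(5′-arm) (NaN when the 5′ mean is zero).

Digestion efficiency from gel densitometry assumes intercalating-stain
intensity proportional to DNA mass. With the default
`mass_correction="length"` each band intensity is divided by its fragment
length before comparison (molar units; cut fragments averaged). Because a
single cut conserves total mass, the raw-intensity variant
(`mass_correction="none"`) gives identical efficiencies under this band
model; the switch exists because real densitometry with background
subtraction can break that equality and the convention used should be
explicit. The 3′-site efficiency is normalized to the 5′ site per
replicate; replicate normalized values are tested against 1 with a
one-sided (lesser) one-sample t test, the direction in which SDSA would
pull the value.

## Repair-outcome classification

Each colony amplicon read is oriented to its better strand and aligned
globally (match 2, mismatch −3, gap open −5, gap extend −2) against the
wild-type amplicon and the expected-edit amplicon (wild type with the
nuclease-targeted block replaced by the 24-nt non-homologous insert).
Categories, in precedence order:

1. **scarless SSTR** — perfect, gapless match to the expected edit across
   the edited window (replaced block plus a 5-bp flank margin);
2. **scarred SSTR** — at least `min_insert_match` (default 8) contiguous
   insert bases present but the edited window not perfect; the exact-substring
   scan is used alongside the alignment because local duplications can hide
   insert bases from a single alignment path;
3. **wild type** — perfect match to the wild type across the window;
4. **indel** — no insert evidence and an insertion/deletion overlapping the
   cut site (±5 bp);
5. **uncalled** — unalignable (identity < 0.7 against both references),
   shorter than half the amplicon, or fitting no rule. Uncalled reads are
   excluded from tally denominators, as only clean colony PCRs get
   sequenced in practice.

The 8-base insert-evidence threshold is a documented parameter, not an
inferred intent: "at least part" of a 24-nt insert is not quantified
anywhere authoritative, and 8 contiguous bases are long enough to make
chance matches in a ~1-kb amplicon unlikely (expected <0.1 per read) while
still counting partial incorporations. Population-level scarless SSTR is
resistance % × scarless colony fraction; the scarred and indel products are
defined identically.

## Plate-count statistics

Editing efficiency of a replicate is
`100 · (c_sel/v_sel) / (c_ns/v_ns)` (counts per plated µL, selective over
non-selective); undefined (missing) when the non-selective count is zero,
and deliberately not clipped at 100% in statistics. Outliers are flagged by
Tukey's fences (k = 1.5) with inclusive, linearly interpolated quartiles
(`p = (i−1)/(n−1)`, the spreadsheet PERCENTILE.INC convention — the
median-exclusive variant shifts fences detectably at these sample sizes),
only for groups with ≥5 replicates, and always retained downstream.

Dunnett's many-to-one comparison uses the pooled variance across all
groups and the equicorrelated multivariate-t distribution implied by the
group sizes (ρᵢⱼ = λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀))); the rectangle probability is
evaluated by scipy's quasi-Monte-Carlo multivariate-t CDF with a fixed
internal seed, so p-values are reproducible to ~1e-4. With one treatment
the test reduces exactly to the pooled two-sample t test (special-cased
analytically). Games–Howell uses Welch standard errors, per-pair
Welch–Satterthwaite degrees of freedom and the studentized-range
distribution with the full group count ("Tukey corrected"); identical
groups give q = 0, p = 1. Levene's test is mean-centred by default (a
`center` switch exists, since implementations differ); Shapiro–Wilk errors
on constant data.

## Synthetic-data generators

The generators define the study conditions under which the package is
validated; all randomness flows through one numpy generator per spec seed,
and identical seeds give byte-identical files.

**Traces.** A 500-nt template embeds the 75-nt target (break-relative −42
to +32) at position 285, so the region of analysis falls inside the default
200–400 calibration window. Context multipliers are lognormal per
(position, base) with log-SD 0.25 (0.3 in stress tests), frozen per
template and shared by the sample and both controls — exactly the artefact
the normalization corrects. Background noise on signal-free channels is
zero-inflated (π₀ = 0.35) gamma (shape 1.5, scale 0.004 on peak-proportion
scale; ≈0.6% mean percent signal, a clean-trace level), with a lognormal
alternative for misspecification tests. Optional multiplicative
peak-height jitter (`signal_noise_cv`, default 0 so algebraic identities
hold exactly; 0.03 in the replicate-level analysis drivers) emulates
replicate-to-replicate variability; under it the normalized estimate
scatters by roughly ±0.01–0.03 around truth. Not emulated: raw
electropherogram signal, dye mobility, basecalling errors, mixed-template
indel dephasing downstream of the cut. Passing tests therefore demonstrate
correctness of the quantification arithmetic and noise calibration, not
robustness to basecaller artefacts.

**Plate counts.** Non-selective counts are Poisson around the expected
colony number (default 2,000/plate); the cells committed to the selective
plate scale by the plated-volume ratio; resistant counts are beta-binomial
with the genotype's true efficiency as mean and overdispersion ρ (default
0.002, giving per-replicate CVs of order 10–20% at few-percent
efficiencies, comparable to biological replicate scatter). Default group
means are the terminally-modified-ssODN comparison layout (unmodified
8.4%, protected 12.3%, …) with its published per-group replicate counts.

**Colony reads.** A 400-nt wild-type amplicon (fixed internal seed) with
the cut at its centre; the expected edit replaces a 24-nt block with the
24-nt insert `CTAAGTAGTTGACATCGGATCCAA` (stop codons in all three frames).
Scarred reads keep 8–24 contiguous insert bases and acquire junction
deletions (≤6 bp), junction SNPs and/or local duplications (≤8 bp); indel
reads carry 2–12-bp deletions (or small insertions) at the cut; reads are
emitted on both strands. A scar draw indistinguishable from another
category at zero noise is regenerated (10 retries, then an error).
Sequencing noise is not simulated, so classifier accuracy on these reads
measures the decision rules, not robustness to read errors.

**Gel lanes.** Band intensity = fragment mass × gain with optional
multiplicative lognormal noise; planted site efficiencies are recovered
exactly at zero noise, making the normalized 3′/5′ value an algebraic
oracle (e.g. 0.72/0.80 = 0.90).

## Problem sizes and numerical choices

The test suite runs in well under a minute: trace sets are 500 nt with a
5-SNP panel; read sets are 60–200 reads; the error-rate simulation uses
10,000 replicates of a 4-group design, made cheap by computing the Dunnett
two-sided critical value once (root-finding on the multivariate-t rectangle
probability, tolerance 1e-5) and comparing each replicate's max |t| against
it. `scripts/acceptance.py` recomputes population-level quantities with 16
simulated replicates per genotype and 400 colony reads — more than one
wet-lab experiment would have — to push Monte-Carlo error on the recomputed
means below a few percent; runtime is a few seconds.

Degenerate inputs are handled explicitly: identical ANOVA groups return
F = 0, p = 1 (scipy emits NaN/negative round-off there); an all-zero
background channel yields a point-mass null flagged degenerate; a zero
anchor peak, a zero-total gel lane, an uninformative control and constant
Shapiro–Wilk data are errors rather than silent values.

## Known limitations

* The chromatogram noise family is a modelling choice (zero-adjusted gamma
  with a lognormal alternative); real basecaller noise is not characterized
  here, so detection p-values should be read as calibrated against the
  fitted family, not as exact frequentist guarantees.
* Indel-bearing sample traces (mixed templates dephased downstream of the
  cut) are outside the quantification model; the package quantifies SNPs at
  positions where the consensus remains alignable.
* The classifier assumes clonal (haploid) colonies — one outcome per read —
  and does not annotate junction microhomologies.
* Efficiencies above 100% are possible with noisy counts and are retained;
  interpretation is left to the caller.
* Whether real densitometry values should be length-corrected before
  ratioing depends on acquisition details; both conventions are exposed and
  agree under the synthetic band model.
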