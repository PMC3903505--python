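# Methods

This note documents the models behind `pyrosip`: what is assumed, what each
parameter means, what the simulator does and does not emulate, and where the
design was genuinely open.

## 1. Isotope arithmetic

Carbon isotope state is carried in three equivalent currencies — the ratio
R = ¹³C/¹²C, the atom fraction x = ¹³C/(¹²C+¹³C), and delta notation
δ¹³C = (R_sample/R_standard − 1)·1000 ‰ — converted by
`pyrosip.isotope`. The reference is VPDB with R = 0.0111802; two conventions
for that ratio circulate (0.0111802 and 0.011237), so it is a field of
`ReferenceStandard` rather than a constant. All transform pairs are mutual
inverses to better than 1e-12 over x ∈ [0, 0.99] (checked in the tests).

**Mixing.** The share f of DNA carbon drawn from a labeled pool solves
x_bulk = f·x_label + (1−f)·x_unlabeled. Mixing is linear in atom fraction,
not in δ; with a label pool near x = 0.99, delta-space mixing would be
visibly wrong, so `mixing_fraction` converts first. Out-of-range estimates
(f ∉ [0,1]) are returned with a flag, never clamped — they are diagnostic of
a violated assumption (wrong baseline, wrong pool composition).

**Group comparison.** `compare_delta_groups` offers a Welch t-test
(optionally pooled-variance Student) and an exact permutation test that
enumerates all distinct group assignments when there are ≤ 10,000. With
triplicates (20 assignments), the two-sided permutation floor is p = 0.1.

## 2. Forward simulator

The simulator emulates a gut-microbiota SIP experiment on a ¹³C substrate.

**Community.** N taxa with GC content uniform on configurable bounds and
relative abundances either uniform or log-normal (σ = 1 in the benchmark:
a few dominants and a long tail, the usual shape of amplicon communities).
Total extracted DNA is normalized to 1 and split three ways:

* `host_dna_fraction` (default 0.5) — co-extracted host (insect) DNA.
  No measurement constrains this number; 0.5 encodes "a large amount".
* `background_fraction` (default 0.05) — nonspecific carryover DNA spread
  uniformly over all fractions, as observed in every real SIP gradient. It
  is bacterial in composition (a miniature of the community), which is why
  control heavy fractions still amplify.
* the remainder — bacterial community DNA, divided by base abundance.

**Labeling.** During the feeding window each taxon replaces a fraction
(*turnover* ∈ [0,1]) of its DNA with new DNA whose atom fraction is
x_new = x_nat + assimilation·(x_substrate − x_nat). Mass is conserved
(replacement, growth factor 1); the model tracks composition, not biomass
growth. Host and background stay at natural abundance
(x_nat = x(δ = −30.7 ‰) ≈ 0.01072, the control baseline).

**Banding.** A DNA pool of GC content g and atom fraction x bands at

BD = 1.660 + 0.098·g + 0.036·(x − x_nat)/(1 − x_nat)  g/ml.

The GC relation and the +0.036 g/ml full-label shift come from the standard
SIP protocol literature; both are `GradientConfig` fields. Fraction centers
fall linearly from `bd_bottom` = 1.761 to `bd_top` = 1.688 g/ml over 12
fractions (fraction 1 = bottom = densest, matching bottom-up displacement
fractionation); each pool's mass is integrated analytically over each
fraction's density window under a Gaussian band of width `band_sigma`
(0.003 g/ml). The outermost windows are open-ended, so mass is conserved
exactly — DNA lighter than the gradient top piles into the last fraction,
as it does in reality. Host DNA bands wider (`host_band_sigma` = 0.008)
because sheared genomic fragments are heterogeneous in GC; one Gaussian
width per pool stands in for a rotor-speed-resolved Meselson–Stahl profile,
which desk-scale inference does not need. A molecule-level Monte-Carlo
bander (`monte_carlo_gradient`) provides an independent cross-check; the
analytic and sampled profiles agree to < 2% total variation at 10⁵
molecules.

**Sequencing.** Per fraction and replicate, reads are multinomial over the
*microbial* mass proportions in that fraction — host DNA is in the gradient
(it shapes DNA-mass profiles and bulk δ¹³C) but invisible to 16S primers.
`replicate_noise` > 0 Dirichlet-perturbs proportions per replicate
(overdispersed biological triplicates); the default 0 is pure multinomial.

**IRMS.** Bulk δ¹³C is the mass-weighted mean atom fraction over all pools
(host and background included), anchored so an all-natural extract reads
exactly the baseline (−30.7 ‰), with Gaussian noise on the δ scale.

**Seeding.** One top-level seed; every stochastic stage draws from
`default_rng([seed, crc32(stage)])`, so adding a stage never perturbs
earlier ones and identical configs are byte-reproducible.

**What is not emulated.** Read-level errors (no FASTQ), chimeras,
homopolymer noise, PCR bias, centrifugation time/speed effects, and biomass
growth during labeling. Passing tests therefore show the *inference* is
sound given multinomial sampling and Gaussian banding; they do not certify
robustness to amplification artifacts.

## 3. Gradient QC and binning

Density should be linear in fraction index in a well-formed gradient; QC
fits OLS and flags R² < 0.98 (configurable). A constant-density profile is
reported as degenerate rather than fit. Density inversions are *warnings*
carrying the offending indices — real fractionation data are noisy and a
hard error would reject usable gradients. The last (topmost) fraction often
contains displacement water; `FractionSet.exclude` supports dropping it,
but the default keeps all 12 so nothing is discarded silently.

DNA distributions are normalized per gradient (fraction mass over total) so
labeled and control gradients are comparable. Peaks are argmax with ties
broken toward the denser fraction (conservative for label detection) and
flagged. Bins (light/middle/heavy) are closed density intervals or explicit
index lists; fractions matched by no bin are excluded, with a log line — in
the gut study this pooling was heavy = fractions 4–5 (1.730–1.735 g/ml),
middle = 7 (≈1.718), light = 9–11 (1.688–1.705), with 1–3, 6, 8, 12 unused;
`paper_bins()` reproduces it. The middle density interval is rendered as
1.718 ± 0.004 g/ml (half a fraction spacing each side), since only "around
1.718" is reported. The benchmark scenarios instead derive their heavy bin
from where labeled DNA must band given the community's GC bounds plus the
full-label shift (fractions 1–6), mirroring how heavy fractions are chosen
from an observed profile before scoring.

## 4. Activity inference

Replicates are converted to proportions *before* any averaging or testing;
raw counts are never compared across samples of unequal depth. The score is
the heavy-bin labeled-minus-control difference in mean relative abundance
(percentage points); scores sum to zero by compositional closure and negate
under condition swap.

**Testing.** Per taxon, a Welch t on replicate proportions; the null is
built by permuting condition labels — all distinct assignments enumerated
when ≤ 10,000, else sampled. Following the METASTATS design, permuted
statistics are pooled **across taxa** by default: with triplicates a single
taxon admits only 20 assignments (two-sided floor p = 0.1), and the pooled
null is what makes p < 0.05 attainable at all with 3 + 3 replicates. The
per-feature null remains available (`pool_null=False`). Taxa whose count
pooled over replicates and conditions falls below `sparse_threshold`
(default 8) are tested by Fisher's exact test on the pooled 2×2 table
instead, where a t on three near-zero proportions is meaningless. p-values
are in (0, 1]. No multiple-testing correction is applied by default (calls
at raw p < α = 0.05); Benjamini–Hochberg q-values are available behind
`fdr=True`.

A known property of the pooled null: under a *dense* alternative (a strong
labeling shift moves every taxon's heavy-bin proportion via closure), the
null pool is contaminated by genuinely shifted features and p-values for
weakly represented true positives inflate somewhat. In the recovery
benchmark this costs a few exact-set recoveries per hundred seeds, almost
always a labeled taxon below ~1% abundance landing just above α.

**Classification.** *active* ⇔ score > 0 and p < α. *less_active* ⇔ not
active, and the taxon's own across-bin profile (replicate-averaged,
normalized within taxon and condition) peaks in the middle bin under
labeling but not in the control — the signature of partial label uptake by
an abundant taxon, which shifts some of its DNA mid-gradient without
reaching the heavy pool. Everything else is *inactive*. The middle-peak
rule is a profile comparison because no closed-form definition of "less
active" exists; normalizing within taxon makes it independent of the
taxon's overall abundance. Ties in the profile break toward the heavier
bin, which is conservative for the less-active call.

**Stimulation factor.** Treated as identical to the score in percentage
points; a ratio reading is not implemented.

## 5. Diversity

Shannon (natural log by default — the base is exposed because published
tables often omit it), Gini–Simpson 1 − Σp² (the raw Σp² and inverse forms
are behind a flag), observed richness, and Faith's PD (scikit-bio, all
observed taxa must be tree tips). Rarefaction uses the exact hypergeometric
expectation E[S_d] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)] via log-gamma; a
resampling mode exists mainly as its own cross-check (the two agree within
3 Monte-Carlo SE). Rank aggregation pools unresolved lineages into "Other",
printed last.

## 6. Benchmark scenarios and problem sizes

The suite's study conditions (in `pyrosip.scenarios`) are fixed, not tuned:

* **Recovery / null benchmark** — 25 taxa, log-normal (σ = 1) abundances,
  GC ∈ [0.30, 0.60] (the span from low-GC Firmicutes to
  enterobacteria-like genomes), host 0.5, background 0.05; 3 labeled taxa
  at turnover 0.6, assimilation 1.0, substrate x = 0.99; 12 fractions,
  5,000 reads per fraction, biological triplicates. The null variant sets
  turnover 0 everywhere. Sizes: 1,000 experiments for calibration, 100
  seeds for recovery — large enough for ±1–2% Monte-Carlo resolution while
  keeping the whole suite around a minute.
* **Gradient demonstration** — five hand-specified taxa (three glucose
  consumers carrying 80% of bacterial DNA at GC 0.42–0.54, two bystanders),
  background 0.05, and host at 0.30: this scenario emulates an extract
  whose microbial DNA is abundant enough to band visibly in the *total*-DNA
  profile, as in a gradient with an observed heavy peak. With the generator
  default of 0.5 the host band dominates every fraction and no labeled peak
  can top the profile — a real limitation of DNA-mass-level peak detection
  in host-dominated extracts, worth knowing before trusting a "no shift"
  readout. The 24 h window is turnover 0.45 with assimilation 0.5 (after
  roughly one generation, new duplexes are hybrid: one old strand, so about
  half the carbon is substrate-derived); the 48 h window is turnover 0.8
  with assimilation 1.0 (newly divided cells have replaced old ones). Band
  *position* depends on atom fraction, band *mass* on turnover — both must
  differ between time points for the peak to move between heavy fractions,
  as observed gradients show.
* **Mixing benchmark** — the demonstration community with turnover 0.004 on
  the consumers: ~0.2% of DNA carbon substrate-derived, which is the scale
  at which bulk IRMS reads ~150 ‰ over the −30.7 ‰ baseline. Noiseless
  recovery is exact to numerical precision; at the control-level noise of
  1.3 ‰ the labeled-carbon fraction is recovered within a few percent.

## 7. Numerical choices

* Zero-variance t cases are defined (0/0 → 0, d/0 → ±∞) so enumeration
  stays exact; a relative tolerance (1e-10 of data magnitude) absorbs
  summation-order roundoff, and the observed statistic is computed through
  the same vectorized path as the permuted ones so the identity assignment
  ties with itself.
* Banding integrals use the normal CDF over window edges with open-ended
  outer windows; mass conservation is exact to 1e-9 by construction.
* Rarefaction uses log-binomials (gammaln) — no overflow at any depth.
* Peak and bin ties always break toward the denser side and are flagged.
* Degenerate inputs (empty samples, zero-mass fractions, inverted bounds,
  overlapping bins, missing tree tips) raise with the offending name in the
  message rather than propagating NaNs.

## 8. Known limitations

* The generator's host share is unconstrained by any measurement; DNA-mass
  profiles (not amplicon inference) are sensitive to it.
* The pooled permutation null assumes most features are null; under dense
  alternatives it is conservative for rare true positives (see §4).
* Activity scores are compositional differences; they rank label uptake
  but are not per-cell rates, and cross-feeding is indistinguishable from
  primary consumption by design.
* Simulated replicates default to pure multinomial; real biological
  replicates are usually overdispersed (set `replicate_noise` > 0).
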