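# Methods

## Problem and scope

`metabomix` implements the computational half of an untargeted LC–MS
metabolomics study comparing wild-type and knockout mice (optionally crossed
with an antibiotic treatment), plus the accompanying 16S taxon-level
comparison. The pipeline consumes an extracted peak table (m/z, retention
time, polarity, apex height, per-sample peak areas), a formula–mass compound
database, and a sample design; it produces formula-level compound
identifications with posterior probabilities, per-compound differential
statistics, and ranked taxon comparisons. Raw feature extraction from
instrument files and 16S read processing are out of scope: the pipeline
starts from extracted tables.

## Identification model

Each peak's m/z is converted to neutral-mass hypotheses under the allowed
adduct species (protonated, sodiated, potassiated in positive mode,
deprotonation in negative mode; charge ≤ 2; mass shifts electron-corrected,
proton = 1.00727647 Da). For every hypothesis the nearest database formula
by signed relative mass error e (ppm) is found; the minimum-|e| formula over
all hypotheses is the best match, and the minimum-|e| formula *distinct* from
it is the second-best match. Best matches are only eligible within a capture
window (default ±50 ppm — wide enough that the statistical model can observe
chance matches well beyond the few-ppm regime of correct identifications);
second-best matches are recorded without a window.

Best-match errors are modeled as a two-component mixture
π₁·f₁(e) + (1 − π₁)·f₀(e) over the capture-window domain:

* **f₀ (false component)** — a Gaussian kernel density over the signed
  second-best errors of all peaks (Silverman rule-of-thumb bandwidth),
  truncated to the domain and renormalized, then held fixed. Second-best
  matches are almost surely wrong, which makes their error distribution an
  empirical stand-in for the distribution of chance matches.
* **f₁ (true component)** — a Gaussian with free location μ₁ and scale σ₁,
  truncated to the same domain (both densities integrate to 1 over the
  modeled domain).

π₁, μ₁, σ₁ are fitted by EM on the in-window best-match errors with
deterministic initialization (π₁ = 0.5, μ₁ = 0, σ₁ = median |e|), a floor of
0.05 ppm on σ₁, and convergence when the log-likelihood changes by < 1e-8
(≤ 500 iterations). The fit is fully deterministic given the data. Signed
(not absolute) errors are modeled so a calibration bias appears as μ₁ ≠ 0.
One model is fitted per (organ, polarity) stratum; positive- and
negative-mode tables are processed separately end to end. Configuration
switches cover the genuinely open choices: the mixture can be fitted on
folded absolute errors instead of signed ones (`error_mode`), fold changes
can use geometric instead of arithmetic group means (`fc_means`), and a peak
table whose masses are already neutralized is matched as-is without adduct
enumeration (`masses_are_neutral`).

Each matched peak receives the posterior probability of true identification

    P(true | e) = π₁ f₁(e) / (π₁ f₁(e) + (1 − π₁) f₀(e)),

a formula-level quantity: mass cannot distinguish compounds sharing a
formula. Assignment rules: peaks hitting an isotopically verified standard
are identified with full confidence (posterior 1) — but only within a tight
10-ppm window (the extraction mass tolerance), because a standard
identification represents external verification that a 50-ppm mass-only hit
cannot claim; a posterior ≥ 0.8 with a unique compound for the formula is
assigned; a posterior ≥ 0.8 on a formula carried by two or more database
compounds is removed as an ambiguous isomer; everything else is unassigned.

Calibration of the posterior is a formula-level property and is evaluated
before the ambiguous-isomer removal: that removal deliberately discards a
block of (mostly correct) identifications for reasons unrelated to mass
error, so the surviving set is no longer the set the posterior speaks about.

## Quantification and differential testing

Technical injections are collapsed onto biological replicates by geometric
mean, with zero areas dropped from the mean (and flagged): a zero from one
failed injection would otherwise erase the signal of the remaining good ones.
Identified peaks are summed per compound and sample (abundant species elute
over several peaks). Values are transformed as log₂(x + c) with the fudge
factor c set to the 10th percentile (linear interpolation) of the stratum's
values, taming fold changes of noisy low-abundance rows. Group comparisons
use a two-sample equal-variance t test on the transformed values (Welch and
paired variants available); the fold change Fc is the ratio of raw-scale
group means (a geometric-mean variant would differ; raw arithmetic means are
the default). Multiple testing uses Storey q-values with a fixed λ = 0.5:
π₀ = max(#{p > λ}, 1)/(m(1 − λ)) capped at 1 (the floor on the count guards
the degenerate π₀ = 0 case and small m), and q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ π₀·m·p₍ⱼ₎/j. A
compound is significant when q ≤ q* and max(Fc, 1/Fc) ≥ 1.2, with q* = 0.15
for kidney and 0.05 for plasma by default.

## 16S comparison

Taxon tables (7-rank semicolon taxonomy; Greengenes prefixes stripped) are
normalized to relative abundances per sample, optionally aggregated to a
rank, and compared with a one-sided equal-variance t test whose direction is
chosen per taxon from the observed change, ranked by |percent change| and
flagged at p < 0.1. Choosing the direction from the data makes the test
anti-conservative (an honest two-sided p would be twice as large); this
mirrors how such screens are commonly reported and is stated here rather
than hidden. Taxonomic flow is summarized as parent→child edges of
group-mean abundance across adjacent ranks, with unclassified tails kept as
explicit "unclassified" children so child weights always sum to the parent.

## Synthetic data generator

The generator emulates the study conditions with exact ground truth:

* **Database** — 500 compounds plus 1500 decoy entries with random CHNOPS
  formulas in 80–1000 Da; 10% of compound formulas are duplicated under a
  second compound id (isomer collisions); the first compound is a
  standard-verified "glutarate" (C5H8O4) and nine further compounds are
  standards. A minimum pairwise formula-mass separation of 120 ppm (> 2× the
  null half-width) is enforced so that every seeded peak's source entry is
  provably its nearest formula — without it, the mass-defect clustering of
  random formulas produces near-isobars that silently distort the realized
  error distributions. Real composite databases *do* contain near-isobaric
  formulas; this idealization trades that realism for exact, identifiable
  ground truth.
* **Peaks** — 2000 peaks, of which a fraction π₁ = 0.6 carry the ionized
  mass of a database compound perturbed by N(0, 2 ppm), and the rest sit at
  a uniform offset within ±50 ppm of a random non-standard entry (a spurious
  feature within a few ppm of a verified standard would be physically
  indistinguishable from the standard, so its "false" label would be
  ill-defined). A rejection step guarantees the seeded entry remains the
  nearest formula. Compounds targeted by an explicit group effect always
  emit one filter-surviving peak, as a targeted panel compound would.
* **Abundances** — per-peak base areas are log-normal (ln-scale sd 1.2);
  group effects are multiplicative (default: glutarate ×11 in the knockout;
  bacterial-origin compounds ÷100 under antibiotics); technical replicates
  carry multiplicative log-normal noise with CV 0.2 (mean-one). Biological
  replicates differ only through technical noise and group effects — there
  is no separate biological-variance knob — so power estimates from these
  simulations are optimistic relative to real cohorts, where biological CV
  often dominates. Small fractions of peaks fall outside the retention-time
  window (2%) or below the height threshold (2%) to exercise ingestion
  filters.
* **Ionization** — peaks are generated (and the synthetic studies matched)
  under the protonated species only; this isolates the mass-error statistics
  from adduct ambiguity, which is exercised separately in the unit tests.
  Cross-adduct collisions in real data add false matches the second-best
  null only partially captures; the calibration shown on these simulations
  is therefore a best case.
* **Taxa** — Dirichlet compositions (total concentration 100) over a
  synthetic 7-rank taxonomy of 60 species in 16 genera, 7 samples per
  genotype; selected genera receive multiplicative concentration shifts in
  the knockout (defaults ×2, ×1.5, ×0.5).

All randomness flows from one master seed through per-subgenerator spawned
streams, so outputs are byte-identical across runs with the same seed.

## Numerical choices and degenerate inputs

Height filtering is strict (> 1000 counts) and applied before replicate
collapsing; retention-time bounds are inclusive. Nearest-match ties are
broken by database order and logged. A biological replicate whose technical
injections are all zero collapses to zero. Zero within-group variance in
both arms yields t = 0, p = 1 when means agree and an undefined, flagged p
otherwise; a taxon with zero baseline mean has an undefined percent change
and is flagged. Posteriors where both densities vanish return 0 with a
warning. An all-zero compound matrix (fudge factor 0 with zeros present) is
an error rather than a silent −inf.

## What the tests do and do not show

The acceptance-style tests demonstrate, on the generator's conditions: π₁
recovery within ±0.05 (mean absolute error < 0.03 over 20 seeds), posterior
calibration (pooled empirical FDP within 3 Monte-Carlo standard errors of
1 − mean posterior, evaluated at formula level), all surviving assignments
within 20 ppm, exact agreement of the q-value implementation with a
brute-force transcription, FDR control on null data, and ≥ 95% recovery of
an 11-fold spike with Fc estimated within 20%. They do not show that the
mixture model is calibrated on real data — where spurious features are not
uniform around database entries, near-isobars exist, several adducts
coexist, and biological variance is substantial. Problem sizes (2000 peaks,
2050 database formulas, 50 replicate studies) were chosen so the full
statistical suite runs in a few minutes on one CPU.
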