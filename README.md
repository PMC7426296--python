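# metabomix

Untargeted LC–MS metabolite identification and differential-abundance
analysis, built around an empirical-Bayes mixture deconvolution of mass
errors, plus a 16S taxon-level group comparison and a seeded synthetic-data
generator with ground truth.

## Who this is for

Metabolomics analysts who have an extracted peak table (m/z, retention time,
polarity, height, per-sample areas) and a formula–mass compound database,
and who want statistically calibrated compound identifications and
differential statistics — and methodologists who want a testbed where the
truth is known, to study how the identification posterior behaves.

## The model

A peak's m/z is converted to neutral-mass hypotheses under the allowed
adduct species ([M+H]⁺, [M+2H]²⁺, [M+Na]⁺, [M+K]⁺; [M−H]⁻ in negative
mode). The signed relative mass error to the nearest database formula,
e (ppm), is a mixture of correct matches (tight) and chance matches (broad):

    p(e) = π₁ f₁(e) + (1 − π₁) f₀(e)

The false density f₀ is learned from the *second-best* matches of all peaks
— the errors to the next-nearest distinct formula, which are almost surely
wrong — as a kernel density held fixed while EM fits π₁ and a Gaussian f₁.
Each peak then gets a posterior probability of true identification,

    P(true | e) = π₁ f₁(e) / (π₁ f₁(e) + (1 − π₁) f₀(e)),

defined up to the formula (mass cannot separate isomers). Assignments are
accepted at posterior ≥ 0.8; formulas carried by several database compounds
are removed as ambiguous isomers; peaks hitting a verified standard within
the extraction mass tolerance are identified with full confidence.

Downstream, technical replicates are collapsed by geometric mean, peak areas
are summed per compound, values are log₂-transformed after adding a fudge
factor (the 10th percentile of the stratum), groups are compared with a
two-sample t test, multiple testing is corrected with Storey q-values
(π₀ estimated at λ = 0.5), and a compound is significant when q ≤ q* and
max(Fc, 1/Fc) ≥ 1.2 on raw-scale group-mean fold changes. The 16S stage
normalizes taxon tables to relative abundances, tests each taxon one-sided
in the direction of the observed change (equal variance, flagged at
p < 0.1), ranks by percent change, and emits Sankey parent→child flows.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Generate a synthetic study (300 compounds + 900 decoys, 1200 peaks, six
biological × three technical replicates per genotype, glutarate spiked
11-fold in the knockout), then annotate, test, and compare taxa:

```sh
metabomix simulate --config config.yaml
metabomix annotate --config config.yaml
metabomix diff     --config config.yaml
metabomix taxa     --config config.yaml
```

`annotate` prints the fitted mixture per stratum:

```
"positive": {
  "pi1": 0.6152793308866279,
  "mu1_ppm": 0.03720339022359804,
  "sigma1_ppm": 2.0363779567034483,
  "n_identified": 594.0,
  "n_ambiguous_isomer_removed": 130.0,
  "max_abs_ppm_assigned": 4.294890829040345,
  ...
}
```

The generator seeded 60% true matches with a 2-ppm error component; the fit
recovers π₁ = 0.615, a centred true component (μ₁ = 0.04 ppm, σ₁ = 2.04 ppm),
and every accepted assignment sits within 4.3 ppm. `diff` reports one
significant compound at (q ≤ 0.15, Fc ≥ 1.2) — the spiked glutarate:

```
fold_change    11.320967
log2fc          3.500925
t_statistic    46.350417
q_value              0.0
significant         True
```

and `taxa` flags 5 of 16 genera, led by the two genera the generator shifted
(+83.5% at one-sided p = 0.0014; −69.3% at p = 0.0040).

Each output directory contains a `manifest.json` (config hash, seed,
versions); identical manifests mean byte-identical deterministic outputs.

## Library use

```python
from metabomix import (SimConfig, simulate_database, simulate_peaks,
                       make_design, filter_peaks, annotate, get_adduct)

cfg = SimConfig(seed=1)
db = simulate_database(cfg)
peaks, truth = simulate_peaks(cfg, db, make_design(cfg))
result = annotate(filter_peaks(peaks), db, adducts=[get_adduct("[M+H]+")])
print(result.model.pi1, result.summary["fraction_assigned"])
```

## Output schemas

* `identifications.tsv` — peak_id, polarity, compound_id (";"-joined for
  ambiguous isomers), formula, adduct, ppm_error, posterior, status
  (standard | assigned | ambiguous_isomer_removed | unassigned).
* `results_<contrast>_<polarity>.tsv` — compound_id, name, formula,
  class_label, mean_numerator, mean_denominator, fold_change, log2fc,
  t_statistic, p_value, q_value, degenerate, significant, direction.
* `volcano_*.tsv` — log2fc, −log10 p, significant. `heatmap_*.tsv` —
  transformed values of significant compounds grouped by class.
  `classes_*.tsv` — per-class significant counts and fractions.
* `taxa_comparison_<rank>.tsv` — group means, percent_change, t_statistic,
  p_one_sided, flagged, undefined_baseline, ranked by |percent change|.
  `sankey_<group>.tsv` — parent_taxon, child_taxon, weight.

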