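# crosskill

Cross-species drug-screen analysis for comparative oncology: from raw
viability-plate luminescence to percent killing, hit calls, top-drug
selection by Analysis of Means, species-concordance clustering and
correlation, target-level roll-up of annotated compound libraries, IC50 and
Bliss-synergy quantification, and xenograft growth-curve and
survival-cutoff statistics.

## The problem

Rare cancers such as osteosarcoma occur spontaneously in pet dogs at ~40×
the human incidence, with strikingly similar biology. A cross-species
discovery pipeline screens matched dog and human patient-derived cell lines
against annotated compound libraries (single dose, e.g. 1 µM, triplicate
384-well plates, CellTiter-Glo luminescence after 72 h), asks whether
responses are concordant across species, rolls per-compound hits up to drug
*targets* to find high-confidence vulnerabilities, and validates top
candidates in patient-derived xenografts (PDX). `crosskill` implements that
analysis chain as a tested, reusable library, together with a synthetic-data
generator that plants ground truth for every stage — so each statistical
step can be validated end to end.

## The statistics

- **Percent killing** for a treated well against its own plate's vehicle
  controls: `100 × (1 − treated / control_center)` (control median by
  default; values outside [0, 100] retained).
- **Hit calling** at a configurable threshold (default killing ≥ 50%), and
  **Analysis of Means**: compound means flagged outside decision limits
  `ȳ ± t(1 − α/2k; df) · s_p · √((k−1)/(k·n))` around the grand mean.
- **Species concordance**: hierarchical clustering of cell lines on their
  response profiles with a k=2 species-purity score, and per-compound
  Pearson correlation between species (p from
  `t = r·√((n−2)/(1−r²))`).
- **Target roll-up**: a target passes when ≥ m of its annotated drugs
  (default m = 3) kill > 50% in all required cell lines.
- **Dose-response**: four-parameter logistic
  `v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` fit by multi-start
  least squares on serial dilutions (default 20 µM, 4-fold);
  **Bliss synergy**: excess = observed − (Ea + Eb − Ea·Eb).
- **In vivo**: caliper volume `(L × W²)/2`, randomization at 100 mm³,
  endpoint at 1500 mm³ or day 18, group × day two-way ANOVA.
- **Survival**: Kaplan–Meier, log-rank `(ΣO − ΣE)²/ΣV`, and an exhaustive
  expression-**cutoff scan** minimizing the log-rank p (the scan count is
  reported because a scanned minimum p is anti-conservative).

## Worked example

```bash
python examples/target_rollup.py
```

plants 9 of 11 proteasome inhibitors and 3 of 4 CRM1 (nuclear-export)
inhibitors as sensitive in a 2100-compound annotated library screened
against a matched dog/human line pair at 8 pp well noise, and prints:

```
top of the target roll-up (drugs killing >50% in BOTH lines):
    target            pathway  n_drugs_total  n_drugs_hit  hit_fraction  passes_filter
proteasome proteasome pathway             11            9      0.818182           True
      CRM1       CRM1 pathway              4            3      0.750000           True
   TGT_073    TGT_073 pathway             11            1      0.090909          False
...
targets passing the >=3-drug filter: ['proteasome', 'CRM1']
```

The roll-up counts, for each annotated target, the drugs killing more than
the threshold in *both* cell lines; with ≥3 such drugs a target passes.
Only the two planted drivers pass — single-compound false positives do not
aggregate into false targets. The other examples
(`examples/*.py`) cover plate normalization and hit calling, species
clustering/concordance, IC50 and Bliss synergy, the xenograft ANOVA, and
the survival-cutoff scan; `examples/full_pipeline.py` (or `crosskill run`)
drives everything from one config and writes a hash-stamped run manifest.

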