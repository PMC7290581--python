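# mircad

Statistical pipeline for discovering and validating **circulating microRNA
biomarkers of coronary artery disease** from serum qPCR panels, with a
case-cohort survival arm and an in-vitro candidate screen.

Circulating miRNAs are attractive cardiovascular biomarkers: they are stable
in serum, measurable by RT-qPCR, and several (e.g. liver-enriched
hsa-miR-122-5p, vascular hsa-miR-143-3p) respond to the atherogenic stimulus
oxidized LDL. Analyzing them correctly is not routine, because qPCR panel
data bring three coupled problems that `mircad` addresses end to end:

1. **Non-detects are censored, not missing.** A reaction that never crosses
   the fluorescence threshold says "expression below the detection limit",
   i.e. ΔCt above an unknown bound. `mircad` treats non-detects as
   right-censored at the per-miRNA maximum observed ΔCt and estimates group
   means with the Kaplan–Meier restricted mean
   (μ̂ = t_min + ∫ Ŝ(t) dt over the observed range); groups are compared
   with the log-rank test and fold changes derived as FC = 2^−(ΔCt̄_case −
   ΔCt̄_control), with Benjamini–Hochberg control across the panel.
2. **Plates are batches.** Before ΔCt normalization (Ct minus the mean of
   each sample's observed Cts), per-plate location/scale effects are removed
   by empirical-Bayes batch correction (ComBat-style shrinkage of per-plate
   means and variances), preceded by validity, feature-missingness (>90%)
   and sample-missingness (>95%) filters.
3. **Case-cohort sampling needs weights.** In a large prospective cohort,
   miRNAs are typically measured only in incident cases plus a random
   subcohort. `mircad` fits the weighted Cox proportional-hazards model with
   Barlow weighting — subcohort person-time weighted 1/f (f = sampling
   fraction), each case entering the risk set just before its own failure
   with weight 1 — maximizing the Breslow partial likelihood with late
   entry, and reports robust (Lin–Wei sandwich, subject-clustered) standard
   errors. Prentice weighting is available as an option.

On top of the survival model, `mircad` quantifies **incremental predictive
value** of a marker over the classical risk factors (age, sex, smoking,
cholesterol, systolic blood pressure, diabetes): continuous and categorical
net reclassification improvement (NRI, in percent; default category cutoff
10% ten-year risk), integrated discrimination improvement (IDI), and the
change in weighted Harrell concordance, each with percentile-bootstrap
confidence intervals.

Two supporting arms mirror how such markers are found in the first place:
a **moderated-t screen** (empirical-Bayes variance shrinkage plus
orthogonal-polynomial dose-response trend tests across nLDL → moxLDL →
hoxLDL exposure in endothelial and smooth-muscle cells; candidates require
|FC| ≥ 1.5, contrast p < 0.05 and trend p < 0.05), and a **target-gene
enrichment** module (score-filtered predicted targets, hypergeometric
over-representation against GMT gene sets, expressed-gene overlap counts).

Because real serum qPCR studies of this kind are rarely deposited, the
package ships a first-class synthetic-data generator (`mircad.simulate`)
that emulates the full study design — plate structure, detection limit,
planted fold changes and hazard ratios, case-cohort subsampling, in-vitro
dose-response profiles — so every method can be validated by parameter
recovery. See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Simulate a 500-sample case-control study with hsa-miR-122-5p planted at
fold change 4.85 (log2 FC 2.278), plus a 5000-person cohort in which
hsa-miR-143-3p is protective with hazard ratio 0.56, then run the whole
pipeline:

```sh
cat > study.yaml <<'EOF'
case_control:
  n_cases: 250
  n_controls: 250
  true_log2_fc:
    hsa-miR-122-5p: 2.278
  baseline_ct:
    hsa-miR-122-5p: 26.0
cohort:
  n_cohort: 5000
EOF

mircad simulate --config study.yaml --seed 12 --out-dir study
mircad normalize --ct study/ct.tsv --meta study/meta.tsv --out study/delta.tsv
mircad de --delta study/delta.tsv --meta study/meta.tsv --out study/de.tsv
mircad cox --survival study/casecohort.tsv --mirnas hsa-miR-143-3p \
           --n-cohort 5000 --out study/cox.tsv
mircad reclassify --survival study/casecohort.tsv --add-mirnas hsa-miR-143-3p \
                  --n-cohort 5000 --out study/reclass.tsv
```

which prints

```
synthetic study written to study
normalized 500 samples x 51 miRNAs; excluded 0 miRNAs, 0 samples
51 miRNAs tested, 2 with adjusted p < 0.05
fitted 1 miRNAs x 2 adjustment sets
cNRI: 48.97
catNRI: 12.87
IDI: 0.01274
deltaC: 0.04344
```

The top of `study/de.tsv` recovers the planted marker:

```
         mirna  mean_case  mean_control  fold_change            p        p_adj
hsa-miR-122-5p  -2.812315     -0.733721     4.223952 1.033588e-42 5.271297e-41
   miR-sim-024   2.455344      2.143450     0.805584 1.515819e-03 3.865337e-02
```

hsa-miR-122-5p comes out at FC ≈ 4.22 — cases carry about four times the
control level, close to the planted 4.85; the gap is the expected mild
attenuation from global-mean normalization (the marker itself is part of
every sample's reference) plus sampling noise at 250/group. One of the 50
null miRNAs (miR-sim-024) squeaks under the adjusted-0.05 line, a reminder
that BH controls the false-discovery *rate*, not its absence.

`study/cox.tsv` holds the case-cohort association (150 events, 1:4
subcohort, Barlow weights):

```
         mirna model       hr   ci_low  ci_high            p  n_events
hsa-miR-143-3p  base 0.564014 0.455186 0.698861 1.641216e-07       150
hsa-miR-143-3p  full 0.575400 0.463440 0.714407 5.552367e-07       150
```

The fully adjusted hazard ratio 0.575 (95% CI 0.463–0.714) recovers the
planted 0.56: one standard deviation more circulating miR-143-3p cuts the
ten-year event hazard roughly by half. The reclassification block above says
what that is worth on top of the classical risk factors: adding the marker
moves risk predictions in the right direction for a net 49% of
subject-comparisons (continuous NRI), net-reclassifies 12.9% across the 10%
risk cutoff, and raises the discrimination slope by 0.013 (IDI) and the
weighted concordance by 0.043.

The in-vitro arms run the same way (`mircad screen`, `mircad enrich`); see
`mircad <command> --help`.

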