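# kincontrol

Ensemble kinetic modelling and metabolic control analysis of central-carbon
metabolism from single steady-state snapshots.

A chemostat experiment yields one steady state per growth condition:
metabolite concentrations, exchange rates and a balanced intracellular flux
distribution. That single snapshot does not pin down enzyme kinetics — but
it *constrains* them. `kincontrol` samples, for each condition, an ensemble
of fully parameterised kinetic models that all (i) reproduce the measured
steady state exactly, (ii) respect thermodynamics (every reaction runs
downhill in Gibbs energy, with elementary-step rate-constant ratios tied to
the reaction's ΔG by the Haldane relation), and (iii) are linearly stable.
On each sampled model it computes scaled flux control coefficients

&nbsp;&nbsp;&nbsp;&nbsp; C<sup>J<sub>i</sub></sup><sub>E<sub>k</sub></sub> = (∂J<sub>i</sub>/J<sub>i</sub>) / (∂E<sub>k</sub>/E<sub>k</sub>)

— the fractional change of steady-state flux J<sub>i</sub> per fractional
change of enzyme level E<sub>k</sub> — and summarises each condition by the
ensemble median per enzyme–flux pair. Comparing these median control
patterns across dilution rates and nutrient limitations shows how metabolic
control shifts with the growth medium. It is written for systems biologists
and metabolic engineers who want condition-specific bottleneck analysis
without literature K<sub>m</sub>/k<sub>cat</sub> values.

The package ships:

* a compartmentalised model layer (stoichiometry, kinetic mechanism labels,
  competitive/allosteric regulators), including an encoded yeast
  central-carbon network (82 reactions, 52 metabolites, 3 compartments,
  4 allosteric enzymes: PFK, PYK, G3PD1ir, ICDHxm);
* omics processing (50 %/150 % concentration bounds, 100-fold mitochondrial
  relaxation, 10 M unmeasured ceiling, pH-pinned protons, chemostat
  exchange rates, drain balancing);
* the thermodynamic layer (reaction ΔG ranges at 30 °C from standard-ΔG
  tables and concentration boxes; joint sampling of concentrations, ΔG° and
  ΔG with sign consistency against the flux direction);
* the elementary kinetic sampler (Dirichlet step reversibilities and
  enzyme-state abundances; rate constants solved so the reference steady
  state is reproduced to 1 part in 10⁹; MWC allosteric modulation);
* stability filtering (moiety-reduced Jacobian eigenvalues, threshold
  1 × 10⁻⁵) and metabolic control analysis (analytic matrix route plus an
  independent perturb-and-resolve oracle);
* a synthetic-data generator that emulates the chemostat study at toy scale
  with known ground truth, so the entire pipeline is testable offline.

## Worked example

Sample a 100-model ensemble for one synthetic glucose-limited condition and
inspect its control pattern:

```python
import kincontrol as kc
from kincontrol.synth import (SyntheticSpec, generate_toy_model,
                              generate_ground_truth, generate_condition_series,
                              standard_gibbs_table)

spec = SyntheticSpec(seed=0)                      # branched toy template
model = generate_toy_model(spec)
truth = generate_ground_truth(model, spec)        # generating instance + true C
datasets = generate_condition_series(truth, spec) # 9 noisy conditions
std = standard_gibbs_table(model, spec)

res = kc.EnsembleModel(model, datasets[2], std,
                       kc.PipelineConfig(base_seed=0)).fit()
print(res.summary())
```

```
Ensemble sampling results
============================================================
condition:          glucose-limited D=0.16
retained instances: 100 (quota 100)
sampling attempts:  371 (quota reached after 371)
rejections:         thermodynamics: 268, unstable: 3
surplus accepted:   0

largest |median control coefficients| (flux <- enzyme):
       FER_sec <- GLCt         +0.683
          FERM <- GLCt         +0.683
           HEX <- GLCt         +0.658
          GLCt <- GLCt         +0.658
        ATPASE <- RESP         +0.646
```

371 sampling attempts were needed to retain 100 models: most rejections are
thermodynamic (the drawn concentrations and ΔG° cannot oppose every flux
direction simultaneously), a few are linearly unstable. The glucose
transporter (GLCt) holds most of the positive control over the fermentative
flux (median C ≈ 0.68) — the pathway is supply-limited at this dilution
rate — while the respiratory branch exerts negative control on fermentation
(−0.19) through the shared adenylate pool. `res.median_matrix()` gives the
full flux × enzyme median table, `res.plot_heatmap()` the blue/red heat
map, and `kincontrol.ks_compare(res_a, res_b, pair)` the two-sample
Kolmogorov–Smirnov comparison of a pair's coefficient distribution between
two conditions.

The same workflow runs from the shell:

```bash
kin-control synth --template branched_glycolysis_mini --conditions 9 --seed 0 --out data/
kin-control run --model data/model.json --data data/ --gibbs data/standard_gibbs.tsv --out run/
kin-control mca --run-dir run/
kin-control compare --run-dir run/ --condition-a "glucose-limited D=0.05" \
    --condition-b "glucose-limited D=0.30"
```

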