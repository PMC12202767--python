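# hotspot-assembly

A null model of early bacterial community assembly on nutrient hotspots.

Marine copiotrophic bacteria find ephemeral nutrient patches by chemotaxis
and then compete by growing on the available substrates. For a strain pair
mixed at inoculum fractions *f* with solo chemotactic indices *I* (metabolite
well cells / seawater-control well cells) and solo maximum growth rates *μ*,
the null model of independent behaviour predicts

* pooled index of the mixture:  I_pool = Σᵢ wᵢ Iᵢ, with entry weights
  wᵢ = fᵢ rᵢ / Σⱼ fⱼ rⱼ (rᵢ = random-motility entry coefficients, equal by
  default),
* metabolite-well composition: shareᵢ ∝ fᵢ rᵢ Iᵢ,
* composition after T = 24 h of growth: nᵢ(T) = nᵢ(0) e^{μᵢ T}, renormalized.

The percentage-point deviation D = 100·maxᵢ |f_pred,i − f_obs,i| between
predicted and observed compositions flags an inter-species interaction when
D > 10. Measurement uncertainty is propagated by Monte Carlo (empirical
CDFs, 95% intervals, two-sided empirical p-values); amplicon read counts
are converted to cell abundances through per-strain calibration lines
fitted on mock communities; metabolite roles per strain (signal /
substrate / both / none) and pairwise interaction directions (−/0/+) are
classified from the same tests. A synthetic-data generator produces every
input table under null and interaction scenarios, so the entire pipeline
is testable without wet-lab data.

The package is aimed at microbial ecologists analysing paired
chemotaxis-growth competition experiments (ISCA-style well assays, OD600
plate reader curves, 16S amplicon tables) and at method developers who
need a calibrated baseline for interaction detection.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (7 strains, DMSP and spermidine, 12 pair experiments with injected
interactions for 9 of them) and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_calibrate_amplicons.py
python analysis/03_single_strain_traits.py
python analysis/04_pair_assembly.py
```

The last step prints the main result table (abridged):

```
       experiment_id outcome_label  post_growth_deviation_pp  growth_deviates
      HF66+HF15@DMSP           +/+                 14.933854             True
HF66+HF15@spermidine           0/+                 67.033886             True
      HF66+HF31@spermidine     -/-                 12.026324             True
      HF66+HF9B@DMSP           -/0                  3.133052            False
...
chemotaxis differed from the null prediction in 9/12 (75%)
final composition deviated > 10 pp in 3/12 (25%); the null model matched 9/12 (75%)
```

Reading it: the two HF66+HF15 experiments carry the injected beneficial
interaction (partner chemotaxis ×2.5, growth ×2) and show the largest
deviations from the null prediction (up to 67 pp), while null pairs like
HF66+HF9A stay within a few percentage points; all nine injected
chemotaxis interactions are recovered as significant pooled-index
differences and as per-strain direction calls (e.g. −/0 when only the
focal strain is hampered).

The same machinery is exposed as a CLI
(`hotspot-assembly simulate|calibrate|ic|growthrate|predict-pair|to-cells|compare|classify-roles|classify-interactions|report|run`);
`hotspot-assembly run --workdir W --scenario scenario.yaml --seed N`
executes every stage and writes a `manifest.json` with input digests and
outputs (identical seed ⇒ byte-identical tables).

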