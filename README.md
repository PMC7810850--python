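# micromash

Analysis tools for micro-scale mash proteomics: how do the proteins and
peptides of malted barley behave as a mash steps through its temperature
rests, and what drives their changes — time at a temperature, or the
temperature change itself?

Brewing mashes extract soluble proteins from milled malt and then
progressively lose them as rising temperature unfolds, aggregates and
precipitates each protein past its melting midpoint. Seed proteases also
clip proteins site-specifically, producing families of semi-tryptic peptide
forms whose thermal stabilities differ from the parent. Miniaturised (1 mL)
mashes make replicated, stage-manipulated experiments cheap; this package
implements the quantitative workflow such experiments need:

* **Simulation** (`micromash.simulate`): a two-compartment
  extraction/denaturation kinetic model
  (dG/dt = −k_ext·G, dS/dt = k_ext·G − k_den·S, with Arrhenius-like
  k_ext(T) and sigmoidal k_den(T)) forward-simulates replicated quant tables
  over a configurable mash program — rests at 52/63/73/78 °C plus boil, each
  rest with a time extension — with trypsin spike-in references, per-run
  scale factors, log-normal noise and exact ground-truth labels.
* **Normalization** (`micromash.normalize`): trypsin-relative abundance
  R = intensity / trypsin intensity per run; normalized abundance
  N(t) = mean R(t) / Σ_t mean R(t) (profiles sum to 1); within-family
  peptide-form fractions; log2 fold changes.
* **Statistics** (`micromash.stats`): equal-variance Student's t-test,
  Bonferroni correction, and a per-protein OLS contrast
  (log2 intensity ~ feature + group) that reduces exactly to the t-test for
  single-feature proteins.
* **Scale comparison** (`micromash.scale_compare`): per-feature,
  per-timepoint difference maps between two mash conditions with
  significance overlay.
* **Dependence classification** (`micromash.stage_extension`): the
  stage-extension decision framework — compare stage end (E), stage
  extension (X, same temperature, more time) and end of next stage (NE):
  significant E–X ⇒ time-dependent, X–NE ⇒ temperature-dependent, only
  E–NE ⇒ time+temperature.
* **Metabolites** (`micromash.metabolites`): MRM external-calibration
  quantification of wort sugars and amino acids (linear curves gated at
  R² > 0.99, 1:1000 dilution) and Brix → specific-gravity conversion.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Classify which benchmark proteins change with time and which with
temperature across the 63 °C → 73 °C transition:

```python
from micromash import classify_all, default_program
from micromash.demo import label_agreement
from micromash.simulate import benchmark_dataset

table, truth, transition = benchmark_dataset(seed=42)   # 200 proteins, n = 6
calls = classify_all(table, default_program(), level="protein", alpha=0.05)
print(calls[calls["transition"] == transition]["label"].value_counts())
print(label_agreement(calls, truth, transition=transition))
```

prints

```
label
temperature         98
time                97
temperature,time     5
0.975
```

97 of the 100 proteins built to decay steadily at 63 °C are called
time-dependent, 98 of the 100 built to melt between 63 and 73 °C are called
temperature-dependent, and 97.5% of all label sets match the simulator's
ground truth exactly (the remainder pick up one extra label from a
false-positive test at α = 0.05).

The `examples/` scripts walk through each capability — simulation,
normalization, scale comparison, dependence classification and metabolite
calibration — each printing the numbers it computes and what they mean. A
complete pipeline run (two conditions, difference map, classification,
metabolite quantification, provenance-stamped outputs) is available as

```bash
micromash full-demo --seed 7 --out demo_out/
```

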