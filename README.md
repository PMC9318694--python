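# pharmasieve

Pharmacophore-based virtual screening and binding-assay analysis for
aminergic GPCR ligand discovery.

Finding new ligands for the dopamine D2 receptor (and its aminergic
relatives) typically combines *in silico* screening — 3D pharmacophore
models that encode the interaction pattern a binder must present
(a positively ionizable amine for the conserved binding-pocket aspartate,
hydrogen-bond partners for the serine microdomain, aromatic/hydrophobic
contacts) — with *in vitro* confirmation by competition binding.
`pharmasieve` implements that whole loop as an open, tested library and CLI:

- **chem** — SMILES/SDF I/O, physicochemical descriptors, ligand-side
  feature perception (PI/HBA/HBD/HC/AI), ETKDG conformer ensembles.
- **pharmacophore** — model schema (JSON), tolerance-sphere matching with
  exclusion volumes, fit scoring, greedy restrictiveness optimization.
- **evaluation** — screening validation on an actives/inactives/decoys
  benchmark: sensitivity, specificity, accuracy, yield of actives
  YoA = TP/(TP+FP), enrichment factor EF = YoA/(n_act/N), prospective hit
  rates.
- **triage** — PAINS and rule-of-five-style filtering, consensus-hit
  categories across models, ECFP4/Tanimoto scaffold-diversity selection.
- **assay** — HTRF plate analysis: 665/620 ratio, normalized decrease in
  fluorescence (DNF, active at ≥ 2), saturation K_D fit, four-parameter
  logistic IC50, Cheng–Prusoff K_I = IC50/(1 + L*/K_D), bootstrap CIs and
  fold differences vs a reference ligand.
- **synthetic** — generates every input with known ground truth: reference
  models M1′–M4′, matched actives, failing inactives, property-matched
  topologically dissimilar decoys (DUD-E-style), and simulated plates.

A conformer matches a model when an injective, kind-compatible assignment
of its features exists whose least-squares rigid superposition puts every
paired feature inside its tolerance sphere with no heavy atom inside an
exclusion volume. The matcher is validated against an exhaustive-search
oracle; the metrics engine reproduces the published benchmark table cells
that are derivable from its printed counts. See `docs/methods.md` for the
full model description and conventions.

## Worked example

```python
from pharmasieve import synthetic, pharmacophore, evaluation, assay

# 1. reference models and a scaled-down labelled benchmark
models = synthetic.make_reference_models()
spec = synthetic.BenchmarkSpec(n_actives=12, n_inactives=12, decoys_per_active=10, seed=7)
ds = synthetic.generate_benchmark(models["M3"], spec)

# 2. screen and evaluate
hits = pharmacophore.screen(models["M3"], ds.actives + ds.inactives + ds.decoys,
                            conformer_cap=5, seed=7)
counts = evaluation.tally([h.molecule_id for h in hits], ds)
metrics = evaluation.compute_metrics(counts, ds.sizes)
print(f"hits={metrics.total_hits}  sensitivity={metrics.sensitivity:.2f}  "
      f"EF={metrics.ef:.2f}  YoA={metrics.yoa:.2f}")

# 3. simulated competition plate -> KI and fold difference vs a reference
plate_spec = synthetic.PlateSpec(ki={"cmp19": 0.32e-6}, noise_cv=0.05, seed=11)
plate = synthetic.simulate_competition_plate(plate_spec)
result = assay.analyze_competition(plate, tracer_conc=plate_spec.tracer_conc,
                                   kd=plate_spec.kd, compound="cmp19",
                                   ki_ref=11.12e-6, n_resamples=200, seed=1)
print(f"KI = {result.ki*1e6:.3f} uM  (95% CI {result.ci95[0]*1e6:.2f}-{result.ci95[1]*1e6:.2f})  "
      f"fold difference vs reference = {result.fold_difference}")
```

Output:

```
hits=12  sensitivity=1.00  EF=12.00  YoA=1.00
KI = 0.342 uM  (95% CI 0.30-0.39)  fold difference vs reference = 32.5
```

All 12 constructed actives are retrieved and none of the 12 inactives or
120 decoys is, so the yield of actives is 1 and the enrichment factor
equals its ceiling N/n_act = 144/12 = 12. The plate was simulated from a
ground-truth K_I of 0.32 µM at 5 % multiplicative noise; the fitted,
Cheng–Prusoff-corrected K_I lands within ~7 % of truth and the bootstrap
CI brackets it. The fold difference divides the reference ligand's K_I
(11.12 µM) by the fitted value.

The same pipeline is scriptable from the shell:

```bash
pharmasieve simulate --seed 7 --out run/
pharmasieve screen   --seed 7 --out run/ --model-file run/M3.json --library run/actives.sdf
pharmasieve evaluate --seed 7 --out run/ --hits run/hits_M3.csv \
    --actives run/actives.sdf --inactives run/inactives.smi --decoys run/decoys.smi
pharmasieve report   --out run/
```

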