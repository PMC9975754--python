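# petburden

Quantifying whole-body metabolic tumor burden on FDG-PET, and asking how
much the answer depends on who curates the lesions.

In systemic lymphoma (and other FDG-avid malignancies), two imaging
biomarkers summarize disease burden on a baseline PET/CT:

- **MTV** (metabolic tumor volume, ml): the cumulative volume of lesion
  voxels whose SUV exceeds 41% of that lesion's SUVmax, summed over all
  accepted lesions;
- **TLG** (total lesion glycolysis, SUV·ml): per-lesion MTV × SUVmean
  over the 41% mask, summed across lesions.

Lesions are found by a liver-referenced rule: a 3-cm-diameter sphere in
normal liver gives a reference mean μ_L and SD σ_L, and connected
components of voxels above μ_L + 2σ_L become candidate lesions. A reader
then curates the candidates in one of two modes — **reader A**
(semi-automated: accept or reject candidates only) or **reader M**
(manual: may also edit boundaries and add missed lesions) — before the
per-lesion 41% isocontour is applied. Downstream, the package measures
how well the two curation styles agree (Lin's concordance correlation
coefficient ρ_c = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²) with Fisher-z CIs, and
Bland-Altman bias ± 1.96·SD limits of agreement), and whether the
biomarkers carry prognosis (median-split Kaplan-Meier with log-rank
tests, univariate and multivariable Cox models with LDH and ECOG, and
Poor/Better cut-point classification with reader/metric discordance
counts).

Because clinical scans are not distributable, the package ships a
synthetic layer with known ground truth: digital PET phantoms
(ellipsoidal liver/lesions/physiologic decoys, Gaussian point-spread
blur, additive noise), paired-reader measurement tables with tunable
multiplicative disagreement, and survival cohorts whose hazard is
log-linear in MTV.

## Worked example

```python
from petburden.phantom import default_phantom_spec, generate_phantom
from petburden.pipeline import quantify_phantom_both_readers

spec = default_phantom_spec(seed=0)
vol, truth = generate_phantom(spec)
q = quantify_phantom_both_readers(vol, truth, spec.liver.center_mm)
ref = q["liver"]
print(f"threshold {ref.detection_threshold:.3f}, sphere {ref.sphere_volume_ml:.2f} ml")
s = q["A"]["summary"]
print(f"reader A: MTV {s.mtv_ml:.2f} ml, TLG {s.tlg_suvml:.2f}, {s.lesion_count} lesions")
```

prints

```
threshold 2.131, sphere 14.33 ml
reader A: MTV 7.96 ml, TLG 45.96, 3 lesions
```

The liver sphere volume (14.33 ml) is the voxelized version of the
analytic 14.14 ml; the detection threshold is liver mean + 2 SD on the
blurred, noisy volume. All three malignant lesions are recovered (the
two physiologic decoys are removed in curation), and the measured MTV of
7.96 ml sits one partial-volume shell above the 7.30 ml analytic truth —
the blur pushes supra-threshold tails slightly outside the true
ellipsoids.

The numbered drivers under `analysis/` run the full study flow on the
simulated cohort and write tables under `results/`:

```bash
python analysis/01_phantom_quantification.py
python analysis/02_reader_concordance.py      # e.g. MTV rho_c 0.963 [0.944, 0.975]
python analysis/03_survival_prognosis.py      # e.g. univariate HR 1.00096 per ml
python analysis/04_cutpoint_discordance.py
```

There is also a CLI (`petburden run --config cfg.yaml`, plus
`phantom`, `simulate`, `quantify`, `concordance`, `survival`,
`prognosis` subcommands) that orchestrates the same stages with a
manifest and fixed seeds.

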