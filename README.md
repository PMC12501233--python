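# mitodyn

Quantitative toolkit for studying how high-grade serous ovarian carcinoma
(HGSC) cells rewire their mitochondria when starved of serum — the nutrient
stress that enriches quiescent, stem-like tumor cells relying on OXPHOS
rather than glycolysis.  The package bundles, as tested and reusable code:

* a **kinetic ODE model** of mitochondrial fusion–fission dynamics coupled
  to ATP energetics, parameterized per cell-line phenotype by measured
  ultrastructure (cristae width and density, crista-junction width,
  membrane potential) and fusion/fission protein levels (OPA1, DRP1);
* the **label-free proteomics (LFQ) enrichment filter** that calls
  condition-exclusive and differentially expressed proteins from triplicate
  intensity matrices;
* the closed-form **bioassay scores**: relative mtDNA content from qPCR
  ΔCt, caliper tumor volume, and the tumor inhibitory score comparing PKH
  label-retaining fractions per tumor volume across drug regimens;
* **seeded synthetic-data generators** with planted ground truth for every
  stage, so the full pipeline runs and is testable without any external
  download.

## The model

Four mitochondrial classes — healthy/deviant × unfused/fused (N_HU, N_DU,
N_HF, N_DF) — and an ATP pool A evolve as

```
dN_HU/dt = (B − M_H − F·A·e^s)·N_HU + K·A·e^(−s)·N_HF
dN_DU/dt = (B − M_D − F·A·e^s)·N_DU + K·A·e^(−s)·N_DF
dN_HF/dt = (B − K·A·e^(−s))·N_HF + F·A·e^s·N_HU
dN_DF/dt = (B − K·A·e^(−s))·N_DF + F·A·e^s·N_DU
dA/dt    = θ·[ε·(α·N_HF + N_DF) + (α·N_HU + N_DU)] − μ
           − K·A·(N_HF+N_DF)·e^(−s) − F·A·(N_HU+N_DU)·e^s
```

with θ = (c_n + e^{m_p})/(c_w + c_jw) the ultrastructural ATP production
factor, F = F₀·[OPA1] and K = K₀·[DRP1] the fusion/fission rates, s the
nutritional stress level, mitophagy (M_H, M_D) acting on unfused classes
only and biogenesis B balancing mitophagy exactly (conserving the total).
The packaged preset table holds the normalized parameters of five HGSC
lines spanning the epithelial→mesenchymal gradient (OVCAR3, CAOV3, OVCA420,
A4, OVMZ6) under serum-fed (+S) and serum-starved (SS) conditions.  See
`docs/methods.md` for assumptions, defaults and their rationale.

## Worked example

```python
from mitodyn import load_presets, run_panel, atp_contrast, unfused_depletion, rank_phenotypes

presets = load_presets(fill_missing="plus_serum")   # documented OVCAR3-SS fill rule
panel = run_panel(presets)                          # 10 scenarios, t ∈ [0, 10]
for cl in ("OVCAR3", "OVMZ6"):
    c = atp_contrast(panel[(cl, "serum_starved")], panel[(cl, "plus_serum")], 10.0)
    d = unfused_depletion(panel[(cl, "serum_starved")], 10.0)
    print(f"{cl}: ATP(SS)-ATP(+S) = {c.difference:+8.2f}  ratio = {c.ratio:5.2f}  "
          f"unfused fraction under SS = {d:.4f}")
print("HF ranking (+S):", rank_phenotypes(panel, "hf_count", "plus_serum", 10.0))
```

prints

```
OVCAR3: ATP(SS)-ATP(+S) =  +541.22  ratio = 10.07  unfused fraction under SS = 0.0220
OVMZ6: ATP(SS)-ATP(+S) =  +274.47  ratio = 11.80  unfused fraction under SS = 0.0011
HF ranking (+S): ['OVMZ6', 'A4', 'CAOV3', 'OVCA420', 'OVCAR3']
```

i.e. starvation raises model ATP roughly tenfold in both the epithelial
(OVCAR3) and mesenchymal (OVMZ6) extremes while the unfused classes are
almost completely depleted (≈2% and 0.1% of mitochondria remain unfused),
and under serum the fused (HF) count ranks highest in the mesenchymal and
lowest in the epithelial phenotype.

The same stages are scriptable from the shell:

```sh
mitodyn panel --fill-missing-ovcar3-ss --out out/panel
mitodyn synth --seed 1 --out out/synth
mitodyn enrich --in out/synth/lfq.csv --out-calls out/calls.csv --out-enriched out/enriched.txt
mitodyn scores --qpcr out/synth/qpcr.csv --xenograft out/synth/xenograft.csv --out out/scores
```

Every output CSV carries a JSON provenance sidecar and is byte-reproducible
given the same seed and configuration.

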