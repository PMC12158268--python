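# halochrom

Analysis toolkit for optimizing halochromic (pH-indicating) sensor films.

Wound pH is a biomarker of chronic-wound status: healthy healing tissue is
acidic, while persistent alkalinity (pH > 7) signals bacterial colonization
and infection. A PVA–PEG–BTB film — polyvinyl alcohol matrix, polyethylene
glycol plasticizer, bromothymol blue indicator — reports wound pH as a
visible color change (yellow in acid, green near neutral, blue in base),
and the quantity to optimize is its **response time**: how quickly the
color transition completes after the film meets the wound environment.

This package implements the computational side of that optimization:

1. **Color features** (`halochrom.color`) — masked film images or RGB
   triples to a 12-channel vector over four color spaces:
   (R, G, B, L, a, b, H, S, V, Y, Cb, Cr).
2. **Response-time detection** (`halochrom.stabilization`) — the transition
   is complete at the first frame from which the moving-averaged |gradient|
   of a channel (hue by default) stays below 0.001 units/frame for the rest
   of the recording, with at least 50 qualifying frames.
3. **Feature selection** (`halochrom.feature_selection`) — correlation-
   matrix PCA with the Kaiser criterion (retain eigenvalues > 1) and a
   from-scratch multiclass ReliefF, to identify the channels that best
   discriminate pH.
4. **Symbolic regression** (`halochrom.gp`) — multigene genetic programming
   fits `y = b₀ + Σᵢ wᵢ gᵢ(x₁, x₂)` where the genes `gᵢ` are evolved
   expression trees over PEG concentration x₁ and BTB concentration x₂ and
   the weights are re-fit by least squares at every evaluation.
5. **Bird-inspired metaheuristics** (`halochrom.optimizers`) — the Parrot
   Optimizer (PO), Pelican Optimization Algorithm (POA) and Secretary Bird
   Optimization Algorithm (SBOA) for bounded continuous minimization, plus
   the published formulation-fitness surface

   ```
   y = 4.34·10⁴x₂ − 123x₁ − 152 ln(x₁ + x₂ + ln x₂ + x₂²) + 1300 ln x₁
       − 668 ln x₂ − 4.17·10⁴x₁x₂² + 96.6x₁²x₂ − 4740
   ```

   on x₁ ∈ [6, 10], x₂ ∈ [0.01, 0.05] % w/v, and a deterministic
   grid + refine cross-check.
6. **Validation** (`halochrom.anova`) — balanced two-factor ANOVA with
   replication (PEG × BTB on response time), built from the sums-of-squares
   decomposition.
7. **Synthetic data** (`halochrom.synthetic`) — since the experimental raw
   data are available only on request, logistic color-kinetics and
   formulation→response-time generators reproduce the study conditions so
   every stage runs self-contained.

## Worked example

Minimize the formulation-fitness surface with all three metaheuristics and
the deterministic grid search:

```
python analysis/05_optimize_formulation.py
```

prints

```
grid+refine: PEG=6.000000 BTB=0.020148 fitness=188.595634
  PO: PEG=6.000000 BTB=0.020148 fitness=188.595635
 POA: PEG=6.000000 BTB=0.020148 fitness=188.595634
SBOA: PEG=6.000000 BTB=0.020148 fitness=188.595634
```

i.e. every optimizer lands on the same formulation — 6 % w/v PEG (the
lower design bound) and ≈0.0201 % w/v BTB — with a predicted transition
time of ≈188.6 s. Completing the published ANOVA decomposition
(`python analysis/06_anova_validation.py`) shows BTB concentration is the
significant driver of response time (F = 4.39 > F₀.₀₅ = 3.05) while PEG is
not (F = 0.48), matching the direction of the optimization result.

The numbered scripts under `analysis/` run the full story in order:
simulate kinetics and the 180-record design (`01`), detect response times
(`02`), select features (`03`), fit the GP surface (`04`), optimize the
formulation (`05`), validate with ANOVA (`06`). Outputs land under
`results/analysis/`. The same stages are callable through the CLI
(`halochrom-opt run --config config.yaml`, or the per-stage subcommands
`simulate`, `stabilize`, `select-features`, `gp-fit`, `optimize`, `anova`).

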