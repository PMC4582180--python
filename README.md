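# sjtools

Quantitative tool-chain for studying occluding-junction biology in
*Drosophila* epithelia: FRAP mobility analysis of septate-junction (SJ)
proteins, dye-penetration quantification of epithelial barriers, and
sequence comparison of tetraspan membrane-protein families.

Septate junctions are large multi-protein complexes that seal the
paracellular space of invertebrate epithelia and glia (including the fly
blood-brain barrier). A protein incorporated into the complex is nearly
immobile in the membrane; when the complex is disrupted, the same protein
diffuses freely. The package turns three raw readouts of this biology into
numbers:

* **FRAP kinetics** (`frap_extract`, `frap_fit`): a ~3 µm membrane segment is
  photobleached and imaged over minutes. After drift registration, ROI
  extraction and full-scale normalization, the post-bleach recovery
  (re-expressed relative to the first post-bleach value) is fitted with the
  one-dimensional free-diffusion model

      R(t) = F_m · (1 − (1 + t/τ_D)^(−1/2))

  yielding the characteristic diffusion time τ_D, the mobile fraction F_m
  (its complement never recovers) and the half time t_1/2 = 3 τ_D. Slow,
  small-F_m recovery ⇒ complex-bound; a ≥4× τ_D drop plus a ≥0.10 F_m rise
  between genotypes ⇒ a disrupted complex. Fits whose τ_D is not resolved
  within the recording window are flagged `extrapolated`.
* **Dye penetration** (`dye_quant`): mean pixel intensity of a nerve-cord ROI
  after excluding overexposed (saturated) regions such as the body cavity,
  followed by one-way ANOVA with the Student–Newman–Keuls step-down
  studentized-range post-hoc across genotypes.
* **Sequence family** (`seqfamily`): pairwise global alignment (BLOSUM62,
  affine gaps), percent identity and strong-group percent similarity under
  two denominator conventions, neighbor-joining trees on alignment
  p-distances, and Kyte–Doolittle hydropathy scans for transmembrane
  segments.

A first-class synthetic-data module (`synthetic_data`) generates FRAP curves
and image stacks (finite-difference diffusion with an immobile component,
PSF blur, photofading, specimen drift), dye-injection snapshots with
saturated regions, group measurement tables and a stand-in tetraspan family
— all with ground truth, so the entire chain is testable end to end.

## Worked example

```python
import sjtools as sj
from sjtools.synthetic_data import FrapSimParams

params = FrapSimParams(tau_d=2.2 * 60, f_m=0.65, noise_sd=0.02, seed=42)
curve, truth = sj.simulate_recovery_curve(params)
fit = sj.fit_recovery(curve, bootstrap=200, seed=1)
print(fit.tau_d / 60, fit.f_m, fit.t_half / 60, fit.extrapolated)

wt_curve, _ = sj.simulate_recovery_curve(FrapSimParams(tau_d=29.5 * 60, f_m=0.29))
print(sj.classify_mobility(sj.fit_recovery(wt_curve), fit).label)
```

prints (one noise realization)

```
3.02387563460927 0.7195769404818605 9.071626903827884 False
complex-disrupted
```

— the mutant-like curve refits to τ_D ≈ 3.0 min and F_m ≈ 0.72 (truth 2.2
min / 0.65, inside the bootstrap CI 2.2–4.1 min), resolved within the
10-minute window (`extrapolated=False`); against a slow wild-type-like
control (τ_D = 29.5 min, F_m = 0.29) the τ_D fold-drop and mobile-fraction
rise classify the protein as released from a disrupted complex.

The `examples/` directory holds one narrative script per capability
(`frap_curve_fitting.py`, `frap_stack_pipeline.py`,
`dye_penetration_stats.py`, `sequence_family.py`); each generates a small
input, runs the method and explains the numbers it prints. A thin CLI wraps
the same functions (`sjtools simulate|extract|fit|dye-quant|dye-stats|seq`).

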