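# fastfuse

Quantitative analysis of reovirus FAST-protein "fusion platform"
stoichiometry: how many protein copies make a fusion-competent cluster, and
how many clusters a cell needs to fuse with its neighbours.

Reovirus p10 is a tiny fusion-associated small transmembrane (FAST) protein
that drives cell–cell fusion from cholesterol-dependent plasma-membrane
microdomains. Because a single defective subunit poisons a whole cluster,
titrating functional against non-functional protein (a dominant-negative
titration) encodes the cluster stoichiometry in the decay of fusion
activity. This package implements that inference and the supporting
quantifications:

* **`fastfuse.stoichiometry`** — the cluster/site fusion model
  `F(f) = 1 − (1 − fⁿ)ˢ` (`f` functional fraction, `n` copies per cluster,
  `s` fusion sites per cell), nonlinear fitting with Jacobian-based
  uncertainties, the single-site binomial `fⁿ`, cluster-size inversion, and
  the half-maximal titration ratio.
* **`fastfuse.pixel_fret`** — pixel-wise sensitized-emission FRET (NFRET):
  background subtraction and blur, spectral bleed-through (SBT) models from
  single-fluorophore controls, `NFRET = Fc/√(I_d·I_a)`, 8-bit histograms
  (256 bins of 0.03906 NFRET units), Gaussian-mixture fits selected by R²,
  and condition-level summaries with propagated errors.
* **`fastfuse.assay_stats`** — percent lipid mixing
  `100·(F − F0)/(F_MAX − F0)` for liposome dequenching assays, and the
  syncytial index (mean ± SEM propagated within and across experiments).
* **`fastfuse.synthetic`** — deterministic generators for all four input
  kinds (titration curves, three-channel punctate FRET images, dequenching
  traces, field counts), each with ground-truth records.
* **`fastfuse.io` / `fastfuse.cli`** — CSV/TIFF/JSON/YAML plumbing and the
  `fastfuse` umbrella command.

## Worked example

```python
from fastfuse import (StoichModel, simulate_titration, fit_stoichiometry,
                      half_max_fraction, infer_cluster_size,
                      single_site_probability)

truth = StoichModel(n=8.74, s=5.17)          # reported best-fit values
curve = simulate_titration(truth, noise_sd=0.03, seed=20260926)
fit = fit_stoichiometry(curve)
print(f"n = {fit.model.n:.2f} +/- {fit.se_n:.2f}, "
      f"s = {fit.model.s:.2f} +/- {fit.se_s:.2f}, R^2 = {fit.r_squared:.4f}")

half = half_max_fraction(fit.model)
print(f"half-max at f* = {half.f_star:.3f} -> ~{half.ratio_rounded}:1")

est = infer_cluster_size(residual=0.0085, f=0.5)
print(est.ranking[:2],
      [round(single_site_probability(0.5, n, as_percent=True), 2)
       for n in est.ranking[:2]])
```

prints

```
n = 9.15 +/- 0.41, s = 5.63 +/- 0.59, R^2 = 0.9964
half-max at f* = 0.790 -> ~4:1
[7, 8] [0.78, 0.39]
```

Reading: the fit recovers the generating stoichiometry within its standard
errors; half-maximal fusion needs roughly four functional copies per
non-functional one; and a 0.85% residual activity at a 50/50 co-expression
is best explained by heptameric clusters (an all-functional heptamer occurs
with probability 0.78%), with octamers (0.39%) a close second.

The full analyses live under `analysis/` and write their tables to
`results/`:

```sh
python analysis/01_simulate_inputs.py          # all four synthetic input kinds
python analysis/02_fit_stoichiometry.py        # titration fit + derived ratios
python analysis/03_nfret_pipeline.py           # SBT -> NFRET -> condition stats
python analysis/04_lipid_mixing_and_syncytia.py
```

On the synthetic imaging conditions, the interacting scenario yields a
condition mNFRET of ≈0.30 against ≈0.018 for the non-interacting negative
control (a 16-fold separation), and the diffuse cholesterol-depleted
scenario shows no appreciable NFRET — mirroring the loss of FRET when
clustering is dissolved.

## Command line

```sh
fastfuse stoich-predict --n 7 --s 1 --f 0.5
fastfuse cluster-size --residual 0.0085 --f 0.5
fastfuse simulate titration --seed 5 --out sim/ && \
  fastfuse stoich-fit --input sim/titration.csv --out fit.json
fastfuse lipid-mix --trace traces.csv --f0 100 --fmax 600
fastfuse syncytia --counts counts.csv
fastfuse nfret --donor-control dctrl/ --acceptor-control actrl/ \
  --samples cells/ --out results/
```

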