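# ldbridges

Quantitative analysis toolkit for protein targeting to lipid droplets (LDs)
through ER–LD membrane bridges.

LDs store neutral lipid behind a phospholipid monolayer, and the enzymes
that expand or shrink them (GPAT4, DGAT2, ATGL) reach the droplet surface by
diffusing out of the ER through membrane bridges. This package implements
the statistics and physical models used to quantify that process in cells
and in vitro, for microscopists and biophysicists who want the analyses as
reusable, tested code rather than one-off scripts:

- **Colocalization vs a random-placement null.** Punctate foci (e.g. COPI
  machinery) overlap droplets when their centers are within `rLD + rA`.
  Under uniform random placement the chance of one focus overlapping any
  droplet equals the dilated-droplet area fraction
  `s = area(∪ disks of radius rLD + rA) / area_f`, so the colocalized count
  out of `nA` foci follows `Binomial(nA, s)`. Observed counts far above the
  null mode `n_s` are called *enriched*, far below *excluded*, using exact
  binomial tails (default α = 0.01), plus a paired t test across fields.
- **Bridge kinetics and bridge counting.** With constant ER concentration
  `C0` and `n_c` bridges of length `l` and section width `L`, droplet-bound
  protein obeys `dN/dt = n_c·kL·(C0 − N/S)` with `k = D/l`, giving
  `N(t) = C0·S·(1 − e^{−t/τ})`, `τ = lS/(n_c·D·L)`. Fitting τ (plus a lag
  and plateau) to a targeting time course and comparing with the
  single-bridge bulk time `τ_bulk = (l/L)·4πR²/D` yields
  `n_c = τ_bulk / τ`.
- **FRAP diffusion estimation.** Recovery at the center of a rectangular
  bleach of width `w` and depth `β` on a quasi-1-D ER tubule follows
  `F(t) = 1 − β·erf(w / 4√(Dt))`; least squares returns the apparent `D`.
- **Drop-weight tensiometry.** Interfacial tension from detachment volumes:
  `γ = mg/(πdf)` with `m = vΔρ` and `f` the Harkins–Brown geometric
  correction, interpolated from the classical table.
- **LD size distributions.** Kernel density estimates, mode counting and
  summaries distinguishing bimodal control-like populations from
  monodisperse or giant-droplet phenotypes.
- **Synthetic data.** Generators for every input above with planted ground
  truth, so each stage is testable end to end without microscope data.

## Worked example

```python
import numpy as np
import ldbridges as lb

# --- bridge counting from a targeting time course -----------------------
tc = lb.gen_timecourse(tau=3.6, lag=5.0, plateau=1.0, noise_sd=0.05, seed=0)
fit = lb.fit_targeting(tc)
est = lb.estimate_connections(fit, (21.0, 31.0))
print(f"tau = {fit.tau_min:.2f} ± {fit.tau_se:.2f} min")
print(f"n_c in [{est.n_c_range[0]:.1f}, {est.n_c_range[1]:.1f}]")

# --- colocalization verdict on a synthetic field ------------------------
spec = lb.FieldSpec(n_ld=30, n_foci=40, enrichment=0.5, seed=1)
image, truth = lb.gen_field(spec)
lds = lb.segment_particles(image[0], "ld", pixel_size_um=spec.pixel_size_um)
foci = lb.segment_particles(image[1], "focus", pixel_size_um=spec.pixel_size_um)
res = lb.analyze_field(foci, lds, alpha=0.01)
print(f"nA={res.nA} n_exp={res.n_exp} s={res.s:.3f} n_s={res.n_s} -> {res.verdict}")
```

prints

```
tau = 3.40 ± 0.19 min
n_c in [6.2, 9.1]
nA=40 n_exp=20 s=0.033 n_s=1 -> enriched
```

i.e. the fitted targeting time of ~3.4 min implies roughly 6–9 ER–LD
bridges given the 21–31 min single-bridge bulk diffusion time, and in the
enriched field 20 of 40 foci touch droplets where random placement over the
3.3% dilated-droplet area would most likely give 1 — decisive enrichment.

The same stages are scriptable from a shell:

```bash
ldbridges simulate timecourse --out tc.csv --tau 3.6 --lag 4
ldbridges kinetics fit tc.csv
ldbridges kinetics connections --tau-fit-min 3.6
ldbridges simulate field --out field.tif --enrichment 1.0
ldbridges segment field.tif --out lds.csv --channel 0 --channel-label ld
```

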