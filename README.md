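# cartiqmap

Quantitative MRI relaxometry of articular cartilage, coupled to a
depth-dependent computational model of tissue composition — packaged as a
reproducible, fully tested pipeline driven by synthetic osteochondral
phantoms.

## The problem

Quantitative MRI (qMRI) maps physical relaxation times — T1 (inversion
recovery), T1ρ (spin-lock) and T2\* (multi-gradient echo) — pixel by pixel
across the cartilage layer of an osteochondral sample. How those
relaxation times relate to the underlying tissue composition (fluid,
collagen and proteoglycan volume fractions, and the collagen fiber
arcade) is the scientific question this pipeline addresses: it fits the
relaxation maps, evaluates a depth-dependent composition model on the
same pixel grid, and correlates the two region by region.

Because pixel-wise fitting, depth normalization, zonal segmentation and
rank statistics each have subtle failure modes, every stage here is
exercised against a **synthetic phantom with known ground truth**: a
convex cartilage cross-section (condylar curvature 4.4/m, thickness
2–3 mm, width 15 mm) whose relaxation maps are generated from the
composition model through known monotone links, imaged through the exact
signal equations under Rician noise.

## The models

**Signal equations** (magnitude MRI, amplitude `A`, noise floor `B`):

- T2\*: `S(TE) = A·exp(−TE/T2*)`, with only echoes TE < 60 ms fitted
- T1ρ: `S(T_SL) = A·exp(−T_SL/T1ρ)`
- T1: `S(TI) = |A·(1 − 2·exp(−TI/T1) + exp(−TR/T1))|`

Each masked pixel is fitted by nonlinear least squares (multi-start for
the folded inversion-recovery magnitude) and gated on adjusted R² ≥ 0.95.

**Composition model.** At normalized depth `z` (0 = articular surface,
1 = osteochondral junction) the constituent volume fractions conserve
volume, `φ_fluid + φ_CO + φ_PG = 1`, with `φ_s = 1 − φ_fluid`. The
default profiles are monotone piecewise-linear curves calibrated so their
zonal means over the superficial (z < 0.15), transitional (0.15–0.65) and
deep (≥ 0.65) zones reproduce reference values of FF 78/70/51 %,
CO 8/9/20 %, PG 14/20/29 %. The mean collagen fiber orientation follows
the Benninghoff arcade: 90° from the surface normal in the superficial
zone, 0° in the deep zone, linear in between; fiber dispersion is
represented by eight equiangular fiber families.

**Statistics.** Spearman's ρ_s between each qMRI map and each modelled
parameter, pixel-wise within the central (6 mm) and peripheral regions;
exponential (`a·exp(b·φ)+c`) and sinusoidal (`a·sin(b·θ)+c`) best fits;
Mann–Whitney U across regions and Kruskal–Wallis with Dunn's post-hoc
test across zones.

## Worked example

```python
import numpy as np
import cartiqmap as cq

model = cq.calibrate_default_profiles()
z = np.array([0.05, 0.40, 0.80])
ff, co, pg = cq.composition_at(z, model)
for zi, f, c, p in zip(z, ff, co, pg):
    print(f"z={zi:.2f}  FF={100*f:5.1f}%  CO={100*c:5.1f}%  PG={100*p:5.1f}%  "
          f"CFO={float(cq.fiber_angle_at(zi)):5.1f} deg")

report = cq.run(cq.RunConfig(seed=7), write_outputs=False)
print("QC pass rates:", {k: round(v, 3) for k, v in report.qc_pass_rates.items()})
t1 = report.correlations.query("qmri == 'T1' and region == 'CR'")
for _, row in t1.iterrows():
    print(f"T1 vs {row['model']:<3} (CR): rho_s = {row['rho_s']:+.2f} {row['stars']}")
```

prints

```
z=0.05  FF= 79.3%  CO=  7.8%  PG= 12.9%  CFO= 90.0 deg
z=0.40  FF= 70.3%  CO=  9.3%  PG= 20.3%  CFO= 45.0 deg
z=0.80  FF= 53.2%  CO= 18.6%  PG= 28.2%  CFO=  0.0 deg
QC pass rates: {'T1': 1.0, 'T1RHO': 0.925, 'T2STAR': 1.0}
T1 vs FF  (CR): rho_s = +0.94 ***
T1 vs CO  (CR): rho_s = -0.94 ***
T1 vs PG  (CR): rho_s = -0.94 ***
T1 vs CFO (CR): rho_s = +0.91 ***
```

The composition evaluations show the depth gradient (fluid-rich
superficial tissue, collagen/proteoglycan-rich deep tissue and the fiber
arcade rotating from 90° to 0°). The end-to-end run at SNR 50 recovers
the designed correlation structure: relaxation times correlate positively
with fluid fraction and fiber angle and negatively with the solid
constituents, all highly significant in the central region. T1ρ loses a
few percent of pixels to QC because its five-point spin-lock series is
the least determined fit.

A command-line interface mirrors the library
(`cartiqmap run --config run.yaml`, plus `phantom`, `geometry`, `fit`,
`model` and `correlate` subcommands).

## Layout

- `src/cartiqmap/phantom.py` — synthetic samples, ground truth, Rician signal simulation
- `src/cartiqmap/geometry.py` — normalized depth, zones (SZ/TZ/DZ), regions (CR/PR), element grids
- `src/cartiqmap/relaxometry.py` — protocols, echo filtering, pixel-wise fits, adjusted-R² QC
- `src/cartiqmap/tissue_model.py` — composition profiles, fiber arcade, calibration
- `src/cartiqmap/stats.py` — Spearman tables, curve fits, group comparisons
- `src/cartiqmap/pipeline.py`, `cli.py` — orchestration, YAML config, CLI
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
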