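# cipls

Circularly polarized light scattering (CiPLS) depth imaging of layered
turbid media — polarimetric image processing plus a polarized Monte Carlo
phantom simulator.

## The problem

Early cervical neoplasia (CIN) is graded by how deep atypical cells extend
within the squamous epithelium, yet those cells are hidden below the
surface where cytology cannot sample them. Atypical cells carry enlarged
nuclei (roughly twice the normal diameter), and in the Mie regime the
depolarization of circularly polarized light (CPL) by multiple scattering
depends sharply on the particle-size-to-wavelength ratio. CPL also retains
its helicity through many forward-peaked scattering events, so
backscattered CPL reports on scatterers millimetres deep. Imaging the
signed degree of circular polarization

    DOCP = S3 / S0

of back-scattered light at two wavelengths (617 and 850 nm), and forming
the per-pixel difference `ΔDOCP = DOCP(617) − DOCP(850)` to cancel
wavelength-independent surface contributions, turns the burial depth of an
enlarged-nucleus layer into a measurable optical trend: as the healthy
overlayer thickness T1 grows, mean DOCP falls at 617 nm and rises at
850 nm, while ΔDOCP falls monotonically — and the thickness T2 of the
buried layer itself matters an order of magnitude less.

`cipls` implements the full analysis for this measurement:

* **`cipls.polarimetry`** — exact Stokes–Mueller algebra for the optical
  chain: the quarter-wave-plate Mueller matrix `M_QWP(θ)` (θ from
  vertical; at θ = 0 it maps `(S0,S1,S2,S3) → (S0,S1,−S3,S2)`), ideal
  analyzers, signed DOCP.
* **`cipls.mosaic`** — the division-of-focal-plane camera: split 2×2
  microgrid frames into `I0, I45, I90, I135`, estimate per-pixel
  `DOCP = −2(I45−I135)/(I0+I45+I90+I135)`, and a forward renderer
  (QWP + analyzer + gain + shot noise + quantization) for testing.
* **`cipls.pipeline`** — tissue segmentation on pseudo-intensity, ROI
  mean ± SD statistics, ΔDOCP maps, T1/T2 trend tables and the
  T2-vs-T1 sensitivity ratio.
* **`cipls.mie`** — Mie scattering-matrix tables (m11, m12, m33, m34),
  cross-sections and anisotropy for sphere scatterers, written from the
  series recurrences and cross-checked in tests against an independent
  evaluation.
* **`cipls.transport` / `cipls.phantom`** — meridian-plane polarized
  Monte Carlo through three-layer healthy/cancerous/healthy slabs under
  oblique elliptical CPL illumination, with the six-sample phantom set
  (T1 = 0–1.5 mm, T2 = 0.1–1.0 mm, total > 3 mm) and a scene renderer
  that turns simulated Stokes states into raw camera frames.
* **`cipls.workflow` / CLI `cipls`** — YAML-configured runs of the two
  experiments (T1 sweep, T2 sweep), CSV/TIFF artifacts, reports.

## Worked example

Simulate the depth experiment (samples 1, 4, 5, 6: T1 = 0.0, 0.5, 1.0,
1.5 mm at fixed T2 = 1.0 mm) and print the trend table:

```python
from cipls.workflow import RunConfig, run_t1_sweep

cfg = RunConfig(out_dir="demo_out", seed=5, n_photons=20000,
                scene_shape=(128, 128))
trend = run_t1_sweep(cfg)
print(trend.table[["sample_id", "t1_mm", "mean_docp_617",
                   "mean_docp_850", "delta_docp"]].to_string(index=False))
```

```
sample_id  t1_mm  mean_docp_617  mean_docp_850  delta_docp
        1    0.0       0.140995       0.047860    0.093135
        4    0.5       0.103848       0.055568    0.048280
        5    1.0       0.070922       0.095865   -0.024943
        6    1.5       0.065623       0.120382   -0.054759
```

Each row is one phantom imaged at both wavelengths through the camera
model and read back through segmentation + ROI statistics. The 617 nm
column falls and the 850 nm column rises as the cancerous layer is buried
deeper, and ΔDOCP falls monotonically — the depth signature. The same from
the shell:

```sh
cipls sweep t1 -c run.yaml && cipls report -d demo_out
```

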