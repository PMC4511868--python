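# hypersr

Multi-frame super-resolution and MCR-ALS unmixing for confocal Raman
hyperspectral maps.

## The problem

Far-field confocal Raman imaging is diffraction-limited: with a visible
laser the practical pixel size is ~1 μm, and even the theoretical confocal
limit `0.46 λ/NA` (272 nm for λ = 532 nm, NA = 0.9) is far better than
what instruments actually deliver (~0.6 μm measured by step-edge
metrology). For sub-micron samples — e.g. individual atmospheric aerosol
particles — that is not enough to see internal chemical structure.

`hypersr` implements a purely computational route past this limit, aimed
at spectroscopists who can command sub-pixel stage shifts between map
acquisitions:

1. **Multi-frame super-resolution.** Each low-resolution chemical map
   `C_k` (M₁ × M₂ pixels) is modelled as a translated, blurred, decimated
   view of one ideal high-resolution map `c`:

   `C_k = X H T_k c + E_k`

   with `T_k` the known integer translation on the fine grid (piezo
   shifts), `H` the optical PSF blur, `X` stride-`k` decimation and `E_k`
   Gaussian noise. Given `N` frames the largest sensible upsampling factor
   is `k = ⌊√N⌋`. The map is recovered by MAP estimation,

   `min_c  Σ_k ‖X H T_k c − C_k‖₁ + λ · BTV(c)`,

   where BTV is the bilateral total-variation prior
   `Σ_{l,m} α^{|l|+|m|} ‖c − S_x^l S_y^m c‖₁`.

2. **MCR-ALS multiset unmixing.** The shifted hyperspectral cubes are
   AsLS baseline-corrected (asymmetric least squares on a Whittaker
   smoother), unfolded, and stacked into a column-wise augmented matrix
   `D = C Sᵀ + E` factored by alternating least squares under
   non-negativity and spectral normalization, initialized by SIMPLISMA.
   Fit quality: `lof = 100·√(Σe²/Σd²)`, `r² = 100·(1 − Σe²/Σd²)`.
   Refolding the per-frame blocks of `C` gives, for every chemical
   component, its own series of shifted maps — each super-resolved
   independently.

3. **Step-edge metrology.** Resolution is quantified from edge-response
   profiles: derivative → FWHM, mean ± std over several profiles, before
   and after reconstruction.

No instrument is required: the `synthetic` module simulates bar/edge
resolution targets and multi-component particle fields through exactly the
forward model above, so the whole chain is testable at desk scale.

## Worked example

Measure the resolution gain on a simulated step-edge target: 25 frames of
12 × 12 pixels (1 μm pitch) shifted on a 5 × 5 grid of 200 nm steps,
imaged through a 0.59 μm FWHM Gaussian PSF at SNR 40, reconstructed with
k = 5:

```python
from hypersr.workflow import RunConfig, run_workflow

config = RunConfig(
    workflow="target_sr", output_dir="demo", seed=0,
    simulate={"n_side": 5, "step_um": 0.2, "canvas": 60,
              "hr_pixel_size": 0.2, "noise_sigma": 0.025},
    sr={"k": 5, "psf_fwhm": 0.59, "n_iter": 50},
)
report = run_workflow(config)
print(report["metrics"]["x"])
```

prints (abridged):

```
{'k': 5, 'sr_shape': [60, 60],
 'lr_fwhm_mean_um': 2.0,        'lr_fwhm_std_um': 0.0,
 'sr_fwhm_mean_um': 0.4420844494, 'sr_fwhm_std_um': 0.0253657753,
 'n_profiles': 8, ...}
```

A single 1 μm-pixel frame is sampling-limited at 2.0 μm FWHM; the fused
60 × 60 map at 200 nm pixels measures 0.442 ± 0.025 μm — a 78% gain, with
the y direction giving 0.431 ± 0.025 μm. The same `run_workflow` with
`workflow="aerosol_mcr_sr"` runs the full chemical-imaging chain (25
simulated cubes → AsLS → multiset MCR-ALS → per-component 60 × 30
super-resolved maps) and reports `lof`, `r²` and per-component geometry.

The same stages are available from the shell:

```bash
hypersr simulate --kind aerosol --out sim --seed 1
hypersr baseline sim/cube_000.h5 --out corrected.h5
hypersr resolution demo/sr_edge_x.h5 --axis x
hypersr run -c config.yaml --seed 1
```

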