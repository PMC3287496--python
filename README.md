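# rdpad — robust detail-preserving anisotropic diffusion for ultrasound speckle

Speckle — the granular interference pattern of coherent imaging — degrades
ultrasound images and complicates downstream tasks such as follicle or lesion
segmentation. This package implements a family of speckle-reducing
anisotropic-diffusion filters for 2-D ultrasound (and other multiplicative-noise)
images, centered on the **robust detail-preserving anisotropic diffusion
filter (RDPAD)**, together with the three filters it descends from: SRAD,
DPAD, and the Tukey-robust SRAD variant. It is aimed at medical-image-analysis
researchers who need an edge-preserving despeckler whose output does not
degrade as the iteration count grows.

It ships with a seeded synthetic speckle-phantom generator and the
region-contrast evaluation metric, so every qualitative claim about the
filters is checkable without any image download.

## The model

All four filters integrate the anisotropic diffusion PDE

```
∂I/∂t = div( c · ∇I ),    I(t=0) = I₀
```

explicitly on the pixel grid, differing only in how the diffusion
coefficient c ∈ [0, 1] is computed from the **instantaneous coefficient of
variation (ICOV)** q(i,j;t) — a per-pixel generalization of std/mean that is
≈ q₀(t) (the speckle scale) in fully developed speckle and large at edges:

| method | ICOV estimator | diffusion coefficient c(q) |
|--------|----------------|-----------------------------|
| `srad`   | differential (gradients + Laplacian) | 1 / (1 + (q²−q₀²)/(q₀²(1+q₀²))) |
| `dpad`   | 5×5 window: s²/Ī² | (1 + 1/q²) / (1 + 1/q₀²) |
| `tauber` | differential | ½(1−S)² if S ≤ 1 else 0, S = (q²−q₀²)/(q₀²(1+q₀²)) |
| `rdpad`  | 13-pixel diamond, pairwise differences | ½(1−R)² if R ≤ 1 else 0, R = (q²−q₀²)/(q₀²(1+q²)) |

The RDPAD coefficient is the Tukey biweight kernel applied to the normalized
excess R; it is **exactly zero** wherever q² > 2q₀²/(1−q₀²), so diffusion
stops at edges instead of slowly eroding them — the DPAD coefficient stays
positive everywhere, which is why DPAD keeps smoothing details as iterations
accumulate. The identity c_dpad = 1/(1+R) links the two rules. The diamond
ICOV uses the 13 pixels at city-block distance ≤ 2:

```
q² = (1/12) Σ_{m<n} (vₙ − vₘ)²  /  Σ_m vₘ²        (v₀..v₁₂ in the diamond)
```

The speckle scale follows q₀(t) = q₀·exp(−ρt) in diffusion time t = n·Δt
(defaults q₀ = 1, ρ = 1/6), or can be re-estimated each iteration as the
median ICOV (`q0_mode="median"`).

## Worked example

```python
from rdpad import (DiffusionConfig, Disk, make_phantom, mse,
                   region_contrast, run)

# 128x128 piecewise-constant phantom: disk at 200 on background 50,
# fully developed multiplicative speckle (looks = 1)
ph = make_phantom(128, 128, [Disk(cy=64, cx=64, r=30, level=200.0)],
                  background=50.0, looks=1.0, seed=0)

filtered, _ = run(ph.noisy, DiffusionConfig(method="rdpad", n_iter=300, dt=0.05))

for name, img in [("noisy", ph.noisy), ("rdpad", filtered)]:
    print(f"{name:>6}  Cw(homog)={region_contrast(img, ph.homog_mask).cw:8.2f}"
          f"  Cw(edge)={region_contrast(img, ph.edge_mask).cw:8.2f}"
          f"  MSE={mse(img, ph.clean):8.1f}")
```

prints

```
 noisy  Cw(homog)= 1465.13  Cw(edge)= 3152.24  MSE=  8934.1
 rdpad  Cw(homog)=    3.79  Cw(edge)=   88.02  MSE=   233.2
```

The region contrast Cw = (1/m) Σ_w |c|·log(1+|c|) (c the local 4-neighbor
Laplacian contrast) drops by 99.7 % in the homogeneous region — the speckle
is gone — while the edge set keeps substantially more contrast than DPAD
does under the same protocol (88.0 vs 32.8), and the error to the clean
phantom falls 38-fold. Running `dpad` and `rdpad` to 1000 iterations shows
RDPAD also drifts less after iteration 300, i.e. it is less sensitive to the
iteration count.

The same pipeline is available from the shell:

```
rdpad phantom --height 128 --width 128 --shape disk:64,64,30,200 \
      --background 50 --looks 1 --seed 0 \
      --out noisy.tif --out-clean clean.tif --out-masks masks.png
rdpad --log-level INFO despeckle --method rdpad --iters 300 --dt 0.05 \
      --in noisy.tif --out filtered.tif
rdpad metrics --in filtered.tif --ref clean.tif \
      --mask masks.png --region edge --json
rdpad compare --in noisy.tif --ref clean.tif --mask masks.png \
      --methods srad,dpad,rdpad --iters 300 --record-every 100 --out-csv cmp.csv
```

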