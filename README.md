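# tubulekit

Quantification of filamentous organelle networks — endoplasmic-reticulum
(ER) tubules in particular — from fluorescence microscopy images and
videos. ER tubules (~100 nm diameter) meet at junctions and behave as
semiflexible polymers jostled by both thermal motion and active,
motor-driven forces. `tubulekit` measures both the static architecture of
such a network and the dynamics of individual tubules, and ships a seeded
filament simulator + video renderer so every analysis stage can be
validated against known ground truth.

## What it measures

**Network morphometrics** (`tubulekit.network`). From SOAX-style snake
tracings of still images: tubule contour lengths L, junction coordination
numbers (2-, 3-, 4-way), junction angles (from line fits to the 5 points
nearest each junction), and the persistence length L_p by fitting the
Kratky–Porod worm-like-chain relation to per-tubule contour length and
end-to-end distance R:

    ⟨R²⟩ = 2 L_p ( L − L_p (1 − e^(−L/L_p)) )

**Sub-pixel point tracking** (`tubulekit.point_tracker`). The tubule
position along a user-drawn perpendicular line, per video frame: bicubic
profile extraction, kriging upsampling to 100 values, an SNR gate
calibrated on simulated profiles, and a robust (Cauchy-weighted) Gaussian
+ offset fit whose centre μ is the tubule position.

**MSD analysis** (`tubulekit.msd`). Time-averaged mean squared
displacement ⟨Δr²(τ)⟩ and the anomalous-diffusion exponent α from a
power-law fit ⟨Δr²(τ)⟩ ∝ τ^α, with a lognormal population summary.
α ≈ 1 is Brownian; untensioned thermal semiflexible filaments give
α = 3/4 transverse to the backbone and tension-dominated filaments give
α = 1/2.

**Whole-contour tracking** (`tubulekit.contour_tracker`). An open active
contour follows the tubule in every frame (seeded frame-to-frame). Per
backbone point it reports the transverse variance, the bias-corrected
skewness s with its standard error σ_s, the z-score s/σ_s (significant if
|z| > 3.29), and the line density of significantly skewed points — skewness
marks activity-driven motion, since purely thermal fluctuations are
symmetric about the backbone.

**Fourier mode decomposition** (`tubulekit.fourier`). Tangent-angle
cosine modes a_n with amplitude a_n = √(2/L) Σ_k θ_k Δs_k cos(nπs_k/L);
a mode is *sustained* (prestress signature) when |⟨a_n⟩| − 1.5 σ_{a_n} > 0.

**Association-rule mining** (`tubulekit.mining`). An 8-column
presence/absence matrix over four per-tubule properties (sustained
curvature, peripheral position, MSD exponent ≥ 0.4, significant skewness)
mined exhaustively for rules A→B scored by support, confidence and lift.

**Simulation** (`tubulekit.simulate`). Static worm-like chains, overdamped
Langevin dynamics of a semiflexible bead chain (thermal, tensioned, or with
intermittent active kicks), Brownian point tracks, and rendering to noisy
microscopy-like image stacks with ground-truth sidecars.

## Worked example

```python
import numpy as np
from tubulekit.network import fit_persistence_length
from tubulekit.simulate import sample_wlc_ensemble, simulate_brownian_track
from tubulekit.msd import compute_msd, fit_msd_exponent

# persistence length from 2000 sampled worm-like chains at Lp = 8.3 um
L_values = np.tile(np.linspace(0.5, 10.0, 20), 100)
L, R = sample_wlc_ensemble(Lp=8.3, L_values=L_values, n_points=50,
                           convention="eq1", seed=0)
fit = fit_persistence_length(list(zip(L, R)))
print(fit.summary())

# anomalous-diffusion exponent of a Brownian control track
track = simulate_brownian_track(D=0.01, dt=0.03, n_frames=1000, seed=1)
msd = fit_msd_exponent(compute_msd(track))
print(msd.summary())
```

prints

```
Persistence length Lp = 8.004 +/- 0.15 um (n = 2000 tubules, RMS residual 8.77 um^2)
MSD over 500 lags (0.03-15 s)
power-law exponent alpha = 0.971 +/- 0.005, prefactor 0.03721 um^2/s^alpha
```

The fitted L_p recovers the generating value within its sampling error,
and the Brownian track's exponent sits at α ≈ 1 as diffusion theory
requires (single-track exponents scatter by about ±0.05 at 10³ frames).

## Command line

A thin CLI wraps the library:

```
tubulekit network traced.txt --pixel-size 0.104
tubulekit track-point video.tif --line 24 10 24 30
tubulekit msd track_point_out/track.csv
tubulekit track-contour video.tif --endpoints 8 20 40 20
tubulekit modes track_contour_out/contours.csv
tubulekit mine matrix.csv
tubulekit simulate --regime thermal --n-frames 2000
tubulekit render sim/truth.csv --noise 3
tubulekit calibrate-snr
```

Every command writes a `manifest.json` recording inputs, parameters and
seeds for reproducibility.

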