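# Methods

This note documents the models, estimators and numerical choices behind
`tubulekit`, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate about real microscopy data.

## Coordinate and unit conventions

Image coordinates are pixels, origin at the centre of the top-left pixel,
x rightward, y downward; physical lengths are converted to micrometres
only at reporting time through `pixel_size` (default 0.104 μm/px, a common
value for a 100× objective on an sCMOS camera). The simulator works
directly in micrometres, seconds, and thermal-energy units (k_BT = 1 by
default), with forces in k_BT/μm and a per-bead drag coefficient.

## Network morphometrics

Tubules are polylines between network branch points, read from SOAX-style
snake text output (a parameter header, `s p x y z fg_int bg_int` point
records grouped by snake id, and a junction-coordinate section after a `#`
line; the package writes the same layout, and parse→write→parse is the
identity). Junction membership uses a 2 px search radius (configurable);
coordination number = number of tubule ends within the radius. Junction
angles come from total-least-squares lines through the 5 points of each
member tubule nearest the junction (all points when a tubule has fewer —
discarding short tubules would bias the angle sample). Two-way junctions
report the single angle between the two emanating rays in (0°, 180°];
higher-order junctions report the angles between angularly adjacent rays,
which sum to 360°.

### Persistence length

The worm-like-chain relation ⟨R²⟩ = 2L_p(L − L_p(1 − e^(−L/L_p))) is fit
to per-tubule (L, R²) pairs by nonlinear least squares (initial guess
median(L), bounds 10⁻³–10⁴ μm, `expm1` used so the small-L/L_p limit
⟨R²⟩→L² is numerically exact). Raw-pair fitting is the default; an
equal-count L-binning option (mean R² per bin) matches classic WLC
practice — on clean synthetic data the two agree. A fit that runs into the
upper bound is flagged `near_rigid`: R = L data carry no curvature
information and L_p is unidentifiable. This relation is the
three-dimensional Kratky–Porod form; applying it to 2D-projected contours
is a modelling choice inherited from common practice, and the simulator's
`"eq1"` sampling convention (tangent correlation e^(−s/L_p)) generates
data exactly consistent with it, while `"2d"` gives the planar convention
e^(−s/2L_p).

## Point tracking

Per frame: (1) optional preprocessing — difference-of-Gaussians band-pass
(suppress structure larger than 10 px and smaller than 1 px) then
rolling-ball background subtraction (radius 50 px), both configurable;
(2) bicubic (order-3 spline) sampling along the fixed user line;
(3) kriging upsampling to 100 values; (4) SNR gate; (5) robust Gaussian
fit. Frames failing the gate or the fit are flagged invalid and excluded
from MSD computation rather than interpolated — interpolation would bias
short-lag MSD downward.

**Kriging.** Universal kriging with a Gaussian covariance (length scale
2× the mean sample spacing, zero nugget) and a linear drift, solved
directly; the drift terms make the interpolant exact on linear ramps and
the zero nugget makes it pass through every raw sample. When the
covariance matrix condition number exceeds 10¹⁰ the routine falls back to
a natural cubic spline and flags it.

**SNR gate.** SNR = (max of lightly smoothed profile − median) / noise,
where noise = 1.4826·MAD(first differences of below-median samples)/√2.
The below-median (background) samples of a ridge profile are nearly
constant, so their difference spread estimates measurement noise without
being inflated by tubule structure; smoothing-residual estimators were
found to saturate at low noise and break the monotonic SNR–noise
relation. An exactly flat background yields zero noise and SNR = +∞ (the
profile passes). The threshold is not hard-coded: `calibrate_snr_threshold`
sweeps simulated profiles over noise levels and returns the SNR at which
the median centre error first reaches 1% of the tubule width.

**Centre fit.** a + b·exp(−(u−μ)²/2σ²) by iteratively reweighted least
squares with Cauchy weights w = 1/(1 + (r/(2.385·ŝ))²), ŝ the MAD scale of
the current residuals (2.385 is the standard Cauchy tuning constant).
Non-convergence flags the frame invalid instead of raising; fits with σ
below 0.5 px or beyond the profile span are also flagged. The fit is
exactly shift-equivariant.

## MSD analysis

Time-averaged MSD over all valid ordered pairs per lag (pairs containing
an invalid frame are skipped; lags with fewer than 3 pairs dropped). The
exponent is fit by weighted linear regression of log MSD on log τ. The
default window runs from the 2nd lag to max lag/10, and weights are
n_pairs·k/(2k²+1) in lag index k — the inverse of the approximate relative
variance of time-averaged MSD, which grows ~k²/n. A long window (¼ of the
track) with pair-count weights was tried first and roughly doubles the
exponent scatter on Brownian controls (SD 0.10 vs 0.05 at 10³ frames),
because long-lag time averages of one trajectory are dominated by a few
highly correlated excursions. Even with the short window, a single
1000-frame track determines α only to about ±0.05 (1 SD) — this is an
information limit of single-trajectory analysis, not an implementation
artefact; ensemble averaging MSDs before fitting (`average_msd`) reduces
it as 1/√replicates.

The population summary fits a lognormal by maximum likelihood on the
exponent samples (bin-free and reproducible; a histogram least-squares
option exists for comparability with binned workflows), and reports the
distribution mean e^(μ+σ²/2) with a delta-method standard error.
Classification: α<1 sub-diffusive, α>1 super-diffusive, with a separate
flag for strongly sub-diffusive α < 0.4.

## Contour tracking

The open snake minimises elasticity (first-difference) + stiffness
(second-difference) internal energy plus an external ridge-attraction
energy whose force is the gradient of the Gaussian-smoothed frame,
normalised to unit maximum so weights transfer across intensity scales.
Each iteration takes an implicit internal step (endpoints held during the
solve), an explicit external step (endpoints included, but with the
tangential force component removed at the tips so the contour cannot slide
or shrink along the ridge), then resamples to K equally spaced points —
fractional-arclength correspondence is what makes per-point statistics
across frames well defined. Convergence: max point displacement < 5·10⁻³
px or 400 iterations. Video tracking seeds each frame from the previous
converged contour; a frame whose length changes by more than 20% is
re-evolved with 4× internal weights and, if still jumping, replaced by the
previous contour and flagged. Defaults were tuned once on the synthetic
renderer (straight and curved ridges converge to ≲0.05 px RMS).

### Backbone statistics and the skewness test

All frames are rotated/translated by one rigid transform putting the
time-mean backbone endpoints on the x-axis; transverse displacement is the
y-deviation from the per-point mean. Variance is the population variance.
Skewness uses the bias-corrected form s = √(n(n−1))/(n−2) · m₃/m₂^{3/2}
and the Cramér standard error σ_s = √(6n(n−1)/((n−2)(n+1)(n+3)));
z = s/σ_s, significant when |z| > 3.29 (a 5% two-sided level adjusted for
the many points tested). An alternative σ_s with the radical over the
numerator only is provided as `ses_form="as_printed"`; at n = 10 it gives
0.020 versus 0.687 and would declare nearly everything significant, so the
standard form is the default. Zero-variance points return NaN skewness and
are never significant. The skewed-point line density is the count of
significant points divided by the backbone length in μm.

## Fourier modes

Tangent angles use the two-argument arctangent of successive point
differences, unwrapped — a single-argument arctangent is ambiguous for
steep segments. Amplitudes a_n = √(2/L) Σ θ_k Δs_k cos(nπs_k/L) with s_k
the segment-midpoint arclengths; with uniform segments this is a DCT-II up
to normalisation, so decompose→reconstruct is an exact projection. In
reconstruction the n = 0 term carries the standard cosine-series half
weight — a uniform sum would return twice the mean angle. Mode count:
n ≤ L/max(Δs) (two samples per wavelength, conservative for nonuniform
segments), n ≤ N−2, and at most 10. Sustained curvature: mode n ≥ 1 with
|⟨a_n⟩| − 1.5·SD(a_n) > 0; mode 0 is excluded because any straight but
tilted tubule has a_0 ≠ 0. Under Gaussian fluctuations the 1.5σ criterion
corresponds to ≈93% of frames on one side of zero; the empirical one-sided
fraction is reported next to the flag so users can see the actual
asymmetry.

## Itemset mining

The matrix has one row per tubule and 8 columns: presence and absence of
sustained curvature, peripheral position, MSD exponent ≥ 0.4 (0.4 itself
counts as present), and significant skewness (≥1 significant backbone
point). Peripheral means the mean normalised depth
d = d_nucleus/(d_nucleus + d_cell-edge) over backbone points is ≥ 0.9
(outermost 10% of the nucleus-to-edge span); a max-depth aggregation is
available since "resides in the outer band" admits either reading.
Mining enumerates all ≤255 nonempty itemsets exhaustively (8 items makes
Apriori-style pruning unnecessary), pruning itemsets that contain a
property's presence and absence simultaneously, and scores every
antecedent/consequent bipartition: support = P(A∪B),
confidence = P(A∪B)/P(A), lift = confidence/P(B). Rules need
support ≥ 0.1 and confidence ≥ 0.9 by default. The miner is checked
rule-for-rule against an independent naive enumerator on random matrices.

## Simulator

**Worm-like chains** are tangent-angle random walks with per-step angle
variance Δs/L_p (`"2d"`) or 2Δs/L_p (`"eq1"`, tangent correlation
e^(−s/L_p), consistent with the 3D Kratky–Porod end-to-end relation).

**Dynamics** are overdamped (inertialess) Euler–Maruyama integration of a
bead chain: harmonic bonds (k_stretch, default 2000 k_BT/μm²), discrete
bending forces from the fourth-difference of positions with
κ = L_p·k_BT, thermal noise of variance 2k_BTγ/dt per axis, and optional
active forcing. Tension is realised by shortening the bond rest length by
T/k_stretch between pinned ends, which places the chain under uniform
line tension T; tension with free ends is rejected. Untensioned pinned
filaments get 5% end-separation slack (a shallow sine arc initial shape)
so transverse fluctuation doesn't have to stretch bonds. A configuration
validates dt against the stiffest mode (dt ≤ γ/max(4k_stretch, 16κ/a³))
and the integrator aborts if any bead moves a bond length in one step.
Runs are warmed up for two relaxation times of the slowest transverse mode
before recording (none for free ends at kT = 0), and are bit-reproducible
under a fixed seed. `simulate_filament_ensemble` integrates replicate
filaments jointly (vectorised) for cheap ensemble statistics.

**Active forcing** is an intermittent telegraph-burst force: bursts start
at a configured rate, last exponentially distributed times, and apply a
constant force along a fixed direction at chosen beads. A persistent
nonzero-mean force was tried first and merely shifts the mean of the
(still symmetric) displacement distribution; intermittent bursts are what
produce the direction-biased, skewed displacements that motor kicks or
membrane-contact pulls would leave. The shipped `active_kick_config`
(T = 3, kT = 0.08, amplitude 12 k_BT/μm, ~12% duty cycle) makes bursts
deflect the kicked bead ~5–6 thermal SDs, i.e. strong rare kicks — the
regime the skewness marker is designed to detect; frames are recorded one
relaxation time apart so successive displacements are nearly independent
and the n-sample skewness standard error applies.

**Rendering** draws each contour as a dense line source (0.2 px spacing)
of 2D Gaussians, giving an exactly Gaussian cross-section of the
configured PSF σ peaking at the configured intensity on the ridge, plus
background and Poisson and/or Gaussian noise. Ground truth is returned in
the pixel coordinates of the rendering.

### Theory-anchored regimes and fit windows

Transverse MSD of a filament point follows τ^{3/4} below the slowest
bending relaxation time for an untensioned thermal filament, and τ^{1/2}
in the tension-dominated case. The shipped regime presets are
L = 10 μm, L_p = 5 μm, 65 beads, free ends (thermal; τ₁ = ξ/(κq₁⁴),
q₁ = 4.73/L) and L = 5 μm, T = 50 k_BT/μm, pinned (tension;
τ₁ = ξ/(Tq₁²), q₁ = π/L), both at dt = 2·10⁻⁵ s with frames every 10⁻³ s.
Midpoint transverse displacement is measured against the instantaneous
end-to-end axis, removing rigid-body translation and rotation of free
filaments. Exponents are fit over (10·frame-interval, min(τ₁/8,
duration/20)): below ~τ₁/8 to stay clear of the terminal-relaxation
shoulder, and capped by duration so long lags with poor time-averaging
statistics are excluded. Acceptance runs average MSDs over 6 jointly
integrated replicates of 10⁴ frames (~30–40 s each on one CPU), which
brings the exponent scatter to ~±0.02.

## What the synthetic tests do and do not show

The renderer produces an idealised microscope: exactly Gaussian PSF,
stationary background, uncorrelated noise, no photobleaching, no focal
drift, no crossing tubules or junction remodelling. Passing tests
demonstrate that each estimator recovers known ground truth under these
conditions and that the statistical machinery (SNR gate, skewness
significance, sustained-curvature rule, rule mining) behaves as designed;
they do not certify performance on real videos with structured background,
out-of-focus light, or tracking through junction rearrangements — the
tool deliberately restricts contour tracking to established tubules
connected at both ends throughout the observation. The bead-chain
simulator likewise omits hydrodynamic coupling, network-level dynamics
(fusion, new junctions) and 3D excursions.

## Known limitations

- The persistence-length relation is the 3D convention applied to
  2D-projected contours; absolute L_p values inherit that convention.
- Single-track MSD exponents carry ±0.05–0.1 statistical scatter at 10³
  frames; population statements should use many tubules or ensemble
  averaging.
- The SNR threshold is calibration-dependent; re-run `calibrate-snr` when
  imaging conditions change materially.
- Bending-rigidity estimation from mode-amplitude variances is
  deliberately out of scope: in vivo boundary conditions and tension
  violate the assumptions that make ⟨a_n²⟩ ∝ 1/n² quantitative.
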