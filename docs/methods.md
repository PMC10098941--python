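# Methods

## Brightness model and colour reconstruction

All enhancement operates on the brightness image L(x,y) = max(R, G, B) of an
RGB frame with channels in [0, 1].  The max-channel definition is load-bearing:
after tone mapping L_out = t(L_in), the colour image is rebuilt per pixel as
I_out = I_in · L_out/L_in.  Because L_in is the channel maximum, every output
channel is bounded by L_out ≤ 1, so the reconstruction can never leave the
display range, and the R:G:B ratios (chromaticity) are preserved exactly
wherever L_in > 0.  Pixels with L_in = 0 are returned black: the scaling is
0/0 there and black is the only chromaticity-free answer.

8-bit files are mapped to [0, 1] by dividing by 255 and written back by
rounding to the nearest 8-bit level.

Histograms use N = 256 half-open bins ((j−1)/N, j/N]; exact zeros — absent
from the idealised (0, 1] brightness domain but present in real images — are
folded into bin 1.  A tone curve is the 256-vector of outputs at the right
bin edges j/N; between nodes it is evaluated by linear interpolation with an
implied (0, 0) anchor.  The source material defines curves only at the 256
samples, so the interpolation rule is this package's choice: linear avoids
overshoot and banding and keeps monotonicity trivially.  Non-monotone curves
are rejected rather than repaired, matching the constraint that only
monotonically increasing tone maps are meaningful here.

## HE and CLHE

Histogram equalisation uses the cumulative histogram as the tone curve; its
slope at node j is N·h_j exactly, so a flat histogram yields the identity
("null") curve.  CLHE bounds those slopes to [m, M] = [0.5, 2] by replacing
the histogram with a proxy h′.  The literature characterises the classic
clip-and-redistribute iteration as *empirically* minimising a least-squares
error without defining it precisely, so this package implements the exact
Euclidean projection onto {h′ : m/N ≤ h′_j ≤ M/N, Σ h′ = 1}: a uniform shift
clipped to the box, h′_j = clip(h_j + τ, m/N, M/N), with τ solved by Brent
root-finding on the sum constraint (the KKT conditions of the projection have
exactly this water-filling form).  The projection is deterministic and
idempotent; tests cross-check it against a generic SLSQP quadratic program at
N = 8.  Bounds are feasible iff m ≤ 1 ≤ M, which the constructor enforces.

## Weibull proxies

The Weibull density h_W(b; λ, k) is truncated at b = 2.55 — beyond which the
distributions of interest carry no appreciable mass — and the axis divided by
2.55 so proxies live on [0, 1].  Discrete proxy masses are CDF differences at
the bin edges (not midpoint density values), which makes the cumulative of
the discrete proxy agree with the analytic CDF at every edge to machine
precision.  Whether the truncated distribution is renormalised was left open
by the source material; we divide by the retained mass T(2.55) so the proxy
is a proper distribution for every (λ, k) — for large λ or small k the tail
mass beyond 2.55 is not negligible and an unnormalised proxy would not sum
to one.

Fitting minimises KL(h ‖ h_W) over the grid λ ∈ {0.1, …, 3.0},
k ∈ {0.1, …, 15.0} (step 0.1; the printed grids start at 0 but the density is
undefined there, so 0 is excluded).  KL uses the natural log — the argmin is
base-invariant — with 0·log(0/·) = 0 for empty observed bins and the proxy
floored at 1e−12 before renormalising to avoid log(0) in numerically empty
proxy bins.  Ties are broken lexicographically (smallest λ, then smallest k)
for determinism.  The 4500 grid log-proxies are precomputed once per bin
count and cached, making each fit a single matrix–vector product.

The WTM curve is the closed-form composition s_j = t_out⁻¹(t_in(j/N)) with
the Weibull inverse CDF applied to the de-renormalised probability; a
cumulative-maximum guard removes float-level non-monotonicity.  Note one
numerical limit: for extreme shapes (e.g. λ = 0.1, k = 15) the CDF saturates
to 1.0 in double precision before b = 1, so strict increase holds only up to
that saturation point; the composition remains monotone non-decreasing.

## Control-point curves

User-style curves pass through six control points at fixed abscissae
{0, 0.2, …, 1} with strictly increasing ordinates, interpolated by monotone
PCHIP (Fritsch–Carlson derivative limiting, one-sided three-point endpoint
rule with clamping — scipy's implementation).  The interpolant reproduces
linear data exactly, so identity knots give the identity curve, and never
overshoots between knots.

## Evaluation

Colour difference is the per-pixel Euclidean distance in CIELAB, averaged
over the frame; a mean below 5 is reported as "visually similar" (ΔE*ab ≈ 1
is a just-noticeable difference).  The working RGB space and illuminant were
not specified by the source material; sRGB with D65 is assumed, using the
Rec. 709-precision sRGB matrix and the classic CIE linear-branch constants
(7.787·t + 16/116), as implemented by scikit-image.

Observer-session statistics operate on tables of repeated enhancements:
agreement is the per-observer fraction of images where the same tool was
chosen on both viewings; CV = σ/μ uses the population σ by default (with two
repeats a sample σ inflates every CV by √2; a flag selects it), and MCV
averages CVs across image pairs — per parameter for the two WTM sliders, and
for control-point curves the six per-ordinate CVs are first averaged within
each pair.  Observers who never used a tool are reported as None, mirroring
the "-" table convention.

## Synthetic scenes

Real survey frames are unavailable (commercial restriction), so tests run on
a seeded generator that emulates their statistical structure only: an i.i.d.
truncated-Weibull brightness texture (inverse-CDF sampling), multiplied by a
Gaussian illumination cone (1 at the centre, 1 − gain in the far periphery;
any smooth unimodal falloff would serve), coloured by a fixed low-saturation
substrate chromaticity with unit value so the max channel equals the
brightness field exactly.  Defaults — 128×128 px, texture λ = 1.2, k = 3.0,
cone gain 0.5, radius 0.45 of the half-diagonal, hue 0.1, saturation 0.35 —
are a mid-grid, sand-coloured frame with a pronounced but not saturating
light cone.  The generator has no spatial correlation, no scattering, no
wavelength-dependent attenuation and no shadows; passing tests therefore
demonstrate the tone-mapping machinery's contracts, not performance on real
optics.  Problem sizes in the test-suite and acceptance script (64–128 px
frames, 20 scenes, 5·10⁵ Monte-Carlo samples, 20 random histograms against
the exhaustive fitting oracle) were chosen as the smallest sizes at which
the Monte-Carlo bounds involved (e.g. the DKW inequality at n = 10⁵ for the
KS check) are comfortably informative.

## Known limitations

- The fitting grid is the method: no off-grid or maximum-likelihood
  refinement is attempted, so recovered parameters are quantised to 0.1.
- The CLHE projection is the least-squares characterisation of the classic
  algorithm, not the clip-and-redistribute iteration itself; the two agree
  closely in practice but are not bit-identical.
- ΔE*ab is CIE 1976; no CIEDE2000 weighting is applied.
- The synthetic generator cannot certify behaviour on real underwater
  imagery (halo artefacts, marine snow, colour casts beyond a global
  chromaticity).
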