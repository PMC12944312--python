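# Methods

## Scope and model

`nirjoint` simulates continuous-wave near-infrared (850 nm) light transport
through a digital finger joint in two probe geometries at once: reflectance
(detector on the illuminated side) and transmission (detector across the
joint).  The scientific question it serves is metric design: which
detector-side statistics separate *presence* of synovitis from its
*severity*, and which survive confounders such as epidermal melanin.

The model chain is: chromophore composition → voxel phantom → photon
transport → CCD binning → metrics → campaigns.  Each stage is exposed as a
module and each is testable against an independent oracle (closed forms,
quadrature, diffusion theory) without any external data.

## Tissue optics composition

All coefficients are in mm⁻¹; literature spectra are stored in their
native cm⁻¹ (or molar-extinction) units and converted at load.

- **Water, lipid**: embedded abridged node tables (650–950 nm) with linear
  interpolation.  Published digitizations of the purified-lipid spectrum
  disagree by ~10% in the 800–880 nm trough; the generic-tissue row is
  therefore only constrained to ±10%.
- **Whole blood**: µ_a = ln10 · [S ε_HbO₂ + (1−S) ε_Hb] · C_Hb/M with the
  base-10 extinction compilation, C_Hb = 150 g/L and M = 64 500 g/mol.
  These conventions are the standard whole-blood ones; they reproduce the
  turbid-pannus catalog value to 0.003%.
- **Melanosome**: the single-power-law approximation
  µ_a = 6.6·10¹¹ λ⁻³·³³ cm⁻¹.
- **Epidermal baseline**: an exponential-plus-constant closed form giving
  ≈ 0.0025 mm⁻¹ at 850 nm.  The conventional melanin-free baseline is ten
  times larger (≈ 0.025 mm⁻¹) but is inconsistent with the composed
  epidermis rows of the material catalog (5.9% error at f_mel = 0.03); the
  small-coefficient form reproduces all three phenotype rows within 0.3%
  and is used throughout.
- **Bone** is a literal catalog row (dry bovine bone matrix); it is not
  reconstructable from the embedded chromophores and is not composed.

Severity mapping (exact, by construction): thickness 0.5 + 0.01·s mm,
swelling 0.01·s mm, lateral extent 8 + 0.02·s mm, synovial fluid only at
s = 0.

## Phantom discretization

Defaults: soft-tissue radius 7.5 mm, bone radius 3.0 mm, grid
30 × 24 × 24 mm, voxel 0.10 mm (campaigns use 0.20 mm; see below),
epidermis shell 0.10 mm as the outermost tissue layer.  These dimensions
are the package's own choices of plausible proximal-interphalangeal
anatomy — the campaign outputs are interpreted directionally, not as
absolute predictions for a specific finger.  Swelling is applied as a
cosine-tapered local increase of the outer radius over the lateral extent,
avoiding an unphysical step in the skin surface.  When the voxel size
exceeds the configured epidermis thickness, campaigns thicken the shell to
one voxel (0.2 mm at campaign resolution) so it remains resolvable; this
strengthens epidermal absorption relative to the 0.1 mm default and is the
main resolution sensitivity of the skin-phenotype results.

## Transport kernel

Weighted hop–drop–spin (the MCML/mcxyz family) on the voxel lattice:

- dimensionless step s = −ln ξ consumed across voxels by a 3-D DDA, with
  s reduced by µ_t × geometric distance per voxel, so interaction sites
  are unbiased at boundaries;
- at interactions, w·µ_a/µ_t is deposited in the voxel and the remainder
  scattered through a Henyey–Greenstein deflection (inverse-CDF sampling)
  with uniform azimuth;
- at index-mismatched crossings, unpolarized Fresnel reflectance decides
  stochastically between specular reflection and Snell refraction; the
  interface normal is the normalized gradient (central differences) of a
  Gaussian-smoothed (σ = 2 voxels; one-voxel smoothing leaves a
  resolution-independent ~7–10° worst-case staircase error, while two
  voxels brings voxelized cylinders within ~4° of the analytic radial
  normal at the default resolution) refractive-index field, falling back to
  the axis-aligned face normal when the gradient is degenerate
  (< 10⁻⁶).  Because a smoothed normal can be strongly oblique to the
  crossed voxel face, the outgoing direction is constrained to actually
  leave (reflection) or enter (refraction) the face; without this guard a
  totally-internally-reflected photon can ping-pong at zero step length.
- Russian roulette below weight 10⁻⁴ with survival probability 0.1.

Specular entry loss is not pre-subtracted: photons launch in ambient and
meet the ambient→tissue Fresnel interface like any other, so skin-phenotype
models differ only by their epidermis voxels.

RNG: per-photon xorshift64* substreams seeded by a splitmix64 hash of
(master seed, batch id, photon index) — reproducible, order-independent,
and batch-independent.  Escapes are classified by exit position and
direction relative to the source face (same side → reflectance, opposite →
transmission, else lateral).

Weight ledger: Russian roulette amplifies survivors, so the per-run
identity launched = absorbed + escaped holds only in expectation.  The
engine therefore tracks the roulette net term explicitly and asserts
launched = absorbed + escaped + roulette_net to < 10⁻⁶ relative — an exact
bookkeeping identity checked on every run.

Validated limits: Beer–Lambert ballistic transmission through a pure
absorber (3σ), Henyey–Greenstein first moment (3σ at 10⁶ draws), Fresnel
closed forms and total internal reflection (exact), and infinite-medium
fluence within 15% of the diffusion Green's function
φ(r) = exp(−µ_eff,d·r)/(4πDr), D = 1/(3(µ_a+µ_s′)),
µ_eff,d = √(3µ_a(µ_a+µ_s′)), for r ∈ [2, 8] transport mean free paths
(measured agreement is ~1–2%).  The infinite-medium (rather than
semi-infinite) oracle avoids boundary-condition convention disputes; the
comparison uses an interior isotropic source with matched indices in a
block large enough that boundary losses are negligible over the fitted
range.

## Detector and metrics

The CCD model bins escape weight on the chosen surface into 128 effective
pixels (0.224 mm pitch; 2048 physical pixels at 14 µm, software-binned by
16), accepting records within ±2 mm of the detector centerline in the
transverse direction.  A 5 mm ROI at 0.224 mm pitch is not an integer bin
count; a half-open window on bin centers is used (22 bins, realized width
4.928 mm), recorded in profile metadata.

ȳ_c is defined as the *mean* bin value over the central ROI (not the sum)
so that W = area/ȳ_c carries length units and the flat-profile identity
W = 28.672 mm holds exactly.  Reflectance ROIs default to 5, 10 and 15 mm
from the source; the 15 mm window is truncated by the detector edge
(support ends 14.336 mm from the source) and is reported over its realized
window.

µ_eff extraction from a transmission measurement uses the bare single-path
exponential estimator ln(I_ref/I)/L, deliberately without diffusion
path-length corrections (no extraction formula is canonical at this probe
geometry); it is suitable for relative comparisons at fixed geometry.

## Campaigns and stopping rule

Each (severity, phenotype) run escalates its photon budget on a doubling
schedule (default 10⁵ → 1.6·10⁶, in batches of 10⁴) until the batch-mean
relative standard error of the monitored ROIs (central transmission ROI
and the 10 mm reflectance ROI) falls below 5%, mirroring the
reproducibility-driven convergence target.  Budgets, achieved errors and
convergence flags are recorded per run.  Campaign voxel size is 0.20 mm,
chosen to keep a full progression + skin sweep around ten minutes on one
CPU core while leaving the metric signs and orderings unchanged from finer
grids on spot checks.

Per-photon-normalized profiles make metrics comparable across runs with
different budgets.

## Synthetic data

The profile generator emulates only the *statistical* structure of diffuse
transmission: smooth unimodal shapes (flat/Gaussian/triangular) with
multiplicative lognormal noise (default σ = 0.05, matching the ±5%
intra-subject reproducibility scale).  It deliberately does not emulate
CCD noise physics, speckle, or probe-contact variability, so passing
metric tests demonstrates correctness of the metric definitions and their
noise response — not end-to-end realism of a physical measurement.
Noiseless outputs carry closed-form ȳ_c and W ground truth.

## Known limitations

- Anatomy is schematic (straight cylinder, no dermis layer, tendons or
  vasculature); absolute flux levels and percentage changes depend on the
  chosen radii and epidermis thickness, and should be read as directional.
- In this geometry the dark-skin phenotype strongly *suppresses* the
  disease-induced beam broadening relative to light/medium skin but, at
  the default dimensions and campaign resolution, does not invert its
  sign; the inversion reported for other (unpublished) joint geometries is
  therefore reproduced here as a strong attenuation of ΔW, not a sign
  flip.  See the acceptance battery for the exact check.
- Reflectance at severity 0 is dominated by light channeled through the
  clear synovial annulus; the 0 → 25% transition appears as the largest
  step in the 10 mm ROI (the detection discontinuity) but its sign is
  geometry-dependent.
- Single wavelength (850 nm) only; no chromophore unmixing, polarization,
  time-resolved transport or tomographic reconstruction.
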