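# Methods

## Descriptor family

All descriptors are functions of local patch self-similarity. For a voxel
`p`, a patch layout places the centre patch `P_0` (edge length R1, odd) at
`p` and six neighbour patches at distance `d` along the grid axes. The
primitive is the mean squared difference between two patches,
`SSD_ij(p)`, computed for every voxel by shifting the image by the offset
difference, squaring, and averaging with a uniform R1³ kernel.

* **MIND** (6 channels): `exp(-D_n / V)` over the six centre-to-neighbour
  distances, `V` = their mean. A per-voxel variance normalizer makes the
  channels invariant to local contrast.
* **SSC** (18 channels): all pairwise patch connections among the seven
  patches except the three collinear opposite pairs — 18 connections in 9
  undirected orientations. Channel value
  `exp(-e_P·SSD_ij / Σ SSD) = exp(-SSD_ij / meanSSD)`. Excluding the
  centre-through pairs makes the measure less sensitive to noise in the
  centre patch; the richer orientation sampling distinguishes more complex
  local geometry than MIND's three axes.
* **msSSC**: `Σ_k α_k SSC_k` with scale k sampling at distance `k·L`,
  channels aligned by pair identity (M stays 18). The α are normalized to
  sum to 1 on construction.
* **macMIND**: each msSSC channel is average-pooled over N cylindrical
  log-polar bins of the R2-wide supporting window centred at the voxel,
  concatenated to an M×N-channel vector. Average pooling (not max) keeps
  fine-scale matching detail; the log-polar geometry makes near-centre
  structure fine-grained and far structure coarse, a standard shape-context
  trade-off.

### Reading of the SSC formula

Written as a single sum over pairs, the self-similarity context collapses
to a scalar per voxel, which cannot produce the M-channel map the
aggregation stage consumes. The implementation therefore treats each
pair's exponential term as one channel (M = 18) and the "sum" as channel
enumeration. This is the only reading consistent with an M×N-channel
output.

### Log-polar binning (3D)

Only a 2D illustration of the binning (8 angle × 2 radial intervals = 16
bins) fixes the intended geometry; the 3D parameterization is this
package's choice: a cylinder inscribed in the R2³ window, with

* azimuth: Na half-open sectors `[k·2π/Na, (k+1)·2π/Na)` starting at +x,
  counter-clockwise (a boundary angle belongs to the sector it opens);
* radius (x–y plane): Nr geometric shells with edge ratio √2, outermost
  edge at R2/2, innermost shell extending to r = 0. The √2 ratio is chosen
  so that at the default R2 = 5, Na = 8 every inner sector is populated
  (ratio 2 would leave the four diagonal inner sectors empty);
* height: Nh equal slabs of [-R2/2, R2/2].

The r = 0 column belongs to the innermost shell, sector 0. Offsets outside
the inscribed cylinder are unassigned. Defaults Na = 8, Nr = 2, Nh = 2
(N = 32), the 3D analogue of the 2D 8×2 example. Bin index =
((height·Nr)+shell)·Na + sector; channel index = bin·M + pair. Empty bins
(possible for small R2) yield all-zero channels with a logged warning
rather than an error.

### Degenerate regions and the denominator floor

On flat image regions every SSD is zero and the normalized exponentials are
0/0. The denominator (meanSSD, and V in MIND) is floored at
`max(eps_rel · volume-mean denominator, 1e-12)` with `eps_rel = 1e-6`, so
constant regions yield channel value 1 (perfect self-similarity). The same
floor is applied in the naive reference implementations.

### Boundary convention and the fast/naive contract

The image is padded once with edge replication (pad width = patch radius +
largest offset); all shifts and patch means are taken inside the padded
array. The naive per-voxel loop oracles use the identical convention, so
fast and naive agree at *every* voxel (tested to 1e-5 absolute on random
volumes), not only in the interior. Edge replication avoids the artificial
gradients a zero padding would inject into boundary SSDs.

### Parameters

| name | default | meaning |
|------|---------|---------|
| L | 2 voxels | base neighbour distance; scale k samples at k·L |
| R1 | 5 voxels | SSD patch edge |
| R2 | 5 voxels | aggregation window edge |
| K | 2 | number of scales |
| alphas | (0.7, 0.3) | per-scale weights (normalized) |
| Na, Nr, Nh | 8, 2, 2 | log-polar bins (N = 32) |
| eps_rel | 1e-6 | relative denominator floor |

Commonly quoted values for the scale weights disagree between (0.3, 0.7)
and (0.7, 0.3) — the latter also quoted as the optimal ratio 7/3. The
library default is (0.7, 0.3), weighting the small scale more; the
contradiction is noted in the shipped config file and the weights are
plain configuration.

## Losses

`E_reg = λ_sim·E_sim + λ_label·E_label + λ_smo·E_smo`, with

* `E_sim`: mean over voxels of the squared descriptor channel-vector
  difference (sum over channels, mean over the domain);
* `E_label`: 1 − softDice (ε = 1e-6 in numerator and denominator), labels
  warped trilinearly as soft masks for loss purposes, nearest-neighbour for
  reported masks;
* `E_smo`: sum over voxels of squared forward-difference gradients of all
  three field components, in voxel units (zero at the far boundary).

The λ_sim factor is written explicitly although one statement of the
objective omits it; the library default is λ_sim = 1 so both readings are
reachable, and the shipped configuration file carries (20, 2, 0.5).

The segmentation-consistency loss has two branches: with ground-truth
labels for both modalities it is the sum of the two prediction-vs-truth
Dice losses; without, it is the Dice loss between the fixed prediction and
the warped moving prediction (the displacement field is then required).

## Registration demo

The deformable optimizer is a classical, deterministic stand-in for a
trained registration network, at desk scale:

* coarse-to-fine pyramid (default downsampling factors 4 and 2; images
  resampled with align-corners trilinear interpolation after Gaussian
  anti-alias smoothing of 0.5·factor);
* at each level, fixed-image descriptors are extracted once; every loss
  evaluation warps the moving *image* and recomputes its descriptors.
  The alternative — warping a pre-computed moving feature map — was
  measured to bias the objective badly: interpolation smooths the feature
  noise, so *any* off-grid field lowers a feature-map SSD, and the loss at
  the true deformation stays far above spurious minima. With
  recomputation, the descriptor's own normalization absorbs the
  interpolation blur and the mono-modal loss landscape has a sharp minimum
  at the true field;
* descent direction: demons-style force `f = Σ_c (W_c − F_c)∇W_c` from the
  warped image's feature gradients (analytic; a full finite-difference
  gradient on the field would need six loss evaluations per voxel),
  normalized per voxel by `(‖∇W‖² + mean‖∇W‖²)` so texture-free regions
  stay quiet, capped at 1 voxel, then Gaussian-smoothed (default σ = 4
  full-resolution voxels, divided by the level factor);
* a step-halving/regrowing line search accepts only non-increasing total
  loss, so the accepted-step trace is monotone within each level;
* the field is upsampled between levels (components rescaled to the new
  grid's voxel units) and returned on the full grid.

The optimizer's internal objective uses the diffusion term *per voxel*
(E_smo/|Ω|) and defaults to λ_smo = 20 at λ_sim = 1 — a much heavier
smoothness prior than the loss-module default. A greedy dense optimizer
needs it: the cross-modality descriptor residual is structured (class
contrasts differ between modalities), and with a weak prior the descent
chases that residual with large spurious smooth displacements. A trained
network averages this away over a cohort; a per-pair classical method must
regularize instead. With these defaults, registration reduces mean
landmark TRE against the unregistered baseline on every default phantom
seed tested, with fold-free recovered fields.

Jacobian folding is computed from central differences of `p + φ(p)` on
interior voxels (boundary shell excluded) and reported as a fraction and
per ten thousand voxels.

## Metrics

* **MI**: joint histogram, 32 equal-width bins per image over each image's
  min-max range, natural log, zero cells skipped. Constant images return 0
  with a warning. Reported raw in nats (no percentage normalization is
  attempted; none is standardized).
* **SSIM**: global (whole-volume) statistics on min-max-normalized images,
  standard product form with c1 = 0.01², c2 = 0.03². A variant sometimes
  printed with a sum in the numerator does not attain 1 for identical
  images and is treated as a typo, but
  remains available behind `literal_form=True` for inspection.
* **DSC/VOE/RVDabs**: voxel-count overlap formulas in percent; DSC of two
  empty masks is 100 with a warning (error in strict mode).
* **Hd95**: surfaces are mask voxels with ≥ 1 background 6-neighbour;
  distances via the exact Euclidean distance transform scaled by spacing;
  95th percentile (linear interpolation) of the pooled symmetric surface
  distances.
* **TRE**: the field is interpolated trilinearly at the fixed-frame
  landmark's voxel position, the displacement converted to mm, and the
  mapped point compared with the corresponding moving-frame landmark
  (matched by id).

## Synthetic phantoms

Each case shares one anatomy: an ellipsoidal organ whose boundary radius
is modulated by low-order angular harmonics (lobulated outline), one
interior ellipsoidal lesion, and three background structures (a rod and
two blobs). Modality A ("CT-like") renders per-class means plus a shared
smooth texture with additive Gaussian noise (2 % of range); modality B
("MR-like") uses a different per-class mapping with the organ/lesion
contrast inverted and the lesion's texture slope negated, Rician-like
noise (4 %), and is rendered in a deformed frame through the ground-truth
field. Labels for frame B are warped from the same geometry; landmarks
(lesion centroid, organ centroid, six boundary extremes) are mapped into
frame B by fixed-point inversion of the field, so correspondence is exact
by construction.

The ground-truth deformation is Gaussian-smoothed white noise per
component (σ = 6 voxels), rescaled to a peak magnitude of 4 voxels and
attenuated to zero at the boundary by a cosine taper. The taper width
scales with the amplitude (`max(4, ceil(2·amplitude))`): a cosine ramp
carrying peak displacement a over w voxels has gradient up to πa/(2w), so
w ≥ 2a keeps the taper itself fold-free; fields are verified fold-free and
rescaled with a warning (error in strict mode) if a configuration still
folds.

Default grid 64×64×48 at 1 mm isotropic — half the in-plane size of a
typical clinical resampling target — keeps a full descriptor extraction
under ~5 s and a registration under ~15 s, so the complete pipeline is
testable in minutes.

What the phantom does and does not emulate: it reproduces the *structure*
of the multimodal problem (shared anatomy, monotone per-class intensity
mappings with a contrast inversion, modality-specific noise character,
smooth diffeomorphic deformation, expert-style landmarks), not the physics
or statistics of clinical CT/MR (no partial volume, bias fields, slice
anisotropy artifacts, breathing-type deformation, or realistic organ
shape). Passing tests therefore demonstrate correctness of the algorithms
and the qualitative modality-independence property, not clinical-level
registration accuracy.

## Problem sizes used in the shipped checks

Oracle comparisons run on ≤ 16³ random volumes (the naive path is
O(voxels × pairs × patch)); the modality-independence suite uses ten
aligned 64×64×48 phantom pairs; the registration suite uses ten default
phantom seeds at 64×64×48 (the acceptance script uses five). These sizes
were chosen so the whole suite runs in a few minutes on one CPU while
still exercising the full default configuration.

## Known limitations

* The optimizer is greedy and dense; it recovers smooth deformations at
  the resolution of its finest pyramid level (half resolution by default)
  and is not expected to match trained-network accuracy or to handle
  large rotations/slips.
* macMIND feature maps are memory-hungry (576 float32 channels ≈ 0.45 GB
  at 64×64×48); full-resolution pyramid levels are therefore off by
  default.
* The 3D binning parameterization and the radial shell ratio are package
  choices (see above); other parameterizations are configurable through
  Na/Nr/Nh but not through the shell ratio.
* RVDabs is asymmetric by definition (segmentation vs ground truth); the
  panel passes the warped mask as the "segmentation".
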