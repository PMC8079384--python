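# Methods

## Scope and intent

`helixforce` estimates the net static electrostatic force inside an
alpha-helix bundle from a coarse-grained structural model. It deliberately
ignores hydrophobic and van der Waals interactions, hydrogen bonds,
dynamics, linker regions between helices, and helix curvature: the model is
a straight rigid cylinder per helix with point charges at sidechain
centroids, evaluated in a single static configuration taken verbatim from
the input structure. The output is one signed scalar per bundle plus
per-pair detail; it is a force-domain summary, not an energy or a free
energy.

## Backbone model

The backbone of an annotated helix (inclusive residue range on one chain)
is the stack **M** of its Cα positions. The fit is:

1. centroid **b**_c = mean of rows of **M**;
2. direction **d̂** = first left singular vector of the covariance
   **S** = **B**ᵀ**B**/(n−1), where **B** = **M** − **b**_c (the n−1
   denominator is used exactly); the sign is fixed so **d̂**·(**b**_n −
   **b**₁) > 0, i.e. the local x-axis runs N→C along the annotated range;
3. axis endpoints = orthogonal projections of **b**₁ and **b**_n onto the
   line (**b**_c, **d̂**), which makes start, centroid and end exactly
   collinear and puts start/end on opposite sides of the centroid;
4. per-residue line parameter t_i and perpendicular distance
   l_i = |**b**_i − foot_i| (true Euclidean norm); the cylinder radius is
   mean(l_i).

Fits require at least 4 residues; fewer makes the axis and the local frame
ill-conditioned and is rejected.

**Known systematic of the axis estimator.** Plain PCA of a finite helix
whose sampled phases do not cancel has a small deterministic tilt relative
to the true axis: the axial coordinate correlates with the radial one
through terms like Σ i·cos(θ_i). For canonical geometry (1.5 Å rise, 100°
twist, 2.3 Å radius) the tilt is 2.2° at 18 residues, ~0.4° at 20–30
residues, and falls below 0.1° past ~90. The tilt also makes the fitted
radius slightly length-dependent (2.27–2.30 Å). This is a property of the
method, not a bug; tests assert the actual convergence behaviour, and the
recovery study (below) uses realistic helix lengths.

## Sidechain model

Each sidechain is approximated as a sphere: center = mean heavy-atom
position, radius = mean atom→center distance. Glycine contributes a
zero-radius sphere at its Cα and is never used as a frame reference.
Hydrogens are excluded everywhere (crystal structures typically lack them;
including them only for NMR entries would bias centroids between input
types), as are HETATM records, waters and alternate conformers other than
blank/'A'. Insertion codes are rejected rather than silently merged.
`SidechainSphere` additionally stores the residue's Cα so shape diagnostics
can normalise instances to their own backbone attachment point.

## Coordinate frames

Transforms are 4×4 homogeneous matrices in the robotics convention: ᴬ_B T
maps B-frame coordinates to A-frame coordinates. Frame names travel with
every transform and are checked at composition, which converts
transform-direction mistakes into immediate errors instead of silent wrong
geometry.

A helix's local frame has x̂ = **d̂**, origin at the axis start, and ŷ from
the axis toward the first non-glycine sidechain center. The printed
definition of ŷ (unit vector from the sidechain's axis foot point to its
center) is only perpendicular to x̂ when the foot point is computed for that
same center; we do exactly that and additionally Gram–Schmidt ŷ against x̂
before taking ẑ = x̂ × ŷ, so the rotation block is orthonormal to machine
precision. A sidechain center within 1e-6 Å of the axis is a degenerate
frame and an error.

A bundle simulation uses a SIM frame defined as helix 1's local frame (the
SIM←helix1 transform is the identity). Placement is a rigid re-expression:
every pairwise distance is preserved to 1e-9, so forces are unchanged by
construction. Only the combined helix1→helix2 relative transform is exposed
for the inter-helix linker; the linker's internal split is unobservable and
therefore not modelled.

## Electrostatics

Charges are integers in {−1, 0, +1} assigned per residue type at pH 7.2:
ASP, GLU → −1; LYS, ARG → +1; everything else 0. Histidine's sidechain pKa
(~6.0) leaves it <10 % protonated at pH 7.2, so the nearest integer — and
our default — is 0; the table is overridable for other protonation
assumptions. Unknown residue names are an error, not a silent 0.

The pair force is Coulomb's law F = k_e q₁q₂/(ε_r r²) with CODATA constants
(k_e = 8.9875517873681764×10⁹ N m² C⁻², e = 1.602176634×10⁻¹⁹ C), r the
center-to-center distance converted from Å, result in pN. ε_r defaults to 1
(vacuum, no solvent screening) and is configurable. The bundle net force is
the plain signed sum over every cross-helix charge pair of every unordered
helix pair; intra-helix pairs are excluded. A per-helix 3D vector sum along
the center-to-center directions is also reported for inspection, but the
headline number is the scalar sum, matching the attract/repel sign
convention (negative = attractive). Summation order is fixed (helix pair,
then donor residue, then acceptor residue), so totals are bit-reproducible.
Charged centers closer than 1e-6 Å are rejected as coincident.

## Diagnostics

* **Skew.** Radial distance l_i is regressed (ordinary least squares,
  `scipy.stats.linregress`) on axial position t_i·|axis| — both in Å, so
  the slope is dimensionless and the skew angle atan(slope) in degrees is
  the angle between the fitted line and the constant-mean-radius line. The
  population summary reports median, mean and sample sd (n−1); a single
  helix reports sd 0 with n = 1.
* **Radial histogram.** Pooled l_i binned at a fixed width (default 0.1 Å)
  with a moment-matched normal (sample mean/sd); no likelihood fit is
  needed for a visual bias check.
* **Sidechain shape.** All instances of a residue type are translated (Cα →
  origin) and rotated (Cα→centroid direction → +x, minimal rotation);
  the spin about that axis is left free, exactly the ambiguity the sphere
  approximation accepts. Distances from the pooled centroid are summarised
  by mean, median and quartiles.

## Synthetic data

The generator emulates the geometry the model assumes: Cα positions on an
exact cylindrical helix with canonical parameters (1.5 Å rise, 100° twist,
2.3 Å radius — right-handed for positive twist), N/C/O at fixed plausible
offsets, and sidechain clusters centred a fixed radial distance (default
2.5 Å) outside each Cα. `jitter_sd` adds i.i.d. Gaussian noise to **every**
atom, so with jitter the Cα cloud, not just the sidechains, is noisy — this
is what makes axis/radius recovery a real test. With `jitter_sd = 0` every
Cα lies exactly on the nominal cylinder.

`generate_charged_pair` builds two parallel helices phased so the residue-0
sidechains face each other: the charged centroid gap is exactly
`separation − 2·(backbone_radius + sidechain_distance)`. Charge patterns
are encoded as residue types (LYS/+1, ASP/−1, ALA/0) so the standard charge
table reproduces them; lists shorter than 4 residues are padded with
neutral alanines to keep the axis fit well-posed without adding force
terms.

What the generator does **not** emulate: real backbone stereochemistry,
rotamer distributions, helix curvature and supercoiling, sequence-dependent
sidechain sizes, crystallographic noise structure. Passing recovery tests
therefore shows the estimators are correct for straight constant-width
helices with isotropic noise — the model's own regime — not that real
helices are straight (that question is what the diagnostics are for on real
structures).

## Problem sizes and numerical choices

* Recovery study (tests and acceptance script): 50 helices, lengths drawn
  uniformly from 20–45 residues — representative of helices in
  mechanosensitive rod-domain bundles — random orientations, 0.2 Å jitter.
  Expected outcomes: mean axis error ≈ 0.5°, mean |radius error| ≈ 0.03 Å,
  constant-width skew ≈ 0°.
* The acceptance script's four-helix toy bundle places 28-residue helices
  on a 15 Å square so the closest cross-helix sidechain centroids sit at
  salt-bridge distances (~5.4 Å) rather than in steric overlap; sequences
  are seeded draws with ~30 % charged residues. Its net force (hundreds of
  pN, seed-dependent sign) is dominated by the few nearest contacts — a
  toy-bundle property worth remembering when comparing against real
  bundles, whose specific charge geometry largely cancels.
* Orthonormality/associativity/round-trip tolerances are 1e-9 absolute on
  matrix entries; the force oracle comparison is 1e-12 relative; degenerate
  geometry thresholds (coincident points, on-axis sidechain, zero-length
  axis) are 1e-6 Å.
* Ties/degenerate inputs: an exactly symmetric point cloud would make the
  principal axis non-unique; in practice SVD returns a deterministic
  vector, and the orientation rule (toward the last residue) fixes the
  sign. If b_n = b_1 exactly the sign is left as SVD returns it.

## Limitations

Electrostatics-only forces overstate repulsion for bundles whose cohesion
is hydrophobic; vacuum permittivity overstates all magnitudes relative to a
solvated environment (ε_r is exposed for sensitivity checks). The straight
rigid axis is a poor model for long curved coiled-coils. Charges are
residue-level integers at a single pH; no partial charges, no pKa shifts
from the local environment. Reproduction of published per-bundle values for
talin requires the original manually-curated helix ranges, which were not
published; HELIX-record-derived ranges are a documented approximation.
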