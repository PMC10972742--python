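# Methods

## The model

`thrkit` builds protein backbones exclusively from ideal straight
α-helices whose axes are parallel to a common direction (z in the block
frame). Under that restriction a repeat protein's trajectory is fully
described by the transform from one repeat's reference helix a₀ to the
next repeat's copy a₁: the in-plane axis-to-axis displacement **d** (Å),
the displacement **Δh** along z (Å), and the helix phase change **Δθ**
(degrees). `repeat_rigid_transform` realizes the triple as an explicit
rigid screw transform:

* Δθ = 0 — pure translation (d, 0, Δh); propagation along +x by
  convention;
* Δθ ≠ 0 — rotation by Δθ about a z-parallel axis through
  (0, sign(Δθ)·R) with **R = d / (2 sin(|Δθ|/2))** (chord relation),
  plus Δh along z.

Applied to the reference helix at the origin, this displaces the axis by
exactly d, raises it by exactly Δh and advances the phase by exactly Δθ;
composing the transform n times with Δθ = 360/n is the identity, which is
why commensurate Δθ produces perfectly closed rings. Note the "exactly d"
statement is specific to the reference helix: other helices of the unit
ride the same screw and traverse slightly different chords.

Conventions fixed once and used everywhere: phase is the azimuth of the
first residue's CA about the helix axis, counterclockwise from +x viewed
from +z, stored in [0, 360); phase differences are reported in
(−180, 180]; positive Δθ is counterclockwise viewed from +z; flipped
(antiparallel) helices are the 180° rotation of the as-built helix about
the x direction through its midpoint, which keeps the axis position and
z-parallelism. Angles are degrees in every API and file; radians appear
only inside formulas.

## Ideal-helix constants

Every atom of the backbone lies on a cylinder coaxial with the helix:
residue i, atom k sits at azimuth `phase + i·100° + Δφ_k`, height
`z_start + i·1.5 Å + Δz_k`, radius `r_k`. The CA parameters are exact by
definition (rise 1.5 Å/residue, twist +100°/residue, radius 2.3 Å). The
N/C/O parameters were derived once by building a poly-backbone chain from
internal coordinates with the standard bond lengths (N–CA 1.458, CA–C
1.525, C–N 1.329, C–O 1.231 Å; trans peptide) and solving the four free
angles (φ, ψ, τ_N-CA-C, ∠CA-C-N) so that the resulting helix has exactly
the CA rise/twist/radius above. The solution — φ = −57.484°,
ψ = −47.313°, τ = 108.783°, ∠CA-C-N = 119.093° — is within ~2° of
textbook α-helix values; fixing all bond *angles* at canonical values
instead leaves a ~0.02 Å residual in the radius, so one angle must float.
The frozen cylinder parameters reproduce the internal-coordinate chain to
~10⁻¹² Å, hence bond lengths in generated helices equal the declared
ideals exactly. Consecutive CA–CA distances come out at 3.830 Å.

Axis fitting (`fit_helix_axis`) uses the fact that second differences of
an ideal helix's CA trace are perpendicular to the axis: the axis
direction is the null singular vector of the stacked second differences,
and the axis position is an algebraic (Kåsa) circle fit of the projected
CAs — both exact for noiseless ideal helices (round-trip error ~10⁻¹⁰).

## Blocks

A repeat unit holds 1–4 helices in N→C traversal order; physically
traversable units alternate up/down helices. Block classes: linear
(Δθ = 0, Δh = 0), stair (Δh ≠ 0), curve (Δθ ≠ 0, anchors coplanar and
concyclic at the chord radius), and turn (an extra helix c₀ collinear
with the a₀→a₁ propagation line; the outgoing direction differs from the
incoming by θ_c − θ_a). Loops are not modelled: `realize_block` either
leaves chain breaks (default) or inserts flagged 3-residue straight-line
placeholders, warning when a span exceeds 12 Å. Capping is metadata only
— a capped terminus differs in sequence, not backbone — and gates
assembly legality (rails must be uncapped; ties must be uncapped at the
C2 midpoint).

## Symmetry and handshakes

Point groups come from generated rotation sets (orders 12/24/60 for
T/O/I), re-oriented canonically: a primary face axis on +z and one edge
axis in the xz half-plane, so outputs are byte-reproducible. Face axes
are read off the group elements themselves (C3 axes from 120° rotations,
C4 from 90°, edges from the 180° rotations that are not C4²); for the
tetrahedron the four face directions are the maximal mutually-109.47°
subset of the eight C3 directions containing +z. The octahedral group
exposes both its octahedron C3 faces (for O3) and cube C4 faces (for O4).

The handshake angle of an architecture is 180° minus the angle between
two adjacent face axes — the polyhedron's dihedral angle — always
computed from the generated axes: 70.53° (T3), 109.47° (O3), 138.19°
(I3), 90.0° (O4). A standalone handshake dimer is built by rotating a
straight block 180° about an axis u = (0, cos α/2, sin α/2): the two
copies' propagation lines stay parallel (antiparallel run), their block
planes meet at α, and the lateral offset between the propagation lines is
the one sampled degree of freedom. The *measured* handshake angle of any
dimer is defined as 180° minus the angle between the two halves' directed
helix-axis directions; in a cage these are the two face axes, so the
measurement reproduces the dihedral exactly.

## Cages and expansion

A cage places one ring (C3 or C4 split) per face and one straight arm per
ring subunit. In the asymmetric face frame with face axis a₁, adjacent
face axis a₂, edge 2-fold axis e ∝ a₁ + a₂ and in-face radial
d̂₁ ∝ e − (e·a₁)a₁: the arm propagates along d̂₁ (parallel to a radial
vector and to the plane spanned by a₁ and e — the expandability
criterion) but is offset by offset/2 along the normal of that plane. The
C2 about e is a group element through the origin, so the two arms meeting
at an edge form an *exact* 2-fold dimer with perpendicular separation
`offset`, with the C2 axis along a radial vector of the cage. The face
distance f is solved from f·tanψ = s_tip − overlap/2 (ψ the a₁–e angle,
s_tip the arm-tip arc length), which makes the ring-center-to-C2-anchor
distance equal s_tip − overlap/2: growing the arm by k repeats grows it
by exactly k·d while the interface-local coordinates are reproduced to
rounding error, because the whole construction is repeat-periodic. Arms
shorter than the overlap cannot form the interface; the builder reports
the minimum repeat count.

The O43 two-component variant locks the trimer: its arm points toward the
adjacent C4 axis in the (C3, C4) axis plane, and f is solved so the arm
tip sits at a prescribed perpendicular distance from the partner's C4
axis (default 52 Å, i.e. the partner ring's outer helix surface plus one
packing gap). That solve is what fixes the trimer rotation and keeps
tip-to-partner geometry exactly invariant under expansion; the free C4
partner samples rotation and radial position on deterministic grids and
candidates are ranked by cross-component CA contacts within 8 Å.

## Strutted rings and train tracks

Two rings with repeat counts n₁, n₂ nest concentrically when
g = gcd(n₁, n₂) ≥ 3: g copies of a composite subunit (n₁/g repeats of one
ring plus n₂/g of the other, each sweeping 360/g) close both rings
simultaneously. The strut is a straight block propagating radially,
centered in the free annulus between the rings' helix edges; the sampled
placement freedoms are the inner ring's twist and z offset.

Train tracks are 1D lattices: two antiparallel uncapped rails (C2 images
about the track axis) and C2 ties every k rail repeats. A tie is an
antiparallel pair of straight blocks, each spanning the full rail gap,
related by the same 2-fold with a 10 Å z gap; because both halves span
the gap, adding t repeats to each half widens the rail separation by
t·d_tie (not 2t·d). Tie spacing is measured along the rail propagation
axis — the only convention consistent with unbounded end-to-end rail
growth, which requires the extension axis to be the propagation axis.
Unit cells are related by pure translation; the branch attachment on the
rail side is recorded as an interface declaration, not modelled atomically.

## Fixtures (demo inputs) and what they do not emulate

The fixture registry reproduces the architecture classes and repeat
counts/splits/angles of named demo designs: rings of 12/18/20/30 repeats
(C4 or C6 splits), triangles and squares from 120°/90° turn modules, the
C10 (30+20) and C6 (30+18) strutted rings, the four cage architectures
with +4/+8/+12-helix expansion variants, the O43 locked trimer and four
track size combinations. Intra-repeat helix placements are this package's
own: 4-helix ring units (two staggered radial columns, half-width 4.5 Å,
d = 20–22 Å) and 2-helix zigzag units (d = 10 Å, flank at ±8 Å), chosen
so every fixture's helix-axis separations stay ≥ ~8.6 Å and all models
pass clash detection at the 3.5 Å CA–CA cutoff. They are backbone-only
poly-alanine ideals: no loops, no sequences, no side chains, no packing
scores, and no claim of atom-level identity to any experimentally
characterized design — real structures deviate from ideal geometry at the
0.5–1.5 Å backbone-RMSD scale, which these generated models cannot and do
not represent. Passing tests therefore certify the *geometric engine*
(closure, symmetry, expandability, interface invariance), not the
designability or stability of any particular protein.

## Numerical choices

Geometric identities are asserted at 10⁻⁶ (degrees/Å), file round-trips
at 10⁻³ Å (PDB precision), group properties at 10⁻⁹. Superposition uses
the standard SVD-based least-squares rotation with a rank check that
rejects collinear point sets (rotation not unique) and always returns a
proper rotation; the residual RMSD is recomputed from the transformed
coordinates rather than the solver's internal residual to keep
exact-recovery tests at the 10⁻⁹ level. Clash detection is a k-d-tree
scan of CA pairs below 3.5 Å, excluding residues within 2 positions on
the same chain. Ring diameters follow a stated convention — twice the
max/min radial CA distance ± a 2.0 Å probe — which carries chord-level
(~1–3 Å) slack for small rings because no CA need point exactly radially;
only monotonic growth with n is asserted strictly. Default handshake
offset sampling is 0–15 Å in 0.5 Å steps. All builders are deterministic;
the only randomized paths (dock-grid subsampling, the acceptance script's
reorientation spot check) take explicit seeds.

Test problem sizes: rings up to n = 30 (2,400 residues), cages up to the
icosahedral I3 (120 chains, 26,400 residues), 1,000-trial superposition
recovery, and 200-entry sampled closure tables for the icosahedral group
— sizes at which every exact property can still be asserted at full
tolerance while the suite runs in seconds.

## Known limitations

* Loop geometry, sequence design and any energetic scoring are out of
  scope by construction; placeholder loops are degenerate markers.
* Helices are perfectly straight; kinks, supercoiling and non-ideal local
  geometry are not representable.
* The blueprint schema stores block/assembly parameters, not arbitrary
  placed coordinates; an assembly outside the six supported architectures
  needs code, not just a file.
* mmCIF output does not carry the per-residue segment annotation (PDB
  segid does); blueprints remain the annotated source of truth.
* Off-target species (rings closing with ±1 chain) and partial assemblies
  are not modelled.
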