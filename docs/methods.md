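# Methods

This note documents the models, numerical machinery, defaults and known
limitations behind `molprint`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Structures, radii, colors

PDB input is parsed from the fixed-column ATOM/HETATM dialect only
(TER/END honored, everything else ignored); the parser reports the exact
line number of a malformed coordinate field. Alternate locations collapse
to the first conformer by default and waters are skipped — a printed model
wants one copy of each atom and no solvent; both are flags. Elements come
from columns 77–78 with an atom-name fallback (a name starting in column
13 with two letters is a two-letter element such as FE; an indented name
is an organic whose element is its first letter).

Van-der-Waals radii use the Bondi (1964) compilation as the bundled
default set (C 1.70 Å, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, …); the
space-filling tradition names these radii but fixes no numeric table, so a
standard published set is pinned and an explicit per-call fallback covers
exotic elements. Element colors follow chemistry convention — black
carbon, red oxygen, blue nitrogen, yellow sulfur, white hydrogen, orange
phosphorus — with magenta flagging anything unassigned; chain coloring
cycles a 10-color qualitative palette in chain order. Radius and color
assignment are pure functions, idempotent and commuting.

## Synthetic builders

**Peptide chains.** Backbone atoms (N, CA, C, O) are placed sequentially
by natural-extension (NeRF) internal-to-Cartesian construction with ideal
bond lengths (N–CA 1.458 Å, CA–C 1.525, C–N 1.329, C=O 1.231) and angles
(N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O 120.8°). Residue *i*
contributes phi = C(i−1)–N–CA–C, psi = N–CA–C–N(i+1) and the peptide-bond
omega (default 180°, cis allowed); the carbonyl O sits at dihedral
psi + 180°, which also makes the terminal psi measurable. Dihedrals follow
the IUPAC sign convention; the first residue anchors at N = origin, CA on
+x, C in the xy-plane. Round-trip identity (build → measure dihedrals)
holds to ~1e-13 degrees; tests cross-check coordinates against a
constraint-solving oracle with no shared frame convention and recover the
1.5 Å/residue alpha-helix rise from a principal-axis fit.

**B-DNA traces.** Two pseudo-atom sites per nucleotide (phosphate at the
9.4 Å backbone radius; a sugar site 2.4 Å inset, trailing by 18°) on a
canonical B-form helix: 3.4 Å rise and 36° twist per base pair. Strand B
is strand A rotated 180° about the dyad through the helix mid-height,
giving exact antiparallel symmetry. The numeric defaults are the textbook
B-form values; the sugar inset/phase are this package's choice of a
recognizable two-site cartoon, not a fit to real geometry.

**Icosahedral capsids.** The 12 vertex directions come from the cyclic
permutations of (0, ±1, ±φ), normalized; each placement is the proper
rotation carrying +z onto a vertex (Rodrigues construction, exact 180°
case handled specially) plus a radial translation. Pentamers are five
successive 72° rotations of a protomer. Placements are rigid, so per-copy
volume, area and chirality are preserved exactly. A bounding-box screen
warns when placed pentamers intersect by more than 1% of one pentamer's
bounding-box volume — a misconfigured-radius alarm, not a collision
solver.

## Representations

**Gaussian surface.** The density D(x) = Σᵢ exp(b(|x−xᵢ|²/rᵢ² − 1)) is
sampled on a regular grid: spacing 0.5 Å default, padding = max radius
+ 2 Å (a warning fires if padding could clip a sphere), per-atom cutoff
where the exponent reaches −14 (contribution < 1e-6). Defaults b = −3,
isovalue 1: an isolated atom's level set is then exactly its vdW sphere,
which anchors the discretization test — the 0.25 Å single-atom surface
volume lands within 3% of (4/3)πr³ and converges under refinement. Lower
resolution is exposed by moving b toward 0 and coarsening the grid, not by
a separate algorithm. The marching-cubes grid is zero-padded by one layer
so surfaces are closed even when density is still above the isovalue at
the box edge, and face winding is normalized to positive enclosed volume.
The Gaussian surface stands in for the solvent-excluded surface; an exact
rolling-probe SES is out of scope.

**CPK solid.** The union of spheres is contoured from its exact signed
distance field maxᵢ(rᵢ − |x − xᵢ|) (the max of sphere SDFs *is* the union
SDF), clamped to a 0–1 occupancy and contoured at ½. One watertight mesh,
no pairwise sphere Booleans, connectivity equal to the sphere-overlap
graph — verified against a brute-force graph oracle, with the caveat that
pairs closer than about one voxel to exact tangency are topologically
ambiguous at that resolution (test fixtures keep a 2× spacing margin).
Vertex colors are inherited from the nearest atom.

**Backbone tube.** Per chain, a natural cubic spline interpolates the CA
trace (phosphates, then all atoms, as fallbacks), sampled 8× per residue,
swept with a 16-gon cross-section under parallel-transport frames (no
twist), closed by hemispherical caps built from 6 latitude rings. The
16-gon inscribes the nominal radius, so volumes run ~3% under the
continuum cylinder — inside the 5% tolerance the tests use. Struts qualify
between trace points more than 2 positions apart along the chain yet
closer than `max_span` in space; each is a capsule-SDF cylinder unioned
through the voxel engine. With no qualifying pair the input mesh is
returned untouched.

## The voxel engine

All volumetric edits (Boolean subtract/intersect, hollowing, strut and
socket carving) share one primitive: a *fractional-occupancy* rasterizer.
One parity ray per sub-column (2×2 per cell) runs along +z; crossings with
transversal triangles are paired into inside-intervals, and each cell
accumulates its exact covered z-length (a difference-array cumulative sum
handles interior runs). The result is the cell's volume fraction,
anti-aliased exactly along z and at sub-column resolution in x/y. Fields
combine pointwise — union max(f₁, f₂), difference min(f₁, 1−f₂) — and
re-contour at ½ with marching cubes. Analytic solids (spheres, capsules)
enter as clamped signed-distance fields rather than meshes.

Numerical choices: default pitch 1/200 of the first operand's
bounding-box diagonal; the grid origin carries a deterministic irrational
sub-cell offset so axis-aligned faces never coincide with sample lines;
samples exactly at the contour level are nudged off it (exact-level values
trigger holes in the marching-cubes case tables); duplicate marching
vertices are welded and degenerate faces dropped; output winding is
normalized outward. On the cube-minus-cylinder fixture the volume error
falls monotonically from coarse pitches and plateaus at sub-voxel noise
(≈0.3% at the default pitch, bounded by 2%/1% at default/half pitch in
the acceptance checks, cross-checked by a seeded Monte-Carlo membership
estimate). Exact polyhedral CSG is deliberately avoided: robustness on
marching-cubes meshes matters more for printing than exact edges.

Hollowing voxelizes the solid, takes the Euclidean distance transform of
the interior (with a half-voxel center correction), and contours the
depth field at the wall thickness to produce the cavity, which is appended
with reversed orientation — two nested watertight shells. If the wall
meets the inradius everywhere, the solid returns unchanged with a warning.

## Validation and repair

`validate_mesh` counts edge incidences (boundary = 1 face, non-manifold
≥ 3), the Euler characteristic V − E + F over referenced vertices,
connected components, and the divergence-theorem signed volume (negative
⇒ inward normals). Self-intersection is a report-only diagnosis: a
KD-tree prunes candidate triangle pairs, pairs sharing a vertex are
excluded, and a vectorized Möller-style transversal test decides the rest;
coplanar overlaps and mere touching are reported clean, and repair makes
no attempt to untangle (documented limitation).

`repair_mesh` merges vertices within 1e-6 × bounding-box diagonal, drops
degenerate faces, closes boundary cycles (a triangle for 3-cycles, a
centroid fan otherwise; cycles above the 100-edge cap raise an error
carrying the residual report), propagates consistent winding by BFS over
the face-adjacency graph, flips each component to positive volume, and
optionally keeps only the largest-|volume| component. The procedure is
idempotent.

`thin_feature_check` casts inward rays (in-package Möller–Trumbore) at up
to 256 face centroids; samples under the profile's `min_wall` warn
individually, and a connected component that is predominantly thinner
than `min_rod_diameter`, elongated (first principal extent ≥ 2× second),
with its long axis more than 45° from the build axis warns as a
cross-layer rod — the anisotropic weak case for extrusion printing. The
bundled printer profiles (FDM, SLA, powder-binder, SLS, laminated) carry
editable placeholder limits; no quantitative vendor limits are asserted.

## Print preparation

The magnification registry is fixed: 40 × 10⁶ (atomically-manipulable
component sets), 20 × 10⁶ (individual proteins), 10 × 10⁶ (multi-chain
assemblies), 5 × 10⁶ (large assemblies and viruses), 1 × 10⁶ (cellular
structures). Scaling multiplies ångström coordinates by
magnification × 10⁻⁷ to yield millimetres, retags the unit, and refuses
to run twice. Fit checking tries the 6 axis permutations of the bounding
box only — predictable and testable; no free-rotation search.

Interface detection pairs atoms of two structures within a cutoff
(KD-tree), single-linkage clusters the pair midpoints at 2× cutoff, and
emits one patch per cluster at the contact centroid with the normal along
the local a→b centroid direction, ranked by contact count with
lexicographic centroid tie-breaks. Socket carving subtracts, at the
surface point nearest each patch centroid, a cylinder of magnet radius
+ 0.1 mm press-fit clearance, sunk one magnet depth along the inward
normal (default magnet 3 mm diameter × 2 mm depth, a common craft size;
all parameterized). Polarity is assigned alternating (+, −, …) in rank
order or uniformly, so two mating parts prepared with complementary
uniform schemes attract at every opposed socket; an inward ray check
warns when a socket would punch through the local wall.

## Export

Binary STL is the default (80-byte header, uint32 count, 50 bytes per
triangle; a tetrahedron is exactly 284 bytes) with an ASCII mode; reading
sniffs the dialect, verifies the declared triangle count against the byte
length, and welds the soup by exact coordinates. Color drops to STL emit a
warning; VRML 2.0 (IndexedFaceSet, −1-terminated indices, per-vertex
Color node) and OBJ (1-based indices, 6-field vertex-color extension)
carry color. Text formats print 9 significant digits — enough to
round-trip float32 exactly without bloat. X3D and Collada are out of
scope. The CLI manifest is a flat key-value text file whose recorded
volume and watertight flag come from a fresh validation of the exported
mesh.

## Fixture scales and what tests do not show

The bundled fixtures are deliberately small: a 12-residue helix, a 10-bp
duplex trace, a 3-residue protomer for the demonstration capsid, grid
spacings of 0.25–0.8 Å and Monte-Carlo samples of 2 × 10⁵. They exercise
every code path with analytic ground truth, but they do not demonstrate
behavior on full-size PDB entries (10⁴–10⁶ atoms), where grid memory and
the O(faces × covered-cells) rasterization cost dominate and coarser
spacings are appropriate. Synthetic geometry is idealized — no side
chains, no real capsid coordinates, no electrostatics (socket polarity is
an abstract stand-in for charge complementarity), and no mechanical
strength prediction beyond the thin-feature screen.
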