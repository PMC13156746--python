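# Methods

`actintools` re-implements, as a tested library, the comparative
trajectory-analysis stack used to ask how a covalent C-terminal
crosslink (PBM, *N,N′-para*-phenylenebismaleimide, bridging C374 of one
actin protomer to K191 of its cross-strand neighbor) reshapes protomer
geometry, nucleotide-cleft architecture and allosteric communication in
F-actin. This note documents the models, the conventions that were
genuinely open, and what the synthetic verification data do and do not
establish.

## Protomer axis frame and D-loop descriptors

Each frame of a trajectory gets its own orthonormal protomer frame built
from subdomain centroids (unweighted means of alpha-carbon positions):

- **X** = unit(SD3c − SD1c); **origin** = midpoint(SD1c, SD3c);
- **Z** = the component of (SD2c − origin) orthogonal to X
  (Gram–Schmidt), pointing toward SD2;
- **Y** = Z × X (right-handed).

The D-loop (DNaseI-binding loop, residues 38–52) is summarized by:

- **width** — |centroid(CA 38–39) − centroid(CA 51–52)| in Å;
- **in-plane angle** — signed angle in the XZ face between Z and the XZ
  projection of (D-loop centroid − origin), positive toward +X (the SD3
  side);
- **out-of-plane angle** — elevation of the same vector toward +Y.

**Domain tilt** is angle(SD2c−SD1c, Z) − angle(SD4c−SD3c, Z) in degrees,
each term the unsigned angle of the inter-centroid vector to Z and the
difference signed. Because the frame is recomputed per frame, every
descriptor is invariant under rigid motion of the whole structure; the
test suite asserts this to 1e-6 under random rotations/translations.

Conventions that the source material leaves open, fixed here:

- Subdomain residue ranges follow the standard actin convention
  (SD1 = 1–32 ∪ 70–144 ∪ 338–375, SD2 = 33–69, SD3 = 145–180 ∪ 270–337,
  SD4 = 181–269), configurable through `SubdomainScheme`.
- Centroids use alpha-carbons only; "mean position of all residues" is
  ambiguous and CA-only is rotation-stable and matches the CA-based
  cleft-hull convention used elsewhere in the stack.
- The geometric D-loop is 38–52; 38–53 appears in some conventions, and
  a scheme overriding the default warns rather than erroring.
- Angles are emitted signed; absolute values are trivially recoverable
  downstream, so either reading of "angle left/right of Z" is served.

## Ensemble statistics

All superposition is least-squares rigid fitting (Kabsch via SVD,
proper rotation enforced). RMSF is measured about the time-average
structure after two rounds of iterative superposition to the evolving
mean; the per-residue RMSD correlation map instead fits to frame 0,
since it correlates displacement-from-start series. Difference maps are
control − crosslinked, so negative ΔRMSF means the crosslinked system
is more mobile. Replicate statistics are computed per replicate and
then averaged; clustering, PCA and networks use the concatenated
trajectory.

Hydrogen bonds use 3.5 Å donor–acceptor distance and ≤30° H–donor–
acceptor deviation (the GROMACS-style defaults, configurable); a
distance-only fallback is flagged when hydrogens are absent.
Residue–target distance maps use the time-averaged minimum heavy-atom
distance, reported only for residues whose average is within 10 Å of
the target (CA–CA available by flag). Histogram bins are 0.1 Å for
distances and 5° for angles.

SASA is Shrake–Rupley with single-atom van der Waals radii and a 1.4 Å
probe. The sphere lattice is sampled in the molecule's principal-axes
frame with third-moment sign fixing, which makes the result exactly
invariant under rigid motions — a fixed space lattice (the common
implementation) drifts by ~0.4% under rotation. The price is that
near-degenerate principal axes (highly symmetric point sets) can make
the canonical frame unstable; per-atom areas are still valid, only
bit-reproducibility across orientations is then lost. Agreement with an
independent lattice implementation is within 2% at 960+ points.

## Nucleotide-cleft hull

Per frame, the cleft is every residue with a heavy atom within 8 Å of
any cleft ligand atom (ADP, inorganic phosphate, Mg). The convex hull
of the selected residues' alpha-carbons (SciPy Qhull) gives the pocket
volume; an all-heavy-atom hull is available by flag. Hull extents are
max−min of vertex coordinates in the protomer axis frame, so X/Y/Z are
comparable across frames. Degenerate hulls (<4 points or coplanar)
return volume 0 with a flag rather than raising, because early
synthetic frames can be planar. The median-hull frame is the lower
median of the volume series (a real frame must exist for structure
extraction); ties resolve to the lowest frame index. Running averages
are centered moving means with shrinking edge windows.

## Clustering, PCA and free-energy landscapes

GROMOS (Daura) clustering: pairwise least-squares-fit RMSD on the CA
selection, neighbor counting at a 1.5 Å cutoff (the 0.15 nm convention;
coordinates are Å everywhere internally), largest neighborhood becomes
a cluster and is removed, repeat. Ties break toward the lowest frame
index so results are deterministic; the implementation is checked
against an independent straight-line reference on random ≤8-frame
fixtures.

PCA diagonalizes the 3N×3N coordinate covariance after iterative
superposition to the mean, computed through the thin SVD of the
centered frame matrix. Eigenvector signs are fixed (largest-magnitude
component positive) so combined-trajectory analyses are reproducible.
`combined_pca` concatenates two systems, extracts common eigenvectors,
and projects each system separately — the construction used to compare
conformational freedom between crosslinked and control runs on a shared
basis.

Free-energy landscapes: ΔG = −k_B·T·ln(P/P_max) over a 2D histogram of
two projections, at T = 310 K (the simulation temperature), k_B in
kJ/(mol·K). The most-populated bin is exactly 0. Empty bins carry the
maximum finite ΔG + 1 kJ/mol and are excluded from the minima search to
avoid spurious infinite walls. Minima are 8-connected local minima
below a configurable depth threshold (default: half the finite range),
thinned to a configurable basin separation (Chebyshev distance, default
2 bins); each minimum keeps the frame nearest its bin center as the
extractable representative. On a two-Gaussian sample the basin depth
difference reproduces −k_B·T·ln(n₁/n₂) within 0.5 kJ/mol.

## Dynamic networks

Nodes are residues (alpha-carbon based). C_ij is the normalized
cross-correlation of residue fluctuations about the superposed mean
(linear DCCM; the estimator is pluggable). Edges exist where the
minimum heavy-atom distance is ≤4.5 Å in ≥75% of frames, excluding
|i−j| ≤ 1 sequence neighbors; these are the conventional defaults of
the VMD NetworkView-style pipeline, hard-documented here because
"default cutoffs" is not reproducible, and every one is configurable.
Edge weights are w = −log|C| (|C| floored at 1e-12), so correlated
residues are close in path length.

Girvan–Newman removes the edge of maximum *weighted* betweenness per
iteration (deterministic lexicographic tie-break) and returns the
partition maximizing modularity. Modularity is evaluated unweighted:
the −log|C| attribute is a distance, and feeding a distance to
modularity would invert its semantics. Edge betweenness is reported as
unnormalized ordered-pair counts (twice the unordered count, equal
split over ties) so absolute thresholds in the thousands are meaningful
at ~375 nodes; the counting convention is pinned by a brute-force
enumeration oracle in the tests. Suboptimal paths are Dijkstra plus
Yen-style enumeration of simple paths within a fractional tolerance of
the optimum, capped (default 100) to bound runtime. A disconnected pair
yields an explicit "no pathway exists" result, and the standard path
table falls back from F375 to C374 when the terminal residue drops out
of the contact graph — mirroring how terminal connectivity loss is
handled in the comparative analysis.

## Synthetic data: what it emulates, and what it does not

The generator produces a 375-residue CA-only protomer whose subdomain
centroids reproduce a planted layout to machine precision, with
ADP/Pi/Mg-like pseudo-ligand point groups surrounded by a 24-residue
cleft cage, plus deterministic motion modes and block-correlated
Gaussian noise (optional AR(1) memory). Every planted parameter is
recoverable by the downstream analysis that measures it, which is the
package's integration-test strategy:

- **D-loop swings** rotate the loop about the frame origin while
  counter-translating the remaining SD2 residues, so the SD2 centroid —
  and hence the axis frame — is exactly unperturbed and the planted
  angle is exactly the measured shift.
- **The SD3→SD4 hinge** rotates SD4 about an axis through the SD3
  centroid. The default SD4 centroid sits off the SD3 vertical so the
  baseline angle to Z is nonzero; with a baseline of 0 the unsigned
  angle folds under noise and biases recovery low.
- **Cleft breathing** scales the z-coordinates of the cage and ligands
  about the cleft center; the cage is built in ±z pairs so subdomain
  centroids are invariant without compensation, and the planted
  compression appears directly in the hull's Z extent.
- **The C374 tether** displaces the residue toward a cross-strand
  anchor by a restoring fraction per frame and rescales C-terminal
  (370–375) noise, emulating the crosslink's pull; downstream this
  signs ΔRMSF negative at the C terminus and, on the communication
  testbed, breaks the tethered residue's contacts so shortest paths
  reroute around it.

Planted amplitudes are recovered by least-squares projection on the
known sinusoidal schedule; a max−min estimate would be inflated by
extreme-value noise at 2000 frames. Default noise is σ = 0.5 Å per
coordinate (a realistic CA fluctuation scale); the cleft-breathing
recovery uses σ = 0.1 Å because extreme-value noise in a 24-point hull
otherwise biases the extent ratio, and the communication testbed uses
σ = 0.25 Å so its planted contacts hold at 75% occupancy. Filament
builders place protomers on the conventional actin helix (27.5 Å rise,
−166.7° twist) with the dimer (3 crosslinks / 6 protomers) and trimer
(6 / 9) crosslink patterns, 26 linker atoms per crosslink.

What passing these tests does **not** show: the synthetic protomer has
no physical energetics, no side chains (a separate small fixture
builder covers dihedral/H-bond geometry), no solvent, and its contact
topology is designed rather than emergent. Recovery results validate
the *analysis code*, not any biological claim; trajectory-scale
conclusions about PBM–actin require real MD input through the same
interfaces.

## Problem sizes and numerical choices

Parameter-recovery analyses run at 2000 frames on the 375-residue
protomer (communication testbed: 1000 frames, 21 residues), sizes at
which every recovery lands comfortably inside its tolerance; oracle
suites use 100 random fixtures of ≤8 frames/nodes and ≤200 hull points.
The pipeline subsamples trajectories to ≤200 frames for pairwise-RMSD
clustering (O(n²) fits) while all other stages use every frame. Ledger
arithmetic treats Mg as ligand-side and Na/Cl/water as the solvent
pseudo-count, which reproduces the printed system-details additivity;
water and ions never carry coordinates. Floating-point output is fixed
at 6 significant digits so identical config + seed gives byte-identical
CSVs.
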