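# Methods

`emplace` implements a desk-scale integrative structure-determination
workflow for large multi-subunit protein complexes characterized by
negative-stain EM (maps at roughly 25–60 Å) and crosslinking mass
spectrometry (XL-MS). The model system is an Elongator-like assembly: a
two-lobed, C2-symmetric scaffold of three subunit types in two copies each,
with a small hetero-oligomeric ring bound asymmetrically to one lobe. This
note records the model, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Representations

Structures are held at two resolutions. The Cα-only representation (one
pseudo-atom per residue, mean residue mass 110 Da) carries the crosslink and
connectivity restraints. The coarse-grained representation converts each
10-residue stretch of a chain (never crossing a rigid-body boundary) into a
single bead whose center is the Cα centroid of the stretch and whose radius
encloses the expected molecular volume at 135 Å³ per residue; beads carry
the clash score and drive density simulation during fitting. Author residue
numbering is preserved verbatim because crosslink tables cite it.

Density maps are regular grids with isotropic voxels; index (i, j, k) sits
at `origin + (i, j, k) · voxel` (0-based, voxel-centered). Simulated
density places one isotropic Gaussian per particle, mass-weighted and
normalized to unit integral, with σ = resolution/(π√2) so that the kernel's
Fourier amplitude falls to 1/e at spatial frequency 1/resolution. The same
convention defines the Gaussian low-pass filter, so filtering and
simulation compose exactly (two Gaussians of widths R₁, R₂ equal one of
width √(R₁²+R₂²)).

## Crosslink handling

Identified links are read from xQuest-style delimited tables and filtered
at an ld (linear discriminant) confidence score of ≥ 30, the inclusive
reading of the usual "highly confident" cutoff; the threshold is a
parameter. Duplicate unordered residue pairs with the same linker collapse
to the highest-scoring record. DSS and DSG share one satisfaction
threshold: a link is satisfied when the Cα–Cα distance is ≤ 30 Å.

When a subunit is present in two copies, each link's reported distance is
the minimum over all copy-pair combinations, independently per link;
dimeric links (a residue crosslinked to itself) are only mappable across
two copies. This minimum rule is the field convention and is conservative
for violations: the satisfaction fraction it yields can only exceed that of
any fixed copy assignment.

## Rigid-body fitting

Each domain is fitted into the map by a global search: poses are drawn with
Haar-uniform rotations and translations uniform over the map box, and each
start is locally optimized by a derivative-free hill climb (translation
steps of 0.25 voxel and rotation steps of 2°, halved when a full sweep of
the twelve axis moves fails; a successful move is repeated while it keeps
improving, so travel is not limited by the initial step). The climbs for
all starts run in lockstep as one vectorized batch; each start's move
sequence is identical to the serial algorithm.

The search objective is a fast surrogate: the map is convolved once with
the simulation Gaussian, so the mass-weighted sum of that field at the
body's bead positions equals the inner product of the body's simulated
density with the map; dividing by the local root-mean-square map intensity
around the body center (floored at 5% of its maximum) prevents the sum from
simply chasing the densest region.

The definitive fitting metric is a masked Pearson normalized
cross-correlation between the body's simulated density and the map,
computed on the bounding subgrid of the transformed body, over a threshold
mask — voxels above 0.2 of the simulated density's maximum, i.e. the body's
own envelope. Two measures keep this metric discriminative in crowded,
noisy maps:

- **Laplacian filtering** (default on): both simulation and map are
  Laplacian-filtered before correlating. Without it, a small body placed
  inside the smooth interior of a larger body's density correlates almost
  as well as at its true site; the Laplacian penalizes such size-mismatched
  placements because their curvature signatures differ.
- **Noise band-limiting**: the map is low-pass filtered at
  min(3 voxels, resolution/2) before the Laplacian, removing voxel-scale
  noise that the Laplacian would otherwise amplify, and the simulation uses
  the matching effective resolution (Gaussian composition), so a perfect
  pose on a clean map scores exactly 1.

Optimized poses are clustered greedily in descending score with tight
thresholds (cluster angle 1°, cluster shift 1 Å; rotation metric
2·arccos|q₁·q₂|, shift metric between transformed body centroids), taking a
cyclic map symmetry into account when present. Every cluster
representative is rescored once with the exact metric; the best ones are
polished by the same hill climb under the exact metric (rotation step
starting at 4°). Because the EM score cannot rank orientations of
near-spherical bodies, an orientational scan supplements the search: at the
top distinct candidate sites (default 40, ≥ 10 Å apart) a fixed set of 48
orientations is scored, the best per site is polished, and the rest enter
the library unpolished so that downstream restraint-based selection can
choose among orientations the density cannot distinguish.

Fit significance follows the empirical-null recipe: scores are mapped
through Fisher's z-transform (atanh), a robust Gaussian null is fitted to
the bulk (location = median, scale = 1.4826 × MAD), and two-sided P-values
are read from its tails. P-values are invariant under recentering. For the
handedness (mirror) test the body is fitted into the map and its mirror
image and the best fits are compared under one *pooled* null over both
libraries — per-library nulls have independently estimated scales and their
P-values are not comparable across hands. The verdict is called
inconclusive below one order of magnitude in P.

## Assembly by Monte Carlo recombination

For assembly, each subunit type is fitted once and symmetry-related copies
share the library: clustering with the map's C2 folds the two equivalent
lobes onto one representative, so libraries are re-expanded through the
symmetry operators, giving every copy fits at both lobes.

Configurations are sampled by independent simulated-annealing runs: random
initial fit assignment, then single-body fit-index redraws (uniform over
the body's library) accepted by the Metropolis criterion on a geometric
temperature schedule; the best state of each run is kept. The initial
temperature auto-calibrates to the 90th percentile of |move delta| at
random states, capped at 1.2 × the EM weight — heat above the EM
reorganization scale only randomizes. Because a desk-scale run cannot visit
every index of every library in its cold phase, the best runs (default 20)
receive a deterministic greedy quench before final ranking: full coordinate
descent over each body's library plus pairwise site-exchange sweeps, the
zero-temperature limit of the move set applied exhaustively. The site-swap
sweep matters: two bodies that have traded sites cannot un-swap through
single-body moves without passing through a clashed intermediate.

The composite objective is the linear combination
`w_em·(−Σ NCC) + w_xl·XL + w_conn·CONN + w_clash·CLASH` (lower is better):

- **EM**: sum of the per-body fit scores, precomputed in library-indexed
  mode and recomputed against the map during continuous refinement.
- **Crosslinks**: per link, zero up to the 30 Å threshold, then
  ((d−30)/σ_xl)² with σ_xl = 7.5 Å, capped at 4. The cap is the robustness
  device for the ~5% decoy identifications expected of XL-MS at the usual
  confidence filter: a badly violated link contributes a constant plateau
  instead of an unbounded quadratic pull, so decoys stop exerting force
  rather than warping the assembly.
- **Connectivity**: per linker of n residues between consecutive domains of
  one chain, free up to n × 3.8 Å + 5 Å slack, quadratic beyond (scaled by
  3.8 Å).
- **Clash**: Σ max(0, rᵢ+rⱼ−dᵢⱼ)² over inter-body bead pairs.

Default weights are (w_em, w_xl, w_conn, w_clash) = (25, 1, 1, 0.1),
calibrated so the terms have comparable magnitude on the standard fixture:
per-body EM differences between alternative placements are ~0.1–0.4 NCC
units, while a single meaningfully violated crosslink costs a few units.
All functional parameters are exposed.

The published-scale preset (10,000 configurations × 60,000 steps; 100,000
fit starts) is available; the desk defaults are 200 × 5,000 with 3,000 fit
starts, which suffice for full placement recovery on the standard fixture.

Continuous refinement then perturbs one body per move (translation ≤ 1
voxel, rotation ≤ 2° about the body centroid) with annealed Metropolis
acceptance, recomputing that EM term exactly; the returned configuration is
never worse than the input. The two-lobe protocol splits a fitted model at
a flexible hinge into two super-rigid bodies (other chains join the lobe
with the nearer hinge-half centroid), fits the lobes independently into the
second map, and refines. Full-atom models are rebuilt by applying each
body's pose to its atoms and re-joining flexible linkers by straight-line
Cα interpolation — a representational choice, not a conformational claim.

## Synthetic ground truth

Bodies are compact self-avoiding Cα walks (3.8 Å steps, 3.6 Å exclusion;
steps that grow the radius of gyration are kept with probability 0.3 only).
Every 8th residue stands in for a crosslinkable lysine. The standard
fixture uses scaffold subunits of 150/100/70 residues (×2 copies, C2 about
z) and ring bodies of 50/40/35 residues — the size ladder of the real
complex, scaled down — on a shared grid with 4 Å voxels; maps are simulated
at 27 Å (scaffold) and 31 Å (full) with additive Gaussian voxel noise at
0.1 × the signal SD. The crosslink table holds 116 unique links, ~41
inter-subunit, with a 5% decoy rate (decoys drawn from pairs farther than
the 30 Å reach); confidence scores are drawn above the ld = 30 filter
(true links around 40, decoys around 33) so decoys are exercised
downstream rather than filtered away. The handedness test body is a
helical arm (corkscrew) — compact globular chains are effectively achiral
below ~20 Å, a corkscrew is not, at any resolution.

What the synthetic data does *not* emulate: stain flattening, the missing
wedge, preferred orientation, heterogeneity/flexible conformers, and
real protein shapes (SAW blobs are rounder than real domains, which makes
orientation recovery *harder* than for, say, a two-lobed WD40 dimer).
Passing placement recovery here shows the estimator machinery is sound
under the stated noise model, not that any particular real complex would be
recovered.

## Known limitations

- Small near-spherical bodies (≲ 70 residues here) cannot be oriented, and
  often not even uniquely sited, from a 27–31 Å map alone: misrotations of
  140–170° score within noise of the truth, and dense regions attract
  small-body fits. This is physics, not implementation: the orientation
  recovery is achieved by the crosslink-driven assembly stage, and the
  per-body fit stage is only expected to recover large, anisotropic bodies
  to a few degrees.
- The MC explores fit-index space; errors of the library (orientation
  granularity at a site) bound the achievable accuracy before refinement.
- The handedness call needs a genuinely chiral, well-resolved body; it is
  meaningless for pseudo-symmetric domains.
- No FFT-accelerated exhaustive 6D search, no flexible fitting, no
  B-factor/half-map machinery; maps are consumed as given.
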