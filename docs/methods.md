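# Methods

This note documents the models implemented in `nanofoci`, the parameters
that matter, the design decisions taken where the procedure was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Image segmentation

Stacks are `(channels, z, y, x)` grids with anisotropic voxel sizes,
default 39 nm lateral and 125 nm axial; a voxel is therefore
1.90 × 10⁻⁴ µm³. Physical coordinates place the centre of voxel *i* at
`i × voxel_size`; all connectivity is 26-connected (the full 3×3×3
neighbourhood), which suits dense blob-like objects.

**Nucleus.** DAPI voxels at or above the threshold are grouped into
components; components below the volume floor (default 200 µm³) are
discarded, holes are filled, then two rounds of (dilate, close) with the
3×3×3 element absorb DAPI-weak internal volumes. These rounds
intentionally grow the mask — by the Minkowski sum with a 2-voxel box
(78 nm laterally, 250 nm axially) — so the reported nuclear volume exceeds
the thresholded volume accordingly; the test suite checks the grown volume
against the exact Steiner formula for ball ⊕ box. The largest surviving
component is the nucleus.

**Nano-foci.** Voxels ≥ 1000 counts (16-bit data) form 26-connected
components; components below 0.001 µm³ (≥ 6 voxels at default geometry)
are removed, and components whose intensity-weighted centroid lies outside
the nuclear mask are discarded. Centroids are intensity-weighted because
the unweighted voxel centroid is unstable under partial voxelisation of
small blobs.

**Touching-object separation.** Components above twice the nominal
single-focus volume (0.05 µm³) are candidates for splitting. Markers are
local intensity maxima, selected bright-first under a minimum pairwise
*physical* spacing equal to the equivalent-sphere diameter of the nominal
volume (≈ 457 nm); a marker-controlled watershed on the inverted intensity
then partitions the component. Fragments falling below the minimum object
size are merged into the neighbouring fragment with the largest contact
surface, so the size floor survives splitting. A component yielding fewer
than two markers is left intact (best-effort separation).

## DNA content, volume fraction, shells

DNA content uses DAPI proportionality:
`content_kb = (focus ∫DAPI / nuclear ∫DAPI) × G × 10³ / c`, with genome
size `G` in Mbp and cell-cycle factor `c`. The cell-cycle correction is
defined as `c = nuclear ∫DAPI / G1-reference ∫DAPI` (1 in G1, 2 in G2);
the G1 reference is supplied by the caller or estimated externally — no
formula for it is asserted here. Values strictly outside the 0.5th–99.5th
percentiles of the pooled distribution are flagged as trimmed; percentiles
interpolate linearly between order statistics (implementations differ, so
the rule is fixed explicitly). For 1000 distinct values this retains
exactly 990.

The γH2AX-occupied volume fraction is `100 × Σ focus volumes / nuclear
volume`; it is the quantity that later selects the genomic percentile
threshold (a fraction of 7.81% ⇒ the 92.19th percentile).

Shells dilate each focus mask by 3 voxels per axis (a Chebyshev ball, so
117 nm laterally and 375 nm axially at default geometry), subtract every
focus voxel, clip to the nucleus, and resolve overlaps by assigning the
contested voxel to the focus with the nearest centroid in physical
distance (the overlap rule is a package decision; nothing in the source
procedure constrains it). A focus whose shell is entirely clipped reports
missing statistics rather than zeros.

## Clustering and cluster metrics

Two foci share a cluster when their centroids are **strictly** closer than
the cutoff (default 500 nm), extended transitively — single-linkage
connected components. Ties at exactly the cutoff are not linked; the
strictness follows the "closer than" phrasing of the rule. The partition
is verified against an O(n³) transitive-closure oracle.

Per cluster: integrated volume (Σ member volumes); inter-focal volume as
the convex hull of member centroids (0 with a degeneracy flag for < 4
points or coplanar/collinear geometry — degenerate clusters are reported,
not dropped); the **shortest path connecting all centroids** interpreted
as the shortest open Hamiltonian path, computed exactly by subset dynamic
programming for ≤ 10 members (clusters typically hold ~4 foci, so the
exact branch dominates) and by nearest-neighbour + 2-opt above, flagged
`path_exact=False`; mean pairwise centroid distance; and summed member DNA
content, which is conserved across the partition by construction.

## Nearest-neighbour null model

Observed inter-channel nearest-neighbour distances are compared with
simulations placing the same numbers of query and target points uniformly
in a sphere whose radius is the sphere-equivalent of the mean segmented
nuclear volume. Sampling uses `r = R·U^{1/3}` with isotropic directions;
the mean radial coordinate is 3R/4, which the tests verify. Points are
dimensionless — no hard-core exclusion is imposed, since none is specified
for the source procedure. Both the pooled distance distribution and
per-iteration medians are reported (which of the two the original analysis
pooled is unstated, so both are emitted). For a centre query the
nearest-distance CDF is `P(d ≤ r) = 1 − (1 − (r/R)³)^n`; for uniformly
placed queries, edge effects displace the empirical CDF by ≈ 0.049 in
Kolmogorov distance at n_target = 200 and R = 5 µm. Checks against this
closed form therefore use enough iterations (400–800) that the Monte-Carlo
error of the KS estimate is small against that deterministic deviation.

Object-count ratios between channels (e.g. foci per DSB-end label) are
reported as both the through-origin least-squares slope `Σab/Σa²` and the
ordinary slope/intercept fit, with a degeneracy flag when the predictor
has zero variance.

## Genomic integration

Tracks are fixed-width bins (default 10 kb), BED-style 0-based half-open.
RPKM assigns each read to the bin containing its midpoint — a rule that
conserves read counts exactly (configurable design choice; the alternative
overlap-proportional assignment is not needed by any downstream step).
Smoothing is a centred moving average of 1–25 bins with truncated windows
at chromosome ends; normalisation divides by the genome-wide mean.
Correlation with feature tracks is Spearman's ρ with average ranks for
ties and pairwise NaN exclusion; a mode excluding zero-signal bins is
provided because the treatment of unmappable bins in the source analysis
is unstated.

Percentile filtering retains bins `≥` the (100 − f)-th percentile of the
pooled distribution, where `f` is the imaging volume fraction in percent;
on a fully tied (constant) track everything is retained — the `≥` tie
rule only matters in that degenerate case. Retained runs merge into
domains with **no gap tolerance**. The smoothing window is chosen by
exhaustive scan over w = 1..25: the target count is the nano-focus count
divided by the ploidy factor (3.12 = aneuploid genome / haploid
reference), and the w minimising |domain count − target| wins, ties going
to the smaller w.

CTCF boundary analysis represents peaks by midpoints, measures each domain
boundary's distance to the nearest (optionally maximum-score-only) peak,
and sums peak scores in 100-kb windows from −300 kb (outside) to +100 kb
(inside) of each boundary. Motif scanning compiles an IUPAC consensus to a
regex, scans both strands (reverse-strand hits located via the reverse
complement, coordinates on the forward strand), merges overlapping
same-strand matches, and reports inter-site gaps overall and per strand.
A consensus that is its own reverse complement yields identical interval
sets on both strands and is reported once, on the forward strand.

Expected DSB counts scale literature yields (30–55 per Gy per **diploid**
genome) by dose and by `ploidy_factor / 2`, rounding to the nearest 10:
470–860 for 10 Gy at ploidy factor 3.12.

## Synthetic data: what it emulates and what it does not

The image generator builds a spherical nucleus (default radius 2.5 µm in a
44 × 160 × 160 grid — a deliberately scaled-down geometry that keeps a
full run in seconds) with a uniform DAPI base level, and plants Gaussian
nano-foci (σ = 40 nm, amplitude 20 000) whose above-threshold lateral
diameter is ~200 nm, matching the measured nano-focus scale. Clusters of 4
foci are placed with ≥ 2 µm separation between cluster centres; foci
within a cluster scatter with σ = 100 nm subject to a 350-nm minimum
spacing (adjacent ~200-nm objects must remain optically separable) and a
430-nm maximum nearest-neighbour link (so a cluster is a connected chain
under the 500-nm cutoff even after ≤ 30 nm centroid measurement error).
Per-focus DNA fractions are planted *exactly*: the DAPI value over each
focus's support region is solved so the focus holds the requested share of
the total signal; the support sits strictly inside what a noisy
segmentation recovers (margin 1.3 × threshold), so segmentation boundary
noise only adds base-level voxels and the recovered fractions stay within
a fraction of a percent. Gaussian read noise (σ = 20) is added to every
channel; track noise is Poisson.

Not emulated: optical transfer functions and reconstruction artefacts,
chromatic shifts between channels, non-spherical nuclei and chromocentre
structure, intensity variation between foci, and the mapping biases of
real sequencing data. Passing tests therefore demonstrate the correctness
of the measurement chain on data satisfying the stated model — not the
robustness of the segmentation to real microscope artefacts.

## Numerical choices and limitations

- Thresholds are raw counts of 16-bit-converted data; detection uses `≥`.
- The minimum object size is the stated 0.001 µm³ value (≈ 5.3 voxels at
  default geometry); an alternative 8-voxel convention exists in the
  field, so the floor is configurable.
- Percentiles interpolate linearly everywhere (trimming, filtering).
- The Hamiltonian-path heuristic above 10 members is flagged, and its
  result is always ≥ the minimum-spanning-tree lower bound.
- Degenerate convex hulls return volume 0 with a flag rather than raising.
- The pipeline's demo configuration lowers the nuclear volume floor to
  20 µm³ because the scaled-down synthetic nucleus (~65 µm³) is smaller
  than a real one; the 200 µm³ default remains on the library function.
- Clustering is pure distance linkage: no density-based variant (minPts)
  is provided, because the rule being modelled is purely geometric.
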