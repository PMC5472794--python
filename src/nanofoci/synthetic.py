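"""Ground-truth generators for every pipeline stage.

Two families of inputs are emulated:

* 3D voxel images of a spherical nucleus with a DAPI-like counterstain and
  DSB-marker channels carrying Gaussian nano-foci arranged in spatial
  clusters (plus optional offset marker blobs, e.g. a CTCF-like channel);
* binned genomic coverage tracks with planted enriched domains and
  BED-style peak features flanking the domain boundaries.

All generators are seeded and deterministic; every planted quantity is
recorded in a truth record so that downstream segmentation, clustering and
domain calling can be scored against known answers.

Default geometry emulates the imaged system: 39 nm lateral / 125 nm axial
voxels, nano-foci whose above-threshold lateral diameter is ~200 nm, and
clusters of four nano-foci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import ImageStack, voxel_volume_um3
from .genomics import BinnedTrack

__all__ = [
    "GeometryError",
    "ImageTruth",
    "TrackTruth",
    "make_nucleus_image",
    "make_chipseq_track",
    "make_ctcf_peaks",
    "write_image_truth",
]


class GeometryError(ValueError):
    """Requested geometry cannot be realised (nucleus or clusters do not fit)."""


@dataclass
class ImageTruth:
    """Everything planted into a synthetic nucleus image.

    ``focus_centroids_nm`` are (x, y, z) physical coordinates;
    ``planted_dna_fractions`` is each focus's exact share of the total
    noiseless DAPI signal (their sum is < 1 by construction).
    """

    focus_centroids_nm: np.ndarray          # (n, 3) x,y,z in nm
    focus_sigma_nm: float
    cluster_assignments: np.ndarray         # (n,) cluster id per focus
    nucleus_radius_um: float
    nucleus_center_nm: np.ndarray           # (3,) x,y,z in nm
    planted_dna_fractions: np.ndarray       # (n,)
    seed: int
    voxel_size_nm: tuple[float, float] = (39.0, 125.0)
    focus_amplitude: float = 20000.0
    ctcf_offset_nm: float | None = None


@dataclass
class TrackTruth:
    """Planted structure of a synthetic binned coverage track.

    ``domain_intervals`` are 0-based half-open (chrom, start, end) triples,
    non-overlapping and sorted per chromosome; rates are expected reads per
    bin inside (``enrichment_rate``) and outside (``background_rate``) the
    domains. ``boundary_peak_offsets`` shifts flanking peak features outward
    from each domain boundary.
    """

    domain_intervals: list[tuple[str, int, int]]
    background_rate: float = 1.0
    enrichment_rate: float = 10.0
    boundary_peak_offsets: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_rate < self.background_rate:
            raise ValueError("enrichment_rate must be >= background_rate")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.domain_intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping domains on {chrom}")
        self.domain_intervals = sorted(self.domain_intervals)


def _grid_coords_nm(shape_zyx, voxel_size_nm):
    """Physical coordinate vectors (z, y, x) of voxel centres."""
    lateral, axial = voxel_size_nm
    nz, ny, nx = shape_zyx
    return (
        np.arange(nz) * axial,
        np.arange(ny) * lateral,
        np.arange(nx) * lateral,
    )


def _place_cluster_centers(
    rng: np.random.Generator,
    n_clusters: int,
    max_radius_nm: float,
    min_inter_nm: float,
    center_nm: np.ndarray,
    max_tries: int = 2000,
    max_restarts: int = 20,
) -> np.ndarray:
    # greedy rejection sampling with restarts (greedy placements can dead-end)
    for _ in range(max_restarts):
        centers: list[np.ndarray] = []
        for _ in range(max_tries):
            if len(centers) == n_clusters:
                return np.array(centers)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = max_radius_nm * rng.random() ** (1.0 / 3.0)
            cand = center_nm + r * direction
            if all(np.linalg.norm(cand - c) >= min_inter_nm for c in centers):
                centers.append(cand)
        if len(centers) == n_clusters:
            return np.array(centers)
    raise GeometryError(
        f"could not place {n_clusters} cluster centres at "
        f">= {min_inter_nm} nm inside a {max_radius_nm:.0f} nm ball"
    )


def _add_gaussian_blob(img, coords_zyx, center_xyz_nm, sigma_nm, amplitude,
                       cutoff_sigmas: float = 4.0):
    """Add an isotropic (in physical space) Gaussian blob in place."""
    zc, yc, xc = coords_zyx
    cx, cy, cz = center_xyz_nm
    zi = np.flatnonzero(np.abs(zc - cz) <= cutoff_sigmas * sigma_nm)
    yi = np.flatnonzero(np.abs(yc - cy) <= cutoff_sigmas * sigma_nm)
    xi = np.flatnonzero(np.abs(xc - cx) <= cutoff_sigmas * sigma_nm)
    if zi.size == 0 or yi.size == 0 or xi.size == 0:
        return
    dz = (zc[zi] - cz)[:, None, None]
    dy = (yc[yi] - cy)[None, :, None]
    dx = (xc[xi] - cx)[None, None, :]
    blob = amplitude * np.exp(-(dx**2 + dy**2 + dz**2) / (2.0 * sigma_nm**2))
    img[np.ix_(zi, yi, xi)] += blob


def make_nucleus_image(
    shape: tuple[int, int, int] = (44, 160, 160),
    voxel_size_nm: tuple[float, float] = (39.0, 125.0),
    n_clusters: int = 5,
    foci_per_cluster: int = 4,
    intra_cluster_sigma_nm: float = 100.0,
    min_inter_cluster_nm: float = 2000.0,
    min_intra_focus_nm: float = 350.0,
    max_intra_link_nm: float = 430.0,
    channels: tuple[str, ...] = ("dapi", "gamma"),
    seed: int = 0,
    nucleus_radius_um: float = 2.5,
    focus_sigma_nm: float = 40.0,
    focus_amplitude: float = 20000.0,
    dapi_base: float = 5000.0,
    dna_fraction_per_focus: float = 0.005,
    focus_support_threshold: float = 1000.0,
    support_margin: float = 1.3,
    dapi_mode: str = "plateau",
    shell_boost: float = 2.0,
    ctcf_offset_nm: float = 250.0,
    noise_sigma: float = 20.0,
) -> tuple[ImageStack, ImageTruth]:
    """Simulate a nucleus with clustered nano-foci; returns (stack, truth).

    The nucleus is a sphere of radius ``nucleus_radius_um`` centred in the
    grid. Cluster centres are sampled uniformly in the (margin-shrunk)
    nuclear ball at pairwise distance >= ``min_inter_cluster_nm``; each
    cluster receives ``foci_per_cluster`` foci scattered isotropically with
    ``intra_cluster_sigma_nm``.

    Channels: ``dapi`` carries a uniform base level inside the nucleus with
    per-focus plateaus sized so each focus holds exactly
    ``dna_fraction_per_focus`` of the total noiseless DAPI signal
    (``dapi_mode='plateau'``); ``dapi_mode='bright_shell'`` additionally
    boosts a one-voxel-dilated shell around each focus support, emulating
    DNA accumulating at the focus periphery. ``gamma`` carries Gaussian
    blobs at the focus centroids; a channel named ``ctcf`` carries blobs
    offset from each centroid by ``ctcf_offset_nm`` in a random direction.
    Gaussian read noise (``noise_sigma``) is added to every channel and the
    result clipped at zero.

    Raises :class:`GeometryError` when the sphere does not fit the grid or
    the clusters cannot be placed at the requested separation.
    """
    if n_clusters > 0 and min_inter_cluster_nm <= 2.0 * intra_cluster_sigma_nm:
        raise ValueError(
            "min_inter_cluster_nm must exceed 2 x intra_cluster_sigma_nm"
        )
    if dapi_mode not in ("plateau", "bright_shell"):
        raise ValueError(f"unknown dapi_mode {dapi_mode!r}")
    lateral, axial = voxel_size_nm
    nz, ny, nx = shape
    radius_nm = nucleus_radius_um * 1000.0
    extent_nm = np.array([nx * lateral, ny * lateral, nz * axial])  # x,y,z
    center_nm = (extent_nm - np.array([lateral, lateral, axial])) / 2.0
    if np.any(radius_nm > extent_nm / 2.0):
        raise GeometryError(
            f"nucleus radius {radius_nm:.0f} nm exceeds half-extents {extent_nm / 2}"
        )

    rng = np.random.default_rng(seed)
    zc, yc, xc = _grid_coords_nm((nz, ny, nx), voxel_size_nm)
    dist2 = (
        (zc[:, None, None] - center_nm[2]) ** 2
        + (yc[None, :, None] - center_nm[1]) ** 2
        + (xc[None, None, :] - center_nm[0]) ** 2
    )
    nucleus = dist2 <= radius_nm**2

    n_foci = n_clusters * foci_per_cluster
    margin = 3.0 * intra_cluster_sigma_nm + 3.0 * focus_sigma_nm
    if n_clusters > 0:
        cluster_centers = _place_cluster_centers(
            rng, n_clusters, max(radius_nm - margin, 1.0),
            min_inter_cluster_nm, center_nm,
        )
        centroids = []
        assignments = []
        for cid, cc in enumerate(cluster_centers):
            placed: list[np.ndarray] = []
            for _ in range(foci_per_cluster):
                for _try in range(5000):
                    p = cc + rng.normal(scale=intra_cluster_sigma_nm, size=3)
                    inside = (np.linalg.norm(p - center_nm)
                              <= radius_nm - 3 * focus_sigma_nm)
                    # adjacent nano-foci must stay optically separable, yet
                    # chained tightly enough to share a cluster downstream
                    dists = [np.linalg.norm(p - q) for q in placed]
                    apart = all(d >= min_intra_focus_nm for d in dists)
                    linked = not placed or min(dists) <= max_intra_link_nm
                    if inside and apart and linked:
                        break
                else:
                    raise GeometryError(
                        "could not place focus inside nucleus at the "
                        "requested intra-cluster spacing"
                    )
                placed.append(p)
                centroids.append(p)
                assignments.append(cid)
        centroids = np.array(centroids)
        assignments = np.array(assignments)
    else:
        centroids = np.empty((0, 3))
        assignments = np.empty((0,), dtype=int)

    coords_zyx = (zc, yc, xc)
    gamma = np.zeros((nz, ny, nx))
    for p in centroids:
        _add_gaussian_blob(gamma, coords_zyx, p, focus_sigma_nm, focus_amplitude)

    # per-focus supports: noiseless gamma voxels above the (margin-raised)
    # detection threshold, each voxel claimed by its nearest centroid; the
    # margin keeps the DNA-carrying plateau strictly inside the region a
    # noisy segmentation recovers, so boundary voxels carry only base signal
    supports = np.zeros((nz, ny, nx), dtype=np.int32)  # 0 = none, i+1 = focus i
    if n_foci:
        above = gamma >= support_margin * focus_support_threshold
        vox = np.argwhere(above)
        phys = vox * np.array([axial, lateral, lateral])
        phys_xyz = phys[:, ::-1]
        from scipy.spatial import cKDTree

        _, owner = cKDTree(centroids).query(phys_xyz)
        supports[tuple(vox.T)] = owner + 1

    fractions = np.full(n_foci, float(dna_fraction_per_focus))
    if fractions.sum() >= 1.0:
        raise ValueError("planted DNA fractions must sum to < 1")

    dapi = np.where(nucleus, float(dapi_base), 0.0)
    if n_foci:
        support_counts = np.bincount(supports.ravel(), minlength=n_foci + 1)[1:]
        if np.any(support_counts == 0):
            raise GeometryError("a focus has an empty above-threshold support")
        n_background = int(nucleus.sum()) - int(support_counts.sum())
        # total chosen so that value_i * count_i = fraction_i * total exactly
        total = dapi_base * n_background / (1.0 - fractions.sum())
        values = fractions * total / support_counts
        dapi[supports > 0] = values[supports[supports > 0] - 1]
        if dapi_mode == "bright_shell":
            from scipy import ndimage as _ndi

            # ring at Chebyshev distance 2-3 voxels from the detection-level
            # support: the 1-voxel buffer keeps the boosted voxels out of a
            # noisy segmentation of the focus itself
            struct = np.ones((3, 3, 3), bool)
            detect = gamma >= focus_support_threshold
            inner = _ndi.binary_dilation(detect, structure=struct, iterations=1)
            outer = _ndi.binary_dilation(detect, structure=struct, iterations=3)
            dapi[outer & ~inner & nucleus] *= shell_boost
        # exact realised fractions (recomputed so any mode stays truthful)
        total = dapi.sum()
        planted = np.array(
            [dapi[supports == i + 1].sum() / total for i in range(n_foci)]
        )
    else:
        planted = np.empty((0,))

    data = {"dapi": dapi, "gamma": gamma}
    used_ctcf_offset = None
    if "ctcf" in channels:
        used_ctcf_offset = float(ctcf_offset_nm)
        ctcf = np.zeros((nz, ny, nx))
        for p in centroids:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            _add_gaussian_blob(
                ctcf, coords_zyx, p + ctcf_offset_nm * direction,
                focus_sigma_nm, focus_amplitude,
            )
        data["ctcf"] = ctcf

    stacks = []
    for name in channels:
        if name not in data:
            raise ValueError(f"unknown channel {name!r}; known: {sorted(data)}")
        img = data[name]
        if noise_sigma > 0:
            img = img + rng.normal(scale=noise_sigma, size=img.shape)
        stacks.append(np.clip(img, 0.0, None))
    stack = ImageStack(np.stack(stacks), voxel_size_nm, tuple(channels))
    truth = ImageTruth(
        focus_centroids_nm=centroids,
        focus_sigma_nm=float(focus_sigma_nm),
        cluster_assignments=assignments,
        nucleus_radius_um=float(nucleus_radius_um),
        nucleus_center_nm=center_nm,
        planted_dna_fractions=planted,
        seed=int(seed),
        voxel_size_nm=(float(lateral), float(axial)),
        focus_amplitude=float(focus_amplitude),
        ctcf_offset_nm=used_ctcf_offset,
    )
    return stack, truth


def make_chipseq_track(
    genome_length: int,
    bin_size: int,
    truth: TrackTruth,
    chrom: str = "chr1",
) -> BinnedTrack:
    """Poisson-noise coverage track with planted enriched domains.

    Bin means are ``truth.enrichment_rate`` inside planted domains and
    ``truth.background_rate`` elsewhere; counts are Poisson draws seeded by
    ``truth.seed``. Domain boundaries must align to the bin grid.
    """
    n_bins = genome_length // bin_size
    means = np.full(n_bins, float(truth.background_rate))
    for c, start, end in truth.domain_intervals:
        if c != chrom:
            continue
        if start % bin_size or end % bin_size:
            raise ValueError(
                f"domain {c}:{start}-{end} not aligned to bin size {bin_size}"
            )
        if end > genome_length:
            raise ValueError(f"domain {c}:{start}-{end} beyond genome length")
        means[start // bin_size: end // bin_size] = truth.enrichment_rate
    rng = np.random.default_rng(truth.seed)
    values = rng.poisson(means).astype(float)
    return BinnedTrack(values={chrom: values}, bin_size=bin_size, state="raw")


def domain_bin_mask(truth: TrackTruth, genome_length: int, bin_size: int,
                    chrom: str = "chr1") -> np.ndarray:
    """Boolean per-bin ground-truth labels (True inside a planted domain)."""
    mask = np.zeros(genome_length // bin_size, dtype=bool)
    for c, start, end in truth.domain_intervals:
        if c == chrom:
            mask[start // bin_size: end // bin_size] = True
    return mask


def make_ctcf_peaks(
    truth: TrackTruth,
    jitter_bp: int = 0,
    score_range: tuple[float, float] = (100.0, 1000.0),
    max_score_fraction: float = 0.5,
    peak_width: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """BED6-style peak set flanking every planted domain boundary.

    Each domain contributes two peaks, shifted outward by
    ``truth.boundary_peak_offsets`` plus uniform jitter in
    ``[-jitter_bp, +jitter_bp]``. A ``max_score_fraction`` share of peaks
    (rounded down, chosen at random) carries exactly the maximum score,
    emulating capped occupancy scores; the rest get uniform scores in
    ``score_range``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    offset = float(truth.boundary_peak_offsets)
    for chrom, start, end in truth.domain_intervals:
        for boundary, sign in ((start, -1), (end, +1)):
            jit = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            center = int(boundary + sign * offset + jit)
            rows.append((chrom, max(center - peak_width // 2, 0),
                         max(center + peak_width // 2, 1)))
    n = len(rows)
    lo, hi = score_range
    scores = lo + (hi - lo) * rng.random(n)
    n_max = int(np.floor(max_score_fraction * n))
    max_idx = rng.choice(n, size=n_max, replace=False) if n_max else []
    scores[max_idx] = hi
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"peak_{i}" for i in range(n)]
    df["score"] = scores
    df["strand"] = "."
    df["is_max_score"] = False
    df.loc[max_idx, "is_max_score"] = True
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_image_truth(truth: ImageTruth, prefix: str) -> tuple[str, str]:
    """Write the truth record as a TSV (per-focus) plus a JSON parameter file."""
    df = pd.DataFrame(
        {
            "focus_id": np.arange(len(truth.focus_centroids_nm)),
            "x_nm": truth.focus_centroids_nm[:, 0] if len(truth.focus_centroids_nm) else [],
            "y_nm": truth.focus_centroids_nm[:, 1] if len(truth.focus_centroids_nm) else [],
            "z_nm": truth.focus_centroids_nm[:, 2] if len(truth.focus_centroids_nm) else [],
            "cluster_id": truth.cluster_assignments,
            "dna_fraction": truth.planted_dna_fractions,
        }
    )
    tsv = f"{prefix}_truth.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    params = asdict(truth)
    for key in ("focus_centroids_nm", "cluster_assignments",
                "planted_dna_fractions", "nucleus_center_nm"):
        params[key] = np.asarray(params[key]).tolist()
    js = f"{prefix}_params.json"
    with open(js, "w") as fh:
        json.dump(params, fh, indent=2)
    return tsv, js
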