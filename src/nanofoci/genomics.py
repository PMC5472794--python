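"""Binned coverage tracks and imaging-guided domain analysis.

This module carries the genomic half of the pipeline: RPKM binning of
mapped reads into fixed 10-kb intervals, moving-average smoothing and
genome-mean normalisation, Spearman correlation against feature tracks,
percentile filtering of a track at the imaging-derived volume fraction,
merging retained bins into contiguous "1D domains", matching the smoothing
window so that the domain count best agrees with the (ploidy-scaled)
nano-focus count, CTCF boundary/occupancy analysis, IUPAC consensus motif
scanning, and the expected DSB-count arithmetic.

Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinnedTrack",
    "bin_rpkm",
    "smooth",
    "normalize_to_genome_mean",
    "correlate_features",
    "percentile_filter",
    "call_domains",
    "linear_coverage",
    "match_smoothing",
    "MatchResult",
    "ctcf_boundary_analysis",
    "scan_motif",
    "expected_dsb_count",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class BinnedTrack:
    """Fixed-width binned signal over one or more chromosomes.

    ``values`` maps chromosome name to a float array, one entry per
    non-overlapping ``bin_size`` bp bin starting at coordinate 0.
    ``state`` records the normalisation history ("raw", "genome-mean
    normalized", "smoothed w=<n>", ...).
    """

    values: dict[str, np.ndarray]
    bin_size: int = 10_000
    assembly: str = ""
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    @property
    def n_bins(self) -> int:
        return sum(v.size for v in self.values.values())

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.chroms]) \
            if self.values else np.empty(0)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack({c: v.copy() for c, v in self.values.items()},
                           self.bin_size, self.assembly, self.state)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                v = self.values[chrom]
                starts = np.arange(v.size) * self.bin_size
                for s, val in zip(starts, v):
                    fh.write(f"{chrom}\t{s}\t{s + self.bin_size}\t{val:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path: str, bin_size: int | None = None) -> "BinnedTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         comment="#")
        if df.empty:
            raise ValueError(f"{path} is empty")
        widths = (df.end - df.start).unique()
        if bin_size is None:
            if widths.size != 1:
                raise ValueError("bedGraph has mixed interval widths; pass bin_size")
            bin_size = int(widths[0])
        values: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            n = int(grp.end.max()) // bin_size
            arr = np.zeros(n)
            arr[grp.start.to_numpy() // bin_size] = grp.value.to_numpy()
            values[chrom] = arr
        return cls(values, bin_size)


def bin_rpkm(
    reads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 10_000,
    assignment: str = "midpoint",
) -> BinnedTrack:
    """RPKM per non-overlapping bin from mapped-read intervals.

    ``reads`` needs columns chrom/start/end. Each read is assigned to the
    bin containing its midpoint (default), so reads are conserved:
    the bin counts sum to the number of reads on known chromosomes.
    RPKM = count / (bin_kb * total_reads / 1e6).
    """
    if assignment != "midpoint":
        raise ValueError("only midpoint assignment is implemented")
    total = len(reads)
    if total == 0:
        raise ValueError("no reads")
    values: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(size / bin_size))) for c, size in chrom_sizes.items()
    }
    mids = (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2
    for chrom, idx in reads.groupby("chrom", sort=False).indices.items():
        if chrom not in values:
            continue
        bins = np.clip(mids[idx] // bin_size, 0, values[chrom].size - 1)
        values[chrom] += np.bincount(bins, minlength=values[chrom].size)
    per_million = total / 1e6
    bin_kb = bin_size / 1000.0
    for chrom in values:
        values[chrom] = values[chrom] / (bin_kb * per_million)
    return BinnedTrack(values, bin_size, state="raw RPKM")


def smooth(track: BinnedTrack, w: int) -> BinnedTrack:
    """Centred moving average of width ``w`` bins (1 = identity).

    Edge bins average over the truncated in-bounds window. ``w`` is limited
    to 1..25, the range scanned when matching imaging and genomic counts.
    """
    if not 1 <= w <= 25:
        raise ValueError("smoothing window must be in 1..25")
    if w == 1:
        return track.copy()
    kernel = np.ones(w)
    values = {}
    for chrom, v in track.values.items():
        num = np.convolve(v, kernel, mode="same")
        den = np.convolve(np.ones_like(v), kernel, mode="same")
        values[chrom] = num / den
    return BinnedTrack(values, track.bin_size, track.assembly,
                       state=f"{track.state}; smoothed w={w}")


def normalize_to_genome_mean(track: BinnedTrack) -> BinnedTrack:
    """Divide every bin by the genome-wide mean (resulting mean is 1)."""
    mean = track.all_values().mean() if track.n_bins else 0.0
    if mean == 0:
        raise ValueError("genome-wide mean is zero; cannot normalize")
    values = {c: v / mean for c, v in track.values.items()}
    return BinnedTrack(values, track.bin_size, track.assembly,
                       state=f"{track.state}; genome-mean normalized")


def correlate_features(
    gamma_track: BinnedTrack,
    feature_tracks: dict[str, BinnedTrack],
    exclude_zero_bins: bool = False,
) -> pd.DataFrame:
    """Genome-wide Spearman rank correlation of each feature with the signal.

    Bins with undefined (NaN) values in either track are excluded pairwise;
    ``exclude_zero_bins`` additionally drops bins where the signal track is
    exactly zero (unmappable-region behaviour). Requires the same binning
    and at least 3 shared bins per feature.
    """
    rows = []
    g_all = gamma_track.all_values()
    for name, feat in feature_tracks.items():
        if feat.bin_size != gamma_track.bin_size:
            raise ValueError(f"feature {name!r} has a different bin size")
        f_all = feat.all_values()
        if f_all.size != g_all.size:
            raise ValueError(f"feature {name!r} has a different bin count")
        keep = ~(np.isnan(g_all) | np.isnan(f_all))
        if exclude_zero_bins:
            keep &= g_all != 0
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 shared bins with feature {name!r}")
        rho, p = stats.spearmanr(g_all[keep], f_all[keep])
        rows.append({"feature": name, "rho": rho, "pvalue": p,
                     "n_bins": int(keep.sum())})
    return pd.DataFrame(rows)


def percentile_filter(
    track: BinnedTrack, volume_fraction_pct: float
) -> tuple[dict[str, np.ndarray], float]:
    """Retain the top ``volume_fraction_pct`` % of bins genome-wide.

    The threshold is the (100 - fraction)-th percentile of the pooled bin
    values (linear interpolation between order statistics); a bin is
    retained when its value is >= the threshold, so a fully tied track
    retains every bin. Returns (per-chromosome boolean masks, threshold).
    """
    if not 0 < volume_fraction_pct < 100:
        raise ValueError("volume fraction must be in (0, 100) percent")
    threshold = float(np.percentile(track.all_values(), 100.0 - volume_fraction_pct))
    masks = {c: v >= threshold for c, v in track.values.items()}
    return masks, threshold


def call_domains(
    mask: dict[str, np.ndarray],
    bin_size: int,
    track: BinnedTrack | None = None,
) -> pd.DataFrame:
    """Merge maximal runs of retained bins into domains (no gap tolerance).

    Returns a BED-like frame with chrom/start/end/n_bins (and mean_signal
    when ``track`` is given); domains are disjoint and sorted per
    chromosome, and their total length equals retained bins x bin size.
    """
    rows = []
    for chrom, m in mask.items():
        m = np.asarray(m, dtype=bool)
        padded = np.diff(np.concatenate(([0], m.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            row = {"chrom": chrom, "start": int(s * bin_size),
                   "end": int(e * bin_size), "n_bins": int(e - s)}
            if track is not None:
                row["mean_signal"] = float(track.values[chrom][s:e].mean())
            rows.append(row)
    columns = ["chrom", "start", "end", "n_bins"]
    if track is not None:
        columns.append("mean_signal")
    return pd.DataFrame(rows, columns=columns)


def linear_coverage(domains: pd.DataFrame) -> int:
    """Total genomic bp covered by the domains."""
    if domains.empty:
        return 0
    return int((domains["end"] - domains["start"]).sum())


@dataclass
class MatchResult:
    """Outcome of the smoothing-window scan."""

    chosen_w: int
    domains: pd.DataFrame
    target: float
    counts: dict[int, int]  # domain count per window width


def match_smoothing(
    track: BinnedTrack,
    volume_fraction_pct: float,
    n_nanofoci: float,
    ploidy_factor: float = 3.12,
    w_range: range = range(1, 26),
) -> MatchResult:
    """Choose the smoothing window matching domain count to nano-focus count.

    The 3D nano-focus count is scaled to the haploid genome by dividing by
    ``ploidy_factor``; for every window width the track is smoothed,
    percentile-filtered at the imaging volume fraction and segmented into
    domains, and the width whose domain count is closest to the target is
    returned (ties resolved toward the smaller width).
    """
    if n_nanofoci <= 0:
        raise ValueError("n_nanofoci must be positive")
    target = n_nanofoci / ploidy_factor
    counts: dict[int, int] = {}
    best_w, best_domains, best_err = None, None, np.inf
    for w in w_range:
        mask, _ = percentile_filter(smooth(track, w), volume_fraction_pct)
        domains = call_domains(mask, track.bin_size)
        counts[w] = len(domains)
        err = abs(len(domains) - target)
        if err < best_err:
            best_w, best_domains, best_err = w, domains, err
    assert best_w is not None
    return MatchResult(chosen_w=best_w, domains=best_domains,
                       target=target, counts=counts)


def ctcf_boundary_analysis(
    domains: pd.DataFrame,
    peaks: pd.DataFrame,
    bin: int = 100_000,
    span: int = 300_000,
    max_score_only: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Distance from every domain boundary to the nearest peak, plus an
    occupancy profile of summed peak scores around the boundaries.

    Peaks are represented by their midpoints. The profile axis is signed:
    negative offsets lie outside the domain, positive inside, with 0 at the
    boundary; scores are summed in ``bin``-wide windows from ``-span`` up
    to ``+bin`` (default -300..-200, -200..-100, -100..0, 0..+100 kb).
    With ``max_score_only`` the peak set is first restricted to peaks whose
    score equals the set's maximum (capped occupancy scores). Boundaries on
    chromosomes without peaks get NaN distances.
    """
    peaks = peaks.copy()
    if max_score_only and not peaks.empty:
        peaks = peaks[peaks["score"] == peaks["score"].max()]
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy() if not peaks.empty \
        else np.empty(0, dtype=int)
    peak_chrom = peaks["chrom"].to_numpy() if not peaks.empty else np.empty(0, object)
    scores = peaks["score"].to_numpy() if not peaks.empty else np.empty(0)

    edges = np.arange(-span, bin + 1, bin)
    labels = [f"{edges[i] // 1000}..{edges[i + 1] // 1000}kb"
              for i in range(len(edges) - 1)]
    profile = pd.Series(0.0, index=labels)

    rows = []
    for _, dom in domains.iterrows():
        on_chrom = peak_chrom == dom["chrom"]
        chrom_mids = mids[on_chrom]
        chrom_scores = scores[on_chrom]
        for side, boundary in (("start", dom["start"]), ("end", dom["end"])):
            if chrom_mids.size == 0:
                rows.append({"chrom": dom["chrom"], "boundary": side,
                             "position": int(boundary), "distance_bp": np.nan})
                continue
            dist = np.abs(chrom_mids - boundary)
            rows.append({"chrom": dom["chrom"], "boundary": side,
                         "position": int(boundary),
                         "distance_bp": int(dist.min())})
            # signed offset: negative outside the domain, positive inside
            if side == "start":
                rel = chrom_mids - boundary
            else:
                rel = boundary - chrom_mids
            which = np.digitize(rel, edges) - 1
            ok = (which >= 0) & (which < len(labels))
            for b, sc in zip(which[ok], chrom_scores[ok]):
                profile.iloc[b] += sc
    return pd.DataFrame(rows), profile


def _iupac_regex(consensus: str) -> str:
    try:
        return "".join(IUPAC[c] for c in consensus.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def scan_motif(
    genome: dict[str, str],
    iupac_consensus: str,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, np.ndarray]]:
    """Scan both strands for an IUPAC consensus motif.

    ``genome`` maps sequence names to strings (a ``pyfaidx.Fasta`` also
    works). Matches on the reverse strand are located by scanning for the
    reverse complement of the consensus; coordinates always refer to the
    forward strand, 0-based half-open. Overlapping same-strand matches are
    merged into one site (the merged interval keeps the first match string).

    Returns ``(sites, distances, distances_by_strand)`` where distances are
    gaps in bp between successive sites along each chromosome (site end to
    next site start, both strands pooled) and the stratified version keeps
    forward-only and reverse-only gaps.
    """
    fwd_re = re.compile(f"(?=({_iupac_regex(iupac_consensus)}))")
    rc = reverse_complement(iupac_consensus)
    rev_re = re.compile(f"(?=({_iupac_regex(rc)}))")
    m = len(iupac_consensus)
    palindromic = rc.upper() == iupac_consensus.upper()

    rows = []
    for chrom in genome.keys():
        seq = str(genome[chrom]).upper()
        for strand, pattern in (("+", fwd_re), ("-", rev_re)):
            if strand == "-" and palindromic:
                continue  # identical interval set; report forward only
            hits = [(mt.start(), mt.start() + m, mt.group(1))
                    for mt in pattern.finditer(seq)]
            # merge overlapping same-strand matches
            merged: list[list] = []
            for s, e, match in hits:
                if merged and s < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e, match])
            for s, e, match in merged:
                rows.append({"chrom": chrom, "start": s, "end": e,
                             "strand": strand, "match": match})
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "match"])
    sites = sites.sort_values(["chrom", "start"], ignore_index=True)

    def _gaps(df: pd.DataFrame) -> np.ndarray:
        out = []
        for _, grp in df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if len(grp) > 1:
                out.append(np.maximum(s[1:] - e[:-1], 0))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    distances = _gaps(sites)
    by_strand = {st: _gaps(sites[sites["strand"] == st]) for st in ("+", "-")}
    return sites, distances, by_strand


def expected_dsb_count(
    yield_low: float = 30.0,
    yield_high: float = 55.0,
    dose_gy: float = 10.0,
    ploidy_factor: float = 3.12,
) -> tuple[int, int]:
    """Expected DSB count range for a dose, scaled to the ploidy-adjusted genome.

    The literature yield is expressed per Gy per *diploid* genome, so the
    ploidy scaling is ``ploidy_factor / 2``; each bound is rounded to the
    nearest 10 DSBs.
    """
    if min(yield_low, yield_high, dose_gy, ploidy_factor) <= 0:
        raise ValueError("all inputs must be positive")

    def _one(y: float) -> int:
        return int(round(y * dose_gy * (ploidy_factor / 2.0) / 10.0) * 10)

    return _one(yield_low), _one(yield_high)
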