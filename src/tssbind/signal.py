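"""TSS-anchored signal matrices, tag-density profiles, and positional K-means.

Rows of a signal matrix are anchored at a TSS and read upstream to
downstream regardless of strand, so position +240 always means 240 bp
into the transcribed region. Clustering is shape-based: rows are
max-normalized first, and clusters are renumbered so "cluster 1" is the
strongest by mean raw signal, matching the usual naming of TF ChIP peak
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans

from .simulate import BinnedTrack

__all__ = [
    "track_from_bedgraph",
    "SignalMatrix",
    "DensityProfile",
    "ClusterAssignment",
    "build_signal_matrix",
    "tag_density_profile",
    "summit_histogram",
    "kmeans_positional",
    "subcluster",
    "classify_subclusters",
    "peak_width_stats",
    "sample_correlation",
    "compare_group_signal",
]


@dataclass
class SignalMatrix:
    row_ids: list
    window: int
    binsize: int
    values: np.ndarray  # rows x bins, upstream -> downstream
    normalization: str = "raw"
    dropped: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(-self.window + self.binsize / 2, self.window, self.binsize)


@dataclass
class DensityProfile:
    bin_centers: np.ndarray
    values: np.ndarray
    primary_mode: float | None  # bin center of the argmax (smoothed)
    shoulder: float | None  # opposite-side secondary local max
    primary_mode_refined: float | None = None  # sub-bin parabolic estimate
    flagged: str = ""


@dataclass
class ClusterAssignment:
    row_ids: list
    labels: np.ndarray  # 1-based, 1 = strongest cluster
    sizes: dict
    centroids: np.ndarray  # label order: centroids[0] is cluster 1
    inertia: float
    seed: int
    dropped: int = 0
    notes: str = ""


def track_from_bedgraph(records, binsize: int = 20,
                        chrom_sizes: dict[str, int] | None = None) -> BinnedTrack:
    """Rebin (chrom, start, end, value) records onto a fixed-width track.

    Each record's value is assigned to the bins it covers (length-weighted
    mean within a bin). Chromosome sizes default to the largest end seen.
    """
    if chrom_sizes is None:
        chrom_sizes = {}
        for chrom, _, end, _ in records:
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    track = BinnedTrack(chrom_sizes, binsize)
    weight = {c: np.zeros_like(v) for c, v in track.values.items()}
    for chrom, start, end, value in records:
        vals = track.values.get(chrom)
        if vals is None:
            continue
        lo, hi = start // binsize, -(-end // binsize)
        for b in range(lo, min(hi, len(vals))):
            cov = min(end, (b + 1) * binsize) - max(start, b * binsize)
            vals[b] += value * cov
            weight[chrom][b] += cov
    for chrom, vals in track.values.items():
        w = weight[chrom]
        np.divide(vals, w, out=vals, where=w > 0)
    return track


def _anchor_triple(a):
    """(chrom, tss, strand) from a TranscriptModel or TssAnnotation."""
    if hasattr(a, "tss_pos"):  # TssAnnotation
        return a.peak.interval.chrom, a.tss_pos, a.tss_strand
    return a.chrom, a.tss, a.strand


def build_signal_matrix(track: BinnedTrack, anchors, window: int = 3000,
                        binsize: int = 20) -> SignalMatrix:
    """One row per anchor: coverage in strand-oriented bins around its TSS.

    ``binsize`` must divide 2*window and be a multiple of the track's bin
    width (each matrix bin averages whole track bins). Bins beyond the
    chromosome end are zero; anchors on chromosomes absent from the track
    are dropped and counted.
    """
    if (2 * window) % binsize != 0:
        raise ValueError("binsize must divide 2*window")
    if binsize % track.binsize != 0:
        raise ValueError("matrix binsize must be a multiple of the track binsize")
    per = binsize // track.binsize
    nbins = 2 * window // binsize
    tb = track.binsize
    nfine = nbins * per
    k = np.arange(nfine)
    rows, ids = [], []
    dropped = 0
    for a in anchors:
        chrom, tss, strand = _anchor_triple(a)
        vals = track.values.get(chrom)
        if vals is None:
            dropped += 1
            continue
        # fine bin k holds the track bin whose left edge sits at signed
        # distance -window + k*tb from the TSS, mapped through strand
        if strand == "-":
            idx = (tss + window - k * tb) // tb
        else:
            idx = (tss - window + k * tb) // tb
        fine = np.zeros(nfine)
        ok = (idx >= 0) & (idx < len(vals))
        fine[ok] = vals[idx[ok]]
        row = fine.reshape(nbins, per).mean(axis=1)
        rows.append(row)
        ids.append(getattr(a, "transcript_id", None)
                   or getattr(getattr(a, "peak", None), "sample_id", None)
                   or f"row_{len(ids)}")
    values = np.vstack(rows) if rows else np.zeros((0, nbins))
    return SignalMatrix(ids, window, binsize, values, "raw", dropped)


def _find_modes(centers, values, smooth_sigma_bins: float, ma_bins: int = 5):
    """Primary mode (argmax of the smoothed curve; ties toward positive
    offsets) plus a sub-bin parabolic refinement, and the largest local
    maximum on the opposite side of the anchor (moving-average smoothed)."""
    sm = gaussian_filter1d(values.astype(float), smooth_sigma_bins)
    best = np.flatnonzero(sm == sm.max())
    i = int(best[np.argmax(centers[best])])  # tie -> positive offset
    mode = float(centers[i])
    refined = mode
    if 0 < i < len(sm) - 1:
        denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
        if denom < 0:
            refined = mode + 0.5 * (sm[i - 1] - sm[i + 1]) / denom * (
                centers[1] - centers[0]
            )
    kernel = np.ones(ma_bins) / ma_bins
    ma = np.convolve(values.astype(float), kernel, mode="same")
    opposite = centers < 0 if mode >= 0 else centers > 0
    local = np.zeros(len(ma), bool)
    local[1:-1] = (ma[1:-1] >= ma[:-2]) & (ma[1:-1] >= ma[2:])
    cand = np.flatnonzero(local & opposite)
    shoulder = None
    if cand.size:
        top = cand[ma[cand] == ma[cand].max()]
        shoulder = float(centers[top[np.argmax(centers[top])]])
    return mode, refined, shoulder


def tag_density_profile(matrix: SignalMatrix,
                        smooth_sigma_bins: float = 3.0) -> DensityProfile:
    """Column means of a signal matrix with detected primary/shoulder modes."""
    if matrix.values.shape[0] < 1:
        raise ValueError("need >= 1 row")
    mean = matrix.values.mean(axis=0)
    centers = matrix.bin_centers
    if not mean.any():
        return DensityProfile(centers, mean, None, None, None, "all-zero matrix")
    mode, refined, shoulder = _find_modes(centers, mean, smooth_sigma_bins)
    return DensityProfile(centers, mean, mode, shoulder, refined)


def summit_histogram(distances, window: int = 3000, binsize: int = 20,
                     smooth_sigma_bins: float = 3.0) -> DensityProfile:
    """Summit-frequency profile from signed TSS distances (annotations or ints)."""
    d = np.asarray([getattr(x, "distance", x) for x in distances], float)
    edges = np.arange(-window, window + binsize, binsize)
    counts, _ = np.histogram(d, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if not counts.any():
        return DensityProfile(centers, counts, None, None, None, "empty histogram")
    mode, refined, shoulder = _find_modes(centers, counts, smooth_sigma_bins)
    return DensityProfile(centers, counts.astype(float), mode, shoulder, refined)


def _max_normalize(values: np.ndarray):
    mx = values.max(axis=1)
    keep = mx > 0
    return values[keep] / mx[keep, None], keep


def kmeans_positional(matrix: SignalMatrix, k: int, seed: int = 0,
                      n_init: int = 10) -> ClusterAssignment:
    """Shape-based K-means on max-normalized rows.

    All-zero rows are dropped (counted in ``dropped``). Labels are 1..k
    renumbered by descending mean total raw signal of the member rows, so
    cluster 1 holds the strongest peaks.
    """
    norm, keep = _max_normalize(matrix.values)
    if norm.shape[0] < k:
        raise ValueError(f"need >= {k} non-empty rows, have {norm.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(norm)
    raw_totals = matrix.values[keep].sum(axis=1)
    order = np.argsort(
        [-raw_totals[km.labels_ == c].mean() if (km.labels_ == c).any() else np.inf
         for c in range(k)]
    )
    relabel = np.empty(k, int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    n_eff = len(np.unique(km.labels_))
    notes = "" if n_eff == k else f"degenerate: {n_eff} effective centroids"
    ids = [r for r, kp in zip(matrix.row_ids, keep) if kp]
    centroids = km.cluster_centers_[order]
    sizes = {int(c): int((labels == c).sum()) for c in range(1, k + 1)}
    return ClusterAssignment(ids, labels, sizes, centroids,
                             float(km.inertia_), seed,
                             int((~keep).sum()), notes)


def classify_subclusters(centroids: np.ndarray, centers: np.ndarray,
                         far_cutoff: float = 1000.0,
                         weak_fraction: float = 0.25) -> list[str]:
    """Name sub-centroids: upstream-far / downstream-far / over-TSS / weak.

    A centroid is 'weak' when its max is below ``weak_fraction`` of the
    global centroid max; otherwise it is placed by its mode location.
    """
    global_max = centroids.max()
    names = []
    for c in centroids:
        mode = centers[int(np.argmax(c))]
        if c.max() < weak_fraction * global_max:
            names.append("weak")
        elif mode > far_cutoff:
            names.append("downstream_far")
        elif mode < -far_cutoff:
            names.append("upstream_far")
        else:
            names.append("over_tss")
    return names


_SUBORDER = {"upstream_far": 0, "downstream_far": 1, "over_tss": 2, "weak": 3}


def subcluster(matrix: SignalMatrix, assignment: ClusterAssignment,
               target_cluster, k: int = 4, seed: int = 0) -> ClusterAssignment:
    """Re-cluster one cluster's rows (or the union of several, when
    ``target_cluster`` is a collection); sublabels '<c>.1'..'<c>.4'
    ordered upstream-far, downstream-far, over-TSS, weak/no-pattern."""
    targets = ({target_cluster} if isinstance(target_cluster, (int, np.integer))
               else set(target_cluster))
    member = {rid for rid, lab in zip(assignment.row_ids, assignment.labels)
              if lab in targets}
    tag = "+".join(str(t) for t in sorted(targets))
    if not member:
        raise ValueError(f"cluster {tag} is empty")
    sel = np.array([rid in member for rid in matrix.row_ids])
    sub = SignalMatrix(
        [r for r in matrix.row_ids if r in member],
        matrix.window, matrix.binsize, matrix.values[sel], matrix.normalization,
    )
    if sub.values.shape[0] < k:
        raise ValueError("target cluster smaller than k")
    inner = kmeans_positional(sub, k, seed)
    names = classify_subclusters(inner.centroids, sub.bin_centers)
    # stable semantic order; ties within a semantic class by amplitude
    order = sorted(range(k),
                   key=lambda c: (_SUBORDER[names[c]], -inner.centroids[c].max()))
    relabel = {old + 1: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[l] for l in inner.labels])
    sizes = {c: int((labels == c).sum()) for c in range(1, k + 1)}
    note = ";".join(f"{tag}.{new + 1}={names[old]}"
                    for new, old in enumerate(order))
    return ClusterAssignment(inner.row_ids, labels, sizes,
                             inner.centroids[order], inner.inertia, seed,
                             inner.dropped, note)


def peak_width_stats(peaks):
    """(mean, median, n) of called peak widths."""
    widths = np.array([p.width for p in peaks], float)
    if widths.size == 0:
        raise ValueError("empty peak set")
    return float(widths.mean()), float(np.median(widths)), int(widths.size)


def sample_correlation(tracks: dict[str, BinnedTrack], bin: int = 10_000):
    """Pearson correlation of log(1 + signal) over genome-wide fixed bins.

    Returns (names, matrix). Zero-variance tracks give NaN rows/columns.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need >= 2 tracks")
    chroms = None
    for t in tracks.values():
        cset = set(t.values)
        chroms = cset if chroms is None else chroms & cset
    cols = []
    for name in names:
        t = tracks[name]
        if bin % t.binsize != 0:
            raise ValueError("bin must be a multiple of the track binsize")
        per = bin // t.binsize
        parts = []
        for c in sorted(chroms):
            v = t.values[c]
            n = len(v) // per * per
            parts.append(v[:n].reshape(-1, per).mean(axis=1))
        cols.append(np.log1p(np.concatenate(parts)))
    X = np.vstack(cols)
    sd = X.std(axis=1)
    flat = sd <= 1e-10 * np.maximum(1.0, np.abs(X).max(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, 1.0)
    return names, corr


def compare_group_signal(matrix: SignalMatrix, group_a, group_b):
    """Per-group mean profiles and the ratio of overall mean signal (a/b)."""
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    idx = {rid: i for i, rid in enumerate(matrix.row_ids)}
    ia = [idx[r] for r in group_a if r in idx]
    ib = [idx[r] for r in group_b if r in idx]
    if not ia or not ib:
        raise ValueError("groups not found in matrix rows")
    prof_a = matrix.values[ia].mean(axis=0)
    prof_b = matrix.values[ib].mean(axis=0)
    mean_b = prof_b.mean()
    ratio = float("inf") if mean_b == 0 else float(prof_a.mean() / mean_b)
    return {"profile_a": prof_a, "profile_b": prof_b, "ratio": ratio,
            "flagged": "group_b all zero" if mean_b == 0 else ""}
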