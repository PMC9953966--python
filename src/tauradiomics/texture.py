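"""Lloyd-Max quantization and the 43-feature texture bank.

Per ROI, voxel intensities are discretized to ``Ng`` gray levels with the
Lloyd-Max algorithm (the MSE-optimal scalar quantizer: centroids are
conditional means, decision boundaries are centroid midpoints), and five
feature families are computed on the quantized levels:

========  ==  =======================================================
family     n  features
========  ==  =======================================================
global     3  variance, skewness, kurtosis of the level histogram
GLCM       9  energy, contrast, entropy, homogeneity, correlation,
              sum_average, variance, dissimilarity, autocorrelation
GLRLM     13  SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE,
              LRLGE, LRHGE, GLV, RLV
GLSZM     13  SZE, LZE, GLN, ZSN, ZP, LGZE, HGZE, SZLGE, SZHGE,
              LZLGE, LZHGE, GLV, ZSV
NGTDM      5  coarseness, busyness, contrast, complexity, strength
========  ==  =======================================================

3 + 9 + 13 + 13 + 5 = 43 features per ROI.

Conventions (documented because published definitions vary):

* GLCM: co-occurrences at Chebyshev distance 1 over the 13 unique 3D
  directions, merged into a single symmetric Ng x Ng matrix; a pair counts
  only when both voxels are inside the ROI; entropy uses log2 with
  0*log(0) := 0.
* GLRLM: maximal constant-level runs along each of the same 13 directions,
  merged into one matrix; runs are truncated at the ROI boundary. Run
  percentage is runs / voxel incidences (= Nvox per direction).
* GLSZM: zones are 26-connected components of equal level inside the ROI
  (direction-free by construction).
* NGTDM: 26-neighborhood; a voxel contributes when it has at least one
  in-ROI neighbor; coarseness carries a 1e-6 guard on its denominator.
* Degenerate inputs (single gray level, single voxel) map to fixed
  constants rather than NaN, and the quantizer flags them.

Because quantization is performed within each ROI and depends on the
intensity ranks only through bin occupancy, all 43 features are invariant
to translating the ROI in the grid and to global affine intensity
rescaling of the input volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .image import Volume
from .roi import ROISet

__all__ = [
    "QuantizedROI",
    "lloyd_max_quantize",
    "quantize_roi",
    "histogram_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "roi_feature_vector",
    "extract_features",
    "FEATURE_NAMES",
    "N_FEATURES",
    "DIRECTIONS_13",
]

EPS_COARSENESS = 1e-6

GLOBAL_NAMES = ["global_variance", "global_skewness", "global_kurtosis"]
GLCM_NAMES = ["glcm_energy", "glcm_contrast", "glcm_entropy", "glcm_homogeneity",
              "glcm_correlation", "glcm_sum_average", "glcm_variance",
              "glcm_dissimilarity", "glcm_autocorrelation"]
GLRLM_NAMES = ["glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
               "glrlm_lgre", "glrlm_hgre", "glrlm_srlge", "glrlm_srhge",
               "glrlm_lrlge", "glrlm_lrhge", "glrlm_glv", "glrlm_rlv"]
GLSZM_NAMES = ["glszm_sze", "glszm_lze", "glszm_gln", "glszm_zsn", "glszm_zp",
               "glszm_lgze", "glszm_hgze", "glszm_szlge", "glszm_szhge",
               "glszm_lzlge", "glszm_lzhge", "glszm_glv", "glszm_zsv"]
NGTDM_NAMES = ["ngtdm_coarseness", "ngtdm_busyness", "ngtdm_contrast",
               "ngtdm_complexity", "ngtdm_strength"]

FEATURE_NAMES: List[str] = (GLOBAL_NAMES + GLCM_NAMES + GLRLM_NAMES
                            + GLSZM_NAMES + NGTDM_NAMES)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 43

# 13 unique 3D directions: one representative per +-d pair of the 26-neighborhood
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


# ---------------------------------------------------------------------------
# Lloyd-Max quantization
# ---------------------------------------------------------------------------

@dataclass
class QuantizedROI:
    """An ROI's voxels mapped to integer gray levels 1..Ng.

    ``grid`` embeds the levels in the ROI bounding box with 0 outside the
    ROI; ``levels`` is the flat per-voxel level array in ROI voxel order.
    """

    grid: np.ndarray  # 3D int array, 0 = outside ROI
    levels: np.ndarray  # 1D levels of ROI voxels
    ng: int
    boundaries: np.ndarray  # Ng-1 interior decision boundaries
    centroids: np.ndarray  # Ng reconstruction levels
    degenerate: bool = False

    @property
    def n_voxels(self) -> int:
        return self.levels.size


def lloyd_max_quantize(values: np.ndarray, ng: int = 64, tol: float = 1e-6,
                       max_iter: int = 500):
    """Lloyd-Max scalar quantization of ``values`` into ``ng`` levels.

    Initialization from equal-probability quantiles; iteration alternates
    centroid updates (bin conditional means) and boundary updates (centroid
    midpoints) until the relative change of the quantization MSE is below
    ``tol`` or ``max_iter`` is reached. Empty bins keep their boundary
    midpoint as centroid so the level order stays strict.

    Returns ``(assignments, boundaries, centroids, degenerate)`` with
    assignments in 1..ng. Constant input yields the degenerate single-level
    result with the flag set.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot quantize an empty ROI")
    if ng < 2:
        raise ValueError("ng must be >= 2")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return (np.ones(x.size, dtype=np.int32), np.array([]),
                np.array([lo]), True)
    xs = np.sort(x)
    n = xs.size
    # prefix sums make each iteration O(ng log n) instead of O(n)
    cs1 = np.concatenate([[0.0], np.cumsum(xs)])
    cs2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
    # init: centroids at equal-probability quantiles, boundaries at their
    # midpoints (for Ng equal point masses this is already the fixed point)
    cent0 = np.quantile(xs, (np.arange(ng) + 0.5) / ng)
    bounds = 0.5 * (cent0[:-1] + cent0[1:])
    prev_mse = np.inf
    centroids = None
    for _ in range(max_iter):
        # bin k holds xs[pos[k] : pos[k+1]]  (matches np.digitize(x, bounds))
        pos = np.concatenate([[0], np.searchsorted(xs, bounds, side="left"), [n]])
        counts = np.diff(pos).astype(np.float64)
        sums = cs1[pos[1:]] - cs1[pos[:-1]]
        sqs = cs2[pos[1:]] - cs2[pos[:-1]]
        edges = np.concatenate([[lo], bounds, [hi]])
        mids = 0.5 * (edges[:-1] + edges[1:])
        with np.errstate(invalid="ignore"):
            centroids = np.where(counts > 0, sums / np.maximum(counts, 1.0), mids)
        mse = max(0.0, float((sqs.sum() - 2.0 * (centroids * sums).sum()
                              + (centroids ** 2 * counts).sum()) / n))
        if prev_mse < np.inf and prev_mse > 0:
            if abs(prev_mse - mse) / prev_mse < tol:
                break
        elif mse <= 0.0:
            break
        prev_mse = mse
        bounds = 0.5 * (centroids[:-1] + centroids[1:])
    idx = np.digitize(x, bounds)
    return idx.astype(np.int32) + 1, bounds, centroids, False


def quantize_roi(vol: Volume, mask: np.ndarray, ng: int = 64) -> QuantizedROI:
    """Quantize the in-mask voxels of ``vol`` and embed them in the ROI
    bounding box (0 outside)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask geometry does not match volume")
    if not mask.any():
        raise ValueError("empty ROI mask")
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    sub_mask = mask[sl]
    vals = vol.data[mask]
    levels, bounds, cents, degen = lloyd_max_quantize(vals, ng=ng)
    grid = np.zeros(sub_mask.shape, dtype=np.int32)
    grid[sub_mask] = levels[_roi_order(mask, sl)]
    return QuantizedROI(grid, levels, ng, bounds, cents, degen)


def _roi_order(mask: np.ndarray, sl) -> np.ndarray:
    """Permutation aligning vol.data[mask] order with sub-grid fill order.

    Both use C order over the same voxels, so this is the identity; kept as
    a function to make the contract explicit."""
    return slice(None)


# ---------------------------------------------------------------------------
# Global (histogram) features
# ---------------------------------------------------------------------------

def histogram_features(q: QuantizedROI) -> Dict[str, float]:
    """Variance, skewness and kurtosis of the quantized gray levels.

    Biased (population) moment estimators; kurtosis is non-excess
    (a symmetric two-point distribution has kurtosis 1). A single-level ROI
    maps skewness and kurtosis to 0.
    """
    x = q.levels.astype(np.float64)
    mu = x.mean()
    var = float(((x - mu) ** 2).mean())
    if var == 0:
        return {"global_variance": 0.0, "global_skewness": 0.0,
                "global_kurtosis": 0.0}
    sd = np.sqrt(var)
    skew = float(((x - mu) ** 3).mean() / sd ** 3)
    kurt = float(((x - mu) ** 4).mean() / var ** 2)
    return {"global_variance": var, "global_skewness": skew,
            "global_kurtosis": kurt}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_pairs(grid: np.ndarray, d: Tuple[int, int, int]):
    """Paired views (a, b) of grid voxels separated by offset d."""
    sl_src, sl_dst = [], []
    for n, step in zip(grid.shape, d):
        if step > 0:
            sl_src.append(slice(0, n - step))
            sl_dst.append(slice(step, n))
        elif step < 0:
            sl_src.append(slice(-step, n))
            sl_dst.append(slice(0, n + step))
        else:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
    return grid[tuple(sl_src)], grid[tuple(sl_dst)]


def glcm_matrix(q: QuantizedROI,
                directions: Sequence[Tuple[int, int, int]] = DIRECTIONS_13
                ) -> np.ndarray:
    """Symmetric Ng x Ng co-occurrence counts merged over ``directions``.

    Each unordered in-ROI pair at offset d contributes to (i, j) and (j, i).
    """
    ng = q.ng
    mat = np.zeros((ng, ng), dtype=np.float64)
    for d in directions:
        a, b = _shifted_pairs(q.grid, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ai, bi = a[valid] - 1, b[valid] - 1
        counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
        mat += counts
        mat += counts.T
    return mat


def glcm_features(mat: np.ndarray) -> Dict[str, float]:
    """The 9 co-occurrence features from a (possibly unnormalized) GLCM."""
    total = mat.sum()
    out = dict.fromkeys(GLCM_NAMES, 0.0)
    if total == 0:  # single-voxel ROI: no pairs
        out["glcm_energy"] = 1.0
        return out
    p = mat / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # row marginal (= column marginal by symmetry)
    mu = float((i * pi).sum())
    sigma2 = float(((i - mu) ** 2 * pi).sum())
    sigma = np.sqrt(sigma2)
    nz = p > 0
    out["glcm_energy"] = float((p ** 2).sum())
    out["glcm_contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["glcm_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["glcm_homogeneity"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    if sigma > 0:
        out["glcm_correlation"] = float(
            (((ii - mu) * (jj - mu) * p).sum()) / (sigma * sigma))
    out["glcm_sum_average"] = float(((ii + jj) * p).sum() / 2.0)
    out["glcm_variance"] = sigma2
    out["glcm_dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["glcm_autocorrelation"] = float((ii * jj * p).sum())
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(q: QuantizedROI,
                 directions: Sequence[Tuple[int, int, int]] = DIRECTIONS_13
                 ) -> np.ndarray:
    """Ng x Rmax counts of maximal constant-level runs merged over directions.

    A run is a maximal sequence of in-ROI voxels of equal level along a
    direction; runs are truncated at the ROI boundary. Implemented by
    propagating run membership: a voxel starts a run if its predecessor
    along d is outside the ROI or has a different level; run length is then
    accumulated by shifting until no run extends further.
    """
    grid = q.grid
    ng = q.ng
    per_dir: List[np.ndarray] = []
    max_len = 1
    base = np.where(grid > 0, 1, 0).astype(np.int32)
    for d in directions:
        sl_src, sl_dst = _views_slices(grid.shape, d)
        # a voxel starts a run iff its predecessor along d is not an
        # equal-level ROI voxel
        prev_view = np.zeros_like(grid)
        prev_view[sl_dst] = grid[sl_src]
        start = (grid > 0) & (prev_view != grid)
        # same[v]: the successor v+d continues the run
        same = np.zeros(grid.shape, dtype=bool)
        same[sl_src] = (grid[sl_dst] == grid[sl_src]) & (grid[sl_src] > 0)
        # fixpoint of l(v) = 1 + l(v+d) on continuing voxels, else 1;
        # converges in max-run-length iterations
        l = base.copy()
        nxt = np.zeros_like(grid)
        while True:
            nxt[:] = 0
            nxt[sl_src] = l[sl_dst]
            new_l = np.where(same, 1 + nxt, base)
            if np.array_equal(new_l, l):
                break
            l = new_l
        run_lengths = l[start]
        lev = grid[start]
        if run_lengths.size:
            max_len = max(max_len, int(run_lengths.max()))
        per_dir.append(np.stack([lev, run_lengths]))
    mat = np.zeros((ng, max_len), dtype=np.float64)
    for lev_len in per_dir:
        if lev_len.size == 0:
            continue
        lev, lens = lev_len
        np.add.at(mat, (lev - 1, lens - 1), 1.0)
    return mat


def _views_slices(shape, d):
    sl_src, sl_dst = [], []
    for n, step in zip(shape, d):
        if step > 0:
            sl_src.append(slice(0, n - step))
            sl_dst.append(slice(step, n))
        elif step < 0:
            sl_src.append(slice(-step, n))
            sl_dst.append(slice(0, n + step))
        else:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
    return tuple(sl_src), tuple(sl_dst)


def _rlm_style_features(mat: np.ndarray, names: List[str], n_incidences: float
                        ) -> Dict[str, float]:
    """Shared formula set for run-length and size-zone matrices.

    ``mat[i-1, j-1]`` counts runs (zones) of gray level i and length (size)
    j; ``n_incidences`` is the denominator of the percentage feature
    (voxel incidences for GLRLM, ROI voxel count for GLSZM).
    """
    out = dict.fromkeys(names, 0.0)
    nr = mat.sum()
    if nr == 0:
        return out
    ng, rmax = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, rmax + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / nr
    ri = mat.sum(axis=1)  # per-level counts
    rj = mat.sum(axis=0)  # per-length counts
    short, long_, gln, rln, rp, lg, hg, slg, shg, llg, lhg, glv, rlv = names
    out[short] = float((mat / jj ** 2).sum() / nr)
    out[long_] = float((mat * jj ** 2).sum() / nr)
    out[gln] = float((ri ** 2).sum() / nr)
    out[rln] = float((rj ** 2).sum() / nr)
    out[rp] = float(nr / n_incidences)
    out[lg] = float((mat / ii ** 2).sum() / nr)
    out[hg] = float((mat * ii ** 2).sum() / nr)
    out[slg] = float((mat / (ii ** 2 * jj ** 2)).sum() / nr)
    out[shg] = float((mat * ii ** 2 / jj ** 2).sum() / nr)
    out[llg] = float((mat * jj ** 2 / ii ** 2).sum() / nr)
    out[lhg] = float((mat * ii ** 2 * jj ** 2).sum() / nr)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    out[glv] = float((((ii - mu_i) ** 2) * p).sum())
    out[rlv] = float((((jj - mu_j) ** 2) * p).sum())
    return out


def glrlm_features(mat: np.ndarray, n_voxels: int,
                   n_directions: int = len(DIRECTIONS_13)) -> Dict[str, float]:
    """13 run-length features; run percentage = runs / (voxels x directions)."""
    return _rlm_style_features(mat, GLRLM_NAMES, float(n_voxels * n_directions))


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Ng x Zmax counts of 26-connected equal-level zones.

    Zones of different levels can never merge, so all zones are found in a
    single connected-components pass over the equal-level 26-neighbor graph.
    """
    grid = q.grid
    ng = q.ng
    idx = np.arange(grid.size).reshape(grid.shape)
    rows, cols = [], []
    for d in DIRECTIONS_13:
        sl_src, sl_dst = _views_slices(grid.shape, d)
        a, b = grid[sl_src], grid[sl_dst]
        eq = (a > 0) & (a == b)
        if eq.any():
            rows.append(idx[sl_src][eq])
            cols.append(idx[sl_dst][eq])
    inroi = grid.ravel() > 0
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        g = csr_matrix((np.ones(r.size, dtype=np.int8), (r, c)),
                       shape=(grid.size, grid.size))
        _, comp = connected_components(g, directed=False)
    else:
        comp = np.arange(grid.size)
    comp = comp[inroi]
    levels = grid.ravel()[inroi]
    # zone sizes and levels via one pass over component ids
    uniq, inv, sizes = np.unique(comp, return_inverse=True, return_counts=True)
    zone_level = np.zeros(uniq.size, dtype=np.int64)
    zone_level[inv] = levels  # all members share the level
    max_size = int(sizes.max()) if sizes.size else 1
    mat = np.zeros((ng, max_size), dtype=np.float64)
    np.add.at(mat, (zone_level - 1, sizes - 1), 1.0)
    return mat


def glszm_features(mat: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """13 size-zone features; zone percentage = zones / ROI voxel count."""
    return _rlm_style_features(mat, GLSZM_NAMES, float(n_voxels))


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(q: QuantizedROI):
    """Per-level neighborhood gray-tone difference table.

    For every ROI voxel with at least one in-ROI neighbor in its
    26-neighborhood: accumulate |level - mean(neighbor levels)| into s_i for
    its level i and count it in n_i. Returns (n, s) of length Ng.
    """
    grid = q.grid.astype(np.float64)
    inroi = q.grid > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.convolve(grid, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(inroi.astype(np.float64), kernel,
                            mode="constant", cval=0.0)
    has_nb = inroi & (ncnt > 0.5)
    n = np.zeros(q.ng, dtype=np.float64)
    s = np.zeros(q.ng, dtype=np.float64)
    if has_nb.any():
        lev = q.grid[has_nb]
        diff = np.abs(grid[has_nb] - nsum[has_nb] / ncnt[has_nb])
        np.add.at(n, lev - 1, 1.0)
        np.add.at(s, lev - 1, diff)
    return n, s


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> Dict[str, float]:
    """Coarseness, busyness, contrast, complexity and strength.

    Formulas follow the neighborhood gray-tone difference construction of
    Amadasun & King; the coarseness (and strength) denominator carries a
    1e-6 guard because it vanishes on constant ROIs.
    """
    out = dict.fromkeys(NGTDM_NAMES, 0.0)
    N = n.sum()
    if N == 0:
        out["ngtdm_coarseness"] = 1.0 / EPS_COARSENESS
        return out
    p = n / N
    act = p > 0
    i = np.arange(1, n.size + 1, dtype=np.float64)
    ngp = int(act.sum())
    out["ngtdm_coarseness"] = float(1.0 / ((p * s).sum() + EPS_COARSENESS))
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p[act], p[act], indexing="ij")
        ii, jj = np.meshgrid(i[act], i[act], indexing="ij")
        out["ngtdm_contrast"] = float(
            (pi_ * pj_ * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / N)
        denom_busy = np.abs(ii * pi_ - jj * pj_).sum()
        if denom_busy > 0:
            out["ngtdm_busyness"] = float((p * s).sum() / denom_busy)
        si_, sj_ = np.meshgrid(s[act], s[act], indexing="ij")
        out["ngtdm_complexity"] = float(
            (np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum() / N)
        out["ngtdm_strength"] = float(
            ((pi_ + pj_) * (ii - jj) ** 2).sum() / (s.sum() + EPS_COARSENESS))
    return out


# ---------------------------------------------------------------------------
# Per-ROI feature vector and cohort-level extraction
# ---------------------------------------------------------------------------

def roi_feature_vector(vol: Volume, mask: np.ndarray, ng: int = 64
                       ) -> Dict[str, float]:
    """All 43 features for one ROI of one subject (family-prefixed names)."""
    q = quantize_roi(vol, mask, ng=ng)
    feats: Dict[str, float] = {}
    feats.update(histogram_features(q))
    feats.update(glcm_features(glcm_matrix(q)))
    feats.update(glrlm_features(glrlm_matrix(q), q.n_voxels))
    feats.update(glszm_features(glszm_matrix(q), q.n_voxels))
    feats.update(ngtdm_features(*ngtdm_table(q)))
    assert len(feats) == N_FEATURES
    return {name: feats[name] for name in FEATURE_NAMES}


def extract_features(vol: Volume, rois: ROISet, ng: int = 64,
                     min_voxels: int = 2) -> Dict[str, float]:
    """One subject's feature row over an ROI set.

    Column names are ``<ROIname>__<family>_<feature>``; 43 columns per ROI.
    ROIs below ``min_voxels`` yield missing values (NaN) with a warning.
    """
    row: Dict[str, float] = {}
    for roi in rois:
        m = roi.mask.data
        if m.shape != vol.shape:
            raise ValueError(f"ROI {roi.name} geometry mismatch with volume")
        if int(m.sum()) < min_voxels:
            warnings.warn(f"ROI {roi.name} below minimum size; features set missing")
            for name in FEATURE_NAMES:
                row[f"{roi.name}__{name}"] = float("nan")
            continue
        feats = roi_feature_vector(vol, m, ng=ng)
        for name, val in feats.items():
            row[f"{roi.name}__{name}"] = val
    return row
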