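"""Data-driven ROI definition by voxelwise group comparison.

The disease-related regions of interest are defined on the *training*
subjects only: a voxelwise pooled-variance two-sample t test between the two
groups, Benjamini–Hochberg FDR control of the voxel p values (default
q = 0.01), a cluster-extent filter keeping connected components strictly
larger than a minimum voxel count (default 500, 18-connectivity), and
finally mapping of the surviving voxels onto the atlas: each atlas region
whose overlap with the surviving mask reaches ``min_overlap`` voxels
contributes one ROI, whose mask is the intersection (the significant voxels
inside that region), not the whole region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .image import LabelMap, Mask, Volume, check_same_geometry, write_labelmap

__all__ = [
    "StatMap",
    "ROI",
    "ROISet",
    "voxelwise_ttest",
    "fdr_threshold",
    "cluster_filter",
    "map_to_atlas",
    "define_rois",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # ndimage structure rank


@dataclass
class StatMap:
    """Voxelwise t statistics and two-sided p values inside an analysis mask."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mask: Mask

    def significant(self, p_cutoff: float) -> Mask:
        """In-mask voxels with p <= cutoff (BH rejection set)."""
        sig = np.zeros(self.mask.shape, dtype=bool)
        m = self.mask.data
        sig[m] = self.p[m] <= p_cutoff
        return Mask(sig, self.mask.affine.copy())


@dataclass
class ROI:
    region_id: int
    name: str
    mask: Mask
    peak_t: float = float("nan")

    @property
    def n_voxels(self) -> int:
        return self.mask.count()


@dataclass
class ROISet:
    rois: List[ROI]
    provenance: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def ids(self) -> Tuple[int, ...]:
        return tuple(r.region_id for r in self.rois)

    def to_files(self, nifti_path, tsv_path, json_path=None) -> None:
        """Serialize: one label map (ROI voxels carry the region id), a TSV
        summary and an optional JSON sidecar with the thresholds used."""
        if self.rois:
            ref = self.rois[0].mask
            labels = np.zeros(ref.shape, dtype=np.int32)
            lookup = {}
            for r in self.rois:
                labels[r.mask.data] = r.region_id
                lookup[r.region_id] = r.name
            lm = LabelMap(labels, ref.affine, lookup)
            write_labelmap(lm, nifti_path)
        lines = ["region_id\tname\tn_voxels\tpeak_t"]
        for r in self.rois:
            lines.append(f"{r.region_id}\t{r.name}\t{r.n_voxels}\t{r.peak_t:.6g}")
        Path(tsv_path).write_text("\n".join(lines) + "\n")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.provenance, indent=2) + "\n")


def voxelwise_ttest(group_a: Sequence[Volume], group_b: Sequence[Volume],
                    mask: Mask) -> StatMap:
    """Pooled-variance two-sample t test at every in-mask voxel.

    t > 0 where group_a exceeds group_b. Voxels with zero pooled variance
    get t = 0, p = 1. Degrees of freedom: n_a + n_b - 2.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 volumes per group")
    check_same_geometry(*group_a, *group_b, mask)
    m = mask.data
    a = np.stack([v.data[m] for v in group_a])
    b = np.stack([v.data[m] for v in group_b])
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ssa = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mean_diff / denom, 0.0)
    p = np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    t_grid = np.full(mask.shape, np.nan)
    p_grid = np.full(mask.shape, np.nan)
    t_grid[m], p_grid[m] = t, p
    return StatMap(t_grid, p_grid, df, mask)


def fdr_threshold(p_values: np.ndarray, q: float = 0.01) -> Optional[float]:
    """Benjamini–Hochberg p-value cutoff at FDR level ``q``.

    Returns the largest p(k) with p(k) <= k*q/m over the sorted p values,
    or None when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value input")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    ps = np.sort(p)
    m = ps.size
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ps <= crit)[0]
    if passing.size == 0:
        return None
    return float(ps[passing[-1]])


def cluster_filter(sig: Mask, min_voxels: int = 500, connectivity: int = 18) -> Mask:
    """Keep connected components strictly larger than ``min_voxels``.

    Connectivity is 6 (faces), 18 (faces+edges, the default) or 26.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    lab, n = ndimage.label(sig.data, structure=structure)
    if n == 0:
        return Mask(np.zeros_like(sig.data), sig.affine.copy())
    counts = np.bincount(lab.ravel())
    keep = np.nonzero(counts > min_voxels)[0]
    keep = keep[keep != 0]
    return Mask(np.isin(lab, keep), sig.affine.copy())


def map_to_atlas(surviving: Mask, lm: LabelMap, min_overlap: int = 64,
                 stat: Optional[StatMap] = None,
                 full_label: bool = False) -> ROISet:
    """Intersect the surviving mask with atlas regions to form the ROI set.

    A region enters the set when its overlap with ``surviving`` is at least
    ``min_overlap`` voxels. By default the ROI mask is that intersection;
    ``full_label=True`` instead takes the whole atlas region once it is
    touched by enough surviving voxels.
    """
    check_same_geometry(surviving, lm)
    rois: List[ROI] = []
    for rid in lm.ids():
        region = lm.labels == rid
        inter = region & surviving.data
        if inter.sum() < min_overlap:
            continue
        roi_vox = region if full_label else inter
        peak = float("nan")
        if stat is not None:
            tv = stat.t[inter]
            tv = tv[np.isfinite(tv)]
            if tv.size:
                peak = float(tv[np.argmax(np.abs(tv))])
        rois.append(ROI(rid, lm.lookup.get(rid, str(rid)),
                        Mask(roi_vox.copy(), lm.affine.copy()), peak))
    return ROISet(rois, provenance={"min_overlap": min_overlap,
                                    "full_label": full_label})


def define_rois(group_a: Sequence[Volume], group_b: Sequence[Volume],
                atlas: LabelMap, q: float = 0.01, min_cluster: int = 500,
                connectivity: int = 18, min_overlap: int = 64,
                full_label: bool = False) -> ROISet:
    """Full ROI-definition chain: t map -> BH-FDR -> cluster extent -> atlas.

    The analysis mask is the atlas foreground. Must be called with training
    subjects only; the pipeline orchestrator enforces that.
    """
    brain = Mask(atlas.labels > 0, atlas.affine.copy())
    sm = voxelwise_ttest(group_a, group_b, brain)
    cutoff = fdr_threshold(sm.p[brain.data], q=q)
    if cutoff is None:
        surv = Mask(np.zeros(atlas.shape, dtype=bool), atlas.affine.copy())
    else:
        surv = cluster_filter(sm.significant(cutoff), min_cluster, connectivity)
    rs = map_to_atlas(surv, atlas, min_overlap=min_overlap, stat=sm,
                      full_label=full_label)
    rs.provenance.update({
        "q": q, "p_cutoff": cutoff, "min_cluster": min_cluster,
        "connectivity": connectivity, "df": sm.df,
        "n_group_a": len(group_a), "n_group_b": len(group_b),
    })
    return rs
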