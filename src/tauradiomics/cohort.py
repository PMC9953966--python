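"""Synthetic phantom cohorts with the statistical structure of a tau-PET study.

Real tau-PET cohorts carry two kinds of group signal inside disease-related
regions: a shift in mean tracer uptake, and a change in local spatial texture
of the uptake pattern. This module builds phantom cohorts with exactly that
skeleton so every downstream stage (ROI definition, texture extraction,
selection, classification) can be exercised and power-tested without any
image download:

* a blob-like parcellation (Voronoi cells of seeded points inside an
  ellipsoidal "brain") standing in for an anatomical atlas, with one
  designated unaffected reference region (the cerebellum stand-in),
* per-subject volumes = baseline uptake + unit-variance Gaussian random
  field, with ``mean_shift`` (in noise-SD units) added in affected regions
  for patients and ``texture_effect`` changing the field's correlation
  length there,
* an optional external-site cohort with a global multiplicative + additive
  shift, emulating a second scanner/tracer,
* a manifest with demographics, a group-dependent cognitive score (MMSE),
  and tau-positivity / risk-allele carrier labels whose probability rises
  with the subject's individual signal amplitude.

Everything is deterministic given ``CohortSpec.seed``; each subject's volume
depends only on (seed, subject index) so cohorts can be regenerated
subject-by-subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import LabelMap, Volume, write_labelmap, write_lookup, write_volume

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "generate_atlas",
    "generate_subject_volume",
    "generate_cohort",
]

REFERENCE_NAME = "cerebellum_ref"


@dataclass
class CohortSpec:
    """Parameters of a phantom cohort.

    Effect sizes are expressed in units of the voxel noise SD (which is 1 by
    construction). ``texture_effect`` is the relative increase of the noise
    correlation length inside affected regions for the patient group; it
    perturbs neighbourhood texture while leaving the region mean nearly
    unchanged, so mean-based and texture-based features are separably
    testable.
    """

    groups: Tuple[str, str] = ("AD", "NC")
    n_per_group: int = 30
    n_external_per_group: int = 0
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    n_regions: int = 61  # 60 cortical stand-ins + 1 reference region
    n_affected: int = 12
    affected_regions: Optional[Tuple[int, ...]] = None
    mean_shift: float = 2.0
    texture_effect: float = 1.0
    noise_corr_mm: float = 4.0
    baseline_uptake: float = 5.0
    # per-subject low-spatial-frequency uptake modulation (amplitude in noise-SD
    # units, correlation length in mm): the inter-subject regional uptake
    # heterogeneity (delivery, perfusion, scanner gradients) that limits SUVR
    # in real cohorts. It moves region means, including the reference, but is
    # too smooth to carry fine-scale texture, and within-ROI quantization makes
    # texture features largely immune to it.
    regional_hetero_sd: float = 0.8
    regional_hetero_corr_mm: float = 16.0
    site_scale: float = 1.1
    site_offset: float = 0.2
    mmse_means: Tuple[float, float] = (24.0, 28.0)  # (patient, control)
    mmse_sd: float = 3.0
    age_mean: float = 73.0
    age_sd: float = 6.0
    tau_base_rate: float = 0.5
    tau_slope: float = 3.0
    apoe_base_rate: float = 0.5
    apoe_slope: float = 1.5
    amplitude_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_regions < 2:
            raise ValueError("need at least one region plus the reference")
        if not np.isfinite([self.mean_shift, self.texture_effect]).all():
            raise ValueError("effect sizes must be finite")
        if self.affected_regions is not None:
            aff = set(self.affected_regions)
            if self.reference_region in aff:
                raise ValueError("reference region cannot be affected")
            if not aff <= set(range(1, self.n_regions + 1)):
                raise ValueError("affected_regions outside atlas id range")

    @property
    def reference_region(self) -> int:
        """Label id of the unaffected reference region (always the last id)."""
        return self.n_regions

    def affected_ids(self) -> Tuple[int, ...]:
        """Affected region ids; default = the first ``n_affected`` non-reference ids."""
        if self.affected_regions is not None:
            return tuple(sorted(self.affected_regions))
        n = min(self.n_affected, self.n_regions - 1)
        return tuple(range(1, n + 1))


@dataclass
class SubjectRecord:
    id: str
    group: str
    cohort: str  # "discovery" or "external"
    age: float
    sex: str  # "M" / "F"
    mmse: int
    tau_status: str  # "+", "-", "NA"
    apoe_status: str  # "carrier", "non-carrier", "NA"
    index: int  # position in the cohort; seeds the per-subject RNG
    path: str = ""


def _brain_mask(shape: Sequence[int]) -> np.ndarray:
    """Ellipsoid filling ~90% of the grid per axis."""
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    c = [(n - 1) / 2.0 for n in shape]
    semi = [0.45 * n for n in shape]
    r2 = sum(((g - ci) / si) ** 2 for g, ci, si in zip(coords, c, semi))
    return r2 <= 1.0


def generate_atlas(spec: CohortSpec, min_region_voxels: int = 64,
                   max_tries: int = 50) -> LabelMap:
    """Voronoi parcellation of an ellipsoidal brain into ``n_regions`` parcels.

    Seed points are drawn inside the brain mask; each in-brain voxel takes
    the label of its nearest seed, giving contiguous blob-like parcels.
    Resampling is attempted until every parcel has at least
    ``min_region_voxels`` voxels. The parcel whose seed sits lowest on the
    third axis becomes the reference region (cerebellum stand-in) and is
    assigned the last label id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    brain = _brain_mask(spec.shape)
    vox = np.argwhere(brain)
    if len(vox) < spec.n_regions * min_region_voxels:
        raise ValueError(
            f"grid too small for {spec.n_regions} regions of >= {min_region_voxels} voxels"
        )
    for _ in range(max_tries):
        pick = rng.choice(len(vox), size=spec.n_regions, replace=False)
        seeds = vox[pick].astype(np.float64)
        _, assign = cKDTree(seeds).query(vox.astype(np.float64))
        counts = np.bincount(assign, minlength=spec.n_regions)
        if counts.min() >= min_region_voxels:
            break
    else:
        raise ValueError("could not place regions with the required minimum size")
    # reference = seed with the smallest z coordinate -> relabel to last id
    ref_seed = int(np.argmin(seeds[:, 2]))
    order = [i for i in range(spec.n_regions) if i != ref_seed] + [ref_seed]
    relabel = np.empty(spec.n_regions, dtype=np.int32)
    for new_id, old in enumerate(order, start=1):
        relabel[old] = new_id
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[tuple(vox.T)] = relabel[assign]
    lookup = {i: f"region_{i:03d}" for i in range(1, spec.n_regions)}
    lookup[spec.n_regions] = REFERENCE_NAME
    affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    return LabelMap(labels, affine, lookup)


def _smooth_unit_field(white: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Smooth white noise and rescale to unit variance (wrap mode keeps the
    field statistically homogeneous so the normalization is exact)."""
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _subject_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 500, index]))


def generate_subject_volume(spec: CohortSpec, record: SubjectRecord,
                            atlas: LabelMap) -> Volume:
    """Render one subject's phantom PET volume.

    volume = baseline + unit-SD correlated noise, with ``mean_shift`` added
    and the noise correlation length stretched by ``1 + texture_effect``
    inside affected regions for the patient group. The reference region is
    never touched by group effects. External-cohort subjects get the global
    site shift ``scale * v + offset`` applied inside the brain.
    """
    if atlas.shape != tuple(spec.shape):
        raise ValueError("atlas geometry does not match spec grid")
    rng = _subject_rng(spec, record.index)
    white = rng.standard_normal(spec.shape)
    sigma0 = spec.noise_corr_mm / spec.spacing_mm
    base_field = _smooth_unit_field(white, sigma0)
    brain = atlas.labels > 0
    data = np.zeros(spec.shape, dtype=np.float64)
    data[brain] = spec.baseline_uptake + base_field[brain]
    if spec.regional_hetero_sd > 0:
        slow = _smooth_unit_field(rng.standard_normal(spec.shape),
                                  spec.regional_hetero_corr_mm / spec.spacing_mm)
        data[brain] += spec.regional_hetero_sd * slow[brain]

    is_patient = record.group == spec.groups[0]
    if is_patient:
        affected = np.isin(atlas.labels, spec.affected_ids())
        # per-subject amplitude modulates both effects and drives the
        # subgroup labels (tau positivity, carrier status)
        amp = getattr(record, "_amplitude", 1.0)
        if spec.texture_effect != 0:
            rough = _smooth_unit_field(white, sigma0 * (1.0 + spec.texture_effect * amp))
            data[affected] = spec.baseline_uptake + rough[affected]
        if spec.mean_shift != 0:
            data[affected] += spec.mean_shift * amp

    if record.cohort == "external":
        data[brain] = spec.site_scale * data[brain] + spec.site_offset
    affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    return Volume(data, affine)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_records(spec: CohortSpec) -> List[SubjectRecord]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    patient, control = spec.groups
    records: List[SubjectRecord] = []
    index = 0
    logit = lambda p: np.log(p / (1.0 - p))
    for cohort, n in (("discovery", spec.n_per_group),
                      ("external", spec.n_external_per_group)):
        for group in (patient, control):
            for k in range(n):
                age = float(rng.normal(spec.age_mean, spec.age_sd))
                sex = "M" if rng.random() < 0.5 else "F"
                mmse_mu = spec.mmse_means[0] if group == patient else spec.mmse_means[1]
                mmse = int(np.clip(round(rng.normal(mmse_mu, spec.mmse_sd)), 0, 30))
                amplitude = float(max(0.1, rng.normal(1.0, spec.amplitude_sd)))
                if group == patient:
                    p_tau = float(_sigmoid(logit(spec.tau_base_rate)
                                           + spec.tau_slope * (amplitude - 1.0)))
                    p_apoe = float(_sigmoid(logit(spec.apoe_base_rate)
                                            + spec.apoe_slope * (amplitude - 1.0)))
                    tau = "+" if rng.random() < p_tau else "-"
                    apoe = "carrier" if rng.random() < p_apoe else "non-carrier"
                else:
                    tau, apoe = "NA", "NA"
                rec = SubjectRecord(
                    id=f"sub-{cohort[:3]}-{group}-{k:03d}", group=group,
                    cohort=cohort, age=round(age, 1), sex=sex, mmse=mmse,
                    tau_status=tau, apoe_status=apoe, index=index,
                )
                rec._amplitude = amplitude  # type: ignore[attr-defined]
                records.append(rec)
                index += 1
    return records


MANIFEST_COLUMNS = ["id", "group", "cohort", "age", "sex", "mmse",
                    "tau_status", "apoe_status", "index", "path"]


def generate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write atlas, per-subject volumes and a manifest TSV; return manifest path.

    Re-running with the same spec reproduces every output byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(spec)
    write_labelmap(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv")
    records = _make_records(spec)
    rows = []
    for rec in records:
        vol = generate_subject_volume(spec, rec, atlas)
        rec.path = f"{rec.id}.nii.gz"
        write_volume(vol, out / rec.path)
        rows.append([str(getattr(rec, c)) for c in MANIFEST_COLUMNS])
    manifest = out / "manifest.tsv"
    lines = ["\t".join(MANIFEST_COLUMNS)] + ["\t".join(r) for r in rows]
    manifest.write_text("\n".join(lines) + "\n")
    log = {
        "seed": spec.seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "reference_region": spec.reference_region,
        "affected_regions": list(spec.affected_ids()),
        "n_subjects": len(records),
    }
    (out / "generation.json").write_text(json.dumps(log, indent=2) + "\n")
    return manifest
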