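"""Baseline comparator feature sets: ROI SUVR and clinical score.

Both comparators feed the identical classification harness as the radiomics
model; they differ only in the feature matrix. SUVR (standardized uptake
value ratio) for an ROI is its mean uptake divided by the mean uptake of an
unaffected reference region (the cerebellum stand-in in phantom cohorts).
The clinical model uses the MMSE score as its single feature.
"""

from __future__ import annotations

from typing import Dict, List

import pandas as pd

from .image import Mask, Volume
from .roi import ROISet

__all__ = ["compute_suvr", "suvr_table", "clinical_table"]


def compute_suvr(pet: Volume, rois: ROISet, reference: Mask) -> Dict[str, float]:
    """Per-ROI SUVR row: mean(ROI) / mean(reference).

    The reference mean must be positive; SUVR of the reference region over
    itself is exactly 1 by construction. Being a ratio, SUVR is invariant
    to global multiplicative rescaling of the volume.
    """
    if reference.count() == 0:
        raise ValueError("empty reference region")
    ref_mean = float(pet.data[reference.data].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean ({ref_mean:g})")
    row: Dict[str, float] = {}
    for roi in rois:
        row[f"{roi.name}__suvr"] = float(pet.data[roi.mask.data].mean()) / ref_mean
    return row


def suvr_table(volumes: Dict[str, Volume], manifest: pd.DataFrame,
               rois: ROISet, reference: Mask) -> pd.DataFrame:
    """SUVR feature table mirroring the radiomics table schema."""
    rows: List[Dict] = []
    for _, rec in manifest.iterrows():
        row = dict(rec)
        row.update(compute_suvr(volumes[rec["id"]], rois, reference))
        rows.append(row)
    return pd.DataFrame(rows)


def clinical_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Single-feature (MMSE) table; subjects with missing MMSE are excluded
    with a warning column-free copy of the manifest rows."""
    df = manifest.copy()
    missing = df["mmse"].isna()
    if missing.any():
        import warnings

        warnings.warn(f"excluding {int(missing.sum())} subjects with missing MMSE: "
                      f"{list(df.loc[missing, 'id'])}")
        df = df[~missing]
    df = df.copy()
    df["clinical__mmse"] = df["mmse"].astype(float)
    return df
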