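"""Voxel-level quantification: two-compartment partial-volume correction,
reference-region SUVR normalization, atlas-based regional extraction, the
global amyloid meta-ROI, and voxel-wise two-sample t-maps with cluster-extent
thresholding.

Conventions
-----------
* Invalid voxels are ``NaN`` and are excluded from every aggregate; they are
  never clamped or zero-filled.
* Regional aggregation uses the median throughout (the reference region and
  the composite are defined by medians; the same statistic is applied to
  single regions for internal consistency and robustness).
* The partial-volume correction divides each voxel by its brain-tissue
  fraction (GM+WM), undoing dilution of the signal by CSF; voxels with less
  tissue than ``min_tissue`` are invalidated because the division is
  unstable in near-pure-CSF voxels.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas import AtlasDefinition
from .volumes import VolumeGrid, check_common_grid

DEFAULT_MIN_TISSUE = 0.2

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


# --------------------------------------------------------------------------
# Partial-volume correction and normalization
# --------------------------------------------------------------------------
def pvc_two_compartment(pet: VolumeGrid, gm: VolumeGrid, wm: VolumeGrid,
                        min_tissue: float = DEFAULT_MIN_TISSUE) -> VolumeGrid:
    """Two-compartment CSF partial-volume correction.

    Each voxel is divided by its brain-tissue fraction ``GM+WM``; voxels with
    ``GM+WM < min_tissue`` become invalid (NaN) and stay excluded downstream.
    """
    check_common_grid(pet, gm, wm)
    if not (0 < min_tissue <= 1):
        raise ValueError("min_tissue must lie in (0, 1]")
    for name, vol in (("gm", gm), ("wm", wm)):
        finite = vol.values[np.isfinite(vol.values)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"negative {name} fractions")
    tissue = gm.values + wm.values
    out = np.where(tissue >= min_tissue, pet.values / np.where(tissue > 0, tissue, np.nan), np.nan)
    if not np.isfinite(out).any():
        raise ValueError("partial-volume correction invalidated every voxel "
                         f"(no voxel has GM+WM >= {min_tissue})")
    return pet.with_values(out, kind="activity")


def normalize_suvr(pet: VolumeGrid, atlas_volume: VolumeGrid,
                   atlas: AtlasDefinition) -> VolumeGrid:
    """Divide every valid voxel by the median of the pooled reference-region
    voxels (bilateral cerebellar crus in the default atlas)."""
    check_common_grid(pet, atlas_volume)
    ref_mask = np.isin(atlas_volume.values, atlas.reference_labels) & pet.valid
    if not ref_mask.any():
        raise ValueError("reference region has no valid voxels")
    ref_median = float(np.median(pet.values[ref_mask]))
    if ref_median <= 0:
        raise ValueError(f"reference-region median is {ref_median}; cannot normalize")
    return pet.with_values(pet.values / ref_median, kind="suvr")


# --------------------------------------------------------------------------
# Regional extraction
# --------------------------------------------------------------------------
def extract_regional(suvr: VolumeGrid, atlas_volume: VolumeGrid,
                     atlas: AtlasDefinition) -> pd.Series:
    """Median SUVR per atlas label, indexed by lateralized region name.

    Regions with no valid voxels — entirely below the tissue floor, or absent
    from the label volume — are reported as missing (NaN), never as zero.
    """
    if suvr.kind != "suvr":
        raise ValueError(f"expected a suvr volume, got kind={suvr.kind!r}")
    check_common_grid(suvr, atlas_volume)
    labels = atlas_volume.values
    valid = suvr.valid
    out = {}
    present = set(np.unique(labels))
    for lab, name in atlas.label_map.items():
        if lab not in present:
            warnings.warn(f"label {lab} ({name}) absent from the label volume; "
                          "reported as missing", stacklevel=2)
            out[name] = np.nan
            continue
        mask = (labels == lab) & valid
        out[name] = float(np.median(suvr.values[mask])) if mask.any() else np.nan
    return pd.Series(out, name="suvr")


def global_meta_roi_suvr(suvr: VolumeGrid, atlas_volume: VolumeGrid,
                         atlas: AtlasDefinition) -> float:
    """Median over the *pooled* valid voxels of all meta-ROI labels (a single
    pooled aggregate, not a mean of per-region values)."""
    if not atlas.meta_roi_labels:
        raise ValueError("atlas defines no meta-ROI labels")
    if suvr.kind != "suvr":
        raise ValueError(f"expected a suvr volume, got kind={suvr.kind!r}")
    check_common_grid(suvr, atlas_volume)
    mask = np.isin(atlas_volume.values, atlas.meta_roi_labels) & suvr.valid
    if not mask.any():
        raise ValueError("meta-ROI has no valid voxels")
    return float(np.median(suvr.values[mask]))


def quantify_volume(pet: VolumeGrid, gm: VolumeGrid | None, wm: VolumeGrid | None,
                    atlas_volume: VolumeGrid, atlas: AtlasDefinition,
                    pvc: bool = True,
                    min_tissue: float = DEFAULT_MIN_TISSUE) -> pd.Series:
    """PVC (optional) → reference normalization → regional medians.

    The correction is applied before normalization and covers the reference
    region identically, so corrected and uncorrected paths share the same
    SUVR scale wherever tissue fractions are uniform.
    """
    vol = pet
    if pvc:
        if gm is None or wm is None:
            raise ValueError("partial-volume correction requires gm and wm volumes")
        vol = pvc_two_compartment(pet, gm, wm, min_tissue=min_tissue)
    suvr = normalize_suvr(vol, atlas_volume, atlas)
    return extract_regional(suvr, atlas_volume, atlas)


# --------------------------------------------------------------------------
# Voxel-wise statistics
# --------------------------------------------------------------------------
def voxelwise_ttest(group_a: list[VolumeGrid], group_b: list[VolumeGrid]
                    ) -> tuple[VolumeGrid, VolumeGrid]:
    """Per-voxel two-sample pooled-variance t map (A minus B) and two-sided p.

    Voxels invalid in any subject are invalid in both maps.  Voxels with zero
    pooled variance get t=0, p=1 (flagged rather than infinite).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two volumes per group")
    check_common_grid(*(group_a + group_b))
    a = np.stack([v.values for v in group_a])
    b = np.stack([v.values for v in group_b])
    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    df = na + nb - 2
    pooled = (ss_a + ss_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    zero_var = np.isfinite(pooled) & (pooled == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df), np.nan)
    p = np.where(np.isfinite(t), p, np.nan)
    grid = group_a[0]
    return grid.with_values(t, kind="stat"), grid.with_values(p, kind="stat")


@dataclass
class StatMapResult:
    """Thresholded voxel-wise comparison: surviving clusters and their mask."""

    t_map: VolumeGrid
    p_map: VolumeGrid
    cluster_mask: VolumeGrid
    clusters: pd.DataFrame  # cluster_id, n_voxels, peak_t, peak_x/y/z


def cluster_threshold(p_map: VolumeGrid, t_map: VolumeGrid,
                      p_thresh: float = 0.001, extent: int = 25,
                      connectivity: int = 18) -> StatMapResult:
    """Threshold at ``p < p_thresh``, label connected components, and discard
    components whose size does not *exceed* ``extent`` (a component of exactly
    ``extent`` voxels is removed).  Default connectivity 18 (faces + edges);
    6 and 26 selectable.  Surviving clusters are numbered by decreasing size.
    """
    if not (0 < p_thresh < 1):
        raise ValueError("p_thresh must lie in (0, 1)")
    if extent < 0:
        raise ValueError("extent must be >= 0")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    check_common_grid(p_map, t_map)
    supra = p_map.valid & (p_map.values < p_thresh)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n_comp = ndimage.label(supra, structure=structure)
    rows = []
    mask = np.zeros(p_map.shape, dtype=np.int32)
    comps = []
    for comp in range(1, n_comp + 1):
        where = labeled == comp
        size = int(where.sum())
        if size > extent:
            comps.append((size, comp, where))
    comps.sort(key=lambda c: (-c[0], c[1]))
    for new_id, (size, _comp, where) in enumerate(comps, start=1):
        mask[where] = new_id
        tv = np.where(where, np.nan_to_num(t_map.values), 0.0)
        peak_flat = int(np.abs(tv).argmax())
        peak = np.unravel_index(peak_flat, tv.shape)
        rows.append({"cluster_id": new_id, "n_voxels": size,
                     "peak_t": float(t_map.values[peak]),
                     "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                     "peak_z": int(peak[2])})
    clusters = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "peak_t",
                                           "peak_x", "peak_y", "peak_z"])
    return StatMapResult(t_map, p_map, p_map.with_values(mask, kind="mask"), clusters)
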