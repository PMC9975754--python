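"""Liver-referenced lesion detection, curation and MTV/TLG quantification.

The measurement procedure:

1. A 3-cm-diameter sphere is placed in normal liver at an expert-supplied
   seed point; the detection threshold is the sphere's mean SUV plus two
   standard deviations.
2. Connected components of supra-threshold voxels become candidate
   lesions (26-connectivity by default; tiny components dropped as noise).
3. A reader curates the candidates.  Mode "A" (semi-automated) may only
   accept or remove candidates; mode "M" (manual) may additionally edit
   boundaries with replacement masks and add lesions the threshold missed.
   Physiologic or inflammatory uptake is removed with its class recorded.
4. Each accepted lesion's final boundary keeps voxels whose SUV exceeds
   41% of that lesion's SUVmax.  Metabolic tumor volume (MTV, ml) is the
   cumulative volume of these voxels; total lesion glycolysis (TLG,
   SUV·ml) is the per-lesion MTV × SUVmean summed across lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .suv import SuvVolume, voxel_volume_ml

__all__ = [
    "LiverReference",
    "Lesion",
    "PatientMeasurement",
    "liver_reference",
    "detect_candidates",
    "curate",
    "isocontour41",
    "patient_totals",
    "percent_difference",
]

DEFAULT_LIVER_DIAMETER_MM = 30.0
DEFAULT_FRACTION = 0.41
DEFAULT_MIN_VOXELS = 2


@dataclass
class LiverReference:
    """Normal-liver reference statistics from a fixed-diameter sphere."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    mean_suv: float
    sd_suv: float
    detection_threshold: float
    sphere_volume_ml: float
    n_voxels: int


@dataclass
class Lesion:
    """One labeled lesion: initial extent, 41% mask and per-lesion metrics.

    ``indices`` is an (N, 3) integer array of voxel indices defining the
    lesion's extent (initial detection boundary, or an edited/added
    boundary).  After :func:`isocontour41`, ``mask41_indices`` holds the
    subset above the 41%-of-SUVmax cutoff and the volume/glycolysis
    fields are populated.
    """

    label: int
    indices: np.ndarray
    suv_max: float
    mask41_indices: np.ndarray | None = None
    mtv_ml: float = 0.0
    suv_mean41: float = 0.0
    tlg: float = 0.0
    state: str = "candidate"  # candidate | accepted | removed | edited | added
    class_tag: str = "candidate"  # candidate | physiologic | inflammatory

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class PatientMeasurement:
    """One reader's per-patient summary."""

    patient_id: str
    reader: str  # "M" | "A"
    mtv_ml: float
    tlg_suvml: float
    lesion_count: int


def liver_reference(vol: SuvVolume, center_mm: tuple[float, float, float],
                    diameter_mm: float = DEFAULT_LIVER_DIAMETER_MM) -> LiverReference:
    """Measure mean/SD SUV in a sphere of normal liver.

    Membership is by voxel-center inclusion.  The detection threshold is
    mean + 2·SD.  Raises if the sphere exits the grid or contains no
    voxel centers.
    """
    r = diameter_mm / 2.0
    extent_lo = [vol.origin_mm[a] for a in range(3)]
    extent_hi = [vol.origin_mm[a] + (vol.shape[a] - 1) * vol.spacing_mm[a] for a in range(3)]
    for a in range(3):
        if center_mm[a] - r < extent_lo[a] or center_mm[a] + r > extent_hi[a]:
            raise ValueError(
                f"liver sphere (center {center_mm}, diameter {diameter_mm} mm) "
                f"exits the volume on axis {a}"
            )
    ax = vol.voxel_centers_mm()
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    inside = ((xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
              + (zz - center_mm[2]) ** 2) <= r ** 2
    n = int(inside.sum())
    if n == 0:
        raise ValueError("liver sphere contains no voxel centers")
    samples = vol.values[inside]
    mean = float(samples.mean())
    sd = float(samples.std(ddof=0))
    return LiverReference(
        center_mm=tuple(float(c) for c in center_mm),
        diameter_mm=float(diameter_mm),
        mean_suv=mean,
        sd_suv=sd,
        detection_threshold=mean + 2.0 * sd,
        sphere_volume_ml=n * voxel_volume_ml(vol),
        n_voxels=n,
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def detect_candidates(vol: SuvVolume, threshold: float,
                      min_voxels: int = DEFAULT_MIN_VOXELS,
                      connectivity: int = 26) -> list[Lesion]:
    """Connected components of voxels with SUV strictly above ``threshold``.

    Components smaller than ``min_voxels`` are dropped as noise.  Returns
    candidates sorted by label, each carrying its within-component SUVmax.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be > 0")
    binary = vol.values > threshold
    labeled, n_comp = ndimage.label(binary, structure=_connectivity_structure(connectivity))
    lesions: list[Lesion] = []
    next_label = 1
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labeled == comp)
        if idx.shape[0] < min_voxels:
            continue
        suv_max = float(vol.values[tuple(idx.T)].max())
        lesions.append(Lesion(label=next_label, indices=idx, suv_max=suv_max))
        next_label += 1
    return lesions


@dataclass
class CurationDecision:
    """One reader decision about a candidate (or an added lesion).

    ``action`` is "accept", "remove" or (mode M only) "edit"; removals may
    carry a ``reason`` of "physiologic" or "inflammatory".  ``mask_indices``
    supplies the replacement boundary for an edit.
    """

    action: str
    reason: str = ""
    mask_indices: np.ndarray | None = None


def curate(candidates: list[Lesion],
           decisions: dict[int, CurationDecision],
           mode: str,
           added: list[np.ndarray] | None = None,
           vol: SuvVolume | None = None) -> list[Lesion]:
    """Apply reader decisions to detected candidates.

    Mode "A" (accept/reject only): every decision must be "accept" or
    "remove"; output voxel sets are exactly the accepted candidates'.
    Mode "M" (manual): decisions may also replace a lesion's boundary
    ("edit" with a mask), and ``added`` lesions (voxel-index arrays) are
    appended.  Candidates without an explicit decision are accepted.
    Edited and added lesions recompute SUVmax over their new extent
    (requires ``vol``).
    """
    if mode not in ("A", "M"):
        raise ValueError(f"mode must be 'A' or 'M', got {mode!r}")
    known = {les.label for les in candidates}
    for label in decisions:
        if label not in known:
            raise ValueError(f"decision references unknown lesion label {label}")
    if mode == "A" and added:
        raise ValueError("mode A may not add lesions")

    accepted: list[Lesion] = []
    for les in candidates:
        dec = decisions.get(les.label, CurationDecision("accept"))
        if dec.action == "accept":
            accepted.append(replace(les, state="accepted"))
        elif dec.action == "remove":
            # physiologic / inflammatory uptake removed; not counted
            continue
        elif dec.action == "edit":
            if mode == "A":
                raise ValueError(
                    f"mode A cannot edit boundaries (lesion {les.label}); "
                    "accept or remove only"
                )
            if dec.mask_indices is None:
                raise ValueError(f"edit decision for lesion {les.label} lacks a mask")
            if vol is None:
                raise ValueError("boundary edits require the SUV volume")
            idx = np.asarray(dec.mask_indices, dtype=int)
            suv_max = float(vol.values[tuple(idx.T)].max())
            accepted.append(replace(les, indices=idx, suv_max=suv_max, state="edited"))
        else:
            raise ValueError(f"unknown curation action {dec.action!r}")

    if added:
        next_label = max(known, default=0) + 1
        if vol is None:
            raise ValueError("added lesions require the SUV volume")
        for idx in added:
            idx = np.asarray(idx, dtype=int)
            suv_max = float(vol.values[tuple(idx.T)].max())
            accepted.append(Lesion(label=next_label, indices=idx, suv_max=suv_max,
                                   state="added"))
            next_label += 1
    return accepted


def isocontour41(vol: SuvVolume, lesion: Lesion,
                 fraction: float = DEFAULT_FRACTION) -> Lesion:
    """Apply the per-lesion fractional-SUVmax isocontour.

    Keeps voxels of the lesion's extent whose SUV is strictly above
    ``fraction`` × the lesion's SUVmax (ties at the cutoff excluded); the
    argmax voxel(s) are always retained, so ``fraction=1.0`` reduces the
    mask to the SUVmax voxel(s).  Populates mtv_ml, suv_mean41 and tlg.
    """
    if lesion.n_voxels == 0:
        raise ValueError("lesion voxel set is empty")
    vals = vol.values[tuple(lesion.indices.T)]
    suv_max = float(vals.max())
    keep = (vals > fraction * suv_max) | (vals == suv_max)
    mask41 = lesion.indices[keep]
    mean41 = float(vals[keep].mean())
    mtv = mask41.shape[0] * voxel_volume_ml(vol)
    return replace(lesion, suv_max=suv_max, mask41_indices=mask41,
                   mtv_ml=mtv, suv_mean41=mean41, tlg=mtv * mean41)


def patient_totals(accepted: list[Lesion], vol: SuvVolume,
                   patient_id: str = "", reader: str = "",
                   fraction: float = DEFAULT_FRACTION,
                   tlg_mode: str = "suvmean") -> PatientMeasurement:
    """Sum per-lesion metrics into the patient-level MTV/TLG summary.

    Lesions lacking a 41% mask are isocontoured first.  ``tlg_mode``
    "suvmean" (default) sums per-lesion MTV × SUVmean over the 41% mask;
    "suvmax_product" instead reports total MTV × mean of per-lesion
    SUVmax (a literal product-of-averages variant).
    """
    contoured = [les if les.mask41_indices is not None else isocontour41(vol, les, fraction)
                 for les in accepted]
    mtv = float(sum(les.mtv_ml for les in contoured))
    if tlg_mode == "suvmean":
        tlg = float(sum(les.mtv_ml * les.suv_mean41 for les in contoured))
    elif tlg_mode == "suvmax_product":
        tlg = mtv * float(np.mean([les.suv_max for les in contoured])) if contoured else 0.0
    else:
        raise ValueError(f"unknown tlg_mode {tlg_mode!r}")
    return PatientMeasurement(patient_id=patient_id, reader=reader,
                              mtv_ml=mtv, tlg_suvml=tlg,
                              lesion_count=len(contoured))


def percent_difference(a_ml: float, b_ml: float) -> float:
    """Percent difference 100·(a − b)/a of two measurements."""
    if a_ml == 0:
        raise ValueError("reference measurement a_ml must be nonzero")
    return 100.0 * (a_ml - b_ml) / a_ml


def lesion_table(lesions: list[Lesion]) -> pd.DataFrame:
    """Per-lesion CSV-ready table (label, voxels, SUVmax, SUVmean41, MTV, TLG)."""
    return pd.DataFrame([
        {
            "label": les.label,
            "voxels": les.n_voxels,
            "suv_max": les.suv_max,
            "suv_mean41": les.suv_mean41,
            "mtv_ml": les.mtv_ml,
            "tlg": les.tlg,
            "state": les.state,
        }
        for les in lesions
    ])
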