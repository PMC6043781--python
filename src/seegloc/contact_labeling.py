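"""Anatomical labeling of electrode contacts by sphere majority vote.

Every contact is labeled in the pre-implantation grid by examining the
voxels whose centers fall within a sphere around the contact center:

* **atlas parcel** — the most common nonzero parcel label in a 3 mm-radius
  sphere.  For cortical atlases the vote is restricted to gray-matter
  voxels, so a contact sitting mostly in white matter still receives a
  cortical label if any labeled GM voxels fall inside its sphere.
* **tissue class** — majority over nonzero tissue voxels (GM/WM/CSF).
* **statistical maps** — the mean map value in a smaller sphere
  (default radius 1.5 mm, i.e. 3 mm diameter).
* **resection membership** — whether the single voxel containing the
  contact center lies inside the resection mask.

Ties in majority votes are broken deterministically: smallest label integer
for atlases, fixed GM > WM > CSF priority for tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrode_geometry import PlacedElectrode
from .errors import ValidationError
from .io_core import (
    TISSUE_CSF,
    TISSUE_GM,
    TISSUE_WM,
    LabelLookup,
    Volume3D,
    voxel_to_world,
    world_to_voxel,
)

__all__ = [
    "ATLAS_RADIUS_MM",
    "STATMAP_RADIUS_MM",
    "SphereSpec",
    "ContactLabels",
    "sphere_voxels",
    "label_atlas",
    "label_tissue",
    "statmap_mean",
    "resection_flag",
    "label_all",
    "labels_to_dataframe",
]

ATLAS_RADIUS_MM = 3.0
STATMAP_RADIUS_MM = 1.5
_MAX_RADIUS_MM = 20.0


@dataclass(frozen=True)
class SphereSpec:
    """Radius (mm) of the neighborhood sampled around a contact center."""

    radius_mm: float = ATLAS_RADIUS_MM

    def __post_init__(self) -> None:
        if not (0 < self.radius_mm <= _MAX_RADIUS_MM):
            raise ValidationError(
                f"sphere radius must be in (0, {_MAX_RADIUS_MM}] mm, got {self.radius_mm}"
            )


@dataclass
class ContactLabels:
    """All labels attached to one contact of one electrode."""

    electrode_name: str
    contact_index: int  # 1-based, 1 = deepest
    atlas_labels: dict[str, tuple[int, str]] = field(default_factory=dict)
    tissue: str = "unlabeled"  # GM | WM | CSF | unlabeled
    statmap_means: dict[str, float] = field(default_factory=dict)
    in_resection: bool = False


def sphere_voxels(center, vol: Volume3D, sphere: SphereSpec | None = None) -> np.ndarray:
    """In-bounds voxel indices whose world-space centers lie within the sphere.

    Returns an (K, 3) integer array in lexicographic index order (empty if
    the sphere lies entirely outside the volume).  Membership is decided on
    voxel centers, at Euclidean distance <= radius.
    """
    if sphere is None:
        sphere = SphereSpec()
    center = np.asarray(center, dtype=float)
    r = sphere.radius_mm
    inv = np.linalg.inv(vol.affine)
    c_idx = inv[:3, :3] @ center + inv[:3, 3]
    # a world displacement of length r moves index axis i by at most r*||row_i||
    reach = r * np.linalg.norm(inv[:3, :3], axis=1)
    lo = np.maximum(np.ceil(c_idx - reach - 1e-9).astype(int), 0)
    hi = np.minimum(np.floor(c_idx + reach + 1e-9).astype(int), np.array(vol.shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"
    )
    cand = np.stack([g.ravel() for g in grids], axis=1)
    world = voxel_to_world(cand, vol)
    d2 = np.sum((world - center) ** 2, axis=1)
    return cand[d2 <= r * r + 1e-9]


def _modal_smallest(values: np.ndarray) -> int:
    """Most frequent value; ties broken by the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])  # uniq sorted -> argmax keeps smallest


def label_atlas(
    center,
    atlas: Volume3D,
    lookup: LabelLookup,
    tissue: Volume3D | None = None,
    sphere: SphereSpec | None = None,
) -> tuple[int, str]:
    """Majority atlas label in the sphere around ``center``.

    With a tissue volume and a cortical atlas, only voxels that are gray
    matter *and* carry a nonzero parcel label are candidates; the modal
    label among them wins even when most of the sphere is white matter.
    Returns ``(0, "unlabeled")`` when no candidate voxel exists.
    """
    if sphere is None:
        sphere = SphereSpec(ATLAS_RADIUS_MM)
    if tissue is not None:
        atlas.require_same_grid(tissue, "tissue volume")
    vox = sphere_voxels(center, atlas, sphere)
    if vox.size == 0:
        return 0, "unlabeled"
    labels = atlas.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    keep = labels != 0
    if tissue is not None and lookup.cortical:
        tvals = tissue.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        keep &= tvals == TISSUE_GM
    cand = labels[keep]
    if cand.size == 0:
        return 0, "unlabeled"
    lab = _modal_smallest(cand)
    return lab, lookup.name(lab)


_TISSUE_PRIORITY = (TISSUE_GM, TISSUE_WM, TISSUE_CSF)
_TISSUE_STR = {TISSUE_GM: "GM", TISSUE_WM: "WM", TISSUE_CSF: "CSF"}


def label_tissue(center, tissue: Volume3D, sphere: SphereSpec | None = None) -> str:
    """Majority tissue class in the sphere; ties resolved GM > WM > CSF."""
    if sphere is None:
        sphere = SphereSpec(ATLAS_RADIUS_MM)
    vox = sphere_voxels(center, tissue, sphere)
    if vox.size == 0:
        return "unlabeled"
    vals = tissue.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    counts = {c: int(np.sum(vals == c)) for c in _TISSUE_PRIORITY}
    best = max(_TISSUE_PRIORITY, key=lambda c: counts[c])  # ties keep priority order
    if counts[best] == 0:
        return "unlabeled"
    return _TISSUE_STR[best]


def statmap_mean(center, stat: Volume3D, sphere: SphereSpec | None = None) -> float:
    """Mean statistical-map value in the sphere (NaN voxels excluded)."""
    if sphere is None:
        sphere = SphereSpec(STATMAP_RADIUS_MM)
    vox = sphere_voxels(center, stat, sphere)
    if vox.size == 0:
        warnings.warn(
            f"statmap sphere around {np.asarray(center)} is outside the volume",
            stacklevel=2,
        )
        return float("nan")
    vals = np.asarray(stat.data[vox[:, 0], vox[:, 1], vox[:, 2]], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        warnings.warn("statmap sphere contains only NaN voxels", stacklevel=2)
        return float("nan")
    return float(vals.mean())


def resection_flag(center, resection: Volume3D) -> bool:
    """True iff the voxel containing ``center`` is inside the resection mask."""
    idx = np.rint(world_to_voxel(center, resection)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(resection.shape)):
        return False
    return bool(resection.data[idx[0], idx[1], idx[2]] == 1)


def label_all(
    electrodes: list[PlacedElectrode],
    atlases: dict[str, tuple[Volume3D, LabelLookup]],
    tissue: Volume3D | None = None,
    resection: Volume3D | None = None,
    statmaps: dict[str, Volume3D] | None = None,
    atlas_sphere: SphereSpec | None = None,
    statmap_sphere: SphereSpec | None = None,
) -> list[ContactLabels]:
    """Label every contact of every electrode; one row per contact.

    All volumes must share the pre-implantation grid (resample first
    otherwise).  Output is ordered by (electrode name, contact index) and is
    fully deterministic.
    """
    statmaps = statmaps or {}
    names = [e.electrode_name for e in electrodes]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate electrode names")
    ref: Volume3D | None = None
    for label, vol in (
        [(f"atlas {a}", v) for a, (v, _) in atlases.items()]
        + ([("tissue", tissue)] if tissue is not None else [])
        + ([("resection", resection)] if resection is not None else [])
        + [(f"statmap {s}", v) for s, v in statmaps.items()]
    ):
        if ref is None:
            ref = vol
        else:
            ref.require_same_grid(vol, label)
    if ref is None:
        raise ValidationError("no volumes to label against")

    rows: list[ContactLabels] = []
    for elec in sorted(electrodes, key=lambda e: e.electrode_name):
        for ci in range(1, elec.n_contacts + 1):
            center = elec.contact(ci)
            row = ContactLabels(electrode_name=elec.electrode_name, contact_index=ci)
            for atlas_name in sorted(atlases):
                vol, lookup = atlases[atlas_name]
                row.atlas_labels[atlas_name] = label_atlas(
                    center, vol, lookup, tissue=tissue, sphere=atlas_sphere
                )
            if tissue is not None:
                row.tissue = label_tissue(center, tissue, sphere=atlas_sphere)
            for stat_name in sorted(statmaps):
                row.statmap_means[stat_name] = statmap_mean(
                    center, statmaps[stat_name], sphere=statmap_sphere
                )
            if resection is not None:
                row.in_resection = resection_flag(center, resection)
            rows.append(row)
    return rows


def labels_to_dataframe(rows: list[ContactLabels]) -> pd.DataFrame:
    """Flatten contact labels to a table (one column pair per atlas)."""
    atlas_names = sorted({a for r in rows for a in r.atlas_labels})
    stat_names = sorted({s for r in rows for s in r.statmap_means})
    records = []
    for r in rows:
        rec: dict = {"electrode": r.electrode_name, "contact": r.contact_index}
        for a in atlas_names:
            lab, name = r.atlas_labels.get(a, (0, "unlabeled"))
            rec[f"{a}_label"] = lab
            rec[f"{a}_name"] = name
        rec["tissue"] = r.tissue
        rec["in_resection"] = r.in_resection
        for s in stat_names:
            rec[f"statmap_{s}"] = r.statmap_means.get(s, float("nan"))
        records.append(rec)
    return pd.DataFrame.from_records(records)
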