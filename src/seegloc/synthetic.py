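"""Deterministic synthetic heads, atlases, implantations and cohorts.

Every other module of the package operates on clinical images that cannot
ship with the code.  This module generates structurally equivalent synthetic
stand-ins, fully determined by a :class:`FixtureSpec` (including its seed):

* an ellipsoidal "brain" with nested CSF / gray-matter / white-matter
  shells and its binary brain mask;
* a gray-matter parcellation splitting the GM shell into angular wedges per
  hemisphere, with a label lookup table;
* straight electrode implantations aimed at parcel centroids (mimicking
  clinical targeting of specific regions), with per-contact ground truth;
* post-operative masks with a rectangular block carved out;
* whole cohorts of patient records with stimulation events, Engel classes,
  resection reports, MNI coordinates, and planted QC outliers.

Default sizes emulate a typical SEEG implantation: 12 electrodes of 15
contacts (180 contacts per patient), 20-patient cohorts with a 10% rate of
planted normalization failures.  The geometry is schematic — no MRI
intensities, no gyri, a GM shell thicker than real cortex so that 3 mm
label spheres fit inside single parcels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contact_labeling import ATLAS_RADIUS_MM, ContactLabels, SphereSpec, label_all, sphere_voxels
from .cohort_db import (
    ENGEL_CLASSES,
    RESPONSE_CATEGORIES,
    RESPONSE_CLASSIFICATIONS,
    STIM_FREQUENCIES_HZ,
    CohortStore,
    PatientRecord,
    StimulationEvent,
)
from .electrode_geometry import (
    ElectrodeModel,
    PlacedElectrode,
    Trajectory,
    default_catalog,
    place_electrode,
)
from .errors import ValidationError
from .io_core import (
    TISSUE_CSF,
    TISSUE_GM,
    TISSUE_WM,
    LabelLookup,
    Volume3D,
)
from .resection_analysis import OverlapReport, ParcelOverlap

__all__ = [
    "FixtureSpec",
    "make_head",
    "make_atlas",
    "make_implantation",
    "make_postop",
    "make_cohort",
    "CohortTruth",
]

# normalized ellipsoid radii delimiting the tissue shells; the GM shell is
# deliberately much thicker than real cortex so that (a) 3 mm label spheres
# fit inside single parcels and (b) several consecutive contacts of each
# electrode land in its target parcel, giving parcel clouds whose spatial
# spread dominates the per-patient MNI jitter
_WM_FRAC = 0.40
_GM_FRAC = 0.92
_BRAIN_SEMIAXIS_FRAC = 0.45  # semi-axes as a fraction of the grid extent


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world; the seed fixes every output."""

    shape: tuple[int, int, int] = (72, 72, 72)
    voxel_size_mm: float = 1.0
    seed: int = 0
    n_parcels: int = 16
    n_electrodes: int = 12
    n_contacts: int = 15
    resection_corner: tuple[int, int, int] = (36, 30, 30)
    resection_size: tuple[int, int, int] = (8, 8, 8)
    n_patients: int = 20
    outlier_rate: float = 0.1
    mni_jitter_mm: float = 2.0
    outlier_shift_mm: float = 40.0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ValidationError("grid too small: need >= 16 voxels per axis")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        if self.n_parcels < 2 or self.n_parcels % 2:
            raise ValidationError("n_parcels must be an even integer >= 2")
        if not 0 <= self.outlier_rate <= 1:
            raise ValidationError("outlier_rate must be in [0, 1]")
        if self.n_electrodes < 1 or self.n_contacts < 1 or self.n_patients < 1:
            raise ValidationError("counts must be positive")


def _affine(spec: FixtureSpec) -> np.ndarray:
    """Isotropic RAS affine placing the world origin at the grid center."""
    a = np.eye(4)
    a[:3, :3] *= spec.voxel_size_mm
    a[:3, 3] = -(np.array(spec.shape) - 1) / 2.0 * spec.voxel_size_mm
    return a


def _semi_axes(spec: FixtureSpec) -> np.ndarray:
    return np.array(spec.shape) * spec.voxel_size_mm * _BRAIN_SEMIAXIS_FRAC


def _normalized_radius(spec: FixtureSpec) -> np.ndarray:
    """Per-voxel normalized ellipsoid radius (1.0 = brain surface)."""
    affine = _affine(spec)
    idx = np.indices(spec.shape, dtype=float)
    world = np.einsum("ij,jabc->iabc", affine[:3, :3], idx) + affine[:3, 3][:, None, None, None]
    semi = _semi_axes(spec)
    return np.sqrt(np.sum((world / semi[:, None, None, None]) ** 2, axis=0))


def make_head(spec: FixtureSpec) -> tuple[Volume3D, Volume3D]:
    """Synthetic tissue volume and brain mask.

    The brain is the ellipsoid of normalized radius <= 1; within it, white
    matter occupies r <= 0.60, gray matter 0.60 < r <= 0.92 and CSF the
    outermost shell.  Deterministic (the seed matters only downstream).
    """
    r = _normalized_radius(spec)
    affine = _affine(spec)
    mask = (r <= 1.0).astype(np.int16)
    tissue = np.zeros(spec.shape, dtype=np.int16)
    tissue[(r <= 1.0)] = TISSUE_CSF
    tissue[(r <= _GM_FRAC)] = TISSUE_GM
    tissue[(r <= _WM_FRAC)] = TISSUE_WM
    return (
        Volume3D(data=tissue, affine=affine, kind="tissue"),
        Volume3D(data=mask, affine=affine, kind="mask"),
    )


def make_atlas(
    tissue: Volume3D, n_parcels: int, seed: int = 0
) -> tuple[Volume3D, LabelLookup]:
    """Partition the GM shell into angular wedge parcels, split by hemisphere.

    Each hemisphere (world x < 0 -> L, x >= 0 -> R) is cut into
    ``n_parcels // 2`` wedges by the azimuth angle around the x axis, with a
    seeded angular offset.  Labels are 1..n_parcels, names ``P01_L``,
    ``P01_R``, ...; every nonzero voxel is gray matter and the parcels
    partition GM exactly.
    """
    if n_parcels < 2 or n_parcels % 2:
        raise ValidationError("n_parcels must be an even integer >= 2")
    gm = tissue.data == TISSUE_GM
    n_gm = int(gm.sum())
    if n_parcels > n_gm:
        raise ValidationError(f"n_parcels={n_parcels} exceeds GM voxel count {n_gm}")
    idx = np.argwhere(gm)
    world = idx @ tissue.affine[:3, :3].T + tissue.affine[:3, 3]
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0, 2 * math.pi)
    m = n_parcels // 2
    phi = np.mod(np.arctan2(world[:, 2], world[:, 1]) - phi0, 2 * math.pi)
    wedge = np.minimum((phi / (2 * math.pi) * m).astype(int), m - 1)
    right = world[:, 0] >= 0
    labels = 2 * wedge + 1 + right.astype(int)  # pair k -> 2k+1 (L), 2k+2 (R)
    data = np.zeros(tissue.shape, dtype=np.int32)
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = labels
    lookup = LabelLookup(atlas_name="synthatlas", cortical=True)
    for k in range(m):
        lookup.add(2 * k + 1, f"P{k + 1:02d}_L", "L")
        lookup.add(2 * k + 2, f"P{k + 1:02d}_R", "R")
    return Volume3D(data=data, affine=tissue.affine.copy(), kind="atlas"), lookup


_ELECTRODE_LETTERS = "ABCDEFGHJKLMNOPRSTUVWXYZ"


def _ellipsoid_radius_along(direction: np.ndarray, semi: np.ndarray) -> float:
    """Distance from the center to the ellipsoid surface along ``direction``."""
    return 1.0 / math.sqrt(float(np.sum((direction / semi) ** 2)))


def make_implantation(
    atlas: Volume3D,
    lookup: LabelLookup,
    spec: FixtureSpec,
    model: ElectrodeModel | None = None,
) -> tuple[list[PlacedElectrode], dict[tuple[str, int], str]]:
    """Plant straight electrodes aimed at parcel centroids.

    Each electrode targets a distinct parcel: its trajectory runs from deep
    near the brain center out through the parcel's GM centroid, entering
    through the brain surface (the clinical pattern of targeting chosen
    regions).  Contact 1 (the tip) is deepest.

    Returns the placed electrodes and a ground-truth map: for each contact
    whose 3 mm sphere lies entirely within one parcel, the parcel name;
    otherwise ``"mixed"``.  Raises if electrodes cannot be placed without
    their contacts overlapping after 1000 attempts.
    """
    if model is None:
        model = next(
            m for m in default_catalog() if m.n_contacts == spec.n_contacts
        )
    labels = lookup.labels()
    if spec.n_electrodes > len(labels):
        raise ValidationError(
            f"cannot target {spec.n_electrodes} distinct parcels with "
            f"{len(labels)} available"
        )
    semi = _semi_axes(spec)
    centroids = {}
    for lab in labels:
        vox = np.argwhere(atlas.data == lab)
        centroids[lab] = vox.mean(axis=0) @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]

    min_sep = 2.0 * model.diameter_mm
    for attempt in range(1000):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        targets = rng.choice(labels, size=spec.n_electrodes, replace=False)
        electrodes = []
        truth: dict[tuple[str, int], str] = {}
        all_centers = []
        for i, lab in enumerate(targets):
            direction = centroids[lab] / np.linalg.norm(centroids[lab])
            surface_r = _ellipsoid_radius_along(direction, semi)
            tip_r = rng.uniform(0.08, 0.15) * surface_r
            tip = direction * tip_r
            shaft = direction * (tip_r + 30.0)
            hemi = lookup.entries[int(lab)].hemisphere
            name = _ELECTRODE_LETTERS[i % len(_ELECTRODE_LETTERS)] + (
                "'" if hemi == "L" else ""
            )
            electrodes.append(place_electrode(model, Trajectory(tip, shaft), name))
            all_centers.append(electrodes[-1].contact_centers)
        ok = True
        for a in range(len(electrodes)):
            for b in range(a + 1, len(electrodes)):
                d = np.linalg.norm(
                    all_centers[a][:, None, :] - all_centers[b][None, :, :], axis=2
                )
                if d.min() < min_sep:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            for elec in electrodes:
                for ci in range(1, elec.n_contacts + 1):
                    vox = sphere_voxels(
                        elec.contact(ci), atlas, SphereSpec(ATLAS_RADIUS_MM)
                    )
                    if vox.size == 0:
                        truth[(elec.electrode_name, ci)] = "mixed"
                        continue
                    vals = np.unique(atlas.data[vox[:, 0], vox[:, 1], vox[:, 2]])
                    if len(vals) == 1 and vals[0] != 0:
                        truth[(elec.electrode_name, ci)] = lookup.name(int(vals[0]))
                    else:
                        truth[(elec.electrode_name, ci)] = "mixed"
            return electrodes, truth
    raise ValidationError(
        "could not place electrodes without contact overlap after 1000 attempts"
    )


def make_postop(
    brain_mask: Volume3D,
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
) -> tuple[Volume3D, Volume3D]:
    """Carve a rectangular block out of the brain mask.

    Returns ``(post_op_mask, truth_resection_mask)`` where the truth mask is
    the intersection of the block with the pre-operative brain.
    """
    corner = np.asarray(corner, dtype=int)
    size = np.asarray(size, dtype=int)
    if np.any(size <= 0):
        raise ValidationError("resection block size must be positive")
    if np.any(corner < 0) or np.any(corner + size > np.array(brain_mask.shape)):
        raise ValidationError("resection block extends outside the volume")
    block = np.zeros(brain_mask.shape, dtype=bool)
    block[
        corner[0] : corner[0] + size[0],
        corner[1] : corner[1] + size[1],
        corner[2] : corner[2] + size[2],
    ] = True
    truth = block & (brain_mask.data == 1)
    if not truth.any():
        raise ValidationError("resection block does not intersect the brain")
    post = (brain_mask.data == 1) & ~block
    return (
        Volume3D(post.astype(np.int16), brain_mask.affine.copy(), "mask"),
        Volume3D(truth.astype(np.int16), brain_mask.affine.copy(), "mask"),
    )


@dataclass
class CohortTruth:
    """Everything the cohort generator planted, for oracle comparisons."""

    outlier_patients: list[str]
    scenario_parcel: str  # parcel used for the contact+resection query scenario
    scenario_expected: list[str]  # patients matching that scenario
    resected_by_patient: dict[str, dict[str, float]]  # pid -> parcel name -> percent
    template_labels: list[ContactLabels]
    template_truth: dict[tuple[str, int], str]
    mni_by_patient: dict[str, dict[tuple[str, int], tuple[float, float, float]]] = field(
        default_factory=dict
    )


_CENTERS = ("CenterA", "CenterB", "CenterC")


def make_cohort(
    spec: FixtureSpec, store_path: str = ":memory:"
) -> tuple[CohortStore, CohortTruth]:
    """Generate a cohort of patients sharing one implantation template.

    All patients carry the same synthetic implantation and contact labels
    (as if implanted with the same stereotactic plan); their MNI contact
    coordinates are the template positions displaced by a patient-level
    Gaussian offset (sigma ``mni_jitter_mm``), emulating normalization
    variability.  ``ceil(outlier_rate * n_patients)`` patients additionally
    get a ``outlier_shift_mm`` shift along +x — planted normalization
    failures that group QC should flag.  Engel classes, stimulation events
    and per-parcel resection percentages are drawn from the closed
    vocabularies.  One parcel is reserved as a query scenario: exactly one
    patient has it partially resected, so (contact in parcel) AND (parcel
    resected) identifies that patient alone.
    """
    tissue, brain = make_head(spec)
    atlas, lookup = make_atlas(tissue, spec.n_parcels, seed=spec.seed)
    electrodes, truth_map = make_implantation(atlas, lookup, spec)
    template_labels = label_all(
        electrodes, atlases={lookup.atlas_name: (atlas, lookup)}, tissue=tissue
    )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9001]))
    n_out = math.ceil(spec.outlier_rate * spec.n_patients)
    ids = [f"P{i:03d}" for i in range(spec.n_patients)]
    outliers = sorted(rng.choice(ids, size=n_out, replace=False).tolist())

    # parcels actually carrying labeled contacts, for resection draws
    contact_parcels = sorted(
        {
            name
            for cl in template_labels
            for (_, name) in cl.atlas_labels.values()
            if name != "unlabeled"
        }
    )
    if not contact_parcels:
        raise ValidationError("template implantation labeled no contacts")
    scenario_parcel = contact_parcels[0]
    other_parcels = [p for p in contact_parcels if p != scenario_parcel]

    store = CohortStore(store_path)
    truth = CohortTruth(
        outlier_patients=outliers,
        scenario_parcel=scenario_parcel,
        scenario_expected=[ids[0]],
        resected_by_patient={},
        template_labels=template_labels,
        template_truth=truth_map,
    )

    centers_world = {
        (e.electrode_name, ci): e.contact(ci)
        for e in electrodes
        for ci in range(1, e.n_contacts + 1)
    }

    for i, pid in enumerate(ids):
        offset = rng.normal(0.0, spec.mni_jitter_mm, size=3)
        if pid in outliers:
            # a broken normalization displaces in a generic 3D direction;
            # the diagonal keeps the shift magnitude at outlier_shift_mm
            offset = offset + spec.outlier_shift_mm * np.ones(3) / math.sqrt(3.0)
        # MNI frame == fixture world frame (fixed identity affine)
        mni = {
            key: tuple(np.asarray(pos, dtype=float) + offset)
            for key, pos in centers_world.items()
        }
        truth.mni_by_patient[pid] = mni

        resected: dict[str, float] = {}
        if i == 0:
            resected[scenario_parcel] = 30.0
        n_res = int(rng.integers(0, 3))
        if other_parcels and n_res:
            for name in rng.choice(other_parcels, size=min(n_res, len(other_parcels)), replace=False):
                resected[str(name)] = float(np.round(rng.uniform(5.0, 80.0), 1))
        truth.resected_by_patient[pid] = resected

        report = None
        if resected:
            report = OverlapReport(total_volume_mm3=float(np.round(rng.uniform(500, 5000), 1)))
            for name, pct in sorted(resected.items()):
                lab = lookup.label_of(name)
                n_parcel = int(np.sum(atlas.data == lab))
                report.per_parcel.append(
                    ParcelOverlap(
                        atlas=lookup.atlas_name,
                        label=lab,
                        name=name,
                        parcel_voxels=n_parcel,
                        resected_voxels=int(round(n_parcel * pct / 100.0)),
                        percent_removed=pct,
                    )
                )

        events = []
        n_stim = int(rng.integers(2, 6))
        for _ in range(n_stim):
            elec = electrodes[int(rng.integers(0, len(electrodes)))]
            a = int(rng.integers(1, elec.n_contacts))
            category = str(rng.choice(RESPONSE_CATEGORIES))
            if category == "not_stimulated":
                classifications: tuple[str, ...] = ()
                intensity = None
            else:
                k = int(rng.integers(0, 3))
                classifications = tuple(
                    sorted(rng.choice(RESPONSE_CLASSIFICATIONS, size=k, replace=False))
                ) if k else ()
                intensity = float(np.round(rng.uniform(0.5, 3.0), 1))
            events.append(
                StimulationEvent(
                    electrode=elec.electrode_name,
                    contact_a=a,
                    contact_b=a + 1,
                    frequency_hz=int(rng.choice(STIM_FREQUENCIES_HZ)),
                    intensity_ma=intensity,
                    response_category=category,
                    classifications=classifications,
                )
            )

        rec = PatientRecord(
            patient_id=pid,
            center=_CENTERS[i % len(_CENTERS)],
            year=int(2008 + rng.integers(0, 10)),
            engel_class=str(rng.choice(ENGEL_CLASSES[:4])) if rng.random() > 0.1 else "unknown",
            electrodes=[replace_electrode(e) for e in electrodes],
            contact_labels=[
                ContactLabels(
                    electrode_name=cl.electrode_name,
                    contact_index=cl.contact_index,
                    atlas_labels=dict(cl.atlas_labels),
                    tissue=cl.tissue,
                    statmap_means=dict(cl.statmap_means),
                    in_resection=cl.in_resection,
                )
                for cl in template_labels
            ],
            overlap_report=report,
            stimulation_events=events,
            mni_coords=mni,
        )
        store.add_patient(rec)
    return store, truth


def replace_electrode(e: PlacedElectrode) -> PlacedElectrode:
    """Deep-ish copy so records never share mutable arrays."""
    return PlacedElectrode(
        electrode_name=e.electrode_name,
        model=e.model,
        contact_centers=e.contact_centers.copy(),
    )
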