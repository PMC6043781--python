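"""Volumetric I/O, affine coordinate handling and nearest-neighbor resampling.

All spatial data in the package lives in :class:`Volume3D`: a 3D scalar grid
plus a 4x4 voxel-index -> world-mm affine (NIfTI convention: the affine maps
0-based voxel *centers* to RAS-oriented world millimeters).  Four kinds of
volume are distinguished and validated on construction:

``atlas``
    non-negative integer parcel labels, 0 = unlabeled;
``tissue``
    tissue classes 0 = background, 1 = CSF, 2 = gray matter, 3 = white matter;
``mask``
    binary {0, 1};
``statmap``
    arbitrary floats (e.g. epileptogenicity or PET values).

Rigid world->world transforms (e.g. post-operative -> pre-implantation frame,
estimated externally by a registration tool) are plain 4x4 matrices stored as
text files; they are inputs here, never estimated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, ValidationError

__all__ = [
    "VOLUME_KINDS",
    "TISSUE_BACKGROUND",
    "TISSUE_CSF",
    "TISSUE_GM",
    "TISSUE_WM",
    "TISSUE_NAMES",
    "Volume3D",
    "LabelEntry",
    "LabelLookup",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_label_lookup",
    "write_label_lookup",
    "voxel_to_world",
    "world_to_voxel",
    "resample_nearest",
]

VOLUME_KINDS = ("atlas", "tissue", "mask", "statmap")

TISSUE_BACKGROUND = 0
TISSUE_CSF = 1
TISSUE_GM = 2
TISSUE_WM = 3
TISSUE_NAMES = {TISSUE_CSF: "CSF", TISSUE_GM: "GM", TISSUE_WM: "WM"}

_ORTHO_TOL = 1e-6


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel->world affine.

    Parameters
    ----------
    data
        3D array. Integer-valued for ``atlas``/``tissue``/``mask`` kinds.
    affine
        4x4 matrix mapping 0-based voxel indices (voxel centers) to world mm.
    kind
        One of ``atlas``, ``tissue``, ``mask``, ``statmap``.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"Volume3D requires 3D data, got {self.data.ndim}D shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0.0:
            raise ValidationError("affine 3x3 part is singular")
        if self.kind not in VOLUME_KINDS:
            raise ValidationError(
                f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}"
            )
        self._check_values()
        if self.kind != "statmap":
            self.data = np.asarray(np.rint(self.data), dtype=np.int32)

    def _check_values(self) -> None:
        if self.kind == "statmap":
            return
        vals = np.unique(self.data)
        if self.kind == "mask":
            bad = vals[~np.isin(vals, (0, 1))]
        elif self.kind == "tissue":
            bad = vals[~np.isin(vals, (0, 1, 2, 3))]
        else:  # atlas
            bad = vals[(vals < 0) | (vals != np.rint(vals))]
        if bad.size:
            raise ValidationError(
                f"{self.kind} volume contains out-of-range value {bad[0]!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's 3x3 part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Length in mm of each voxel edge (column norms of the 3x3 part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "Volume3D", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume3D", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} is not on the same grid: shapes {self.shape} vs {other.shape}"
            )


@dataclass(frozen=True)
class LabelEntry:
    name: str
    hemisphere: str  # "L", "R" or "none"
    atlas_name: str


@dataclass
class LabelLookup:
    """Label-integer -> (name, hemisphere) table for one atlas.

    ``cortical`` marks atlases whose parcels live in gray matter (MarsAtlas,
    Destrieux, Brodmann style); contact labeling restricts the majority vote
    to GM voxels for those atlases only.
    """

    atlas_name: str
    entries: dict[int, LabelEntry] = field(default_factory=dict)
    cortical: bool = True

    def __post_init__(self) -> None:
        if 0 in self.entries:
            raise ValidationError("label 0 is reserved for 'unlabeled'")
        names = [e.name for e in self.entries.values()]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate parcel names in atlas {self.atlas_name}")

    def add(self, label: int, name: str, hemisphere: str = "none") -> None:
        if label == 0:
            raise ValidationError("label 0 is reserved for 'unlabeled'")
        if hemisphere not in ("L", "R", "none"):
            raise ValidationError(f"bad hemisphere {hemisphere!r}")
        self.entries[int(label)] = LabelEntry(name, hemisphere, self.atlas_name)

    def name(self, label: int) -> str:
        if label == 0:
            return "unlabeled"
        try:
            return self.entries[int(label)].name
        except KeyError:
            raise ValidationError(
                f"label {label} not in lookup for atlas {self.atlas_name}"
            ) from None

    def label_of(self, name: str) -> int:
        for lab, e in self.entries.items():
            if e.name == name:
                return lab
        raise ValidationError(f"parcel {name!r} unknown in atlas {self.atlas_name}")

    def labels(self) -> list[int]:
        return sorted(self.entries)


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (rotation + translation) world-mm -> world-mm transform."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (4, 4):
            raise ValidationError(f"transform must be 4x4, got {m.shape}")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValidationError("transform 3x3 part is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValidationError("transform determinant is negative (reflection)")
        if not np.allclose(m[3], (0, 0, 0, 1), atol=_ORTHO_TOL):
            raise ValidationError("transform last row must be [0, 0, 0, 1]")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: np.ndarray
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single triple) of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out


# ---------------------------------------------------------------------------
# NIfTI and text-file I/O


def read_volume(path: str | Path, kind: str) -> Volume3D:
    """Read a single-frame 3D NIfTI-1 image as a :class:`Volume3D`.

    The affine is the header's voxel->world mapping; value constraints of
    ``kind`` are verified (a tissue volume containing 7, say, is rejected).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(
            f"{path.name}: expected a 3D volume, got shape {data.shape}"
        )
    return Volume3D(data=data, affine=np.asarray(img.affine), kind=kind)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a :class:`Volume3D` as NIfTI-1 (.nii or .nii.gz)."""
    if vol.kind == "statmap":
        data = np.asarray(vol.data, dtype=np.float32)
    else:
        data = np.asarray(vol.data, dtype=np.int16)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def read_label_lookup(path: str | Path) -> LabelLookup:
    """Read a TSV lookup: ``label<TAB>name<TAB>hemisphere<TAB>atlas``.

    Header comment lines start with ``#``; ``# cortical: false`` marks a
    non-cortical (whole-brain) atlas.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    cortical = True
    rows: list[tuple[int, str, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta = line.lstrip("#").strip().lower()
            if meta.startswith("cortical"):
                cortical = meta.split(":", 1)[1].strip() in ("true", "yes", "1")
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(f"{path.name}:{lineno}: expected 4 TSV columns")
        rows.append((int(parts[0]), parts[1], parts[2], parts[3]))
    if not rows:
        raise ValidationError(f"{path.name}: empty lookup table")
    atlases = {r[3] for r in rows}
    if len(atlases) != 1:
        raise ValidationError(f"{path.name}: mixed atlas names {sorted(atlases)}")
    lookup = LabelLookup(atlas_name=rows[0][3], cortical=cortical)
    for label, name, hemi, _ in rows:
        lookup.add(label, name, hemi)
    return lookup


def write_label_lookup(lookup: LabelLookup, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(f"# atlas: {lookup.atlas_name}\n")
    buf.write(f"# cortical: {'true' if lookup.cortical else 'false'}\n")
    for label in lookup.labels():
        e = lookup.entries[label]
        buf.write(f"{label}\t{e.name}\t{e.hemisphere}\t{lookup.atlas_name}\n")
    Path(path).write_text(buf.getvalue())


def read_transform(path: str | Path) -> RigidTransform:
    """Read a 4x4 transform from a plain-text file (one row per line).

    Lines starting with ``#`` are comments; by convention the header states
    the direction (target world -> source world for resampling).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    rows = [
        [float(x) for x in line.split()]
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise ValidationError(f"{path.name}: expected a 4x4 matrix")
    return RigidTransform(np.asarray(rows))


def write_transform(t: RigidTransform, path: str | Path, comment: str | None = None) -> None:
    lines = []
    lines.append("# rigid transform, world mm -> world mm")
    lines.append("# direction: target grid world -> source image world")
    if comment:
        lines.append(f"# {comment}")
    for row in t.matrix:
        lines.append(" ".join(f"{x:.17g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coordinate transforms and resampling


def voxel_to_world(v, vol: Volume3D) -> np.ndarray:
    """Map (possibly fractional) voxel indices to world mm via the affine."""
    pts = np.atleast_2d(np.asarray(v, dtype=float))
    out = pts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if np.asarray(v).ndim == 1 else out


def world_to_voxel(w, vol: Volume3D) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_world` (fractional indices)."""
    inv = np.linalg.inv(vol.affine)
    pts = np.atleast_2d(np.asarray(w, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(w).ndim == 1 else out


def resample_nearest(
    src: Volume3D, target_grid: Volume3D, t: RigidTransform | None = None
) -> Volume3D:
    """Resample ``src`` onto ``target_grid`` by nearest neighbor.

    ``t`` maps *target* world coordinates into the *source* image's world
    frame (identity if omitted).  Each output voxel takes the value of the
    source voxel whose center is nearest to the mapped point; points falling
    outside the source grid get 0 (background / unlabeled), never an edge
    clamp.  Intended for labels and masks; no interpolation of intensities.
    """
    if t is None:
        t = RigidTransform.identity()
    # target index -> target world -> src world -> src index, one 4x4 matrix
    m = np.linalg.inv(src.affine) @ t.matrix @ target_grid.affine
    nx, ny, nz = target_grid.shape
    idx = np.indices((nx, ny, nz), dtype=float).reshape(3, -1)
    src_idx = m[:3, :3] @ idx + m[:3, 3:4]
    src_idx = np.rint(src_idx).astype(np.int64)
    inb = np.ones(src_idx.shape[1], dtype=bool)
    for ax, n in enumerate(src.shape):
        inb &= (src_idx[ax] >= 0) & (src_idx[ax] < n)
    out = np.zeros(src_idx.shape[1], dtype=src.data.dtype)
    out[inb] = src.data[src_idx[0, inb], src_idx[1, inb], src_idx[2, inb]]
    return Volume3D(
        data=out.reshape(nx, ny, nz),
        affine=target_grid.affine.copy(),
        kind=src.kind,
    )
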