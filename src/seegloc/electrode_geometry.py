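"""Parametric depth-electrode models and contact placement along trajectories.

A depth electrode is modeled as an ordered list of contact segments.  Each
segment is ``(n_contacts, contact_length_mm, gap_after_mm)``: ``n_contacts``
cylindrical contacts of length ``contact_length_mm``, each followed by an
insulating gap of ``gap_after_mm`` (the gap after a segment's last contact
separates it from the next segment; the trailing gap of the final segment is
ignored).  This encodes both regular electrodes (one segment) and
grouped-contact layouts (several segments with a wider inter-group gap)
without per-manufacturer code.

An implantation trajectory is two clicked points: the electrode tip (deepest
point) and any other point along the shaft.  Contact 1 starts at the tip
(plus an optional ``tip_offset_mm`` for models whose first contact is
recessed) and contacts are numbered from the tip outward, matching the
clinical convention that contact 1 is the deepest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = [
    "ContactSegment",
    "ElectrodeModel",
    "Trajectory",
    "PlacedElectrode",
    "load_model_catalog",
    "default_catalog",
    "place_electrode",
    "electrode_length",
    "save_electrodes",
    "load_electrodes",
]

_MIN_TRAJECTORY_MM = 1e-6


@dataclass(frozen=True)
class ContactSegment:
    n_contacts: int
    contact_length_mm: float
    gap_after_mm: float

    def __post_init__(self) -> None:
        if int(self.n_contacts) < 1 or self.n_contacts != int(self.n_contacts):
            raise ValidationError(f"n_contacts must be a positive int, got {self.n_contacts}")
        if not (np.isfinite(self.contact_length_mm) and self.contact_length_mm > 0):
            raise ValidationError(f"contact_length_mm must be > 0, got {self.contact_length_mm}")
        if not (np.isfinite(self.gap_after_mm) and self.gap_after_mm >= 0):
            raise ValidationError(f"gap_after_mm must be >= 0, got {self.gap_after_mm}")


@dataclass(frozen=True)
class ElectrodeModel:
    model_name: str
    diameter_mm: float
    segments: tuple[ContactSegment, ...]
    tip_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.model_name:
            raise ValidationError("model_name must be non-empty")
        if not (np.isfinite(self.diameter_mm) and self.diameter_mm > 0):
            raise ValidationError(
                f"model {self.model_name}: diameter_mm must be > 0, got {self.diameter_mm}"
            )
        if not self.segments:
            raise ValidationError(f"model {self.model_name}: at least one segment required")
        object.__setattr__(self, "segments", tuple(self.segments))
        if not (np.isfinite(self.tip_offset_mm) and self.tip_offset_mm >= 0):
            raise ValidationError(
                f"model {self.model_name}: tip_offset_mm must be >= 0, got {self.tip_offset_mm}"
            )

    @property
    def n_contacts(self) -> int:
        return sum(s.n_contacts for s in self.segments)

    def contact_center_offsets(self) -> np.ndarray:
        """Distance from the tip to each contact center, in contact order."""
        offsets = []
        pos = self.tip_offset_mm
        total = self.n_contacts
        k = 0
        for seg in self.segments:
            for _ in range(seg.n_contacts):
                offsets.append(pos + seg.contact_length_mm / 2.0)
                pos += seg.contact_length_mm
                k += 1
                if k < total:
                    pos += seg.gap_after_mm
        return np.asarray(offsets)


def electrode_length(model: ElectrodeModel) -> float:
    """Tip-to-end-of-last-contact length in mm (trailing gap excluded)."""
    offsets = model.contact_center_offsets()
    last_seg = model.segments[-1]
    return float(offsets[-1] + last_seg.contact_length_mm / 2.0)


@dataclass(frozen=True)
class Trajectory:
    """Two world-mm points defining the electrode axis.

    ``tip_point`` is the deepest end; ``shaft_point`` is any other point
    along the shaft, further from the tip in the exit direction.
    """

    tip_point: np.ndarray
    shaft_point: np.ndarray

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip_point, dtype=float)
        shaft = np.asarray(self.shaft_point, dtype=float)
        object.__setattr__(self, "tip_point", tip)
        object.__setattr__(self, "shaft_point", shaft)
        if tip.shape != (3,) or shaft.shape != (3,):
            raise ValidationError("trajectory points must be 3-vectors")
        if np.linalg.norm(shaft - tip) <= _MIN_TRAJECTORY_MM:
            raise ValidationError("degenerate trajectory: tip and shaft points coincide")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from the tip toward the shaft point."""
        d = self.shaft_point - self.tip_point
        return d / np.linalg.norm(d)


@dataclass
class PlacedElectrode:
    """An electrode instantiated along a trajectory; contact 1 is deepest."""

    electrode_name: str
    model: ElectrodeModel
    contact_centers: np.ndarray  # (n_contacts, 3) world mm, index 0 = contact 1

    def __post_init__(self) -> None:
        self.contact_centers = np.asarray(self.contact_centers, dtype=float)
        if self.contact_centers.shape != (self.model.n_contacts, 3):
            raise ValidationError(
                f"electrode {self.electrode_name}: expected "
                f"{self.model.n_contacts} contact centers"
            )

    @property
    def n_contacts(self) -> int:
        return self.model.n_contacts

    def contact(self, index: int) -> np.ndarray:
        """World position of 1-based contact ``index`` (1 = deepest)."""
        if not 1 <= index <= self.n_contacts:
            raise ValidationError(
                f"electrode {self.electrode_name} has contacts 1..{self.n_contacts}, "
                f"got {index}"
            )
        return self.contact_centers[index - 1]


def place_electrode(
    model: ElectrodeModel, traj: Trajectory, name: str
) -> PlacedElectrode:
    """Compute contact centers for ``model`` along ``traj``.

    Contact i's center lies at ``tip + u * (offset_i + L_i/2)`` where ``u``
    points from the tip toward the shaft point and ``offset_i`` accumulates
    preceding contact lengths and gaps (contact 1 starts at the tip).
    """
    u = traj.direction
    offsets = model.contact_center_offsets()
    centers = traj.tip_point[None, :] + offsets[:, None] * u[None, :]
    return PlacedElectrode(electrode_name=name, model=model, contact_centers=centers)


# ---------------------------------------------------------------------------
# Catalog I/O

def _model_from_dict(d: dict, where: str) -> ElectrodeModel:
    name = d.get("model_name")
    if not isinstance(name, str) or not name:
        raise ValidationError(f"{where}: missing or empty 'model_name'")
    if "diameter_mm" not in d:
        raise ValidationError(f"model {name}: missing field 'diameter_mm'")
    segs_raw = d.get("segments")
    if not isinstance(segs_raw, list) or not segs_raw:
        raise ValidationError(f"model {name}: 'segments' must be a non-empty list")
    segments = []
    for i, s in enumerate(segs_raw):
        for key in ("n_contacts", "contact_length_mm", "gap_after_mm"):
            if key not in s:
                raise ValidationError(f"model {name}: segment {i} missing field '{key}'")
        try:
            segments.append(
                ContactSegment(
                    n_contacts=s["n_contacts"],
                    contact_length_mm=float(s["contact_length_mm"]),
                    gap_after_mm=float(s["gap_after_mm"]),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"model {name}: segment {i}: {e}") from None
    return ElectrodeModel(
        model_name=name,
        diameter_mm=float(d["diameter_mm"]),
        segments=tuple(segments),
        tip_offset_mm=float(d.get("tip_offset_mm", 0.0)),
    )


def load_model_catalog(path: str | Path) -> list[ElectrodeModel]:
    """Load a JSON electrode-model catalog, validating every model."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    raw = json.loads(path.read_text())
    if not isinstance(raw, list):
        raise ValidationError(f"{path.name}: catalog must be a JSON array of models")
    return [_model_from_dict(d, f"{path.name}[{i}]") for i, d in enumerate(raw)]


def default_catalog() -> list[ElectrodeModel]:
    """The bundled catalog of illustrative electrode geometries.

    Dimensions are plausible depth-electrode layouts (2 mm contacts at
    3.5 mm pitch, etc.), NOT certified manufacturer specifications; supply
    your own catalog for clinical geometry.
    """
    raw = json.loads(
        resources.files("seegloc.data").joinpath("electrode_models.json").read_text()
    )
    return [_model_from_dict(d, f"builtin[{i}]") for i, d in enumerate(raw)]


def save_electrodes(electrodes: list[PlacedElectrode], path: str | Path) -> None:
    doc = [
        {
            "electrode_name": e.electrode_name,
            "model": {
                "model_name": e.model.model_name,
                "diameter_mm": e.model.diameter_mm,
                "tip_offset_mm": e.model.tip_offset_mm,
                "segments": [
                    {
                        "n_contacts": s.n_contacts,
                        "contact_length_mm": s.contact_length_mm,
                        "gap_after_mm": s.gap_after_mm,
                    }
                    for s in e.model.segments
                ],
            },
            "contact_centers": e.contact_centers.tolist(),
        }
        for e in electrodes
    ]
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_electrodes(path: str | Path) -> list[PlacedElectrode]:
    raw = json.loads(Path(path).read_text())
    out = []
    for i, d in enumerate(raw):
        model = _model_from_dict(d["model"], f"electrodes[{i}].model")
        out.append(
            PlacedElectrode(
                electrode_name=d["electrode_name"],
                model=model,
                contact_centers=np.asarray(d["contact_centers"], dtype=float),
            )
        )
    return out
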