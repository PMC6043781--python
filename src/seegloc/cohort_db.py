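"""Patient cohort store and multi-criteria queries.

One :class:`PatientRecord` bundles everything known about an implanted
patient: metadata (center, year of acquisition, Engel surgical-outcome
class), placed electrodes, per-contact anatomical labels, the resection
overlap report, stimulation responses and normalized (MNI) contact
coordinates.  Records are persisted in a single-file SQLite database with
normalized side tables so that multi-criteria queries (contact in parcel X
AND parcel X at least partially resected AND Engel I...) run as SQL; a
canonical JSON dump provides a portable, byte-stable export.

Stimulation semantics use explicit enumerated columns rather than the
spreadsheet color coding used clinically.  The color legend maps onto the
schema as follows — response categories (font color): gray = not_stimulated,
black = no_response (stimulated, no clinical observation), blue =
response_non_epileptic, red = seizure_like (response similar to a seizure
onset); response classifications (background color): red = motor, blue =
sensitive, green = sensory, yellow = vegetative, purple = emotional, pink =
experiential, brown = superior_function.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_labeling import ContactLabels
from .electrode_geometry import PlacedElectrode, _model_from_dict
from .errors import ValidationError
from .resection_analysis import OverlapReport, ParcelOverlap

__all__ = [
    "ENGEL_CLASSES",
    "STIM_FREQUENCIES_HZ",
    "RESPONSE_CATEGORIES",
    "RESPONSE_CLASSIFICATIONS",
    "StimulationEvent",
    "PatientRecord",
    "QueryCriteria",
    "CohortStore",
    "import_stim_table",
    "flip_left_right",
]

ENGEL_CLASSES = ("I", "II", "III", "IV", "unknown")
STIM_FREQUENCIES_HZ = (1, 50)
RESPONSE_CATEGORIES = (
    "not_stimulated",
    "no_response",
    "response_non_epileptic",
    "seizure_like",
)
RESPONSE_CLASSIFICATIONS = (
    "motor",
    "sensitive",
    "sensory",
    "vegetative",
    "emotional",
    "experiential",
    "superior_function",
)


@dataclass(frozen=True)
class StimulationEvent:
    """One bipolar stimulation of two adjacent contacts."""

    electrode: str
    contact_a: int
    contact_b: int
    frequency_hz: int
    response_category: str
    intensity_ma: float | None = None
    classifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(self.contact_a - self.contact_b) != 1:
            raise ValidationError(
                f"bipole {self.electrode}:{self.contact_a}-{self.contact_b} "
                "must use adjacent contacts"
            )
        if self.frequency_hz not in STIM_FREQUENCIES_HZ:
            raise ValidationError(
                f"stimulation frequency must be one of {STIM_FREQUENCIES_HZ} Hz, "
                f"got {self.frequency_hz}"
            )
        if self.response_category not in RESPONSE_CATEGORIES:
            raise ValidationError(f"unknown response category {self.response_category!r}")
        bad = [c for c in self.classifications if c not in RESPONSE_CLASSIFICATIONS]
        if bad:
            raise ValidationError(f"unknown response classification {bad[0]!r}")
        if self.intensity_ma is not None and not self.intensity_ma > 0:
            raise ValidationError(f"intensity_ma must be > 0, got {self.intensity_ma}")
        if self.response_category == "not_stimulated" and self.classifications:
            raise ValidationError("a not_stimulated bipole cannot carry classifications")
        object.__setattr__(self, "classifications", tuple(sorted(set(self.classifications))))


@dataclass
class PatientRecord:
    """One implanted patient with all derived labels and outcomes."""

    patient_id: str
    center: str
    year: int
    engel_class: str = "unknown"
    electrodes: list[PlacedElectrode] = field(default_factory=list)
    contact_labels: list[ContactLabels] = field(default_factory=list)
    overlap_report: OverlapReport | None = None
    stimulation_events: list[StimulationEvent] = field(default_factory=list)
    mni_coords: dict[tuple[str, int], tuple[float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not (1000 <= int(self.year) <= 9999):
            raise ValidationError(f"year must be a 4-digit integer, got {self.year}")
        if self.engel_class not in ENGEL_CLASSES:
            raise ValidationError(f"unknown Engel class {self.engel_class!r}")
        names = [e.electrode_name for e in self.electrodes]
        if len(names) != len(set(names)):
            raise ValidationError(f"patient {self.patient_id}: duplicate electrode names")
        n_by_elec = {e.electrode_name: e.n_contacts for e in self.electrodes}
        for ev in self.stimulation_events:
            self._check_contact(n_by_elec, ev.electrode, ev.contact_a)
            self._check_contact(n_by_elec, ev.electrode, ev.contact_b)
        for elec, contact in self.mni_coords:
            self._check_contact(n_by_elec, elec, contact)

    def _check_contact(self, n_by_elec: dict[str, int], elec: str, contact: int) -> None:
        if elec not in n_by_elec:
            raise ValidationError(
                f"patient {self.patient_id}: unknown electrode {elec!r}"
            )
        if not 1 <= contact <= n_by_elec[elec]:
            raise ValidationError(
                f"patient {self.patient_id}: contact {elec}{contact} out of range "
                f"1..{n_by_elec[elec]}"
            )

    # -- canonical (de)serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "center": self.center,
            "year": int(self.year),
            "engel_class": self.engel_class,
            "electrodes": [
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
                    "contact_centers": np.asarray(e.contact_centers).tolist(),
                }
                for e in self.electrodes
            ],
            "contact_labels": [
                {
                    "electrode": cl.electrode_name,
                    "contact": cl.contact_index,
                    "atlas_labels": {
                        a: [lab, name] for a, (lab, name) in sorted(cl.atlas_labels.items())
                    },
                    "tissue": cl.tissue,
                    "statmap_means": dict(sorted(cl.statmap_means.items())),
                    "in_resection": cl.in_resection,
                }
                for cl in self.contact_labels
            ],
            "overlap_report": self.overlap_report.to_dict() if self.overlap_report else None,
            "stimulation_events": [
                {
                    "electrode": ev.electrode,
                    "contact_a": ev.contact_a,
                    "contact_b": ev.contact_b,
                    "frequency_hz": ev.frequency_hz,
                    "intensity_ma": ev.intensity_ma,
                    "response_category": ev.response_category,
                    "classifications": list(ev.classifications),
                }
                for ev in self.stimulation_events
            ],
            "mni_coords": {
                f"{elec}|{contact}": list(map(float, xyz))
                for (elec, contact), xyz in sorted(self.mni_coords.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientRecord":
        electrodes = [
            PlacedElectrode(
                electrode_name=e["electrode_name"],
                model=_model_from_dict(e["model"], "record"),
                contact_centers=np.asarray(e["contact_centers"], dtype=float),
            )
            for e in d.get("electrodes", [])
        ]
        labels = [
            ContactLabels(
                electrode_name=cl["electrode"],
                contact_index=int(cl["contact"]),
                atlas_labels={
                    a: (int(v[0]), v[1]) for a, v in cl.get("atlas_labels", {}).items()
                },
                tissue=cl.get("tissue", "unlabeled"),
                statmap_means=dict(cl.get("statmap_means", {})),
                in_resection=bool(cl.get("in_resection", False)),
            )
            for cl in d.get("contact_labels", [])
        ]
        rep = None
        if d.get("overlap_report"):
            rd = d["overlap_report"]
            rep = OverlapReport(
                total_volume_mm3=float(rd["total_volume_mm3"]),
                brain_shift_unreliable=bool(rd.get("brain_shift_unreliable", True)),
                per_parcel=[
                    ParcelOverlap(
                        atlas=p["atlas"],
                        label=int(p["label"]),
                        name=p["name"],
                        parcel_voxels=int(p["parcel_voxels"]),
                        resected_voxels=int(p["resected_voxels"]),
                        percent_removed=float(p["percent_removed"]),
                    )
                    for p in rd.get("per_parcel", [])
                ],
            )
        events = [
            StimulationEvent(
                electrode=ev["electrode"],
                contact_a=int(ev["contact_a"]),
                contact_b=int(ev["contact_b"]),
                frequency_hz=int(ev["frequency_hz"]),
                intensity_ma=ev.get("intensity_ma"),
                response_category=ev["response_category"],
                classifications=tuple(ev.get("classifications", ())),
            )
            for ev in d.get("stimulation_events", [])
        ]
        mni = {}
        for key, xyz in d.get("mni_coords", {}).items():
            elec, contact = key.rsplit("|", 1)
            mni[(elec, int(contact))] = tuple(float(x) for x in xyz)
        return cls(
            patient_id=d["patient_id"],
            center=d["center"],
            year=int(d["year"]),
            engel_class=d.get("engel_class", "unknown"),
            electrodes=electrodes,
            contact_labels=labels,
            overlap_report=rep,
            stimulation_events=events,
            mni_coords=mni,
        )


@dataclass(frozen=True)
class QueryCriteria:
    """Conjunctive (AND) search criteria over the cohort.

    Every field is optional; an empty criteria object matches all patients.
    ``resected_parcel`` matches resections removing strictly more than
    ``resected_min_percent`` of the parcel ("at least partially" resected by
    default).  A stimulated bipole counts as being in a parcel if either of
    its contacts carries that parcel label (``stim_parcel_mode="both"``
    requires both).
    """

    center: str | None = None
    year_range: tuple[int, int] | None = None
    contact_in_parcel: tuple[str, str] | None = None  # (atlas, parcel name)
    resected_parcel: tuple[str, str] | None = None
    resected_min_percent: float = 0.0
    stimulated_parcel: tuple[str, str] | None = None
    stim_parcel_mode: str = "either"  # or "both"
    stim_frequency_hz: int | None = None
    stim_response_category: str | None = None
    stim_classification: str | None = None
    engel_classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.stim_parcel_mode not in ("either", "both"):
            raise ValidationError(f"bad stim_parcel_mode {self.stim_parcel_mode!r}")
        if self.stim_frequency_hz is not None and self.stim_frequency_hz not in STIM_FREQUENCIES_HZ:
            raise ValidationError(f"bad stimulation frequency {self.stim_frequency_hz}")
        if self.stim_response_category is not None and self.stim_response_category not in RESPONSE_CATEGORIES:
            raise ValidationError(f"bad response category {self.stim_response_category!r}")
        if self.stim_classification is not None and self.stim_classification not in RESPONSE_CLASSIFICATIONS:
            raise ValidationError(f"bad response classification {self.stim_classification!r}")
        if self.engel_classes is not None:
            bad = [e for e in self.engel_classes if e not in ENGEL_CLASSES]
            if bad:
                raise ValidationError(f"bad Engel class {bad[0]!r}")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS patients (
    patient_id TEXT PRIMARY KEY, center TEXT, year INTEGER, engel TEXT, doc TEXT);
CREATE TABLE IF NOT EXISTS contact_labels (
    patient_id TEXT, electrode TEXT, contact INTEGER, atlas TEXT,
    label INTEGER, name TEXT);
CREATE TABLE IF NOT EXISTS mni (
    patient_id TEXT, electrode TEXT, contact INTEGER, x REAL, y REAL, z REAL);
CREATE TABLE IF NOT EXISTS resected (
    patient_id TEXT, atlas TEXT, label INTEGER, name TEXT, percent REAL);
CREATE TABLE IF NOT EXISTS stim (
    patient_id TEXT, electrode TEXT, contact_a INTEGER, contact_b INTEGER,
    frequency INTEGER, intensity REAL, category TEXT, classifications TEXT);
CREATE INDEX IF NOT EXISTS idx_cl ON contact_labels (patient_id, atlas, name);
CREATE INDEX IF NOT EXISTS idx_res ON resected (patient_id, atlas, name);
"""


class CohortStore:
    """Single-file (or in-memory) SQLite-backed cohort of patient records."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM patients").fetchone()[0]

    def patient_ids(self) -> list[str]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT patient_id FROM patients ORDER BY patient_id"
            )
        ]

    def add_patient(self, rec: PatientRecord, overwrite: bool = False) -> None:
        cur = self._conn.execute(
            "SELECT 1 FROM patients WHERE patient_id = ?", (rec.patient_id,)
        )
        if cur.fetchone() is not None:
            if not overwrite:
                raise ValidationError(f"patient {rec.patient_id!r} already in store")
            self.remove_patient(rec.patient_id)
        doc = json.dumps(rec.to_dict(), sort_keys=True, separators=(",", ":"))
        with self._conn:
            self._conn.execute(
                "INSERT INTO patients VALUES (?,?,?,?,?)",
                (rec.patient_id, rec.center, int(rec.year), rec.engel_class, doc),
            )
            for cl in rec.contact_labels:
                for atlas, (lab, name) in cl.atlas_labels.items():
                    self._conn.execute(
                        "INSERT INTO contact_labels VALUES (?,?,?,?,?,?)",
                        (rec.patient_id, cl.electrode_name, cl.contact_index, atlas, lab, name),
                    )
            for (elec, contact), xyz in rec.mni_coords.items():
                self._conn.execute(
                    "INSERT INTO mni VALUES (?,?,?,?,?,?)",
                    (rec.patient_id, elec, contact, *map(float, xyz)),
                )
            if rec.overlap_report is not None:
                for p in rec.overlap_report.per_parcel:
                    self._conn.execute(
                        "INSERT INTO resected VALUES (?,?,?,?,?)",
                        (rec.patient_id, p.atlas, p.label, p.name, p.percent_removed),
                    )
            for ev in rec.stimulation_events:
                self._conn.execute(
                    "INSERT INTO stim VALUES (?,?,?,?,?,?,?,?)",
                    (
                        rec.patient_id,
                        ev.electrode,
                        ev.contact_a,
                        ev.contact_b,
                        ev.frequency_hz,
                        ev.intensity_ma,
                        ev.response_category,
                        ";" + ";".join(ev.classifications) + ";",
                    ),
                )

    def remove_patient(self, patient_id: str) -> None:
        with self._conn:
            for table in ("patients", "contact_labels", "mni", "resected", "stim"):
                self._conn.execute(
                    f"DELETE FROM {table} WHERE patient_id = ?", (patient_id,)
                )

    def get_patient(self, patient_id: str) -> PatientRecord:
        row = self._conn.execute(
            "SELECT doc FROM patients WHERE patient_id = ?", (patient_id,)
        ).fetchone()
        if row is None:
            raise ValidationError(f"no patient {patient_id!r} in store")
        return PatientRecord.from_dict(json.loads(row[0]))

    def records(self) -> list[PatientRecord]:
        return [self.get_patient(pid) for pid in self.patient_ids()]

    def known_parcels(self, atlas: str) -> set[str]:
        rows = self._conn.execute(
            "SELECT DISTINCT name FROM contact_labels WHERE atlas = ? "
            "UNION SELECT DISTINCT name FROM resected WHERE atlas = ?",
            (atlas, atlas),
        )
        return {r[0] for r in rows} - {"unlabeled"}

    def atlases(self) -> list[str]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT DISTINCT atlas FROM contact_labels ORDER BY atlas"
            )
        ]

    # -- queries ---------------------------------------------------------
    def _check_parcel(self, atlas: str, name: str) -> None:
        known = self.known_parcels(atlas)
        if not known:
            raise ValidationError(f"atlas {atlas!r} unknown in store")
        if name not in known:
            raise ValidationError(f"parcel {name!r} unknown in atlas {atlas!r}")

    def query(self, c: QueryCriteria) -> list[str]:
        """Patient ids satisfying ALL provided criteria, sorted."""
        clauses: list[str] = []
        params: list = []
        if c.center is not None:
            clauses.append("p.center = ?")
            params.append(c.center)
        if c.year_range is not None:
            clauses.append("p.year BETWEEN ? AND ?")
            params.extend([int(c.year_range[0]), int(c.year_range[1])])
        if c.engel_classes is not None:
            marks = ",".join("?" * len(c.engel_classes))
            clauses.append(f"p.engel IN ({marks})")
            params.extend(c.engel_classes)
        if c.contact_in_parcel is not None:
            atlas, name = c.contact_in_parcel
            self._check_parcel(atlas, name)
            clauses.append(
                "EXISTS (SELECT 1 FROM contact_labels cl WHERE "
                "cl.patient_id = p.patient_id AND cl.atlas = ? AND cl.name = ?)"
            )
            params.extend([atlas, name])
        if c.resected_parcel is not None:
            atlas, name = c.resected_parcel
            self._check_parcel(atlas, name)
            clauses.append(
                "EXISTS (SELECT 1 FROM resected r WHERE r.patient_id = p.patient_id "
                "AND r.atlas = ? AND r.name = ? AND r.percent > ?)"
            )
            params.extend([atlas, name, float(c.resected_min_percent)])
        if (
            c.stimulated_parcel is not None
            or c.stim_frequency_hz is not None
            or c.stim_response_category is not None
            or c.stim_classification is not None
        ):
            sub = "SELECT 1 FROM stim s WHERE s.patient_id = p.patient_id"
            if c.stim_frequency_hz is not None:
                sub += " AND s.frequency = ?"
                params_sub_tail: list = [c.stim_frequency_hz]
            else:
                params_sub_tail = []
            if c.stim_response_category is not None:
                sub += " AND s.category = ?"
                params_sub_tail.append(c.stim_response_category)
            if c.stim_classification is not None:
                sub += " AND s.classifications LIKE ?"
                params_sub_tail.append(f"%;{c.stim_classification};%")
            if c.stimulated_parcel is not None:
                atlas, name = c.stimulated_parcel
                self._check_parcel(atlas, name)
                in_parcel = (
                    "EXISTS (SELECT 1 FROM contact_labels cl WHERE "
                    "cl.patient_id = s.patient_id AND cl.electrode = s.electrode "
                    "AND cl.contact = {contact} AND cl.atlas = ? AND cl.name = ?)"
                )
                if c.stim_parcel_mode == "either":
                    sub += (
                        " AND ("
                        + in_parcel.format(contact="s.contact_a")
                        + " OR "
                        + in_parcel.format(contact="s.contact_b")
                        + ")"
                    )
                    params_sub_tail.extend([atlas, name, atlas, name])
                else:
                    sub += (
                        " AND "
                        + in_parcel.format(contact="s.contact_a")
                        + " AND "
                        + in_parcel.format(contact="s.contact_b")
                    )
                    params_sub_tail.extend([atlas, name, atlas, name])
            clauses.append(f"EXISTS ({sub})")
            params.extend(params_sub_tail)
        sql = "SELECT p.patient_id FROM patients p"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY p.patient_id"
        return [r[0] for r in self._conn.execute(sql, params)]

    # -- portable dump ----------------------------------------------------
    def save_json(self, path: str | Path) -> None:
        """Canonical JSON dump of all records (byte-stable across rounds)."""
        doc = {"patients": [r.to_dict() for r in self.records()]}
        Path(path).write_text(
            json.dumps(doc, sort_keys=True, indent=1) + "\n"
        )

    @classmethod
    def load_json(cls, path: str | Path, store_path: str | Path = ":memory:") -> "CohortStore":
        doc = json.loads(Path(path).read_text())
        store = cls(store_path)
        for d in doc["patients"]:
            store.add_patient(PatientRecord.from_dict(d))
        return store

    # -- group export ------------------------------------------------------
    def export_group_cloud(
        self,
        atlas: str,
        parcel: str | None = None,
        patient_ids: list[str] | None = None,
    ) -> tuple[pd.DataFrame, list[str]]:
        """Flat per-contact table of MNI coordinates and labels.

        Restricted to contacts labeled ``parcel`` when given (the glass-brain
        "all contacts in parcel X" view).  Returns the table and a list of
        warnings naming patients that lack MNI coordinates.
        """
        if parcel is not None:
            self._check_parcel(atlas, parcel)
        ids = patient_ids if patient_ids is not None else self.patient_ids()
        warnings_: list[str] = []
        rows = []
        for pid in sorted(ids):
            rec = self.get_patient(pid)
            if not rec.mni_coords:
                warnings_.append(f"patient {pid} has no MNI coordinates")
                continue
            stim_by_contact: dict[tuple[str, int], set[str]] = {}
            for ev in rec.stimulation_events:
                for contact in (ev.contact_a, ev.contact_b):
                    stim_by_contact.setdefault((ev.electrode, contact), set()).add(
                        ev.response_category
                    )
            for cl in rec.contact_labels:
                lab, name = cl.atlas_labels.get(atlas, (0, "unlabeled"))
                if parcel is not None and name != parcel:
                    continue
                key = (cl.electrode_name, cl.contact_index)
                if key not in rec.mni_coords:
                    continue
                x, y, z = rec.mni_coords[key]
                rows.append(
                    {
                        "patient_id": pid,
                        "electrode": cl.electrode_name,
                        "contact": cl.contact_index,
                        "mni_x": x,
                        "mni_y": y,
                        "mni_z": z,
                        "atlas": atlas,
                        "label": lab,
                        "name": name,
                        "tissue": cl.tissue,
                        "stim_responses": ";".join(
                            sorted(stim_by_contact.get(key, ()))
                        ),
                    }
                )
        df = pd.DataFrame.from_records(
            rows,
            columns=[
                "patient_id",
                "electrode",
                "contact",
                "mni_x",
                "mni_y",
                "mni_z",
                "atlas",
                "label",
                "name",
                "tissue",
                "stim_responses",
            ],
        )
        df = df.sort_values(["patient_id", "electrode", "contact"]).reset_index(drop=True)
        return df, warnings_


def flip_left_right(coords: np.ndarray) -> np.ndarray:
    """Mirror left-hemisphere MNI points onto the right (x < 0 -> -x).

    Used to pool left and right implantations when laterality does not
    matter; idempotent, midline points are fixed.
    """
    out = np.array(np.atleast_2d(coords), dtype=float, copy=True)
    neg = out[:, 0] < 0
    out[neg, 0] = -out[neg, 0]
    return out[0] if np.asarray(coords).ndim == 1 else out


def import_stim_table(path: str | Path, patient: PatientRecord) -> list[StimulationEvent]:
    """Import a stimulation-response CSV and attach the events to ``patient``.

    Expected columns: ``bipole`` (``ELEC:A-B``, adjacent contacts),
    ``frequency_hz`` (1 or 50), ``intensity_ma`` (may be empty),
    ``response_category``, ``classifications`` (semicolon-separated, may be
    empty).  Rows referencing unknown contacts or vocabulary are rejected
    with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"bipole", "frequency_hz", "intensity_ma", "response_category", "classifications"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"stimulation table missing columns: {sorted(missing)}")
    n_by_elec = {e.electrode_name: e.n_contacts for e in patient.electrodes}
    events = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header line
        bipole = row["bipole"]
        try:
            elec, contacts = bipole.rsplit(":", 1)
            a_str, b_str = contacts.split("-")
            ev = StimulationEvent(
                electrode=elec,
                contact_a=int(a_str),
                contact_b=int(b_str),
                frequency_hz=int(row["frequency_hz"]),
                intensity_ma=float(row["intensity_ma"]) if row["intensity_ma"] else None,
                response_category=row["response_category"],
                classifications=tuple(
                    c for c in row["classifications"].split(";") if c
                ),
            )
            patient._check_contact(n_by_elec, ev.electrode, ev.contact_a)
            patient._check_contact(n_by_elec, ev.electrode, ev.contact_b)
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"stimulation table row {rowno}: {e}") from None
        events.append(ev)
    patient.stimulation_events.extend(events)
    return events
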