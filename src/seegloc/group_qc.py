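"""Group-level parcellation quality control by robust outlier statistics.

Atlas parcellation occasionally fails on individual patients (cortical
malformations, poor T1 contrast, bad normalization).  Failures are visible
at the group level: when all contacts labeled with one parcel are pooled in
MNI space, a mislabeled patient's contacts sit far from the cluster formed
by everyone else.  Two detectors flag such contacts per parcel cloud:

* **4xMAD rule** — compute each point's Euclidean distance to the
  component-wise median of the cloud; with MAD the median absolute
  deviation of those distances, flag points whose distance exceeds the
  median distance by more than four MADs.  Rotation- and
  translation-invariant.
* **Chauvenet criterion** — per coordinate axis, flag x_i when
  ``n * erfc(|x_i - mean| / std) < 0.5`` (population standard deviation;
  the scaled argument without a sqrt(2) factor, which makes the test
  stricter than the classical textbook criterion — ``classic=True``
  restores the textbook form).

Clouds with fewer than three points are reported as "insufficient data" and
never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .cohort_db import CohortStore

__all__ = [
    "ParcelCloud",
    "OutlierResult",
    "QCReport",
    "mad_outliers",
    "chauvenet_outliers",
    "qc_report",
]

MIN_CLOUD_SIZE = 3
MAD_FACTOR = 4.0


@dataclass
class ParcelCloud:
    """All contacts labeled with one parcel, pooled over a cohort, in MNI mm."""

    atlas: str
    parcel: str
    points: list[tuple[str, str, int]]  # (patient_id, electrode, contact_index)
    coords: np.ndarray  # (n, 3) MNI mm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.points) != len(self.coords):
            raise ValueError("points and coords length mismatch")
        if len(self.coords) < 1:
            raise ValueError("a parcel cloud needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass
class OutlierResult:
    """Per-point flags plus the cloud statistics they were derived from."""

    method: str
    flags: np.ndarray  # (n,) bool
    stats: dict = field(default_factory=dict)
    insufficient_n: bool = False


def mad_outliers(
    cloud: ParcelCloud, factor: float = MAD_FACTOR, mode: str = "distance"
) -> OutlierResult:
    """Flag points far from the cloud median by the 4xMAD rule.

    ``mode="distance"`` (default) works on Euclidean distances to the
    component-wise median; ``mode="axis"`` applies the rule per coordinate
    axis and flags a point deviant on any axis.
    """
    if mode not in ("distance", "axis"):
        raise ValueError(f"bad mode {mode!r}")
    coords = cloud.coords
    n = cloud.n
    stats = {
        "n": n,
        "mean": coords.mean(axis=0),
        "median": np.median(coords, axis=0),
    }
    if n < MIN_CLOUD_SIZE:
        return OutlierResult("mad", np.zeros(n, dtype=bool), stats, insufficient_n=True)
    if mode == "axis":
        flags = np.zeros(n, dtype=bool)
        mads = []
        for ax in range(3):
            x = coords[:, ax]
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            mads.append(mad)
            if mad > 0:
                flags |= np.abs(x - med) > factor * mad
            else:
                flags |= np.abs(x - med) > 0
        stats.update({"mad": np.asarray(mads), "deviation": None, "threshold": None})
        return OutlierResult("mad", flags, stats)
    d = np.linalg.norm(coords - stats["median"], axis=1)
    med_d = float(np.median(d))
    mad = float(np.median(np.abs(d - med_d)))
    if mad > 0:
        flags = (d - med_d) > factor * mad
        threshold = med_d + factor * mad
    else:  # degenerate scale: flag any strictly excess distance
        flags = d > med_d
        threshold = med_d
    stats.update({"distances": d, "median_distance": med_d, "mad": mad, "threshold": threshold})
    return OutlierResult("mad", flags, stats)


def chauvenet_outliers(cloud: ParcelCloud, classic: bool = False) -> OutlierResult:
    """Flag points by the Chauvenet criterion, applied per axis.

    A point is suspicious when ``n * erfc(|x - mean| / std) < 0.5`` on at
    least one axis (population std; axes with zero variance are skipped).
    ``classic=True`` divides the argument by an additional sqrt(2), the
    textbook normal-model form.
    """
    coords = cloud.coords
    n = cloud.n
    stats = {
        "n": n,
        "mean": coords.mean(axis=0),
        "median": np.median(coords, axis=0),
    }
    if n < MIN_CLOUD_SIZE:
        return OutlierResult(
            "chauvenet", np.zeros(n, dtype=bool), stats, insufficient_n=True
        )
    flags = np.zeros(n, dtype=bool)
    stds = coords.std(axis=0)  # population (ddof=0)
    expected = np.full((n, 3), np.nan)
    for ax in range(3):
        if stds[ax] == 0:
            continue
        arg = np.abs(coords[:, ax] - stats["mean"][ax]) / stds[ax]
        if classic:
            arg = arg / np.sqrt(2.0)
        expected[:, ax] = n * erfc(arg)
        flags |= expected[:, ax] < 0.5
    stats.update({"std": stds, "expected_count": expected})
    return OutlierResult("chauvenet", flags, stats)


@dataclass
class QCReport:
    """Suspicious contacts per parcel and method, over a whole cohort."""

    table: pd.DataFrame  # one row per flagged contact per method
    skipped_parcels: list[tuple[str, int]]  # (parcel, n) with n < MIN_CLOUD_SIZE
    warnings: list[str] = field(default_factory=list)

    def flagged_patients(self, method: str | None = None) -> list[str]:
        t = self.table
        if method is not None:
            t = t[t["method"] == method]
        return sorted(t["patient_id"].unique())

    def patient_summary(self) -> pd.DataFrame:
        """Flag counts aggregated per patient (one column per method)."""
        if self.table.empty:
            return pd.DataFrame(columns=["patient_id", "mad", "chauvenet"])
        pivot = (
            self.table.groupby(["patient_id", "method"]).size().unstack(fill_value=0)
        )
        return pivot.reindex(columns=["mad", "chauvenet"], fill_value=0).reset_index()


_QC_COLUMNS = [
    "patient_id",
    "electrode",
    "contact",
    "atlas",
    "parcel",
    "method",
    "deviation",
    "threshold",
]


def build_parcel_clouds(store: CohortStore, atlas: str) -> tuple[list[ParcelCloud], list[str]]:
    """Group a cohort's labeled, MNI-positioned contacts by parcel."""
    by_parcel: dict[str, tuple[list, list]] = {}
    warnings_: list[str] = []
    for pid in store.patient_ids():
        rec = store.get_patient(pid)
        if not rec.mni_coords:
            warnings_.append(f"patient {pid} has no MNI coordinates")
            continue
        for cl in rec.contact_labels:
            lab, name = cl.atlas_labels.get(atlas, (0, "unlabeled"))
            if lab == 0:
                continue
            key = (cl.electrode_name, cl.contact_index)
            if key not in rec.mni_coords:
                continue
            pts, xyz = by_parcel.setdefault(name, ([], []))
            pts.append((pid, cl.electrode_name, cl.contact_index))
            xyz.append(rec.mni_coords[key])
    clouds = [
        ParcelCloud(atlas=atlas, parcel=name, points=pts, coords=np.asarray(xyz))
        for name, (pts, xyz) in sorted(by_parcel.items())
    ]
    return clouds, warnings_


def qc_report(
    store: CohortStore,
    atlas: str,
    methods: tuple[str, ...] = ("mad", "chauvenet"),
    mad_factor: float = MAD_FACTOR,
    chauvenet_classic: bool = False,
) -> QCReport:
    """Run the selected outlier detectors over every parcel cloud.

    One output row per flagged contact per method; parcels with fewer than
    three points are skipped and listed separately.  Ordering is
    deterministic: (parcel, method, patient, electrode, contact).
    """
    clouds, warnings_ = build_parcel_clouds(store, atlas)
    if not clouds:
        warnings_.append("no patient has MNI coordinates and labels for this atlas")
    rows = []
    skipped: list[tuple[str, int]] = []
    for cloud in clouds:
        if cloud.n < MIN_CLOUD_SIZE:
            skipped.append((cloud.parcel, cloud.n))
            continue
        results = []
        if "mad" in methods:
            results.append(mad_outliers(cloud, factor=mad_factor))
        if "chauvenet" in methods:
            results.append(chauvenet_outliers(cloud, classic=chauvenet_classic))
        for res in results:
            for i in np.flatnonzero(res.flags):
                pid, elec, contact = cloud.points[i]
                if res.method == "mad":
                    deviation = float(res.stats["distances"][i])
                    threshold = float(res.stats["threshold"])
                else:
                    exp = res.stats["expected_count"][i]
                    deviation = float(np.nanmin(exp))
                    threshold = 0.5
                rows.append(
                    {
                        "patient_id": pid,
                        "electrode": elec,
                        "contact": contact,
                        "atlas": cloud.atlas,
                        "parcel": cloud.parcel,
                        "method": res.method,
                        "deviation": deviation,
                        "threshold": threshold,
                    }
                )
    table = pd.DataFrame.from_records(rows, columns=_QC_COLUMNS)
    table = table.sort_values(
        ["parcel", "method", "patient_id", "electrode", "contact"]
    ).reset_index(drop=True)
    return QCReport(table=table, skipped_parcels=skipped, warnings=warnings_)
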