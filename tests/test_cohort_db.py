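"""Cohort store: persistence, stimulation import, queries, group export."""

import numpy as np
import pandas as pd
import pytest

from seegloc.cohort_db import (
    CohortStore,
    PatientRecord,
    QueryCriteria,
    StimulationEvent,
    flip_left_right,
    import_stim_table,
)
from seegloc.errors import ValidationError


# ---------------------------------------------------------------------------
# independent brute-force query oracle (pure-Python filter over records)

def _matches(rec: PatientRecord, c: QueryCriteria) -> bool:
    if c.center is not None and rec.center != c.center:
        return False
    if c.year_range is not None and not (c.year_range[0] <= rec.year <= c.year_range[1]):
        return False
    if c.engel_classes is not None and rec.engel_class not in c.engel_classes:
        return False
    if c.contact_in_parcel is not None:
        atlas, name = c.contact_in_parcel
        if not any(
            cl.atlas_labels.get(atlas, (0, ""))[1] == name for cl in rec.contact_labels
        ):
            return False
    if c.resected_parcel is not None:
        atlas, name = c.resected_parcel
        hits = (
            [
                p
                for p in rec.overlap_report.per_parcel
                if p.atlas == atlas and p.name == name and p.percent_removed > c.resected_min_percent
            ]
            if rec.overlap_report
            else []
        )
        if not hits:
            return False
    stim_criteria = (
        c.stimulated_parcel,
        c.stim_frequency_hz,
        c.stim_response_category,
        c.stim_classification,
    )
    if any(x is not None for x in stim_criteria):
        labels = {
            (cl.electrode_name, cl.contact_index): cl.atlas_labels
            for cl in rec.contact_labels
        }

        def ev_ok(ev):
            if c.stim_frequency_hz is not None and ev.frequency_hz != c.stim_frequency_hz:
                return False
            if c.stim_response_category is not None and ev.response_category != c.stim_response_category:
                return False
            if c.stim_classification is not None and c.stim_classification not in ev.classifications:
                return False
            if c.stimulated_parcel is not None:
                atlas, name = c.stimulated_parcel
                in_a = labels.get((ev.electrode, ev.contact_a), {}).get(atlas, (0, ""))[1] == name
                in_b = labels.get((ev.electrode, ev.contact_b), {}).get(atlas, (0, ""))[1] == name
                if c.stim_parcel_mode == "either" and not (in_a or in_b):
                    return False
                if c.stim_parcel_mode == "both" and not (in_a and in_b):
                    return False
            return True

        if not any(ev_ok(ev) for ev in rec.stimulation_events):
            return False
    return True


def brute_force_query(records, c):
    return sorted(r.patient_id for r in records if _matches(r, c))


def random_criteria(rng, parcels, atlas):
    kwargs = {}
    if rng.random() < 0.4:
        kwargs["center"] = str(rng.choice(["CenterA", "CenterB", "CenterC", "CenterX"]))
    if rng.random() < 0.3:
        lo = int(rng.integers(2006, 2016))
        kwargs["year_range"] = (lo, lo + int(rng.integers(0, 6)))
    if rng.random() < 0.5:
        kwargs["contact_in_parcel"] = (atlas, str(rng.choice(parcels)))
    if rng.random() < 0.5:
        kwargs["resected_parcel"] = (atlas, str(rng.choice(parcels)))
        if rng.random() < 0.5:
            kwargs["resected_min_percent"] = float(rng.uniform(0, 60))
    if rng.random() < 0.3:
        kwargs["stim_frequency_hz"] = int(rng.choice([1, 50]))
    if rng.random() < 0.3:
        kwargs["stim_response_category"] = str(
            rng.choice(["no_response", "seizure_like", "response_non_epileptic"])
        )
    if rng.random() < 0.2:
        kwargs["stimulated_parcel"] = (atlas, str(rng.choice(parcels)))
        kwargs["stim_parcel_mode"] = str(rng.choice(["either", "both"]))
    if rng.random() < 0.2:
        kwargs["stim_classification"] = str(rng.choice(["motor", "sensory"]))
    if rng.random() < 0.3:
        k = int(rng.integers(1, 4))
        kwargs["engel_classes"] = tuple(
            sorted(set(rng.choice(["I", "II", "III", "IV", "unknown"], size=k)))
        )
    return QueryCriteria(**kwargs)


class TestStimulationEvent:
    def test_non_adjacent_bipole_rejected(self):
        with pytest.raises(ValidationError, match="adjacent"):
            StimulationEvent("A", 1, 3, 50, "no_response")

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValidationError, match="frequency"):
            StimulationEvent("A", 1, 2, 20, "no_response")

    def test_not_stimulated_with_classifications_rejected(self):
        with pytest.raises(ValidationError, match="not_stimulated"):
            StimulationEvent("A", 1, 2, 50, "not_stimulated", classifications=("motor",))


class TestStoreRoundtrip:
    def test_add_then_get_equal(self, cohort):
        store, _ = cohort
        pid = store.patient_ids()[0]
        rec = store.get_patient(pid)
        assert rec.patient_id == pid
        assert rec.to_dict() == PatientRecord.from_dict(rec.to_dict()).to_dict()

    def test_duplicate_id_rejected(self, cohort):
        store, _ = cohort
        rec = store.get_patient(store.patient_ids()[0])
        with pytest.raises(ValidationError, match="already"):
            store.add_patient(rec)
        store.add_patient(rec, overwrite=True)  # explicit overwrite allowed
        assert store.patient_ids().count(rec.patient_id) == 1

    def test_generator_count(self, cohort, spec):
        store, _ = cohort
        assert len(store) == spec.n_patients

    def test_save_load_save_byte_stable(self, cohort, tmp_path):
        store, _ = cohort
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        store.save_json(p1)
        CohortStore.load_json(p1).save_json(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestStimTableImport:
    @pytest.fixture()
    def patient(self, cohort):
        store, _ = cohort
        return store.get_patient(store.patient_ids()[0])

    def _write(self, tmp_path, rows):
        p = tmp_path / "stim.csv"
        pd.DataFrame(
            rows,
            columns=["bipole", "frequency_hz", "intensity_ma", "response_category", "classifications"],
        ).to_csv(p, index=False)
        return p

    def test_valid_rows_imported(self, tmp_path, patient):
        elec = patient.electrodes[0].electrode_name
        before = len(patient.stimulation_events)
        path = self._write(
            tmp_path,
            [
                [f"{elec}:1-2", 50, 1.2, "seizure_like", "motor;sensitive"],
                [f"{elec}:2-3", 1, 2.0, "no_response", ""],
                [f"{elec}:3-4", 50, "", "not_stimulated", ""],
            ],
        )
        events = import_stim_table(path, patient)
        assert len(events) == 3
        assert len(patient.stimulation_events) == before + 3
        assert events[0].classifications == ("motor", "sensitive")

    def test_bad_frequency_names_row(self, tmp_path, patient):
        elec = patient.electrodes[0].electrode_name
        path = self._write(tmp_path, [[f"{elec}:1-2", 20, 1.0, "no_response", ""]])
        with pytest.raises(ValidationError, match="row 2"):
            import_stim_table(path, patient)

    def test_unknown_contact_names_row(self, tmp_path, patient):
        elec = patient.electrodes[0].electrode_name
        path = self._write(
            tmp_path,
            [
                [f"{elec}:1-2", 50, 1.0, "no_response", ""],
                [f"{elec}:98-99", 50, 1.0, "no_response", ""],
            ],
        )
        with pytest.raises(ValidationError, match="row 3"):
            import_stim_table(path, patient)


class TestQuery:
    def test_empty_criteria_returns_all(self, cohort):
        store, _ = cohort
        assert store.query(QueryCriteria()) == store.patient_ids()

    def test_unknown_parcel_rejected(self, cohort):
        store, _ = cohort
        with pytest.raises(ValidationError, match="unknown"):
            store.query(QueryCriteria(contact_in_parcel=("synthatlas", "NOPE")))
        with pytest.raises(ValidationError, match="unknown"):
            store.query(QueryCriteria(contact_in_parcel=("nosuchatlas", "P01_L")))

    def test_planted_contact_and_resection_scenario(self, cohort):
        """Contact in parcel AND parcel partially resected -> the one planted patient."""
        store, truth = cohort
        c = QueryCriteria(
            contact_in_parcel=("synthatlas", truth.scenario_parcel),
            resected_parcel=("synthatlas", truth.scenario_parcel),
        )
        assert store.query(c) == truth.scenario_expected

    def test_random_criteria_match_bruteforce_oracle(self, cohort, rng):
        store, truth = cohort
        records = store.records()
        parcels = sorted(store.known_parcels("synthatlas"))
        for _ in range(60):
            c = random_criteria(rng, parcels, "synthatlas")
            try:
                got = store.query(c)
            except ValidationError:
                # criteria referencing vocabulary absent from this store
                continue
            assert got == brute_force_query(records, c)

    def test_conjunction_semantics(self, cohort):
        store, _ = cohort
        parcels = sorted(store.known_parcels("synthatlas"))
        c1 = QueryCriteria(contact_in_parcel=("synthatlas", parcels[0]))
        c2 = QueryCriteria(engel_classes=("I", "II"))
        both = QueryCriteria(
            contact_in_parcel=("synthatlas", parcels[0]), engel_classes=("I", "II")
        )
        assert set(store.query(both)) == set(store.query(c1)) & set(store.query(c2))


class TestFlipLeftRight:
    def test_left_point_flipped(self):
        assert np.allclose(flip_left_right(np.array([-42.0, 10, 5])), (42, 10, 5))

    def test_right_and_midline_fixed(self):
        pts = np.array([[42.0, 10, 5], [0.0, 0, 0]])
        assert np.allclose(flip_left_right(pts), pts)

    def test_idempotent_involution(self, rng):
        pts = rng.normal(0, 30, (50, 3))
        once = flip_left_right(pts)
        assert np.allclose(flip_left_right(once), once)
        assert np.all(once[:, 0] >= 0)
        assert np.allclose(np.abs(pts[:, 0]), once[:, 0])


class TestGroupCloudExport:
    def test_parcel_selection_counts_match_labels(self, cohort):
        store, truth = cohort
        parcel = truth.scenario_parcel
        df, warns = store.export_group_cloud("synthatlas", parcel=parcel)
        n_template = sum(
            1
            for cl in truth.template_labels
            if cl.atlas_labels["synthatlas"][1] == parcel
        )
        assert len(df) == n_template * len(store)
        assert not warns

    def test_single_patient_single_electrode(self, cohort):
        store, _ = cohort
        pid = store.patient_ids()[0]
        rec = store.get_patient(pid)
        elec = rec.electrodes[0]
        df, _ = store.export_group_cloud("synthatlas", patient_ids=[pid])
        sub = df[df.electrode == elec.electrode_name]
        assert len(sub) == elec.n_contacts

    def test_rerun_byte_identical(self, cohort, tmp_path):
        store, _ = cohort
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        store.export_group_cloud("synthatlas")[0].to_csv(a, index=False)
        store.export_group_cloud("synthatlas")[0].to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_missing_mni_warned(self, cohort):
        store, _ = cohort
        rec = store.get_patient(store.patient_ids()[0])
        bare = PatientRecord(
            patient_id="ZZ_no_mni",
            center="CenterA",
            year=2015,
            electrodes=rec.electrodes,
            contact_labels=rec.contact_labels,
        )
        store.add_patient(bare)
        try:
            _, warns = store.export_group_cloud("synthatlas")
            assert any("ZZ_no_mni" in w for w in warns)
        finally:
            store.remove_patient("ZZ_no_mni")
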