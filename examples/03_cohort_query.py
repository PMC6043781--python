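"""Multi-criteria search over a synthetic patient cohort.

Generates a 20-patient cohort and answers the canonical clinical question:
"which patients had an electrode contact in parcel X *and* had X at least
partially resected?" — then narrows further by surgical outcome.  Criteria
combine with AND; an empty criteria object matches everyone.
"""

from seegloc import FixtureSpec, QueryCriteria, make_cohort

store, truth = make_cohort(FixtureSpec(seed=5))
parcel = truth.scenario_parcel

print(f"cohort: {len(store)} patients; scenario parcel: {parcel}\n")

c1 = QueryCriteria(contact_in_parcel=("synthatlas", parcel))
print(f"contact in {parcel}: {len(store.query(c1))} patients")

c2 = QueryCriteria(
    contact_in_parcel=("synthatlas", parcel),
    resected_parcel=("synthatlas", parcel),  # "at least partially" resected
)
hits = store.query(c2)
print(f"... AND {parcel} partially resected: {hits}")

c3 = QueryCriteria(
    contact_in_parcel=("synthatlas", parcel),
    resected_parcel=("synthatlas", parcel),
    engel_classes=("I", "II"),
)
print(f"... AND favorable outcome (Engel I-II): {store.query(c3)}")
print("\n(planted ground truth for the combined contact+resection query:", truth.scenario_expected, ")")
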