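"""Place a depth electrode and label its contacts anatomically.

Builds a small synthetic head (tissue classes + gray-matter parcellation),
places one 15-contact electrode along a two-point trajectory aimed at a
parcel, and prints each contact's parcel label and tissue class.  Deep
contacts come out as white matter / unlabeled; contacts crossing the
gray-matter shell pick up their parcel by sphere majority vote.
"""

import numpy as np

from seegloc import (
    FixtureSpec,
    Trajectory,
    default_catalog,
    label_all,
    make_atlas,
    make_head,
    place_electrode,
)

spec = FixtureSpec(seed=7)
tissue, brain = make_head(spec)
atlas, lookup = make_atlas(tissue, n_parcels=16, seed=7)

# aim from deep in the white matter out through the centroid of parcel 2
target_vox = np.argwhere(atlas.data == 2).mean(axis=0)
target = atlas.affine[:3, :3] @ target_vox + atlas.affine[:3, 3]
direction = target / np.linalg.norm(target)
traj = Trajectory(tip_point=direction * 3.0, shaft_point=direction * 40.0)

model = next(m for m in default_catalog() if m.model_name == "depth-15-generic")
electrode = place_electrode(model, traj, "Q'")

rows = label_all([electrode], {lookup.atlas_name: (atlas, lookup)}, tissue=tissue)
print(f"electrode Q' along {np.round(direction, 2)}; contact 1 is deepest\n")
print(f"{'contact':>7}  {'parcel':<12} tissue")
for r in rows:
    print(f"{r.contact_index:>7}  {r.atlas_labels[lookup.atlas_name][1]:<12} {r.tissue}")
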