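"""Sphere neighborhoods and majority-vote contact labeling."""

import numpy as np
import pytest

from seegloc.contact_labeling import (
    SphereSpec,
    label_all,
    label_atlas,
    label_tissue,
    labels_to_dataframe,
    resection_flag,
    sphere_voxels,
    statmap_mean,
)
from seegloc.errors import GridMismatchError, ValidationError
from seegloc.io_core import TISSUE_GM, TISSUE_WM, LabelLookup, Volume3D


def brute_force_sphere(center, vol, radius):
    """Per-voxel distance check over the whole grid."""
    out = []
    for idx in np.ndindex(vol.shape):
        w = vol.affine[:3, :3] @ idx + vol.affine[:3, 3]
        if np.sum((w - np.asarray(center)) ** 2) <= radius**2 + 1e-9:
            out.append(idx)
    return np.asarray(out, dtype=int).reshape(-1, 3)


def make_lookup(labels, cortical=True):
    lookup = LabelLookup("a1", cortical=cortical)
    for lab in labels:
        lookup.add(lab, f"parcel{lab}")
    return lookup


class TestSphereVoxels:
    def test_radius3_isotropic_count_is_123(self):
        vol = Volume3D(np.zeros((21, 21, 21)), np.eye(4), "atlas")
        vox = sphere_voxels((10, 10, 10), vol, SphereSpec(3.0))
        # independent oracle: lattice points with |v|^2 <= 9
        count = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if i * i + j * j + k * k <= 9
        )
        assert count == 123
        assert len(vox) == 123

    def test_small_radius_single_voxel(self):
        vol = Volume3D(np.zeros((9, 9, 9)), np.eye(4), "atlas")
        assert len(sphere_voxels((4, 4, 4), vol, SphereSpec(0.4))) == 1

    def test_far_outside_volume_is_empty(self):
        vol = Volume3D(np.zeros((9, 9, 9)), np.eye(4), "atlas")
        assert len(sphere_voxels((60, 4, 4), vol, SphereSpec(3.0))) == 0

    def test_matches_bruteforce_on_random_anisotropic_grids(self, rng):
        for _ in range(30):
            spacing = rng.uniform(0.5, 3.0, size=3)
            affine = np.diag((*spacing, 1.0))
            affine[:3, 3] = rng.uniform(-5, 5, 3)
            vol = Volume3D(np.zeros((10, 11, 9)), affine, "atlas")
            center = rng.uniform(-5, 20, 3)
            r = float(rng.uniform(1.0, 5.0))
            got = sphere_voxels(center, vol, SphereSpec(r))
            expect = brute_force_sphere(center, vol, r)
            assert np.array_equal(got, expect)

    def test_lexicographic_order(self):
        vol = Volume3D(np.zeros((9, 9, 9)), np.eye(4), "atlas")
        vox = sphere_voxels((4, 4, 4), vol, SphereSpec(2.0))
        assert np.array_equal(vox, vox[np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))])

    def test_radius_bounds_validated(self):
        with pytest.raises(ValidationError):
            SphereSpec(0.0)
        with pytest.raises(ValidationError):
            SphereSpec(25.0)


class TestLabelAtlas:
    def test_uniform_atlas(self):
        vol = Volume3D(np.full((11, 11, 11), 7), np.eye(4), "atlas")
        lab, name = label_atlas((5, 5, 5), vol, make_lookup([7]))
        assert (lab, name) == (7, "parcel7")

    def test_gm_minority_beats_wm_majority(self):
        """A few labeled GM voxels win over an unlabeled WM majority."""
        shape = (11, 11, 11)
        atlas = np.zeros(shape, dtype=int)
        tissue = np.full(shape, TISSUE_WM)
        # 5 GM voxels with label 4 near the center; everything else WM, label 0
        gm_spots = [(5, 5, 7), (5, 7, 5), (7, 5, 5), (5, 5, 3), (5, 3, 5)]
        for s in gm_spots:
            atlas[s] = 4
            tissue[s] = TISSUE_GM
        atlas_vol = Volume3D(atlas, np.eye(4), "atlas")
        tissue_vol = Volume3D(tissue, np.eye(4), "tissue")
        lab, name = label_atlas(
            (5, 5, 5), atlas_vol, make_lookup([4]), tissue=tissue_vol
        )
        assert lab == 4

    def test_tie_breaks_to_smallest_label(self):
        shape = (11, 11, 11)
        atlas = np.zeros(shape, dtype=int)
        atlas[5, 5, 4] = 5
        atlas[5, 5, 6] = 3
        vol = Volume3D(atlas, np.eye(4), "atlas")
        lab, _ = label_atlas((5, 5, 5), vol, make_lookup([3, 5]), sphere=SphereSpec(1.5))
        assert lab == 3

    def test_empty_candidates_unlabeled(self):
        vol = Volume3D(np.zeros((11, 11, 11)), np.eye(4), "atlas")
        assert label_atlas((5, 5, 5), vol, make_lookup([1])) == (0, "unlabeled")

    def test_non_cortical_atlas_ignores_tissue(self):
        shape = (11, 11, 11)
        atlas = np.full(shape, 2)
        tissue = np.full(shape, TISSUE_WM)  # no GM anywhere
        lab, _ = label_atlas(
            (5, 5, 5),
            Volume3D(atlas, np.eye(4), "atlas"),
            make_lookup([2], cortical=False),
            tissue=Volume3D(tissue, np.eye(4), "tissue"),
        )
        assert lab == 2

    def test_grid_mismatch_rejected(self):
        atlas = Volume3D(np.zeros((5, 5, 5)), np.eye(4), "atlas")
        tissue = Volume3D(np.zeros((6, 6, 6)), np.eye(4), "tissue")
        with pytest.raises(GridMismatchError):
            label_atlas((2, 2, 2), atlas, make_lookup([1]), tissue=tissue)

    def test_matches_bruteforce_majority_on_random_volumes(self, rng):
        """Exhaustive candidate-count oracle over random volumes and centers."""
        lookup = make_lookup(list(range(1, 7)))
        for _ in range(60):
            atlas = Volume3D(
                rng.integers(0, 7, size=(14, 14, 14)), np.eye(4), "atlas"
            )
            tissue = Volume3D(
                rng.integers(0, 4, size=(14, 14, 14)), np.eye(4), "tissue"
            )
            for _ in range(5):
                center = rng.uniform(0, 13, 3)
                r = float(rng.uniform(1.0, 4.0))
                got, _ = label_atlas(center, atlas, lookup, tissue=tissue, sphere=SphereSpec(r))
                vox = brute_force_sphere(center, atlas, r)
                counts = {}
                for i, j, k in vox:
                    lab = atlas.data[i, j, k]
                    if lab != 0 and tissue.data[i, j, k] == TISSUE_GM:
                        counts[lab] = counts.get(lab, 0) + 1
                expect = min(
                    (lab for lab, c in counts.items() if c == max(counts.values())),
                    default=0,
                )
                assert got == expect

    def test_growing_uniform_parcel_never_changes_label(self):
        """Monotonicity: enlarging the parcel around a contact is stable."""
        shape = (15, 15, 15)
        lookup = make_lookup([9])
        for half in (2, 3, 5, 7):
            atlas = np.zeros(shape, dtype=int)
            lo, hi = 7 - half, 7 + half + 1
            atlas[lo:hi, lo:hi, lo:hi] = 9
            vol = Volume3D(atlas, np.eye(4), "atlas")
            assert label_atlas((7, 7, 7), vol, lookup)[0] == 9


class TestLabelTissue:
    def test_all_wm(self):
        vol = Volume3D(np.full((11, 11, 11), TISSUE_WM), np.eye(4), "tissue")
        assert label_tissue((5, 5, 5), vol) == "WM"

    def test_majority_gm(self):
        data = np.full((11, 11, 11), TISSUE_WM)
        data[:, :, 5:] = TISSUE_GM  # more GM than WM in a centered sphere
        vol = Volume3D(data, np.eye(4), "tissue")
        assert label_tissue((5, 5, 5.4), vol) == "GM"

    def test_matches_bruteforce_histogram(self, rng):
        for _ in range(40):
            vol = Volume3D(
                rng.integers(0, 4, size=(13, 13, 13)), np.eye(4), "tissue"
            )
            for _ in range(5):
                center = rng.uniform(0, 12, 3)
                r = float(rng.uniform(1.0, 4.0))
                got = label_tissue(center, vol, SphereSpec(r))
                vox = brute_force_sphere(center, vol, r)
                counts = {c: 0 for c in (1, 2, 3)}
                for i, j, k in vox:
                    v = vol.data[i, j, k]
                    if v:
                        counts[v] += 1
                if not any(counts.values()):
                    expect = "unlabeled"
                else:
                    best = max((2, 3, 1), key=lambda c: counts[c])
                    expect = {2: "GM", 3: "WM", 1: "CSF"}[best]
                assert got == expect


class TestStatmapMean:
    def test_constant_field(self):
        vol = Volume3D(np.full((11, 11, 11), 2.5), np.eye(4), "statmap")
        assert statmap_mean((5, 5, 5), vol, SphereSpec(3.0)) == pytest.approx(2.5)

    def test_seven_voxel_cross_mean(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 10.0
        vol = Volume3D(data, np.eye(4), "statmap")
        assert statmap_mean((5, 5, 5), vol, SphereSpec(1.0)) == pytest.approx(10 / 7)

    def test_empty_sphere_nan_with_warning(self):
        vol = Volume3D(np.zeros((5, 5, 5)), np.eye(4), "statmap")
        with pytest.warns(UserWarning):
            assert np.isnan(statmap_mean((50, 50, 50), vol, SphereSpec(1.0)))

    def test_nan_voxels_excluded(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = np.nan
        data[5, 5, 6] = 6.0
        vol = Volume3D(data, np.eye(4), "statmap")
        # cross of 7 voxels, one NaN -> mean over remaining 6
        assert statmap_mean((5, 5, 5), vol, SphereSpec(1.0)) == pytest.approx(1.0)


class TestResectionFlag:
    def test_inside_filled_cube(self):
        data = np.zeros((11, 11, 11))
        data[3:8, 3:8, 3:8] = 1
        vol = Volume3D(data, np.eye(4), "mask")
        assert resection_flag((5, 5, 5), vol) is True

    def test_empty_mask_false_everywhere(self, rng):
        vol = Volume3D(np.zeros((11, 11, 11)), np.eye(4), "mask")
        for _ in range(20):
            assert resection_flag(rng.uniform(-5, 15, 3), vol) is False

    def test_boundary_equals_nearest_voxel_lookup(self):
        data = np.zeros((11, 11, 11))
        data[5:, :, :] = 1
        vol = Volume3D(data, np.eye(4), "mask")
        assert resection_flag((4.4, 5, 5), vol) is False  # rounds to voxel 4
        assert resection_flag((4.6, 5, 5), vol) is True  # rounds to voxel 5

    def test_out_of_bounds_false(self):
        vol = Volume3D(np.ones((5, 5, 5)), np.eye(4), "mask")
        assert resection_flag((-30, 0, 0), vol) is False


class TestLabelAll:
    def test_cardinality_and_order(self, implantation, atlas_and_lookup, tissue_vol):
        electrodes, _ = implantation
        atlas, lookup = atlas_and_lookup
        rows = label_all(
            electrodes[:2], atlases={lookup.atlas_name: (atlas, lookup)}, tissue=tissue_vol
        )
        assert len(rows) == sum(e.n_contacts for e in electrodes[:2])
        keys = [(r.electrode_name, r.contact_index) for r in rows]
        assert keys == sorted(keys)

    def test_pure_contacts_recover_planted_parcel(
        self, implantation, template_labels, atlas_and_lookup
    ):
        _, truth = implantation
        _, lookup = atlas_and_lookup
        pure = {k: v for k, v in truth.items() if v != "mixed"}
        assert pure, "fixture should plant ground-truth-pure contacts"
        for row in template_labels:
            key = (row.electrode_name, row.contact_index)
            if key in pure:
                assert row.atlas_labels[lookup.atlas_name][1] == pure[key]

    def test_rerun_is_byte_identical(self, implantation, atlas_and_lookup, tissue_vol, tmp_path):
        electrodes, _ = implantation
        atlas, lookup = atlas_and_lookup
        paths = []
        for i in range(2):
            rows = label_all(
                electrodes, atlases={lookup.atlas_name: (atlas, lookup)}, tissue=tissue_vol
            )
            p = tmp_path / f"labels{i}.csv"
            labels_to_dataframe(rows).to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_duplicate_electrode_names_rejected(self, implantation, atlas_and_lookup):
        electrodes, _ = implantation
        atlas, lookup = atlas_and_lookup
        with pytest.raises(ValidationError, match="duplicate"):
            label_all(
                [electrodes[0], electrodes[0]],
                atlases={lookup.atlas_name: (atlas, lookup)},
            )
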