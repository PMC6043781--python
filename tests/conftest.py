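"""Shared fixtures: one synthetic world, generated once per session."""

import numpy as np
import pytest

from seegloc.contact_labeling import label_all
from seegloc.synthetic import (
    FixtureSpec,
    make_atlas,
    make_cohort,
    make_head,
    make_implantation,
)

SEED = 1


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def head(spec):
    return make_head(spec)


@pytest.fixture(scope="session")
def tissue_vol(head):
    return head[0]


@pytest.fixture(scope="session")
def brain_mask(head):
    return head[1]


@pytest.fixture(scope="session")
def atlas_and_lookup(tissue_vol, spec):
    return make_atlas(tissue_vol, spec.n_parcels, seed=spec.seed)


@pytest.fixture(scope="session")
def implantation(atlas_and_lookup, spec):
    atlas, lookup = atlas_and_lookup
    return make_implantation(atlas, lookup, spec)


@pytest.fixture(scope="session")
def template_labels(implantation, atlas_and_lookup, tissue_vol):
    electrodes, _ = implantation
    atlas, lookup = atlas_and_lookup
    return label_all(
        electrodes, atlases={lookup.atlas_name: (atlas, lookup)}, tissue=tissue_vol
    )


@pytest.fixture(scope="session")
def cohort(spec):
    return make_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
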