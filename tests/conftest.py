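import numpy as np
import pytest

from gross.alignment import BWAnchor
from gross.contacts import BWPosition, Contact, ContactSet
from gross.synthetic import BundleSpec, FamilySpec, make_bundle, make_family


@pytest.fixture(scope="session")
def default_bundle():
    """One idealized 7-TM bundle shared by read-only tests."""
    return make_bundle(BundleSpec(seed=7))


@pytest.fixture(scope="session")
def family_entries():
    """Four divergent families x six members, moderate within-family noise."""
    return make_family(FamilySpec(n_families=4, n_members=6, substitution_prob=0.1, seed=11))


def contact(a_helix, a_idx, b_helix, b_idx):
    return Contact(BWPosition(a_helix, a_idx), BWPosition(b_helix, b_idx))


def contact_set(sid, pairs):
    return ContactSet(structure_id=sid, contacts=frozenset(contact(*p) for p in pairs))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
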