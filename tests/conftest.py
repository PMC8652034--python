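import numpy as np
import pytest

from flatfold.family_stats import compute_family_stats
from flatfold.layout_engine import LayoutConfig, layout_family
from flatfold.sse_annotation import annotate_family, detect_sses
from flatfold.synthetic_data import (
    FamilySpec,
    SSESpec,
    hairpin_recipe,
    make_domain,
    make_family,
    meander_recipe,
    mixed_recipe,
)

#: Family-wide study conditions used throughout: 10 members, 0.3 A jitter.
FAMILY_SPEC = dict(n_members=10, jitter_sigma=0.3, deletion_prob=0.0, seed=7)


@pytest.fixture(scope="session")
def helix_domain():
    dom, truth = make_domain([SSESpec("helix", 12, (0, 0, 0), (0, 0, 1))])
    return dom, truth


@pytest.fixture(scope="session")
def hairpin_domain():
    dom, truth = make_domain(hairpin_recipe(n_res=5))
    return dom, truth


@pytest.fixture(scope="session")
def meander_domain():
    dom, truth = make_domain(meander_recipe())
    return dom, truth


@pytest.fixture(scope="session")
def mixed_domain():
    dom, truth = make_domain(mixed_recipe())
    return dom, truth


@pytest.fixture(scope="session")
def jittered_family():
    """10 jittered copies of the mixed recipe with ground truth."""
    return make_family(FamilySpec(recipe=mixed_recipe(), **FAMILY_SPEC))


@pytest.fixture(scope="session")
def annotated_family(jittered_family):
    members = {
        dom_id: (dom, detect_sses(dom))
        for dom_id, (dom, _) in jittered_family.items()
    }
    return annotate_family("9.99.99.99", members)


@pytest.fixture(scope="session")
def family_stats(annotated_family):
    return compute_family_stats(annotated_family)


@pytest.fixture(scope="session")
def family_diagrams(jittered_family, annotated_family, family_stats):
    structures = {d: dom for d, (dom, _) in jittered_family.items()}
    return layout_family(annotated_family, structures, family_stats, LayoutConfig())
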