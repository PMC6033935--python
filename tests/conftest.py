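import pytest

from mendelsieve import build_paper_fixture
from mendelsieve.simulate import FIXTURE_VARIANTS


@pytest.fixture(scope="session")
def bundle():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def peds_by_id(bundle):
    return {p.family_id: p for p in bundle.pedigrees}


@pytest.fixture(scope="session")
def variant_by_label(bundle):
    by_pos = {r.pos: r for r in bundle.records}
    return {
        label: by_pos[pos]
        for label, (pos, _r, _a, _t, _c) in FIXTURE_VARIANTS.items()
    }
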