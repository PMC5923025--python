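import pytest

from triagesim import generate_vignette_pool, load_bundled_tree
from triagesim.cohort import ProviderProfile, SkillState


@pytest.fixture(scope="session")
def asav_tree():
    return load_bundled_tree("asav")


@pytest.fixture(scope="session")
def demo_tree():
    return load_bundled_tree("start_demo")


@pytest.fixture(scope="session")
def pool(asav_tree):
    return generate_vignette_pool(40, tree=asav_tree, seed=123)


def make_provider(pid: str, p: float, **kw) -> ProviderProfile:
    return ProviderProfile(id=pid, skill=SkillState.uniform(p, **kw))


@pytest.fixture()
def perfect_team():
    return make_provider("A", 1.0, floor=0.5), make_provider("B", 1.0, floor=0.5)
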