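import pathlib
import sys

import pytest
from hypothesis import settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from immunomart.synthetic import StudySpec, generate_study  # noqa: E402
from immunomart.pipeline import load_study_dir  # noqa: E402


@pytest.fixture()
def mem_store():
    from immunomart.warehouse import create_store

    store = create_store(":memory:")
    yield store
    store.close()


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Default synthetic flu-vaccine study written to disk once per run."""
    d = tmp_path_factory.mktemp("study")
    generate_study(StudySpec(), d)
    return d


@pytest.fixture(scope="session")
def full_store(study_dir):
    """Warehouse with the default study fully ingested and linked."""
    store = load_study_dir(study_dir)
    yield store
    store.close()


@pytest.fixture(scope="session")
def small_study():
    """A small in-memory study (fast unit-level fixture)."""
    from immunomart.synthetic import generate_study_data

    return generate_study_data(StudySpec(n_persons=30, seed=99))


@pytest.fixture(scope="session")
def small_store(small_study):
    from immunomart.pipeline import build_study_store

    store = build_study_store(small_study)
    yield store
    store.close()
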