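import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dircause.corpus import CorpusCounts, VerbLexicon
from dircause.semantics import ProfileMap

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture
def lexicon3() -> VerbLexicon:
    return VerbLexicon(("boil", "break", "cry"))


@pytest.fixture
def lexicon5() -> VerbLexicon:
    return VerbLexicon.default(5)


@pytest.fixture
def small_counts(lexicon3) -> CorpusCounts:
    return CorpusCounts(
        language="toy",
        counts=np.array([[5, 2, 10], [1, 7, 4], [0, 3, 9]], dtype=np.int64),
    )


@pytest.fixture
def profiles5(lexicon5) -> ProfileMap:
    rng = np.random.default_rng(1234)
    return ProfileMap(values=rng.uniform(0.0, 1.0, (5, 4)))


def counts_frame(language, rows):
    """rows: iterable of (verb, construction, count)."""
    return pd.DataFrame(
        [(language, v, c, n) for v, c, n in rows],
        columns=["language", "verb", "construction", "count"],
    )


@pytest.fixture
def counts_csv(tmp_path):
    def write(rows, language="toy", name="counts.csv"):
        path = tmp_path / name
        counts_frame(language, rows).to_csv(path, index=False)
        return path

    return write
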