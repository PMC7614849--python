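import datetime as dt
import os
import tempfile

# keep hypothesis' runtime caches out of the working tree
os.environ.setdefault(
    "HYPOTHESIS_STORAGE_DIRECTORY",
    os.path.join(tempfile.gettempdir(), "hypothesis-cache"),
)

import pytest
from hypothesis import settings

settings.register_profile("repro", database=None, derandomize=True)
settings.load_profile("repro")

from prodromal_text import GeneratorConfig, build_cohort, generate_cohort
from prodromal_text.corpus_io import Post, UserRecord


def make_user(uid, n_posts, label="control", start=dt.date(2014, 1, 1),
              step_days=1, text="hello world"):
    """User with n_posts evenly spaced posts of fixed text."""
    posts = [Post(uid, start + dt.timedelta(days=i * step_days), text)
             for i in range(n_posts)]
    return UserRecord(user_id=uid, posts=posts, label=label)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator: 20 cases, 1:3, ~60 posts/user."""
    return GeneratorConfig(
        seed=101,
        n_cases=20,
        controls_per_case=3,
        pool_factor=1.5,
        post_count_distribution={"depressed": (60.0, 5.0), "control": (60.0, 5.0)},
        observation_span_weeks=40,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_corpus):
    users, anns, _ = small_corpus
    cohort = build_cohort(users, anns, k=3, seed=5)
    cohort.validate()
    return cohort
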