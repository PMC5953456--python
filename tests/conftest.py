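import numpy as np
import pytest
from hypothesis import settings

from uqm import birthday_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from uqm.datasets import doping_study_counts, study_condition


@pytest.fixture(scope="session")
def one_third():
    return birthday_design("one_third")


@pytest.fixture(scope="session")
def two_thirds():
    return birthday_design("two_thirds")


@pytest.fixture(scope="session")
def study_counts():
    """The four published (item, design) count pairs."""
    return doping_study_counts()


@pytest.fixture(scope="session")
def physical_conditions():
    return (
        study_condition("physical", "one_third"),
        study_condition("physical", "two_thirds"),
    )


@pytest.fixture(scope="session")
def cognitive_conditions():
    return (
        study_condition("cognitive", "one_third"),
        study_condition("cognitive", "two_thirds"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20180515)


@pytest.fixture()
def counts_file(tmp_path, study_counts):
    """The published counts as a tab-separated file."""
    path = tmp_path / "counts.tsv"
    lines = ["item\tdesign_label\tyes\tno"]
    variant = {True: "one_third", False: "two_thirds"}
    for c in study_counts:
        v = variant[float(c.design.p) < 0.5]
        lines.append(f"{c.item}\t{v}\t{c.yes}\t{c.no}")
    path.write_text("\n".join(lines) + "\n")
    return path
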