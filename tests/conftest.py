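import numpy as np
import pytest

from srs_chaos.core import AudioSegment, SegmentPart
from srs_chaos.fixtures import load_paper_fixtures
from srs_chaos.preprocess import segments_to_parts
from srs_chaos.synthetic import DatasetDesign, generate_dataset


@pytest.fixture(scope="session")
def paper_fixtures():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def small_dataset():
    """A small multi-subject dataset: 2 subjects x 3 classes x 4 segments."""
    design = DatasetDesign(
        [(s, label, 4) for s in ("s1", "s2") for label in ("snore", "breathing", "silence")]
    )
    return generate_dataset(design, seed=42)


@pytest.fixture(scope="session")
def small_parts(small_dataset):
    return segments_to_parts(small_dataset)


@pytest.fixture(scope="session")
def small_features(small_parts):
    from srs_chaos.features import extract_features

    return extract_features(small_parts)


def make_part(samples, label="silence", subject="s0"):
    return SegmentPart(
        samples=np.asarray(samples, dtype=float),
        label=label,
        subject_id=subject,
        part_index=0,
    )
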