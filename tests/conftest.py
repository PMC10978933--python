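import pytest

from mbaqc.io import merge_plates, parse_xponent
from mbaqc.synth import AnomalySpec, SyntheticStudySpec, default_anomalies, generate_study

#: study seed used throughout the suite
SEED = 11


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Five plates with low-bead injections on plates 2 and 4."""
    out = tmp_path_factory.mktemp("small_study")
    spec = SyntheticStudySpec(n_plates=5, seed=SEED)
    anomalies = [AnomalySpec(kind="low_bead_bias", target_plates=(2, 4))]
    paths, truth = generate_study(spec, anomalies, out)
    return spec, paths, truth


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The default 32-plate study (antigens on 29/19/32 plates, 4 controls)
    with the full demonstration anomaly set."""
    out = tmp_path_factory.mktemp("full_study")
    spec = SyntheticStudySpec(seed=SEED)
    paths, truth = generate_study(spec, default_anomalies(), out)
    return spec, paths, truth


@pytest.fixture(scope="session")
def full_plates(full_study):
    _, paths, _ = full_study
    return [parse_xponent(p) for p in paths]


@pytest.fixture(scope="session")
def merged_full(full_plates):
    return merge_plates(full_plates)


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """An anomaly-free 12-plate study for false-positive checks."""
    out = tmp_path_factory.mktemp("clean_study")
    spec = SyntheticStudySpec(n_plates=12, seed=SEED + 1)
    paths, truth = generate_study(spec, [], out)
    return spec, paths, truth


@pytest.fixture(scope="session")
def one_plate(full_plates):
    return full_plates[3]  # plate 4: no injected anomalies
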