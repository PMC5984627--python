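import pytest

from fuscan import synthetic_data as sd
from fuscan.cli_report import load_config, run_pipeline
from fuscan.io_formats import Parameters


@pytest.fixture(scope="session")
def params() -> Parameters:
    return Parameters()


@pytest.fixture(scope="session")
def fos_bundle() -> sd.ScenarioBundle:
    return sd.build_scenario("fos-like", 7)


@pytest.fixture(scope="session")
def fosb_bundle() -> sd.ScenarioBundle:
    return sd.build_scenario("fosb-like", 7)


@pytest.fixture(scope="session")
def negative_bundle() -> sd.ScenarioBundle:
    return sd.build_scenario("negative", 7)


@pytest.fixture(scope="session")
def fos_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fos-like")
    return sd.generate_scenario("fos-like", 11, d)


@pytest.fixture(scope="session")
def fosb_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fosb-like")
    return sd.generate_scenario("fosb-like", 11, d)


@pytest.fixture(scope="session")
def negative_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("negative")
    return sd.generate_scenario("negative", 11, d)


@pytest.fixture(scope="session")
def fos_run(fos_dir):
    paths, truth = fos_dir
    return run_pipeline(load_config(paths["config"])), truth


@pytest.fixture(scope="session")
def fosb_run(fosb_dir):
    paths, truth = fosb_dir
    return run_pipeline(load_config(paths["config"])), truth


@pytest.fixture(scope="session")
def negative_run(negative_dir):
    paths, truth = negative_dir
    return run_pipeline(load_config(paths["config"])), truth
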