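import pytest

from ocuperm import builtin_models, published_fixtures


@pytest.fixture(scope="session")
def bundle():
    return published_fixtures()


@pytest.fixture(scope="session")
def models():
    return builtin_models()


@pytest.fixture(scope="session")
def models_by_name(models):
    return {m.name: m for m in models}


@pytest.fixture()
def descriptor_csv(tmp_path, bundle):
    path = tmp_path / "descriptors.csv"
    bundle.descriptor_table.to_csv(path, index=False)
    return path


@pytest.fixture()
def ki_csv(tmp_path, bundle):
    path = tmp_path / "ki_panel.csv"
    bundle.ki_panel.to_csv(path, index=False)
    return path
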