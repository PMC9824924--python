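import pytest

from bioforge import Measurement, SimConfig, simulate


def make_measurement(**kwargs) -> Measurement:
    """A well-formed exact IC50 measurement, overridable per test."""
    defaults = dict(
        source_id="S1",
        molecule_ref="c1ccccc1O",
        target_accession="P00001",
        assay_id="A001",
        activity_type="IC50",
        relation="=",
        value=100.0,
        unit="nM",
        year=2010,
        target_mapping="single",
    )
    defaults.update(kwargs)
    return Measurement(**defaults)


@pytest.fixture(scope="session")
def noiseless_world():
    """Zero-noise, zero-bias, artefact-free world: observed == truth."""
    cfg = SimConfig(
        noise_sd=0.0,
        assay_bias_sd=0.0,
        censored_fraction=0.0,
        binary_fraction=0.0,
        variant_fraction=0.0,
        homolog_fraction=0.0,
        source_overlap=0.0,
        detection_window=(-50.0, 50.0),
        seed=7,
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def messy_world():
    """Default-config world with every planted artefact switched on."""
    cfg = SimConfig(seed=3)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def messy_measurements(messy_world):
    _, data = messy_world
    return [m for src in data.sources.values() for m in src]
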