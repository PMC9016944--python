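import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gutsulfur.catalog import GeneCatalog, GeneDefinition, default_catalog
from gutsulfur.ingest import MagRecord


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def mini_catalog():
    """Small hand-built catalog with one cutoff-less entry."""
    defs = [
        GeneDefinition("dsrA", "dsr subunit A", "inorganic", True, "K11180", 50.0),
        GeneDefinition("dsrB", "dsr subunit B", "inorganic", True, "K11181", 60.0),
        GeneDefinition("mgl", "methionine gamma-lyase", "organic_cys_met", True, "K01761", 40.0),
        GeneDefinition("tpa", "taurine-pyruvate aminotransferase", "organic_taurine", False, "K03851", 30.0),
        GeneDefinition("toa", "taurine-2-oxoglutarate transaminase", "organic_taurine", False, "toa_custom", None),
    ]
    return GeneCatalog(entries={d.symbol: d for d in defs}, version="mini")


def make_record(mag_id, participant_id="P1", state="healthy", **kw):
    defaults = dict(
        study="synthetic",
        completeness=95.0,
        contamination=1.0,
        strain_heterogeneity=0.1,
    )
    defaults.update(kw)
    return MagRecord(
        mag_id=mag_id, participant_id=participant_id, disease_state=state, **defaults
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
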