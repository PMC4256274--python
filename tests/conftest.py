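import pytest
from hypothesis import HealthCheck, settings

from slipscan import Cds, GeneDesign, design_gene, designed_run

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# the 56-nt synthetic RNA used as the reverse-transcription control
SYNTHETIC_RNA_56NT = "GCCGGCUAUUAUGAGGCGUUUAAAAAAAAAAAUGGGUCCGGGGCUGAUGCUGUUAG"


@pytest.fixture(scope="session")
def synthetic_rna():
    return Cds(id="synthetic_56nt", seq=SYNTHETIC_RNA_56NT, alphabet="RNA", source="synthetic")


@pytest.fixture(scope="session")
def default_design():
    return GeneDesign(seed=7)


@pytest.fixture(scope="session")
def fixture_gene(default_design):
    """Designed gene with the natural tssM1-like geometry (807/1129 aa)."""
    return design_gene(default_design)


@pytest.fixture(scope="session")
def fixture_run(default_design):
    return designed_run(default_design)


def small_design(seed, **overrides):
    """A compact slippery-gene design for oracle sweeps (fast to generate)."""
    kwargs = dict(upstream_codons=25, run_length=11, spacer_nt=28,
                  plus1_orf_codons=12, seed=seed)
    kwargs.update(overrides)
    return GeneDesign(**kwargs)
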