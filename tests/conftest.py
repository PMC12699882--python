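import pytest
from hypothesis import settings

from mitoscope import locpred, ppr, synth

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


#: a small configuration for tests that only need valid files, not power
SMALL_SYNTH = synth.SynthConfig(
    n_proteins=80,
    n_ppr_proteins=6,
    n_decoy_proteins=20,
    n_cx9c_proteins=3,
    n_ak_proteins=3,
    protein_ref_sizes=(15, 15),
    motif_ref_sizes=(8, 40),
    seed=7,
)


@pytest.fixture(scope="session")
def small_data():
    return synth.generate_all(SMALL_SYNTH)


@pytest.fixture(scope="session")
def default_data():
    """The default-condition benchmark dataset (study-sized references)."""
    return synth.generate_all(synth.SynthConfig())


@pytest.fixture(scope="session")
def default_calls(default_data):
    return {r.protein_id: locpred.wa_score(r)
            for r in default_data.predictor_rows}


@pytest.fixture(scope="session")
def default_discovery(default_data):
    """Full two-iteration PPR discovery on the default dataset (the
    expensive end-to-end fixture; computed once per session)."""
    tracks = {t.protein_id: t for t in default_data.tracks}
    return ppr.iterate_discovery(
        default_data.proteins, default_data.hits,
        ref=default_data.motif_reference, tracks=tracks,
        config=ppr.PprConfig())


def overlap_fraction(a, b):
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])
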