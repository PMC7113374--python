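import numpy as np
import pytest

from mutaccum import calls, simulate


def make_call(
    sample="S1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="C",
    origin=calls.ORIGIN_SMALL,
    af=0.9,
    zygosity=None,
    **kwargs,
):
    """Terse CandidateCall builder for unit tests."""
    c = calls.CandidateCall(
        sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        origin=origin, af=af, **kwargs,
    )
    c.zygosity = zygosity
    return c


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    """A small simulated cohort with default noise, shared across tests.

    The induced rate is scaled up so the 400 kb test genome carries a few
    dozen events; everything else follows the gamma-1500 preset.
    """
    import dataclasses

    outdir = tmp_path_factory.mktemp("cohort")
    preset = simulate.get_preset("gamma-1500")
    profile = dataclasses.replace(preset.profile, mf_per_site=2e-5)
    return simulate.simulate_cohort(
        preset="gamma-1500", profile=profile, n_samples=4,
        genome_length=400_000, n_genes=20, seed=11, outdir=outdir,
    )
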