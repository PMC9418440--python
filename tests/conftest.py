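import numpy as np
import pandas as pd
import pytest

from modcall.models import PipelineConfig, TranscriptModel
from modcall.simulate import SimParams, simulate_study


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A compact study: quick, but enough sites for distributional checks."""
    return SimParams(n_transcripts=30, n_truth_sites=120, seed=7)


@pytest.fixture(scope="session")
def study(small_params):
    return simulate_study(small_params)


@pytest.fixture()
def toy_transcript() -> TranscriptModel:
    """5'UTR 100 nt | CDS 300 nt | 3'UTR 200 nt, deterministic sequence."""
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGU"), size=600))
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="g1",
        len_5utr=100,
        len_cds=300,
        len_3utr=200,
        sequence=seq,
    )


def make_site(
    site_id,
    transcript_id,
    start,
    end=None,
    rate_stress=0.5,
    rate_control=0.25,
    kmer="GGACU",
):
    from modcall.models import ModSite

    return ModSite(
        site_id=site_id,
        transcript_id=transcript_id,
        start=start,
        end=start + 5 if end is None else end,
        n_xpore=1,
        n_nanocompore=1,
        best_p_xpore=1e-4,
        best_p_nanocompore=1e-4,
        rate_stress=rate_stress,
        rate_control=rate_control,
        kmer=kmer,
    )


def make_xpore_row(
    transcript_id="tx1",
    position=100,
    kmer="GGACU",
    rate_stress=0.48,
    rate_control=0.27,
    pvalue=0.005,
):
    return {
        "transcript_id": transcript_id,
        "position": position,
        "kmer": kmer,
        "rate_stress": rate_stress,
        "rate_control": rate_control,
        "pvalue": pvalue,
    }


def make_nano_row(
    transcript_id="tx1",
    position=100,
    kmer="GGACU",
    p_gmm_logit=0.001,
    p_ks_intensity=0.003,
    p_ks_dwell=0.009,
):
    return {
        "transcript_id": transcript_id,
        "position": position,
        "kmer": kmer,
        "p_gmm_logit": p_gmm_logit,
        "p_ks_intensity": p_ks_intensity,
        "p_ks_dwell": p_ks_dwell,
    }


def xpore_frame(rows):
    return pd.DataFrame([make_xpore_row(**r) for r in rows])


def nano_frame(rows):
    return pd.DataFrame([make_nano_row(**r) for r in rows])
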