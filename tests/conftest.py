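import numpy as np
import pandas as pd
import pytest

from mvi import synthetic as syn
from mvi.io_model import ContigRecord, OmicsMatrix, SampleMeta


@pytest.fixture(scope="session")
def small_community():
    """A small seeded community with sequences plus simulated counts."""
    spec = syn.CommunitySpec.small(seed=7)
    com = syn.generate_community(spec)
    sim = syn.simulate_counts(spec, com.truth, com.samples)
    return com, sim


@pytest.fixture()
def tiny_matrix():
    counts = pd.DataFrame(
        {"s1": [100, 50], "s2": [0, 10]}, index=["A", "B"], dtype=np.int64
    )
    breadth = pd.DataFrame({"s1": [0.9, 0.8], "s2": [0.0, 0.5]}, index=["A", "B"])
    return OmicsMatrix(counts=counts, breadth=breadth, dataset="MV")


def make_contig(contig_id, length, seq=None, **kw):
    return ContigRecord(contig_id=contig_id, length_bp=length, sequence=seq, **kw)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def trio_samples():
    out = []
    for participant in ("U1", "U2"):
        for site in ("PC", "DC", "STL"):
            for dataset in ("MG", "MV"):
                out.append(
                    SampleMeta(
                        sample_id=f"{participant}_{site}_{dataset}",
                        participant=participant,
                        site=site,
                        dataset=dataset,
                    )
                )
            if site != "STL":
                out.append(
                    SampleMeta(
                        sample_id=f"{participant}_{site}_MT",
                        participant=participant,
                        site=site,
                        dataset="MT",
                    )
                )
    return out
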