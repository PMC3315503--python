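import numpy as np
import pytest

from domainmine.reference_db import load_packaged_db
from domainmine.search import HitRecord
from domainmine.synthetic import simulate_reference_family
from domainmine.trimming import TrimmedDomain


@pytest.fixture(scope="session")
def ks_db():
    return load_packaged_db("KS")


@pytest.fixture(scope="session")
def c_db():
    return load_packaged_db("C")


@pytest.fixture(scope="session")
def small_family():
    """Compact 4-class KS family for fast unit tests."""
    db, newick = simulate_reference_family(
        n_classes=4, members_per_class=3, domain_length=120, seed=7, domain_type="KS"
    )
    return db


def make_tag(tag_id: str, seq: str, subject_class: str = "Cis-AT", e_value: float = 1e-20) -> TrimmedDomain:
    """Free-standing trimmed tag for stages downstream of search."""
    hit = HitRecord(
        query_id=tag_id,
        subject_id="ref",
        raw_score=100,
        bit_score=50.0,
        e_value=e_value,
        percent_identity=100.0,
        alignment_length=len(seq),
        q_start=0,
        q_end=len(seq),
        s_start=0,
        s_end=len(seq),
        subject_product="product",
        subject_class=subject_class,
        subject_pathway_type="PKS",
    )
    return TrimmedDomain(
        tag_id=tag_id,
        aa_sequence=seq,
        parent_query_id=tag_id,
        frame=None,
        strand=None,
        aa_start=0,
        aa_end=len(seq),
        nt_start=None,
        nt_end=None,
        best_hit=hit,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
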