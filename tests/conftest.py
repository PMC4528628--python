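import pytest
from hypothesis import HealthCheck, settings

from tissuerank import (
    GeneRecord,
    GeneRegistry,
    PlantedSignal,
    SyntheticSpec,
    build_profiles_by_source,
    generate_bundle,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(
    canonical_id,
    symbol,
    species="human",
    chromosome="chr1",
    start=1_000,
    end=2_000,
    aliases=(),
    **kwargs,
):
    return GeneRecord(
        canonical_id=canonical_id,
        approved_symbol=symbol,
        species=species,
        chromosome=chromosome,
        span_start=start,
        span_end=end,
        aliases=frozenset(aliases),
        **kwargs,
    )


@pytest.fixture()
def registry():
    """Small registry with an ambiguous alias (X1 on both G1 and G2)."""
    records = [
        make_record(
            "G1", "BRCA1", aliases={"X1", "RNF53"},
            ensembl_id="ENSG00000012048", entrez_id="672", refseq_id="NM_007294",
            start=1_000, end=5_000, exons=((1_000, 1_500), (4_000, 5_000)),
        ),
        make_record(
            "G2", "TP53", aliases={"X1", "P53"},
            ensembl_id="ENSG00000141510", entrez_id="7157", refseq_id="NM_000546",
            start=10_000, end=15_000, exons=((10_000, 10_800), (14_000, 15_000)),
        ),
        make_record(
            "G3", "EGFR", aliases={"ERBB1"}, chromosome="chr2",
            ensembl_id="ENSG00000146648", entrez_id="1956", refseq_id="NM_005228",
            start=2_000, end=9_000, exons=((2_000, 2_400), (8_000, 9_000)),
        ),
    ]
    return GeneRegistry(records)


@pytest.fixture(scope="session")
def planted_bundle():
    """Synthetic study: gene G0001 planted 3 log-units high in liver."""
    spec = SyntheticSpec(
        n_genes=80,
        planted=(PlantedSignal("G0001", frozenset({"liver"}), 3.0),),
        seed=11,
    )
    bundle = generate_bundle(spec)
    profiles = build_profiles_by_source(bundle.datasets)
    return bundle, profiles
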