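import pytest

from osteoproba import pipeline, synthetic
from osteoproba.psm_io import SampleResult, SpectrumMatch


def make_match(
    sample_id="S1",
    spectrum_id="sp1",
    peptide="GPAGK",
    e_value=0.001,
    is_decoy=False,
    species=("homo sapiens",),
):
    return SpectrumMatch(
        sample_id=sample_id,
        spectrum_id=spectrum_id,
        peptide=peptide,
        e_value=e_value,
        is_decoy=is_decoy,
        species=frozenset(species),
    )


def make_sample(rows, sample_id="S1", **kwargs):
    """rows: iterable of dicts forwarded to make_match."""
    matches = [make_match(sample_id=sample_id, **row) for row in rows]
    return SampleResult(sample_id=sample_id, matches=matches, **kwargs)


@pytest.fixture
def make_sample_factory():
    return make_sample


def small_species_table():
    S = synthetic.SpeciesSpec
    return [
        S("Homo sapiens", "Primates", "Mammalia", 50000, 4),
        S("Macaca mulatta", "Primates", "Mammalia", 30000, 1),
        S("Ovis aries", "Artiodactyla", "Mammalia", 30000, 3),
        S("Bos taurus", "Artiodactyla", "Mammalia", 40000, 3),
        S("Odocoileus virginianus", "Artiodactyla", "Mammalia", 0, 2),
        S("Felis catus", "Carnivora", "Mammalia", 25000, 3),
        S("Gallus gallus", "Galliformes", "Aves", 30000, 2),
    ]


@pytest.fixture(scope="session")
def small_config():
    return synthetic.CohortConfig(
        species_table=small_species_table(),
        n_ovicaprid=0,
        spectra_range=(40, 90),
        consensus_pool_size=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    samples, truth, taxonomy, pools = synthetic.generate_cohort(small_config)
    filtered, _ = pipeline.filter_cohort(samples)
    return {
        "samples": samples,
        "filtered": filtered,
        "truth": truth,
        "taxonomy": taxonomy,
        "pools": pools,
        "config": small_config,
    }


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the study's default conditions: 58 samples, 18 taxa."""
    config = synthetic.CohortConfig(seed=11)
    samples, truth, taxonomy, pools = synthetic.generate_cohort(config)
    filtered, _ = pipeline.filter_cohort(samples)
    return {
        "samples": samples,
        "filtered": filtered,
        "truth": truth,
        "taxonomy": taxonomy,
        "pools": pools,
        "config": config,
    }


@pytest.fixture(scope="session")
def truth_map(default_cohort):
    return {
        r["sample_id"]: r.to_dict() for _, r in default_cohort["truth"].iterrows()
    }
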