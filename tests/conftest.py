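import pytest

from pvsignal.dedup import deduplicate
from pvsignal.io import assemble_cases, read_package
from pvsignal.synthetic import DrugSpec, SyntheticConfig, generate_database, simulate


def study_catalog(n_drugs: int = 30, n_planted: int = 3, rr: float = 8.0,
                  use_prob: float = 0.02) -> list[DrugSpec]:
    """A screening catalog: the first n_planted drugs carry the elevated RR."""
    return [
        DrugSpec(
            name=f"STUDY DRUG {i:02d}",
            use_prob=use_prob,
            rr=rr if i < n_planted else 1.0,
            atc_class="planted class" if i < n_planted else "null class",
        )
        for i in range(n_drugs)
    ]


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small database with injected duplicates, shared across tests."""
    return SyntheticConfig(
        n_cases=8000,
        drug_catalog=study_catalog(),
        baseline_event_prob=0.01,
        duplicate_fraction=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_db(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("srs") / "db"
    generate_database(small_config, out)
    return out


@pytest.fixture(scope="session")
def small_cases(small_db):
    """Assembled + deduplicated cases read back from the files on disk."""
    tables = read_package(small_db)
    assembly = assemble_cases(tables)
    cases, report = deduplicate(assembly.cases)
    return cases, report
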