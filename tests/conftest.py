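import pytest

from cerna import (
    SpongeMap,
    TargetMap,
    load_table1_sponge,
    load_table1_targets,
    load_table2_sponge,
    load_table2_targets,
)


@pytest.fixture(scope="session")
def table1_sponge() -> SpongeMap:
    return load_table1_sponge()


@pytest.fixture(scope="session")
def table2_sponge() -> SpongeMap:
    return load_table2_sponge()


@pytest.fixture(scope="session")
def table1_targets() -> TargetMap:
    return load_table1_targets()


@pytest.fixture(scope="session")
def table2_targets() -> TargetMap:
    return load_table2_targets()


@pytest.fixture(scope="session")
def combined_sponge(table1_sponge, table2_sponge) -> SpongeMap:
    return SpongeMap(table1_sponge.edges | table2_sponge.edges, group_label="combined")


@pytest.fixture(scope="session")
def combined_targets(table1_targets, table2_targets) -> TargetMap:
    return TargetMap(table1_targets.edges | table2_targets.edges)
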