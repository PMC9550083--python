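"""Shared fixtures: a tiny cohort for unit tests and the full study-size
cohort (2 × 10 samples, 200/100/50/30 planted classes) for closure tests.

Everything is generated programmatically and seeded; session scope keeps the
expensive pieces (reference, genome index, designed panel) to one build.
"""

from __future__ import annotations

import pytest

from indelmark import indel_catalog, primer_engine
from indelmark.synthetic_data import (
    CohortDesign,
    generate_reference,
    plant_cohort,
)


def make_tiny_design(**overrides) -> CohortDesign:
    base = dict(
        n_chromosomes=2,
        chrom_length=60_000,
        n_per_group=3,
        n_group_specific=12,
        n_group_common_shared=6,
        n_private=4,
        n_sub_threshold=3,
        seed=7,
    )
    base.update(overrides)
    return CohortDesign(**base)


@pytest.fixture(scope="session")
def tiny_design() -> CohortDesign:
    return make_tiny_design()


@pytest.fixture(scope="session")
def tiny_reference(tiny_design):
    return generate_reference(tiny_design)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design, tiny_reference):
    return plant_cohort(tiny_reference, tiny_design)


@pytest.fixture(scope="session")
def tiny_catalogs(tiny_cohort, tiny_reference):
    call_sets, _ = tiny_cohort
    by_group: dict[str, list] = {}
    for cs in call_sets:
        by_group.setdefault(cs.group, []).append(cs)
    return {
        g: indel_catalog.group_common(members, tiny_reference)
        for g, members in by_group.items()
    }


@pytest.fixture(scope="session")
def tiny_index(tiny_reference):
    return primer_engine.GenomeIndex(tiny_reference, k=18)


# --- full study-scale cohort (used by the closure/acceptance tests) ---------

@pytest.fixture(scope="session")
def full_design() -> CohortDesign:
    return CohortDesign(seed=1)


@pytest.fixture(scope="session")
def full_reference(full_design):
    return generate_reference(full_design)


@pytest.fixture(scope="session")
def full_cohort(full_design, full_reference):
    return plant_cohort(full_reference, full_design)


@pytest.fixture(scope="session")
def full_catalogs(full_cohort, full_reference):
    call_sets, _ = full_cohort
    by_group: dict[str, list] = {}
    for cs in call_sets:
        by_group.setdefault(cs.group, []).append(cs)
    return {
        g: indel_catalog.group_common(members, full_reference)
        for g, members in by_group.items()
    }


@pytest.fixture(scope="session")
def full_specific(full_catalogs):
    from indelmark.synthetic_data import GROUP_A, GROUP_B

    return indel_catalog.specific_indels(
        full_catalogs[GROUP_B], full_catalogs[GROUP_A], min_len=10
    )


@pytest.fixture(scope="session")
def full_panel(full_reference, full_specific):
    index = primer_engine.GenomeIndex(full_reference, k=18)
    return primer_engine.design_panel(
        full_reference, full_specific.variants, index=index
    )
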