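"""Shared fixtures: one session-scoped synthetic cohort plus derived tables."""

from __future__ import annotations

import pandas as pd
import pytest

from fusionscope.domain_architecture import (
    call_domains,
    classify_specificity,
    instances_from_table,
)
from fusionscope.fusion_annotation import (
    annotate_calls,
    deduplicate,
    deduplicate_for_domains,
)
from fusionscope.synthetic_data import SyntheticCohortSpec, generate_all

COHORT_SPEC = SyntheticCohortSpec(n_genes=60, n_samples=50, n_fusions=150, seed=11)


@pytest.fixture(scope="session")
def cohort():
    return generate_all(COHORT_SPEC)


@pytest.fixture(scope="session")
def annotated(cohort) -> pd.DataFrame:
    return annotate_calls(
        cohort.calls,
        cohort.models.models,
        cohort.models.contigs,
        cohort.models.pk_genes,
        cohort.models.tf_genes,
    )


@pytest.fixture(scope="session")
def unique(annotated) -> pd.DataFrame:
    return deduplicate(annotated)


@pytest.fixture(scope="session")
def domain_instances(cohort):
    return instances_from_table(cohort.domains, cohort.models.proteins)


@pytest.fixture(scope="session")
def domain_calls(unique, domain_instances) -> pd.DataFrame:
    dom_fusions = deduplicate_for_domains(unique[unique["protein_producing"]])
    return call_domains(dom_fusions, domain_instances)


@pytest.fixture(scope="session")
def specificity(domain_calls, cohort) -> pd.DataFrame:
    return classify_specificity(
        domain_calls, cohort.models.pk_genes, cohort.models.tf_genes
    )
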