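"""Shared fixtures: small hand-built tables and the default simulated cohort."""
import numpy as np
import pandas as pd
import pytest

from psomi.core_io import AbundanceTable, SampleMetadata, parse_taxonomy_string
from psomi.synthetic import default_psoriasis_config, generate_cohort


def make_table(values, taxa, samples, lineage_strings=None, is_relative=False):
    """Build an AbundanceTable from nested lists plus optional lineage text."""
    data = pd.DataFrame(np.asarray(values), index=list(taxa),
                        columns=list(samples))
    lineages = {}
    if lineage_strings:
        lineages = {t: parse_taxonomy_string(s)
                    for t, s in zip(taxa, lineage_strings)}
    return AbundanceTable(data, lineages, is_relative=is_relative)


def make_metadata(groups, severities=None):
    """Metadata from {sample_id: group}; case severities default to mild."""
    sample_ids = list(groups)
    if severities is None:
        severities = {s: ("not_applicable" if groups[s] == "control"
                          else "mild") for s in sample_ids}
    return SampleMetadata(pd.DataFrame(
        {"group": [groups[s] for s in sample_ids],
         "severity": [severities[s] for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id")))


@pytest.fixture(scope="session")
def default_cohort():
    """Default psoriasis-like cohort at 50 samples per group (seed 7)."""
    cfg = default_psoriasis_config(seed=7, n_cases=50, n_controls=50)
    table, md, truth = generate_cohort(cfg)
    return cfg, table, md, truth
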