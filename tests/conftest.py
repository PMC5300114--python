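"""Shared fixtures: the default synthetic study, run once per session.

The expensive pieces (training-set build, clustering, the two scans) are
session-scoped so the planted-signature, label-swap and residue-argmax
checks all read from one computation.
"""

from __future__ import annotations

import pytest

from simbal.domain_tools import cluster_nonredundant
from simbal.postprocess import residue_scores
from simbal.scan_engine import LabeledDatabase, ScanParams, scan
from simbal.synthetic_fixtures import FixtureSpec, generate_genome_set
from simbal.training_set_builder import parse_config, partition_targets

#: Scan resolution for the end-to-end study: window lengths 30 and up in
#: steps of 6, every start position. Length 30 is the residue-
#: extrapolation window; shorter windows carry tie-dominated rankings.
PIPELINE_PARAMS = ScanParams(min_length=30, length_step=6, position_step=1)


@pytest.fixture(scope="session")
def default_fixture():
    return generate_genome_set(FixtureSpec())


@pytest.fixture(scope="session")
def default_rules(default_fixture):
    return parse_config(default_fixture.config_text)


@pytest.fixture(scope="session")
def default_training_set(default_fixture, default_rules):
    return partition_targets(
        default_fixture.genomes, default_fixture.hits_by_genome, default_rules
    )


@pytest.fixture(scope="session")
def clustered_partitions(default_training_set):
    yes = cluster_nonredundant(default_training_set.yes_records)
    no = cluster_nonredundant(default_training_set.no_records)
    return yes, no


@pytest.fixture(scope="session")
def pipeline_scan(default_fixture, clustered_partitions):
    yes, no = clustered_partitions
    db = LabeledDatabase.from_partitions(yes, no)
    return scan(default_fixture.query, db, PIPELINE_PARAMS)


@pytest.fixture(scope="session")
def pipeline_scan_swapped(default_fixture, clustered_partitions):
    yes, no = clustered_partitions
    db = LabeledDatabase.from_partitions(no, yes)
    return scan(default_fixture.query, db, PIPELINE_PARAMS)


@pytest.fixture(scope="session")
def pipeline_residue_profiles(pipeline_scan):
    return residue_scores(pipeline_scan, 30)
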