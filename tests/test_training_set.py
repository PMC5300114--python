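"""Configuration grammar, genome verdicts, gene distance, partitioning."""

from __future__ import annotations

import math

import pytest

from simbal.io_formats import GeneFeature, HmmHit, SequenceRecord
from simbal.training_set_builder import (
    GenomeRecord,
    PartitionRuleSet,
    ThresholdClause,
    Verdict,
    evaluate_genome,
    gene_distance,
    parse_config,
    partition_targets,
)

RHOMBOID_CONFIG = """\
TARGET: PFAM/PF01694.HMM
TARGET SCORE: 21.9
NO: TIGRFAM/TIGR03501.HMM<12.5
NO: TIGRFAM/TIGR03867.HMM<16
NO: TIGRFAM/TIGR04212.HMM<210
NO: TIGRFAM/TIGR04179.HMM<40
YES: (TIGRFAM/TIGR03501.HMM>16, TIGRFAM/TIGR03867.HMM>20, TIGRFAM/TIGR04212.HMM>295, TIGRFAM/TIGR04179.HMM>150)
"""

RADICAL_SAM_CONFIG = """\
TARGET: PFAM/PF04055.HMM
TARGET SCORE: 29.4
YES: ([500] TIGRFAM/TIGR03973.HMM>35)
NO: TIGRFAM/TIGR03973.HMM<35
"""


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

def test_parse_sorting_signal_config():
    rules = parse_config(RHOMBOID_CONFIG)
    assert rules.target_hmm == "PF01694"
    assert rules.target_cutoff == 21.9
    assert rules.yes_distance_bp is None
    assert [(c.hmm_id, c.threshold) for c in rules.no_clauses] == [
        ("TIGR03501", 12.5), ("TIGR03867", 16), ("TIGR04212", 210),
        ("TIGR04179", 40),
    ]
    assert all(c.direction == "below" for c in rules.no_clauses)
    assert len(rules.yes_groups) == 1
    group = rules.yes_groups[0]
    assert [(c.hmm_id, c.threshold) for c in group] == [
        ("TIGR03501", 16), ("TIGR03867", 20), ("TIGR04212", 295),
        ("TIGR04179", 150),
    ]
    assert all(c.direction == "above" for c in group)


def test_parse_distance_config():
    rules = parse_config(RADICAL_SAM_CONFIG)
    assert rules.target_hmm == "PF04055"
    assert rules.target_cutoff == 29.4
    assert rules.yes_distance_bp == 500
    assert rules.yes_groups == [[ThresholdClause("TIGR03973", "above", 35.0)]]
    assert rules.no_clauses == [ThresholdClause("TIGR03973", "below", 35.0)]


def test_parse_config_missing_keys_listed():
    with pytest.raises(ValueError) as err:
        parse_config("TARGET: X.HMM\nTARGET SCORE: 10\n")
    assert "YES" in str(err.value) and "NO" in str(err.value)


@pytest.mark.parametrize("text, match", [
    ("TARGET: A.HMM\nTARGET: B.HMM\nTARGET SCORE: 1\nYES: (A.HMM>1)\nNO: A.HMM<1\n",
     "duplicate TARGET"),
    ("TARGET: A.HMM\nTARGET SCORE: 1\nYES: (A.HMM~1)\nNO: A.HMM<1\n",
     "line 3"),
])
def test_parse_config_errors(text, match):
    with pytest.raises(ValueError, match=match):
        parse_config(text)


def test_comments_and_blank_lines_ignored():
    rules = parse_config("# comment\n\n" + RADICAL_SAM_CONFIG)
    assert rules.target_hmm == "PF04055"


# ---------------------------------------------------------------------------
# Genome verdicts
# ---------------------------------------------------------------------------

def _hit(hmm, score):
    return HmmHit("px", hmm, score)


def test_one_marker_above_trusted_cutoff_is_yes_eligible():
    rules = parse_config(RHOMBOID_CONFIG)
    assert evaluate_genome([_hit("TIGR03501", 20)], rules) is Verdict.YES_ELIGIBLE


def test_no_attribute_hits_is_no_genome():
    rules = parse_config(RHOMBOID_CONFIG)
    assert evaluate_genome([], rules) is Verdict.NO


def test_gray_zone_hit_is_indeterminate():
    rules = parse_config(RHOMBOID_CONFIG)
    # 14 sits between the noise cutoff 12.5 and the trusted cutoff 16
    assert evaluate_genome([_hit("TIGR03501", 14)], rules) is Verdict.INDETERMINATE


def test_multiple_yes_groups_are_anded():
    rules = PartitionRuleSet(
        target_hmm="T", target_cutoff=10,
        yes_groups=[[ThresholdClause("A", "above", 5)],
                    [ThresholdClause("B", "above", 5)]],
        no_clauses=[ThresholdClause("A", "below", 2),
                    ThresholdClause("B", "below", 2)],
    )
    assert evaluate_genome([_hit("A", 9)], rules) is Verdict.INDETERMINATE
    assert evaluate_genome([_hit("A", 9), _hit("B", 9)], rules) is Verdict.YES_ELIGIBLE


# ---------------------------------------------------------------------------
# Gene distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a, b, expected", [
    (("chr1", 100, 400), ("chr1", 350, 600), 0),      # overlap
    (("chr1", 100, 400), ("chr1", 401, 600), 0),      # abut
    (("chr1", 100, 400), ("chr1", 501, 900), 100),    # gap
    (("chr1", 501, 900), ("chr1", 100, 400), 100),    # symmetric
])
def test_gene_distance_arithmetic(a, b, expected):
    fa = GeneFeature("a", a[0], a[1], a[2], "+")
    fb = GeneFeature("b", b[0], b[1], b[2], "-")
    assert gene_distance(fa, fb) == expected
    assert gene_distance(fb, fa) == expected


def test_gene_distance_across_replicons_is_infinite():
    fa = GeneFeature("a", "chr1", 100, 400, "+")
    fb = GeneFeature("b", "plasmid1", 100, 400, "+")
    assert gene_distance(fa, fb) == math.inf


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _genome(gid, n_targets, features=None):
    prots = [SequenceRecord(id=f"{gid}_t{i}", residues="MKTLVAAA")
             for i in range(n_targets)]
    return GenomeRecord(id=gid, proteins=prots, features=features)


def _simple_rules(distance=None):
    return PartitionRuleSet(
        target_hmm="T", target_cutoff=25,
        yes_groups=[[ThresholdClause("A", "above", 30)]],
        no_clauses=[ThresholdClause("A", "below", 20)],
        yes_distance_bp=distance,
    )


def _target_hits(gid, n, score=40.0):
    return [HmmHit(f"{gid}_t{i}", "T", score) for i in range(n)]


def test_partition_without_distance_rule():
    rules = _simple_rules()
    genomes = [_genome("gY", 2), _genome("gN", 1), _genome("gI", 1)]
    hits = {
        "gY": _target_hits("gY", 2) + [HmmHit("x", "A", 50)],
        "gN": _target_hits("gN", 1),
        "gI": _target_hits("gI", 1) + [HmmHit("x", "A", 25)],  # gray zone
    }
    ts = partition_targets(genomes, hits, rules)
    assert len(ts.yes_records) == 2
    assert len(ts.no_records) == 1
    assert len(ts.far_records) == 0
    assert {r.id for r in ts.no_records} == {"gN_t0"}


def test_partition_distance_rule_near_and_far():
    rules = _simple_rules(distance=500)
    features = {
        "gY_t0": GeneFeature("gY_t0", "chr", 2100, 3000, "+"),   # gap 99
        "gY_t1": GeneFeature("gY_t1", "chr", 90000, 91000, "+"),  # far
        "attr": GeneFeature("attr", "chr", 1000, 2000, "+"),
    }
    genome = _genome("gY", 2, features=features)
    hits = {"gY": _target_hits("gY", 2) + [HmmHit("attr", "A", 50)]}
    ts = partition_targets([genome], hits, rules)
    assert [r.id for r in ts.yes_records] == ["gY_t0"]
    assert [r.id for r in ts.far_records] == ["gY_t1"]
    assert ts.no_records == []


def test_attribute_present_but_no_near_target_contributes_nothing():
    rules = _simple_rules(distance=500)
    features = {
        "gY_t0": GeneFeature("gY_t0", "chr", 12001, 13000, "+"),  # 10 kb away
        "attr": GeneFeature("attr", "chr", 1000, 2000, "+"),
    }
    genome = _genome("gY", 1, features=features)
    hits = {"gY": _target_hits("gY", 1) + [HmmHit("attr", "A", 50)]}
    ts = partition_targets([genome], hits, rules)
    assert ts.yes_records == [] and ts.far_records == [] and ts.no_records == []


def test_subthreshold_attribute_gene_cannot_anchor_neighborhood():
    rules = _simple_rules(distance=500)
    features = {
        "gY_t0": GeneFeature("gY_t0", "chr", 2100, 3000, "+"),
        "attr_strong": GeneFeature("attr_strong", "chr", 90000, 91000, "+"),
        "attr_weak": GeneFeature("attr_weak", "chr", 1000, 2000, "+"),
    }
    genome = _genome("gY", 1, features=features)
    hits = {"gY": _target_hits("gY", 1)
            + [HmmHit("attr_strong", "A", 50), HmmHit("attr_weak", "A", 22)]}
    # genome is YES-eligible via attr_strong, but the only near gene is the
    # gray-zone attr_weak, which must not anchor the neighborhood
    ts = partition_targets([genome], hits, rules)
    assert ts.yes_records == [] and ts.far_records == []


def test_distance_mode_missing_features_raises():
    rules = _simple_rules(distance=500)
    genome = _genome("gY", 1)  # no feature table
    hits = {"gY": _target_hits("gY", 1) + [HmmHit("attr", "A", 50)]}
    with pytest.raises(ValueError, match="gY"):
        partition_targets([genome], hits, rules)


# ---------------------------------------------------------------------------
# Partition invariants on the default synthetic study
# ---------------------------------------------------------------------------

def test_partitions_are_disjoint(default_training_set):
    keys = [(p.genome_id, p.protein_id) for p in default_training_set.provenance]
    assert len(keys) == len(set(keys))


def test_partition_matches_truth_table(default_fixture, default_training_set):
    expected = {"YES": set(), "NO": set(), "FAR": set()}
    for row in default_fixture.truth_rows:
        if row.expected_partition in expected:
            expected[row.expected_partition].add(
                (row.genome_id, row.protein_id))
    got = {"YES": set(), "NO": set(), "FAR": set()}
    for p in default_training_set.provenance:
        got[p.partition].add((p.genome_id, p.protein_id))
    assert got == expected


def test_raising_target_cutoff_never_adds_records(default_fixture, default_rules):
    import dataclasses
    ts_low = partition_targets(default_fixture.genomes,
                               default_fixture.hits_by_genome, default_rules)
    strict = dataclasses.replace(default_rules,
                                 target_cutoff=default_rules.target_cutoff + 30)
    ts_high = partition_targets(default_fixture.genomes,
                                default_fixture.hits_by_genome, strict)
    for attr in ("yes_records", "no_records", "far_records"):
        low_ids = {r.id for r in getattr(ts_low, attr)}
        high_ids = {r.id for r in getattr(ts_high, attr)}
        assert high_ids <= low_ids


def test_infinite_distance_equals_no_distance_with_empty_far(
    default_fixture, default_rules
):
    import dataclasses
    no_dist = dataclasses.replace(default_rules, yes_distance_bp=None)
    huge = dataclasses.replace(default_rules, yes_distance_bp=10 ** 12)
    ts_plain = partition_targets(default_fixture.genomes,
                                 default_fixture.hits_by_genome, no_dist)
    ts_huge = partition_targets(default_fixture.genomes,
                                default_fixture.hits_by_genome, huge)
    assert {r.id for r in ts_huge.yes_records} == {
        r.id for r in ts_plain.yes_records}
    assert ts_huge.far_records == []
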