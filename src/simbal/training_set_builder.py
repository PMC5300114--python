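"""Partition a target protein family into YES/NO/FAR training sets.

The builder collects every protein that matches a *target* family HMM
above a cutoff, then sorts those proteins according to whether their
source genome carries (YES) or lacks (NO) one or more *attribute*
families, each defined by its own HMM and bit-score threshold. Genomes
that satisfy neither the full YES criteria nor the full NO criteria fall
in a gray zone and contribute nothing.

Optionally a YES group may carry a distance constraint: only target genes
lying within a given number of base pairs of a qualifying attribute gene
go to YES; the remaining target genes of that genome go to the FAR set,
but only if the genome sent at least one protein to YES.

The rule grammar is a plain-text configuration file::

    TARGET: PFAM/PF01694.HMM
    TARGET SCORE: 21.9
    NO: TIGRFAM/TIGR03501.HMM<12.5
    YES: ([500] TIGRFAM/TIGR03501.HMM>16, TIGRFAM/TIGR03867.HMM>20)

Separate NO lines are AND-ed ("all families absent"); clauses inside a
parenthesised YES group are OR-ed ("any of these present") and separate
YES lines are AND-ed groups. ``<`` means *absence*: no hit may score at
or above the threshold. ``>`` means *presence*: some hit must score
strictly above. A ``[N]`` prefix inside a YES group sets the distance
constraint in base pairs. ``#`` begins a comment.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from simbal.io_formats import GeneFeature, HmmHit, SequenceRecord


class Verdict(enum.Enum):
    """Genome-level outcome of the attribute rules."""

    YES_ELIGIBLE = "YES-eligible"
    NO = "NO"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ThresholdClause:
    """One HMM/bit-score test.

    ``direction="above"`` asserts presence: some hit with
    ``full_score > threshold``. ``direction="below"`` asserts absence: no
    hit with ``full_score >= threshold`` (every hit strictly below).
    """

    hmm_id: str
    direction: str  # "above" | "below"
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def satisfied(self, hits: Sequence[HmmHit]) -> bool:
        scores = [h.full_score for h in hits if h.hmm_id == self.hmm_id]
        if self.direction == "above":
            return any(s > self.threshold for s in scores)
        return all(s < self.threshold for s in scores)  # vacuously true


@dataclass
class PartitionRuleSet:
    """Parsed configuration: target family plus YES/NO criteria."""

    target_hmm: str
    target_cutoff: float
    yes_groups: list[list[ThresholdClause]]  # groups AND-ed, clauses OR-ed
    no_clauses: list[ThresholdClause]        # AND-ed
    yes_distance_bp: int | None = None


@dataclass
class GenomeRecord:
    """One genome: identifier, proteome, optional gene coordinates."""

    id: str
    proteins: list[SequenceRecord]
    features: dict[str, GeneFeature] | None = None  # protein_id -> feature


@dataclass
class ProvenanceRow:
    genome_id: str
    protein_id: str
    partition: str  # YES | NO | FAR
    reason: str


@dataclass
class TrainingSet:
    """The YES/NO/FAR partitions with per-record provenance."""

    yes_records: list[SequenceRecord] = field(default_factory=list)
    no_records: list[SequenceRecord] = field(default_factory=list)
    far_records: list[SequenceRecord] = field(default_factory=list)
    provenance: list[ProvenanceRow] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Configuration grammar
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(r"^\s*(\S+?)\s*([<>])\s*([-+]?\d+(?:\.\d+)?)\s*$")
_DIST_RE = re.compile(r"^\s*\[\s*(\d+)\s*\]\s*(.*)$", re.S)


def hmm_stem(token: str) -> str:
    """Reduce an HMM path token like ``TIGRFAM/TIGR03501.HMM`` to its id."""
    name = token.rsplit("/", 1)[-1]
    if name.upper().endswith(".HMM"):
        name = name[:-4]
    return name


def _parse_clause(text: str, lineno: int) -> ThresholdClause:
    m = _CLAUSE_RE.match(text)
    if not m:
        raise ValueError(f"line {lineno}: cannot parse clause {text.strip()!r}")
    token, op, score = m.groups()
    return ThresholdClause(
        hmm_id=hmm_stem(token),
        direction="above" if op == ">" else "below",
        threshold=float(score),
    )


def parse_config(text: str) -> PartitionRuleSet:
    """Parse the configuration grammar into a :class:`PartitionRuleSet`."""
    target: str | None = None
    cutoff: float | None = None
    yes_groups: list[list[ThresholdClause]] = []
    no_clauses: list[ThresholdClause] = []
    distance: int | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'KEY: VALUE', got {line!r}")
        key, value = line.split(":", 1)
        key = key.strip().upper()
        value = value.strip()
        if key == "TARGET":
            if target is not None:
                raise ValueError(f"line {lineno}: duplicate TARGET")
            target = hmm_stem(value)
        elif key == "TARGET SCORE":
            if cutoff is not None:
                raise ValueError(f"line {lineno}: duplicate TARGET SCORE")
            cutoff = float(value)
        elif key == "NO":
            no_clauses.append(_parse_clause(value, lineno))
        elif key == "YES":
            body = value
            if body.startswith("(") and body.endswith(")"):
                body = body[1:-1]
            m = _DIST_RE.match(body)
            if m:
                if distance is not None:
                    raise ValueError(
                        f"line {lineno}: distance constraint given twice"
                    )
                distance = int(m.group(1))
                body = m.group(2)
            group = [
                _parse_clause(part, lineno)
                for part in body.split(",") if part.strip()
            ]
            if not group:
                raise ValueError(f"line {lineno}: empty YES group")
            yes_groups.append(group)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")

    missing = [k for k, v in (("TARGET", target), ("TARGET SCORE", cutoff))
               if v is None]
    if not yes_groups:
        missing.append("YES")
    if not no_clauses:
        missing.append("NO")
    if missing:
        raise ValueError("configuration missing required keys: "
                         + ", ".join(missing))
    return PartitionRuleSet(
        target_hmm=target,
        target_cutoff=cutoff,
        yes_groups=yes_groups,
        no_clauses=no_clauses,
        yes_distance_bp=distance,
    )


# ---------------------------------------------------------------------------
# Genome-level verdicts
# ---------------------------------------------------------------------------

def evaluate_genome(hits: Sequence[HmmHit], rules: PartitionRuleSet) -> Verdict:
    """Classify a genome from its attribute-HMM hits.

    YES-eligible iff every YES group has at least one satisfied clause;
    NO iff every NO clause (absence test) is satisfied; anything else is
    indeterminate (the TC/NC gray zone) and contributes nothing.
    """
    if all(any(c.satisfied(hits) for c in group) for group in rules.yes_groups):
        return Verdict.YES_ELIGIBLE
    if all(c.satisfied(hits) for c in rules.no_clauses):
        return Verdict.NO
    return Verdict.INDETERMINATE


def gene_distance(a: GeneFeature, b: GeneFeature) -> float:
    """Nucleotide gap between two gene intervals, strand-agnostic.

    Returns ``math.inf`` for genes on different replicons, 0 when the
    intervals overlap or abut, otherwise the number of bases strictly
    between them.
    """
    if a.replicon_id != b.replicon_id:
        return math.inf
    if a.start <= b.end and b.start <= a.end:  # overlap
        return 0
    if a.end < b.start:
        return max(0, b.start - a.end - 1)
    return max(0, a.start - b.end - 1)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _target_proteins(
    genome: GenomeRecord, hits: Sequence[HmmHit], rules: PartitionRuleSet
) -> list[SequenceRecord]:
    eligible = {
        h.protein_id for h in hits
        if h.hmm_id == rules.target_hmm and h.full_score > rules.target_cutoff
    }
    return [p for p in genome.proteins if p.id in eligible]


def _distance_anchors(
    genome: GenomeRecord, hits: Sequence[HmmHit], rules: PartitionRuleSet
) -> list[GeneFeature]:
    """Attribute genes that can anchor the distance constraint.

    Only hits satisfying an ``above`` clause of a YES group count; a
    sub-threshold attribute hit must not define a neighborhood.
    """
    anchors: list[GeneFeature] = []
    assert genome.features is not None
    clauses = [c for g in rules.yes_groups for c in g if c.direction == "above"]
    for hit in hits:
        if any(c.hmm_id == hit.hmm_id and hit.full_score > c.threshold
               for c in clauses):
            feat = genome.features.get(hit.protein_id)
            if feat is not None:
                anchors.append(feat)
    return anchors


def partition_targets(
    genomes: Iterable[GenomeRecord],
    hits_by_genome: Mapping[str, Sequence[HmmHit]],
    rules: PartitionRuleSet,
) -> TrainingSet:
    """Sort target-family proteins into YES/NO/FAR partitions.

    Without a distance constraint every target from a YES-eligible genome
    goes to YES and every target from a NO genome goes to NO. With a
    distance constraint, targets of a YES-eligible genome within
    ``yes_distance_bp`` of a qualifying attribute gene go to YES and the
    rest go to FAR -- but only when the genome contributed at least one
    YES record; a YES-eligible genome with no near target contributes
    nothing. Indeterminate genomes never contribute.
    """
    ts = TrainingSet()
    for genome in genomes:
        hits = list(hits_by_genome.get(genome.id, ()))
        verdict = evaluate_genome(hits, rules)
        targets = _target_proteins(genome, hits, rules)
        if not targets or verdict is Verdict.INDETERMINATE:
            continue
        if verdict is Verdict.NO:
            for rec in targets:
                ts.no_records.append(rec)
                ts.provenance.append(ProvenanceRow(
                    genome.id, rec.id, "NO", "genome satisfies all NO clauses"))
            continue
        # YES-eligible
        if rules.yes_distance_bp is None:
            for rec in targets:
                ts.yes_records.append(rec)
                ts.provenance.append(ProvenanceRow(
                    genome.id, rec.id, "YES", "genome satisfies YES criteria"))
            continue
        if genome.features is None:
            raise ValueError(
                f"genome {genome.id}: distance rule requires gene features"
            )
        anchors = _distance_anchors(genome, hits, rules)
        near: list[tuple[SequenceRecord, float]] = []
        far: list[SequenceRecord] = []
        for rec in targets:
            feat = genome.features.get(rec.id)
            if feat is None:
                raise ValueError(
                    f"genome {genome.id}: no feature for target {rec.id}"
                )
            d = min((gene_distance(feat, a) for a in anchors), default=math.inf)
            if d <= rules.yes_distance_bp:
                near.append((rec, d))
            else:
                far.append(rec)
        if not near:
            continue  # attribute present but no near target: contribute nothing
        for rec, d in near:
            ts.yes_records.append(rec)
            ts.provenance.append(ProvenanceRow(
                genome.id, rec.id, "YES",
                f"within {rules.yes_distance_bp} bp of attribute (gap {d:.0f})"))
        for rec in far:
            ts.far_records.append(rec)
            ts.provenance.append(ProvenanceRow(
                genome.id, rec.id, "FAR",
                f"beyond {rules.yes_distance_bp} bp of nearest attribute"))
    return ts
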