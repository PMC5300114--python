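"""Seeded synthetic genomes, hit tables and planted-signature proteins.

Every stage of the pipeline is testable offline against fixtures built
here: toy genomes whose proteomes contain a *target* family (homologs of
a shared consensus), an optional *attribute* protein, per-genome HMM hit
tables consistent with a known truth table, and GFF3 gene coordinates
that place one "true" target near the attribute gene and decoys far
away.

The planted biology: every true target carries a short signature motif
(lightly mutated per copy); decoy targets and targets from
attribute-free genomes do not. A scan of a true-target query against the
resulting YES/NO training set should therefore peak over the motif span
and nowhere else, and swapping the labels should abolish the peak.

Family members are drawn at *unequal* distances from the consensus
(a per-record divergence rate), mimicking the phylogenetic structure of
real families: hit rankings at non-signature windows are then dominated
by each record's overall proximity to the query rather than by
independent per-window noise, exactly the label correlation the scan
statistic is known not to correct for.

Hit tables are generated directly rather than by running a profile-HMM
search, so the rule engine is exercised independently of any external
executable; scores are placed unambiguously above or below the fixture's
cutoffs according to the truth table (gray-zone genomes get attribute
scores between the NO and YES thresholds).

All randomness flows from the single ``seed`` through one generator:
the same spec yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from simbal.io_formats import (
    AMINO_ACIDS,
    GeneFeature,
    HmmHit,
    SequenceRecord,
    write_fasta,
)
from simbal.training_set_builder import GenomeRecord

TARGET_HMM = "TARGETFAM"
ATTRIBUTE_HMM = "ATTRFAM"

#: Signature motif planted in true targets: rich in rare residues (W, C,
#: Y, H) so that even short windows align to it unmistakably.
DEFAULT_MOTIF = "WCHKEYWNDQMRFCW"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic genome set.

    Defaults model a desk-scale version of a real training-set build:
    attribute-positive genomes average 2.7 target-family paralogs and
    attribute-free genomes 1.5, with a distance rule (500 bp) so that
    only the one attribute-adjacent paralog per positive genome reaches
    the YES partition.
    """

    n_genomes: int = 40
    p_attribute: float = 0.3
    p_gray: float = 0.1
    yes_targets_mean: float = 2.7
    no_targets_mean: float = 1.5
    motif: str = DEFAULT_MOTIF
    motif_position: int = 61
    mutation_rate: float = 0.1
    protein_length: int = 140
    divergence_range: tuple[float, float] = (0.20, 0.50)
    distance_mode: bool = True
    yes_distance_bp: int = 500
    near_gap_bp: int = 100
    far_gap_bp: int = 5000
    target_cutoff: float = 25.0
    attr_yes_threshold: float = 30.0
    attr_no_threshold: float = 20.0
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("p_attribute", "p_gray", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_attribute + self.p_gray > 1:
            raise ValueError("p_attribute + p_gray must not exceed 1")
        if len(self.motif) < 6:
            raise ValueError("motif must be at least 6 residues")
        if self.motif_position + len(self.motif) - 1 > self.protein_length:
            raise ValueError("motif does not fit in the protein")

    @property
    def motif_span(self) -> tuple[int, int]:
        """1-based inclusive residue span of the planted motif."""
        return (self.motif_position, self.motif_position + len(self.motif) - 1)


@dataclass(frozen=True)
class TruthRow:
    genome_id: str
    protein_id: str
    role: str               # true_target | decoy_target | attribute | junk
    genome_verdict: str     # YES-eligible | NO | indeterminate
    expected_partition: str  # YES | NO | FAR | -


@dataclass
class FixtureSet:
    """Everything one synthetic study needs, in memory."""

    spec: FixtureSpec
    genomes: list[GenomeRecord]
    hits_by_genome: dict[str, list[HmmHit]]
    truth_rows: list[TruthRow]
    query: SequenceRecord
    config_text: str


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: tuple[int, int] | None = None) -> str:
    """Substitute each residue with probability ``rate`` (never to itself).

    ``protected`` is an optional 1-based inclusive span left untouched.
    """
    out = list(seq)
    for i in range(len(out)):
        if protected and protected[0] - 1 <= i <= protected[1] - 1:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def plant_signature(
    base: str,
    motif: str,
    position: int,
    mutation_rate: float,
    seed: int,
    conserved_core: tuple[int, int] | None = None,
) -> str:
    """Write ``motif`` into ``base`` at 1-based ``position``, then apply
    per-residue substitutions at ``mutation_rate`` everywhere outside the
    optional ``conserved_core`` span. Deterministic per seed."""
    if position < 1 or position + len(motif) - 1 > len(base):
        raise ValueError(
            f"motif of length {len(motif)} at position {position} does not "
            f"fit in a base of length {len(base)}"
        )
    rng = np.random.default_rng(seed)
    planted = base[:position - 1] + motif + base[position - 1 + len(motif):]
    return _mutate(rng, planted, mutation_rate, protected=conserved_core)


# ---------------------------------------------------------------------------
# Genome-set generation
# ---------------------------------------------------------------------------

def _fake_evalue(score: float) -> float:
    return 10 ** (2.0 - score / 2.0)


def generate_genome_set(spec: FixtureSpec) -> FixtureSet:
    """Generate genomes, hit tables, gene coordinates and the truth table.

    Genome composition: with probability ``p_attribute`` a genome carries
    the attribute protein plus exactly one motif-bearing true target and
    Poisson-distributed decoy targets (mean ``yes_targets_mean`` - 1);
    with probability ``p_gray`` it carries an attribute protein scoring
    in the gray zone between the NO and YES thresholds; otherwise it is
    attribute-free with Poisson(``no_targets_mean``) targets. Gene
    coordinates place the true target within ``near_gap_bp`` of the
    attribute gene and everything else ``far_gap_bp`` apart.

    A dedicated motif-bearing query sequence (not a member of any
    genome) is generated last.
    """
    rng = np.random.default_rng(spec.seed)
    consensus = _random_protein(rng, spec.protein_length)
    lo, hi = spec.divergence_range

    genomes: list[GenomeRecord] = []
    hits_by_genome: dict[str, list[HmmHit]] = {}
    truth: list[TruthRow] = []

    # Divergences follow a golden-ratio ladder rather than iid draws, so
    # the YES and NO classes end up with matched distance-to-consensus
    # profiles. Without this matching, whichever class happened to draw
    # the least-diverged members would dominate every hit ranking -- a
    # lineage-depth confound that would swamp the planted signature.
    target_counter = [0]

    def make_target(true: bool) -> str:
        i = target_counter[0]
        target_counter[0] += 1
        divergence = lo + (hi - lo) * ((0.5 + i * 0.6180339887498949) % 1.0)
        seq = _mutate(rng, consensus, divergence)
        if true:
            motif_copy = _mutate(rng, spec.motif, spec.mutation_rate)
            p = spec.motif_position
            seq = seq[:p - 1] + motif_copy + seq[p - 1 + len(motif_copy):]
        return seq

    for g in range(spec.n_genomes):
        gid = f"G{g + 1:03d}"
        u = rng.random()
        if u < spec.p_attribute:
            gtype = "YES"
        elif u < spec.p_attribute + spec.p_gray:
            gtype = "gray"
        else:
            gtype = "NO"

        proteins: list[SequenceRecord] = []
        hits: list[HmmHit] = []
        rows: list[tuple[str, str]] = []  # (protein_id, role)

        if gtype == "YES":
            n_decoys = int(rng.poisson(max(0.0, spec.yes_targets_mean - 1)))
            plan = ["attribute", "true_target"] + ["decoy_target"] * n_decoys
        elif gtype == "gray":
            n_targets = int(rng.poisson(spec.no_targets_mean))
            plan = ["attribute_gray"] + ["decoy_target"] * n_targets
        else:
            n_targets = int(rng.poisson(spec.no_targets_mean))
            plan = ["decoy_target"] * n_targets
        plan.append("junk")

        for k, role in enumerate(plan):
            pid = f"{gid}_P{k + 1:02d}"
            if role in ("attribute", "attribute_gray"):
                seq = _random_protein(rng, 120)
                if role == "attribute":
                    score = float(rng.uniform(spec.attr_yes_threshold + 5,
                                              spec.attr_yes_threshold + 30))
                else:
                    score = float(rng.uniform(spec.attr_no_threshold + 1,
                                              spec.attr_yes_threshold - 1))
                hits.append(HmmHit(pid, ATTRIBUTE_HMM, round(score, 1),
                                   [(5, 100, round(score, 1))]))
                rows.append((pid, "attribute"))
            elif role in ("true_target", "decoy_target"):
                seq = make_target(true=(role == "true_target"))
                score = float(rng.uniform(spec.target_cutoff + 5,
                                          spec.target_cutoff + 55))
                env = (8, spec.protein_length - 12)
                hits.append(HmmHit(pid, TARGET_HMM, round(score, 1),
                                   [(env[0], env[1], round(score, 1))]))
                rows.append((pid, role))
            else:  # junk: unrelated protein, no hits
                seq = _random_protein(rng, 90)
                rows.append((pid, "junk"))
            proteins.append(SequenceRecord(id=pid, residues=seq))

        features = _layout_genes(spec, gid, proteins, dict(rows))
        genomes.append(GenomeRecord(id=gid, proteins=proteins,
                                    features=features))
        hits_by_genome[gid] = hits

        verdict = {"YES": "YES-eligible", "NO": "NO",
                   "gray": "indeterminate"}[gtype]
        for pid, role in rows:
            truth.append(TruthRow(
                genome_id=gid, protein_id=pid, role=role,
                genome_verdict=verdict,
                expected_partition=_expected_partition(spec, gtype, role),
            ))

    query_seq = make_target(true=True)
    query = SequenceRecord(id="QUERY1", residues=query_seq,
                           description="synthetic true-target query")
    return FixtureSet(
        spec=spec,
        genomes=genomes,
        hits_by_genome=hits_by_genome,
        truth_rows=truth,
        query=query,
        config_text=fixture_config_text(spec),
    )


def _expected_partition(spec: FixtureSpec, gtype: str, role: str) -> str:
    if role in ("attribute", "junk") or gtype == "gray":
        return "-"
    if gtype == "NO":
        return "NO" if role == "decoy_target" else "-"
    # YES genome
    if role == "true_target":
        return "YES"
    if spec.distance_mode:
        return "FAR"
    return "YES"


def _layout_genes(
    spec: FixtureSpec,
    gid: str,
    proteins: Sequence[SequenceRecord],
    roles: Mapping[str, str],
) -> dict[str, GeneFeature]:
    """Lay genes along one replicon: true target adjacent to the
    attribute gene, everything else widely separated."""
    features: dict[str, GeneFeature] = {}
    cursor = 1000
    prev_role: str | None = None
    for i, prot in enumerate(proteins):
        role = roles[prot.id]
        if i > 0:
            gap = (spec.near_gap_bp
                   if prev_role in ("attribute", "attribute_gray")
                   and role == "true_target"
                   else spec.far_gap_bp)
            cursor = features[proteins[i - 1].id].end + gap + 1
        glen = 3 * len(prot.residues) + 3
        features[prot.id] = GeneFeature(
            protein_id=prot.id,
            replicon_id=f"{gid}_chr",
            start=cursor,
            end=cursor + glen - 1,
            strand="+" if i % 2 == 0 else "-",
        )
        prev_role = role
    return features


def fixture_config_text(spec: FixtureSpec) -> str:
    """The rule file matching the generated hit tables."""
    prefix = f"[{spec.yes_distance_bp}] " if spec.distance_mode else ""
    return (
        "# synthetic fixture rules\n"
        f"TARGET: FIX/{TARGET_HMM}.HMM\n"
        f"TARGET SCORE: {spec.target_cutoff:g}\n"
        f"YES: ({prefix}FIX/{ATTRIBUTE_HMM}.HMM>{spec.attr_yes_threshold:g})\n"
        f"NO: FIX/{ATTRIBUTE_HMM}.HMM<{spec.attr_no_threshold:g}\n"
    )


# ---------------------------------------------------------------------------
# On-disk fixture trees
# ---------------------------------------------------------------------------

def write_domtblout(
    hits: Iterable[HmmHit],
    lengths: Mapping[str, int],
    path: str | Path,
    qlen: int = 130,
) -> None:
    """Write hits as an hmmsearch per-domain (domtblout) table."""
    grouped: dict[str, list[HmmHit]] = {}
    for h in hits:
        grouped.setdefault(h.hmm_id, []).append(h)
    with open(path, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "hmm-from hmm-to ali-from ali-to env-from env-to acc "
                 "description\n")
        for hmm_id, hmm_hits in grouped.items():
            for h in hmm_hits:
                envs = h.envelopes or [(1, lengths[h.protein_id], h.full_score)]
                n = len(envs)
                for idx, (es, ee, ds) in enumerate(envs, 1):
                    fh.write(
                        f"{h.protein_id} - {lengths[h.protein_id]} {hmm_id} - "
                        f"{qlen} {_fake_evalue(h.full_score):.2g} "
                        f"{h.full_score:.1f} 0.1 {idx} {n} "
                        f"{_fake_evalue(ds):.2g} {_fake_evalue(ds):.2g} "
                        f"{ds:.1f} 0.1 1 {qlen} {es} {ee} {es} {ee} 0.90 "
                        f"synthetic\n"
                    )


def write_tblout(hits: Iterable[HmmHit], path: str | Path) -> None:
    """Write hits as an hmmsearch per-sequence (tblout) table."""
    with open(path, "w") as fh:
        fh.write("# target name accession query name accession E-value "
                 "score bias E-value score bias exp reg clu ov env dom "
                 "rep inc description\n")
        for h in hits:
            ev = _fake_evalue(h.full_score)
            fh.write(
                f"{h.protein_id} - {h.hmm_id} - {ev:.2g} {h.full_score:.1f} "
                f"0.1 {ev:.2g} {h.full_score:.1f} 0.1 1.0 1 0 0 1 1 1 1 "
                f"synthetic\n"
            )


def write_gff(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 CDS lines."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.replicon_id, f.start)):
            fh.write(
                f"{f.replicon_id}\tsimbal_fixture\tCDS\t{f.start}\t{f.end}\t."
                f"\t{f.strand}\t0\tID={f.protein_id}_cds;"
                f"protein_id={f.protein_id}\n"
            )


def write_fixture_dir(fixture: FixtureSet, outdir: str | Path) -> None:
    """Write the fixture as the on-disk tree the CLI consumes.

    Layout: ``genomes/<id>.fasta``, ``genomes/<id>.gff``,
    ``hits/<id>.domtbl``, ``config.txt``, ``query.fasta``, ``truth.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(parents=True, exist_ok=True)
    for genome in fixture.genomes:
        write_fasta(genome.proteins, outdir / "genomes" / f"{genome.id}.fasta")
        assert genome.features is not None
        write_gff(genome.features.values(),
                  outdir / "genomes" / f"{genome.id}.gff")
        lengths = {p.id: len(p.residues) for p in genome.proteins}
        write_domtblout(fixture.hits_by_genome[genome.id], lengths,
                        outdir / "hits" / f"{genome.id}.domtbl")
    (outdir / "config.txt").write_text(fixture.config_text)
    write_fasta([fixture.query], outdir / "query.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("genome_id\tprotein_id\trole\tgenome_verdict\t"
                 "expected_partition\n")
        for row in fixture.truth_rows:
            fh.write(f"{row.genome_id}\t{row.protein_id}\t{row.role}\t"
                     f"{row.genome_verdict}\t{row.expected_partition}\n")
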