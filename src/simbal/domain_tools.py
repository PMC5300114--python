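"""Domain extraction and redundancy reduction.

Two standard preparation steps between training-set construction and
scanning: cutting HMM-matched domain regions (plus optional flanking
residues) out of full-length proteins, and greedy identity clustering so
that no two retained sequences exceed a given pairwise identity (default
80%). Domain extraction should precede clustering so that unequal domain
architectures do not confound either step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from simbal.io_formats import HmmHit, SequenceRecord

DEFAULT_IDENTITY_THRESHOLD = 0.80


@dataclass(frozen=True)
class DomainCut:
    """One extracted domain region, 1-based inclusive coordinates."""

    source_id: str
    ordinal: int
    cut_start: int
    cut_end: int
    residues: str

    @property
    def export_id(self) -> str:
        return f"{self.source_id}/{self.cut_start}-{self.cut_end}"

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.export_id, residues=self.residues,
                              description=f"domain {self.ordinal}")


def extract_domains(
    seqs: Sequence[SequenceRecord],
    hits: Sequence[HmmHit],
    flank: int = 0,
) -> list[DomainCut]:
    """Cut each domain envelope (with ``flank`` extra residues each side)
    out of its source protein.

    Envelopes come from per-domain (domtblout) hit tables; a protein with
    several envelopes yields several cuts, numbered by ordinal. Cuts are
    clamped to the sequence bounds. A hit naming an unknown sequence, or
    an envelope past the end of its sequence, is an error: those inputs
    are corrupt.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    by_id = {s.id: s for s in seqs}
    cuts: list[DomainCut] = []
    for hit in hits:
        seq = by_id.get(hit.protein_id)
        if seq is None:
            raise ValueError(f"hit references unknown sequence {hit.protein_id!r}")
        for ordinal, (env_start, env_end, _score) in enumerate(hit.envelopes, 1):
            if env_end > len(seq) or env_start < 1:
                raise ValueError(
                    f"{hit.protein_id}: envelope {env_start}-{env_end} outside "
                    f"sequence of length {len(seq)}"
                )
            cut_start = max(1, env_start - flank)
            cut_end = min(len(seq), env_end + flank)
            cuts.append(DomainCut(
                source_id=seq.id,
                ordinal=ordinal,
                cut_start=cut_start,
                cut_end=cut_end,
                residues=seq.residues[cut_start - 1:cut_end],
            ))
    return cuts


# ---------------------------------------------------------------------------
# Pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps: domain cuts of unequal flank length should still align
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER: Align.PairwiseAligner | None = None


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two residue strings in [0, 1].

    Identity is matches divided by alignment columns, excluding columns
    that fall in a terminal gap (so a sequence fully contained in a
    longer one at 100% match scores 1.0). Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _identity_aligner()
    aln = _ALIGNER.align(a, b)[0]
    s0, s1 = str(aln[0]), str(aln[1])
    lead = max(len(s0) - len(s0.lstrip("-")), len(s1) - len(s1.lstrip("-")))
    trail = max(len(s0) - len(s0.rstrip("-")), len(s1) - len(s1.rstrip("-")))
    end = len(s0) - trail
    if end <= lead:
        return 0.0
    matches = sum(1 for i in range(lead, end) if s0[i] == s1[i] and s0[i] != "-")
    return matches / (end - lead)


def cluster_nonredundant(
    seqs: Iterable[SequenceRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[SequenceRecord]:
    """Greedy centroid clustering; returns one representative per cluster.

    Sequences are processed longest-first (ties broken by input order).
    Each sequence joins the first existing centroid with identity at or
    above the threshold, otherwise founds a new centroid. Output
    centroids are therefore actual input records, never consensus
    chimeras, and no two centroids reach the threshold identity.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    ordered = sorted(
        enumerate(seqs), key=lambda item: (-len(item[1].residues), item[0])
    )
    centroids: list[SequenceRecord] = []
    for _idx, rec in ordered:
        for centroid in centroids:
            if pairwise_identity(rec.residues, centroid.residues) >= identity_threshold:
                break
        else:
            centroids.append(rec)
    return centroids


def cluster_assignments(
    seqs: Sequence[SequenceRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> dict[str, str]:
    """Map every input id to its centroid id under the greedy scheme."""
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    ordered = sorted(
        enumerate(seqs), key=lambda item: (-len(item[1].residues), item[0])
    )
    centroids: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for _idx, rec in ordered:
        for centroid in centroids:
            if pairwise_identity(rec.residues, centroid.residues) >= identity_threshold:
                assignment[rec.id] = centroid.id
                break
        else:
            centroids.append(rec)
            assignment[rec.id] = rec.id
    return assignment
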