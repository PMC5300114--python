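"""Readers and writers for the formats the suite touches.

Four external formats cross the package boundary: protein FASTA (read and
write), GFF3 gene features (read), HMMER3 tabular hit files in both the
per-sequence (``tblout``) and per-domain (``domtblout``) dialects (read),
and the suite's own tab-delimited scan table (read and write).

Coordinate conventions: GFF3 nucleotide positions and all residue
coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SearchIO, SeqIO

logger = logging.getLogger("simbal")

#: The closed residue alphabet: the 20 standard amino acids plus X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: unique id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """Location of a protein-coding gene on its replicon.

    ``start``/``end`` are 1-based inclusive nucleotide positions with
    ``start <= end`` regardless of strand.
    """

    protein_id: str
    replicon_id: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.protein_id}: bad strand {self.strand!r}")


@dataclass
class HmmHit:
    """One protein-vs-HMM match.

    ``full_score`` is the full-sequence bit score used for all threshold
    tests. ``envelopes`` holds per-domain (env_start, env_end, dom_score)
    triples, 1-based inclusive; empty for tblout-derived hits.
    """

    protein_id: str
    hmm_id: str
    full_score: float
    envelopes: list[tuple[int, int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _clean_residues(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("*", "")
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        logger.warning(
            "record %s: ambiguous residues %s mapped to X", record_id, "".join(bad)
        )
        seq = "".join(c if c in ALPHABET else "X" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and any ambiguity code outside the 20 standard
    amino acids is mapped to X with a logged warning. A duplicate id is an
    error; an empty file yields an empty list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        residues = _clean_residues(str(rec.seq), rec.id)
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has no residues")
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_features(
    path: str | Path,
    id_attribute_keys: Sequence[str] = ("protein_id", "ID"),
) -> list[GeneFeature]:
    """Read CDS features from a GFF3 file.

    Each CDS line contributes one :class:`GeneFeature`; the protein id is
    taken from the first attribute key in ``id_attribute_keys`` that is
    present. Non-CDS feature types are ignored. A CDS whose attributes
    yield no id is skipped with a logged warning.

    Which attribute carries the protein accession varies between
    annotation providers, hence the configurable key order.
    """
    from gffutils.feature import feature_from_line

    features: list[GeneFeature] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 columns, "
                    f"got {len(line.split(chr(9)))}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line: {exc}")
            if feat.featuretype != "CDS":
                continue
            protein_id = next(
                (feat.attributes[k][0] for k in id_attribute_keys
                 if k in feat.attributes and feat.attributes[k]), None
            )
            if protein_id is None:
                skipped += 1
                logger.warning(
                    "%s:%d: CDS with no id under keys %s; skipped",
                    path, lineno, list(id_attribute_keys),
                )
                continue
            features.append(
                GeneFeature(
                    protein_id=protein_id,
                    replicon_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                )
            )
    if skipped:
        logger.warning("%s: %d CDS feature(s) skipped for missing ids", path, skipped)
    return features


# ---------------------------------------------------------------------------
# HMMER3 tabular hit files
# ---------------------------------------------------------------------------

_DIALECTS = {
    "tblout": ("hmmer3-tab", 18),
    "domtblout": ("hmmsearch3-domtab", 22),
}


def read_hmm_hits(path: str | Path, dialect: str) -> list[HmmHit]:
    """Read an ``hmmsearch`` tabular output file.

    ``dialect`` is ``"tblout"`` (per-sequence table; hits carry a full
    score and no envelopes) or ``"domtblout"`` (per-domain table; hits
    carry one envelope per domain line). Multiple lines for one
    protein/HMM pair are merged into a single :class:`HmmHit` keeping the
    maximum full score and the union of envelopes.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tblout' or 'domtblout'")
    fmt, min_cols = _DIALECTS[dialect]
    _check_columns(path, dialect, min_cols)
    merged: dict[tuple[str, str], HmmHit] = {}
    for qresult in SearchIO.parse(str(path), fmt):
        hmm_id = qresult.id
        for hit in qresult:
            key = (hit.id, hmm_id)
            envelopes: list[tuple[int, int, float]] = []
            if dialect == "domtblout":
                for hsp in hit:
                    # SearchIO env_start is 0-based; env_end is inclusive.
                    envelopes.append(
                        (hsp.env_start + 1, hsp.env_end, float(hsp.bitscore))
                    )
            if key in merged:
                prev = merged[key]
                prev.full_score = max(prev.full_score, float(hit.bitscore))
                prev.envelopes.extend(
                    e for e in envelopes if e not in prev.envelopes
                )
            else:
                merged[key] = HmmHit(
                    protein_id=hit.id,
                    hmm_id=hmm_id,
                    full_score=float(hit.bitscore),
                    envelopes=envelopes,
                )
    return list(merged.values())


def _check_columns(path: str | Path, dialect: str, min_cols: int) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ncols = len(line.split())
            # the trailing free-text description may itself contain spaces
            if ncols < min_cols + 1:
                raise ValueError(
                    f"{path}: {dialect} requires at least {min_cols} columns "
                    f"plus a description, found {ncols} -- wrong dialect?"
                )
            return


# ---------------------------------------------------------------------------
# Scan table (the suite's tab-delimited scan output)
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = (
    "start", "length", "midpoint", "score", "k_at_min", "y_at_min",
    "min_probability",
)


def write_scan_table(result, path: str | Path) -> None:
    """Write a scan result as the suite's tab-delimited table.

    A commented header preserves the query identity, scan parameters and
    training-set label counts so that :func:`read_scan_table` inverts the
    file losslessly (scores to 6 decimal places, probabilities to 6
    significant figures).
    """
    if not result.windows:
        raise ValueError("refusing to write an empty scan result")
    p = result.params
    with open(path, "w") as fh:
        fh.write("# simbal scan table v1\n")
        fh.write(f"# query_id: {result.query_id}\n")
        fh.write(f"# query_length: {result.query_length}\n")
        fh.write(f"# min_length: {p.min_length}\n")
        fh.write(f"# length_step: {p.length_step}\n")
        fh.write(f"# position_step: {p.position_step}\n")
        fh.write(f"# max_length: {p.max_length if p.max_length else '-'}\n")
        fh.write(f"# max_hits: {p.max_hits if p.max_hits else '-'}\n")
        fh.write(f"# backend: {p.backend}\n")
        fh.write(f"# yes_count: {result.yes_count}\n")
        fh.write(f"# no_count: {result.no_count}\n")
        fh.write("\t".join(_SCAN_COLUMNS) + "\n")
        for w in result.windows:
            fh.write(
                f"{w.start}\t{w.length}\t{w.midpoint:.1f}\t{w.score:.6f}\t"
                f"{w.k_at_min}\t{w.y_at_min}\t{w.min_probability:.6e}\n"
            )


def read_scan_table(path: str | Path):
    """Read a scan table written by :func:`write_scan_table`."""
    from simbal.scan_engine import ScanParams, ScanResult, ScoredWindow

    meta: dict[str, str] = {}
    windows: list[ScoredWindow] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _SCAN_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected scan-table header"
                    )
                header_seen = True
                continue
            cols = line.split("\t")
            if len(cols) != len(_SCAN_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_SCAN_COLUMNS)} columns, got {len(cols)}")
            start, length = int(cols[0]), int(cols[1])
            windows.append(
                ScoredWindow(
                    start=start,
                    length=length,
                    score=float(cols[3]),
                    k_at_min=int(cols[4]),
                    y_at_min=int(cols[5]),
                    min_probability=float(cols[6]),
                )
            )
    required = {"query_id", "query_length", "yes_count", "no_count", "min_length",
                "length_step", "position_step", "backend"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: scan table header missing {sorted(missing)}")

    def _opt(key: str) -> int | None:
        v = meta.get(key, "-")
        return None if v == "-" else int(v)

    params = ScanParams(
        min_length=int(meta["min_length"]),
        length_step=int(meta["length_step"]),
        position_step=int(meta["position_step"]),
        max_length=_opt("max_length"),
        max_hits=_opt("max_hits"),
        backend=meta["backend"],
    )
    return ScanResult(
        query_id=meta["query_id"],
        query_length=int(meta["query_length"]),
        params=params,
        yes_count=int(meta["yes_count"]),
        no_count=int(meta["no_count"]),
        windows=windows,
    )
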