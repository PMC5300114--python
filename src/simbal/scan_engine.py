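"""Sliding-window scan of a query protein against a labeled training set.

Every subsequence (window) of the query, enumerated at a configurable
length step ``j`` and position step ``w``, is searched against a database
built from the YES and NO training partitions. Walking down the ranked
hit list, each prefix of depth k containing y YES labels is assigned the
binomial tail probability P(X >= y) for X ~ Binomial(k, p) with
p = Y/(Y+N); the window's score is the negative log10 of the smallest
tail probability over all prefix depths. A high score marks a window
whose closest homologs skew toward the YES partition far beyond what
label frequency alone would produce.

Because nearby homologs are phylogenetically correlated, these scores
rank regions of one query against each other; they are not calibrated
p-values and must not be read as significance tests.

Two interchangeable search backends rank the hits: a builtin
Smith-Waterman backend (BLOSUM62, gap open -11 / extend -1, ranked by
raw alignment score) that needs no external executables, and an external
NCBI BLAST+ backend (``makeblastdb``/``blastp``, ranked by E-value) for
full-size runs.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import binom

from simbal.io_formats import SequenceRecord

BACKEND_BUILTIN = "builtin-alignment"
BACKEND_BLAST = "external-blast"


@dataclass(frozen=True)
class ScanParams:
    """Resolution and backend parameters for one scan.

    ``length_step`` (the -j flag) and ``position_step`` (the -w flag)
    subsample window lengths and start positions; both default to full
    resolution. ``min_length`` defaults to 6 residues; 9 is a common
    alternative that avoids the least reliable ultra-short searches.
    ``max_length`` optionally truncates the scan (a trapezoidal rather
    than triangular score landscape); ``max_hits`` caps the ranked-list
    depth considered per window.
    """

    min_length: int = 6
    length_step: int = 1
    position_step: int = 1
    max_length: int | None = None
    max_hits: int | None = None
    backend: str = BACKEND_BUILTIN

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.length_step < 1 or self.position_step < 1:
            raise ValueError("min_length, length_step and position_step must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")
        if self.backend not in (BACKEND_BUILTIN, BACKEND_BLAST):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class ScoredWindow:
    """One scored subsequence (1-based inclusive start)."""

    start: int
    length: int
    score: float
    k_at_min: int
    y_at_min: int
    min_probability: float

    @property
    def midpoint(self) -> float:
        return self.start + (self.length - 1) / 2

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class ScanResult:
    """The full grid of scored windows for one query."""

    query_id: str
    query_length: int
    params: ScanParams
    yes_count: int
    no_count: int
    windows: list[ScoredWindow]

    def peak(self) -> ScoredWindow:
        """Highest-scoring window (ties: shortest, then leftmost)."""
        return max(self.windows, key=lambda w: (w.score, -w.length, -w.start))


class LabeledDatabase:
    """YES/NO-labeled training sequences forming one searchable database."""

    def __init__(self, records: Sequence[tuple[SequenceRecord, str]]):
        seen: set[str] = set()
        for rec, label in records:
            if label not in ("YES", "NO"):
                raise ValueError(f"bad label {label!r} for {rec.id}")
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in database")
            seen.add(rec.id)
        self.records: list[tuple[SequenceRecord, str]] = list(records)
        self.yes_count = sum(1 for _r, lab in self.records if lab == "YES")
        self.no_count = len(self.records) - self.yes_count
        if self.yes_count < 1 or self.no_count < 1:
            raise ValueError(
                "database needs at least one YES and one NO record "
                f"(got Y={self.yes_count}, N={self.no_count})"
            )

    @classmethod
    def from_partitions(
        cls,
        yes_records: Iterable[SequenceRecord],
        no_records: Iterable[SequenceRecord],
    ) -> "LabeledDatabase":
        recs = [(r, "YES") for r in yes_records] + [(r, "NO") for r in no_records]
        return cls(recs)

    @property
    def p(self) -> float:
        """Prior probability that a randomly drawn record is YES."""
        return self.yes_count / (self.yes_count + self.no_count)

    def without(self, exclude_ids: Iterable[str]) -> "LabeledDatabase":
        excl = set(exclude_ids)
        return LabeledDatabase(
            [(r, lab) for r, lab in self.records if r.id not in excl]
        )

    def write_labeled_fasta(self, path: str | Path) -> None:
        """Write the combined database with label-prefixed ids (YES|id)."""
        with open(path, "w") as fh:
            for rec, label in self.records:
                fh.write(f">{label}|{rec.id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Window enumeration
# ---------------------------------------------------------------------------

def enumerate_windows(query_length: int, params: ScanParams) -> list[tuple[int, int]]:
    """All (start, length) windows for a query, ordered by (length, start).

    Lengths run from ``min_length`` in steps of ``length_step`` up to the
    scan ceiling (the query length, or ``max_length`` if smaller), always
    including the ceiling itself; starts run from 1 in steps of
    ``position_step``.
    """
    if params.min_length > query_length:
        raise ValueError(
            f"min_length {params.min_length} exceeds query length {query_length}"
        )
    ceiling = min(query_length, params.max_length or query_length)
    lengths = list(range(params.min_length, ceiling + 1, params.length_step))
    if lengths and lengths[-1] != ceiling:
        lengths.append(ceiling)
    windows: list[tuple[int, int]] = []
    for length in lengths:
        for start in range(1, query_length - length + 2, params.position_step):
            windows.append((start, length))
    return windows


def full_resolution_count(query_length: int, min_length: int) -> int:
    """Closed-form window count at j=1, w=1: sum over L of (Nq - L + 1)."""
    n = query_length - min_length + 1
    return n * (n + 1) // 2


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------

def binomial_tail(k: int, y: int, p: float) -> float:
    """Upper-tail probability P(X >= y), X ~ Binomial(k, p).

    The chance that drawing k training sequences at random (with
    replacement, YES probability p) yields y or more YES sequences.
    """
    if not 0 < p < 1:
        raise ValueError("p must be strictly between 0 and 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= y <= k:
        raise ValueError("y must satisfy 0 <= y <= k")
    if y == 0:
        return 1.0
    return float(binom.sf(y - 1, k, p))


class WindowScore(NamedTuple):
    min_probability: float
    k_at_min: int
    y_at_min: int
    score: float


def score_window(
    ranked_labels: Sequence[str],
    yes_count: int,
    no_count: int,
    max_hits: int | None = None,
) -> WindowScore:
    """Score one ranked hit list by the minimum binomial tail.

    For every prefix depth k of the ranked label list the tail
    probability of the observed YES count is computed; the window score
    is -log10 of the smallest probability, reported with the shallowest
    depth attaining it. An empty hit list scores 0.
    """
    p = yes_count / (yes_count + no_count)
    depth = len(ranked_labels)
    if max_hits is not None:
        depth = min(depth, max_hits)
    best_prob = 1.0
    best_k = 0
    best_y = 0
    y = 0
    for k in range(1, depth + 1):
        if ranked_labels[k - 1] == "YES":
            y += 1
        prob = binomial_tail(k, y, p)
        if prob < best_prob:
            best_prob, best_k, best_y = prob, k, y
    score = -math.log10(best_prob) if best_prob > 0 else math.inf
    return WindowScore(best_prob, best_k, best_y, max(0.0, score))


# ---------------------------------------------------------------------------
# Search backends
# ---------------------------------------------------------------------------

class BuiltinAlignmentBackend:
    """Rank database records by Smith-Waterman score against a fragment.

    Local alignment with BLOSUM62, gap open -11 / extend -1 -- the
    standard protein scoring scheme -- computed score-only. One entry per
    database record (its best local alignment), ranked by raw score with
    ties broken by record id for determinism. Records with no positive-
    scoring alignment are dropped.
    """

    def __init__(self, db: LabeledDatabase):
        self.db = db
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "local"
        self._aligner = aligner

    def rank(self, fragment: str) -> list[tuple[str, str, float]]:
        scored: list[tuple[float, str, str]] = []
        for rec, label in self.db.records:
            s = self._aligner.score(fragment, rec.residues)
            if s > 0:
                scored.append((s, rec.id, label))
        scored.sort(key=lambda t: (-t[0], t[1]))
        return [(rid, label, s) for s, rid, label in scored]


class BlastBackend:
    """Rank database records with NCBI BLAST+ (makeblastdb / blastp).

    Hits are ranked by E-value, then bit score descending, then record
    id; only the best HSP per subject is kept, since the sampling unit is
    a labeled sequence. Short fragments (< 30 residues) use the
    blastp-short task; composition-based statistics are disabled and the
    E-value ceiling is 10 so that short windows can return hits.
    """

    def __init__(self, db: LabeledDatabase, evalue: float = 10.0):
        if shutil.which("makeblastdb") is None or shutil.which("blastp") is None:
            raise RuntimeError(
                "NCBI BLAST+ executables not found on PATH; "
                "use the builtin-alignment backend instead"
            )
        self.db = db
        self.evalue = evalue
        self._tmpdir = tempfile.TemporaryDirectory(prefix="simbal-blastdb-")
        self._db_path = str(Path(self._tmpdir.name) / "training")
        fasta = Path(self._tmpdir.name) / "training.fasta"
        db.write_labeled_fasta(fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot",
             "-out", self._db_path],
            check=True, capture_output=True,
        )

    def rank(self, fragment: str) -> list[tuple[str, str, float]]:
        n_records = len(self.db.records)
        cmd = [
            "blastp", "-db", self._db_path,
            "-evalue", str(self.evalue),
            "-max_target_seqs", str(max(n_records, 500)),
            "-comp_based_stats", "0",
            "-seg", "no",
            "-outfmt", "6 sseqid evalue bitscore",
        ]
        if len(fragment) < 30:
            cmd += ["-task", "blastp-short"]
        proc = subprocess.run(
            cmd, input=f">frag\n{fragment}\n", text=True,
            check=True, capture_output=True,
        )
        best: dict[str, tuple[float, float]] = {}
        for line in proc.stdout.splitlines():
            sseqid, evalue, bitscore = line.split("\t")
            ev, bs = float(evalue), float(bitscore)
            cur = best.get(sseqid)
            if cur is None or (ev, -bs) < (cur[0], -cur[1]):
                best[sseqid] = (ev, bs)
        ranked = sorted(best.items(), key=lambda kv: (kv[1][0], -kv[1][1], kv[0]))
        out: list[tuple[str, str, float]] = []
        for labeled_id, (_ev, bs) in ranked:
            label, _, rid = labeled_id.partition("|")
            out.append((rid, label, bs))
        return out


def make_backend(db: LabeledDatabase, backend: str):
    if backend == BACKEND_BUILTIN:
        return BuiltinAlignmentBackend(db)
    if backend == BACKEND_BLAST:
        return BlastBackend(db)
    raise ValueError(f"unknown backend {backend!r}")


def rank_hits(
    query_fragment: str,
    db: LabeledDatabase,
    backend: str | BuiltinAlignmentBackend | BlastBackend = BACKEND_BUILTIN,
) -> list[tuple[str, str, float]]:
    """Rank database records against one query fragment, best first.

    Returns (record id, label, sort score) triples, at most one per
    database record. Convenience wrapper: pass a backend instance when
    ranking many fragments to reuse the prepared database.
    """
    if isinstance(backend, str):
        backend = make_backend(db, backend)
    return backend.rank(query_fragment)


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

_WORKER_STATE: dict = {}


def _init_worker(db_payload, backend_name, query_residues, max_hits):
    records = [
        (SequenceRecord(id=rid, residues=res), label)
        for rid, label, res in db_payload
    ]
    db = LabeledDatabase(records)
    _WORKER_STATE["db"] = db
    _WORKER_STATE["backend"] = make_backend(db, backend_name)
    _WORKER_STATE["query"] = query_residues
    _WORKER_STATE["max_hits"] = max_hits


def _score_chunk(chunk: list[tuple[int, int]]) -> list[ScoredWindow]:
    db = _WORKER_STATE["db"]
    backend = _WORKER_STATE["backend"]
    query = _WORKER_STATE["query"]
    max_hits = _WORKER_STATE["max_hits"]
    out: list[ScoredWindow] = []
    for start, length in chunk:
        fragment = query[start - 1:start - 1 + length]
        ranked = backend.rank(fragment)
        ws = score_window(
            [label for _rid, label, _s in ranked],
            db.yes_count, db.no_count, max_hits,
        )
        out.append(ScoredWindow(
            start=start, length=length, score=ws.score,
            k_at_min=ws.k_at_min, y_at_min=ws.y_at_min,
            min_probability=ws.min_probability,
        ))
    return out


def scan(
    query: SequenceRecord,
    db: LabeledDatabase,
    params: ScanParams | None = None,
    jobs: int = 1,
    exclude_ids: Iterable[str] | None = None,
) -> ScanResult:
    """Scan every enumerated window of ``query`` against ``db``.

    Deterministic for a given backend and parameters; ``jobs > 1``
    distributes windows over worker processes without changing the
    output (windows are returned in (length, start) order either way).
    ``exclude_ids`` removes the named records -- typically the query's
    own training-set entry -- before scoring.
    """
    params = params or ScanParams()
    if exclude_ids:
        db = db.without(exclude_ids)
    windows = enumerate_windows(len(query.residues), params)
    payload = [(rec.id, label, rec.residues) for rec, label in db.records]
    scored: list[ScoredWindow] = []
    if jobs <= 1:
        _init_worker(payload, params.backend, query.residues, params.max_hits)
        try:
            scored = _score_chunk(windows)
        finally:
            _WORKER_STATE.clear()
    else:
        chunk_size = max(1, math.ceil(len(windows) / (jobs * 8)))
        chunks = [windows[i:i + chunk_size]
                  for i in range(0, len(windows), chunk_size)]
        with ProcessPoolExecutor(
            max_workers=jobs,
            initializer=_init_worker,
            initargs=(payload, params.backend, query.residues, params.max_hits),
        ) as pool:
            for part in pool.map(_score_chunk, chunks):
                scored.extend(part)
    return ScanResult(
        query_id=query.id,
        query_length=len(query.residues),
        params=params,
        yes_count=db.yes_count,
        no_count=db.no_count,
        windows=scored,
    )
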