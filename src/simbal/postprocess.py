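"""Post-processing of scan results: inheritance rescoring and
per-residue score extrapolation.

High scores concentrate in V-shaped "plumes" whose apex points at the
short discriminative region, but the shortest windows themselves score
poorly because homology search with very short peptides is unreliable.
Two tools counter this. Inheritance rescoring lets each window inherit
part of the (already rescored) scores of its two minimally longer parent
windows, sweeping once from the longest length down; with heritability h
the blend is

    new(s, L) = (1 - h) * raw(s, L) + h * mean(new(parents of (s, L)))

so a short window gains when every longer window containing it scores
well. Per-residue extrapolation averages, for each residue, the scores
of all fixed-length-W windows that contain it (up to W of them),
approximating a single-residue score that the scan itself never asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from simbal.scan_engine import ScanResult, ScoredWindow

#: Heritability used for the reference smoothing of the score landscape.
DEFAULT_HERITABILITY = 0.93


@dataclass(frozen=True)
class RescoreParams:
    """Inheritance weights: h is the parent share, in [0, 1)."""

    heritability: float = DEFAULT_HERITABILITY

    def __post_init__(self) -> None:
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")


@dataclass(frozen=True)
class ResidueProfile:
    """Extrapolated per-residue score with its window support count."""

    position: int
    value: float
    support: int


def rescore_inheritance(
    result: ScanResult, params: RescoreParams | None = None
) -> ScanResult:
    """Return a rescored copy of ``result`` under the inheritance scheme.

    Windows are processed by length, longest first, so parent scores are
    final before any child reads them. The parents of window (s, L) are
    the windows at the next longer length present in the grid whose span
    contains [s, s+L-1] -- at full resolution (s-1, L+1) and (s, L+1).
    Windows at the longest length have no parent and keep their raw
    score; edge windows with a single parent inherit from it alone.
    """
    params = params or RescoreParams()
    h = params.heritability
    by_length: dict[int, dict[int, ScoredWindow]] = {}
    for w in result.windows:
        by_length.setdefault(w.length, {})[w.start] = w
    lengths = sorted(by_length, reverse=True)
    new_scores: dict[tuple[int, int], float] = {}
    for i, length in enumerate(lengths):
        parent_length = lengths[i - 1] if i > 0 else None
        parent_starts = sorted(by_length[parent_length]) if parent_length else []
        for start, w in by_length[length].items():
            parents: list[float] = []
            if parent_length is not None:
                end = start + length - 1
                lo = end - parent_length + 1  # parent span must contain [start, end]
                for ps in parent_starts:
                    if lo <= ps <= start:
                        parents.append(new_scores[(ps, parent_length)])
            if parents:
                value = (1 - h) * w.score + h * (sum(parents) / len(parents))
            else:
                value = w.score
            new_scores[(start, length)] = value
    rescored = [
        replace(w, score=new_scores[(w.start, w.length)]) for w in result.windows
    ]
    return replace_windows(result, rescored)


def replace_windows(result: ScanResult, windows: list[ScoredWindow]) -> ScanResult:
    return ScanResult(
        query_id=result.query_id,
        query_length=result.query_length,
        params=result.params,
        yes_count=result.yes_count,
        no_count=result.no_count,
        windows=windows,
    )


def residue_scores(
    result: ScanResult,
    window_length: int,
    source: Literal["raw", "rescored"] = "raw",
    rescore_params: RescoreParams | None = None,
) -> list[ResidueProfile]:
    """Extrapolate window scores down to single residues.

    For each residue position i the value is the mean score of every
    length-``window_length`` window whose span contains i; the support is
    the number of such windows, which reaches ``window_length`` for
    interior residues and drops linearly toward 1 at either terminus.
    Requires that the scan covered every start position at that length
    (a position step of 1).
    """
    if source == "rescored":
        result = rescore_inheritance(result, rescore_params)
    windows = [w for w in result.windows if w.length == window_length]
    if not windows:
        raise ValueError(
            f"no windows of length {window_length} in the scan grid; "
            f"rerun the scan with that length included"
        )
    n_q = result.query_length
    expected_starts = set(range(1, n_q - window_length + 2))
    present = {w.start for w in windows}
    if present != expected_starts:
        raise ValueError(
            f"length-{window_length} windows are incomplete "
            f"({len(present)}/{len(expected_starts)} start positions); "
            "a position step of 1 is required for residue extrapolation"
        )
    by_start = {w.start: w.score for w in windows}
    profiles: list[ResidueProfile] = []
    for i in range(1, n_q + 1):
        first = max(1, i - window_length + 1)
        last = min(i, n_q - window_length + 1)
        if last < first:
            # can only happen for window_length > n_q, excluded above
            raise AssertionError("unreachable: empty support")
        scores = [by_start[s] for s in range(first, last + 1)]
        profiles.append(
            ResidueProfile(
                position=i,
                value=sum(scores) / len(scores),
                support=len(scores),
            )
        )
    return profiles


def write_residue_table(profiles: list[ResidueProfile], path) -> None:
    """Write per-residue profiles as TSV (position, value, support)."""
    with open(path, "w") as fh:
        fh.write("position\tvalue\tsupport\n")
        for p in profiles:
            fh.write(f"{p.position}\t{p.value:.6f}\t{p.support}\n")
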