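"""Per-residue sequence simplicity (SIM) and repetitiveness (REP) scores.

Both scores are evaluated in a sliding window nominally 20 residues long,
centered on each residue: 9 residues upstream, 10 downstream, clipped at the
sequence ends (the window grows from 11 to 20 residues over the first ten
positions and shrinks from 20 to 10 over the last ten).

For a window, let ``a`` be the 20-vector of occurrence counts of the
canonical amino acids and ``b`` the number of amino acids present at least
once. Then

    SIM = CV(a) / (1 + log b)

where CV is the population coefficient of variation of ``a``. SIM ranges
from 0 (all 20 amino acids present once, CV = 0) to sqrt(19) ~ 4.36
(homopolymer: CV = sqrt(19), b = 1). The quotient form is required by these
endpoints: a product CV*(1+log b) would exceed the homopolymer value for
mixed windows, and a sample (n-1) standard deviation would give 4.47 for the
homopolymer rather than the 4.35 anchor. Truncating to two decimals gives
the conventional printed range 0-4.35.

For the same window, let ``a_total`` be the summed length of maximal runs of
>= 2 identical residues, ``b_runs`` the number of such runs and ``c_distinct``
the number of distinct amino acids forming them. Then

    REP = a_total / (b_runs * c_distinct)

with REP = 0 when no run exists. REP ranges from 0 to 20, the maximum
attained only by a pure homopolymer window (a_total 20, one run, one amino
acid). Given equal composition REP ranks arrangements: "AQAQ..." scores 0,
"AAAAAQQQQQAAAAAQQQQQ" 2.5, "AAAAAAAAAAQQQQQQQQQQ" 5.

Ambiguity codes (B/J/O/U/X/Z) occupy window positions but enter no count
and break runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .seqio import CANONICAL_AA, ProteinRecord

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: Exact SIM upper bound: population CV of (20,0,...,0) with b = 1.
SIM_MAX = math.sqrt(19.0)
REP_MAX = 20.0


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 9 residues upstream, 10 downstream."""

    upstream: int = 9
    downstream: int = 10

    @property
    def nominal_length(self) -> int:
        return self.upstream + self.downstream + 1


DEFAULT_WINDOW = WindowSpec()


@dataclass(frozen=True)
class WindowCounts:
    """Amino-acid occurrence counts for one window.

    ``a`` is ordered as ACDEFGHIKLMNPQRSTVWY; ``b`` is the number of
    nonzero entries; ``w`` the effective window length (ambiguity codes
    count toward ``w`` only).
    """

    a: tuple[int, ...]
    b: int
    w: int


@dataclass(frozen=True)
class RepeatStats:
    """Run statistics for one window: total run length, run count,
    distinct run-forming amino acids (runs = maximal stretches of >= 2
    identical canonical residues)."""

    a_total: int
    b_runs: int
    c_distinct: int


@dataclass
class ScoreTrack:
    """Per-residue score values aligned to one protein sequence."""

    protein_id: str
    score_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return mean_track(self)


def window_bounds(i: int, L: int, spec: WindowSpec = DEFAULT_WINDOW) -> tuple[int, int]:
    """Inclusive 1-based window bounds around residue ``i`` of an
    ``L``-residue sequence: ``[max(1, i-9), min(L, i+10)]``."""
    if not 1 <= i <= L:
        raise ValueError(f"position {i} out of range 1..{L}")
    return max(1, i - spec.upstream), min(L, i + spec.downstream)


def count_window(window_sequence: str) -> WindowCounts:
    """Count canonical amino-acid occurrences in a window substring."""
    if not window_sequence:
        raise ValueError("empty window")
    a = [0] * 20
    for ch in window_sequence:
        idx = AA_INDEX.get(ch)
        if idx is not None:
            a[idx] += 1
    return WindowCounts(a=tuple(a), b=sum(1 for x in a if x), w=len(window_sequence))


def coefficient_of_variation(counts: WindowCounts) -> float:
    """Population CV of the 20-entry count vector (SD / mean, divide-by-n)."""
    total = sum(counts.a)
    if total == 0:
        raise ValueError("all-zero count vector: CV undefined")
    mean = total / 20.0
    var = sum((x - mean) ** 2 for x in counts.a) / 20.0
    return math.sqrt(var) / mean


def sim_window(counts: WindowCounts, log_base: float | None = None) -> float:
    """SIM = CV(a) / (1 + log b); natural log unless ``log_base`` given."""
    if counts.b == 0:
        raise ValueError("no canonical residues in window: SIM undefined")
    logb = math.log(counts.b) if log_base is None else math.log(counts.b, log_base)
    return coefficient_of_variation(counts) / (1.0 + logb)


def repeat_stats(window_sequence: str) -> RepeatStats:
    """Maximal runs of >= 2 identical canonical residues in one scan.

    Ambiguity codes break runs and never form them.
    """
    if not window_sequence:
        raise ValueError("empty window")
    a_total = 0
    b_runs = 0
    aas: set[str] = set()
    for ch, grp in groupby(window_sequence):
        n = sum(1 for _ in grp)
        if n >= 2 and ch in AA_INDEX:
            a_total += n
            b_runs += 1
            aas.add(ch)
    return RepeatStats(a_total=a_total, b_runs=b_runs, c_distinct=len(aas))


def rep_window(stats: RepeatStats) -> float:
    """REP = a_total / (b_runs * c_distinct); 0 when no run exists."""
    if stats.b_runs == 0:
        return 0.0
    return stats.a_total / (stats.b_runs * stats.c_distinct)


# ---------------------------------------------------------------------------
# Whole-sequence profiles (vectorized; the scalar functions above are the
# reference semantics and the test oracle route)


def _encode(sequence: str) -> np.ndarray:
    """Map residues to 0..19 canonical codes, -1 for ambiguity codes."""
    return np.array([AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)


def _window_arrays(L: int, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    pos = np.arange(1, L + 1)
    starts = np.maximum(1, pos - spec.upstream)
    ends = np.minimum(L, pos + spec.downstream)
    return starts, ends


def _sim_profile(codes: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                 log_base: float | None) -> np.ndarray:
    L = len(codes)
    # cumulative per-amino-acid counts; window counts by prefix differences
    onehot = np.zeros((L, 20), dtype=np.int64)
    valid = codes >= 0
    onehot[np.nonzero(valid)[0], codes[valid]] = 1
    cum = np.zeros((L + 1, 20), dtype=np.int64)
    np.cumsum(onehot, axis=0, out=cum[1:])
    a = cum[ends] - cum[starts - 1]  # (L, 20)

    s = a.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s / 20.0
        var = ((a - mean[:, None]) ** 2).sum(axis=1) / 20.0
        cv = np.sqrt(var) / mean
        b = (a > 0).sum(axis=1)
        logb = np.log(b, where=b > 0, out=np.full(L, np.nan))
        if log_base is not None:
            logb = logb / math.log(log_base)
        sim = cv / (1.0 + logb)
    sim[s == 0] = np.nan  # windows with no canonical residue
    return sim


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs >= 2 of canonical residues as (code, start, end), 1-based."""
    runs = []
    i, L = 0, len(codes)
    while i < L:
        j = i
        while j + 1 < L and codes[j + 1] == codes[i]:
            j += 1
        if codes[i] >= 0 and j > i:
            runs.append((int(codes[i]), i + 1, j + 1))
        i = j + 1
    return runs


def _rep_profile(codes: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    L = len(codes)
    a_total = np.zeros(L, dtype=np.int64)
    b_runs = np.zeros(L, dtype=np.int64)
    present = np.zeros((L, 20), dtype=bool)
    for code, rs, re_ in _runs(codes):
        clipped = np.minimum(re_, ends) - np.maximum(rs, starts) + 1
        mask = clipped >= 2
        a_total += np.where(mask, clipped, 0)
        b_runs += mask
        present[:, code] |= mask
    c = present.sum(axis=1)
    denom = b_runs * c
    return np.divide(a_total, denom, out=np.zeros(L, dtype=float), where=denom > 0)


def score_profile(
    record: ProteinRecord | str,
    score: Literal["SIM", "REP"],
    spec: WindowSpec = DEFAULT_WINDOW,
    log_base: float | None = None,
) -> ScoreTrack:
    """Per-residue SIM or REP track for a whole sequence.

    Equivalent to evaluating the scalar window functions on the substring
    ``sequence[start-1:end]`` of :func:`window_bounds` at every position,
    but computed with cumulative counts / run clipping in O(L).
    """
    if isinstance(record, str):
        record = ProteinRecord(id="<anon>", sequence=record)
    codes = _encode(record.sequence)
    starts, ends = _window_arrays(len(codes), spec)
    if score == "SIM":
        values = _sim_profile(codes, starts, ends, log_base)
    elif score == "REP":
        values = _rep_profile(codes, starts, ends)
    else:
        raise ValueError(f"unknown score {score!r}")
    return ScoreTrack(protein_id=record.id, score_name=score, values=values)


def mean_track(track: ScoreTrack) -> float:
    """Arithmetic mean of the per-residue values (the per-protein score)."""
    if len(track) == 0:
        raise ValueError("empty track")
    return float(np.mean(track.values))


def write_score_tracks(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    """Export tracks as TSV (protein_id, score_name, position, value) in the
    same layout :func:`lcrevol.seqio.read_external_scores` ingests."""
    rows = [
        {"protein_id": t.protein_id, "score_name": t.score_name,
         "position": i + 1, "value": v}
        for t in tracks
        for i, v in enumerate(t.values)
    ]
    pd.DataFrame(rows, columns=["protein_id", "score_name", "position", "value"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.17g")
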