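"""Shared fixtures and fully independent scoring oracles.

The oracle functions here deliberately avoid the package's code paths: they
use ``collections.Counter``, the ``statistics`` module and regex run
scanning, so track/score equality tests compare two independent routes.
"""

from __future__ import annotations

import math
import re
import statistics
from collections import Counter

import numpy as np
import pytest

from lcrevol.seqio import CANONICAL_AA, ProteinRecord

AA = CANONICAL_AA


def naive_window(i: int, L: int) -> tuple[int, int]:
    return max(1, i - 9), min(L, i + 10)


def naive_sim(window: str, log_base: float | None = None) -> float:
    counts = Counter(c for c in window if c in AA)
    a = [counts.get(aa, 0) for aa in AA]
    if sum(a) == 0:
        return float("nan")
    cv = statistics.pstdev(a) / statistics.mean(a)
    b = len(counts)
    logb = math.log(b) if log_base is None else math.log(b, log_base)
    return cv / (1 + logb)


def naive_rep(window: str) -> float:
    runs = [m.group(0) for m in re.finditer(r"(.)\1+", window)
            if m.group(1) in AA]
    if not runs:
        return 0.0
    a = sum(len(r) for r in runs)
    b = len(runs)
    c = len({r[0] for r in runs})
    return a / (b * c)


def naive_track(sequence: str, score: str) -> list[float]:
    """Per-residue scores via explicit window substring extraction."""
    L = len(sequence)
    out = []
    for i in range(1, L + 1):
        s, e = naive_window(i, L)
        win = sequence[s - 1:e]
        out.append(naive_sim(win) if score == "SIM" else naive_rep(win))
    return out


def naive_aars(sequence: str, min_len: int = 4) -> list[tuple[str, int, int]]:
    """Regex-based homorepeat scan, 1-based inclusive coordinates."""
    return [
        (m.group(1), m.start() + 1, m.end())
        for m in re.finditer(r"(.)\1*", sequence)
        if m.group(1) in AA and (m.end() - m.start()) >= min_len
    ]


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = AA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def small_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "MAAAQQQQWSSSSSSS", species="Homo_sapiens",
                      clade="Pri", paralog="SYN1"),
        ProteinRecord("P2", "MACDEFGHIKLMNPQRSTVWY", species="Mus_musculus",
                      clade="Gli", paralog="SYN1"),
        ProteinRecord("P3", "MPPPPPPGGGGACDEFGHIK", species="Danio_rerio",
                      clade="Act", paralog="SYN1"),
    ]
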