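"""Amino-acid composition, homorepeat (AAR) detection and enrichment flags.

An AAR is a maximal run of >= 4 identical residues (the conventional
homorepeat threshold). Per-protein composition is expressed as percent
occurrence of each canonical amino acid; enrichment relative to a proteome
baseline uses strict +/-20% relative-deviation thresholds, chosen so that a
compositionally biased region of even modest length in an average-size
protein shifts the whole-protein percentage past the flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seqio import CANONICAL_AA, ProteinRecord

Flag = Literal["enriched", "depleted", "neutral", "undefined"]


@dataclass(frozen=True)
class AAR:
    """One homorepeat: amino acid, 1-based inclusive coordinates."""

    amino_acid: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CompositionProfile:
    """Percent occurrence and total AAR length per amino acid, one protein."""

    percents: dict[str, float]
    aar_totals: dict[str, int]
    length: int


@dataclass
class EnrichmentReport:
    """Per-amino-acid deviation from a baseline composition.

    ``deviation`` is (observed - baseline)/baseline * 100; flags use strict
    inequality at the threshold, so a deviation of exactly +20% is neutral
    (boundary).
    """

    baseline: dict[str, float]
    observed: dict[str, float]
    deviation: dict[str, float]
    flags: dict[str, Flag]
    threshold: float


def aa_percentages(sequence: str | ProteinRecord) -> dict[str, float]:
    """Percent occurrence of each canonical amino acid.

    Ambiguity codes count toward the length (denominator) only.
    """
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    return {aa: seq.count(aa) / L * 100.0 for aa in CANONICAL_AA}


def find_aars(sequence: str | ProteinRecord, min_len: int = 4) -> list[AAR]:
    """All maximal runs of >= ``min_len`` identical canonical residues.

    Runs are reported in positional order and are disjoint by maximality.
    Ambiguity codes break runs and never seed them.
    """
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    if not seq:
        raise ValueError("empty sequence")
    out: list[AAR] = []
    i, L = 0, len(seq)
    while i < L:
        j = i
        while j + 1 < L and seq[j + 1] == seq[i]:
            j += 1
        if seq[i] in CANONICAL_AA and (j - i + 1) >= min_len:
            out.append(AAR(amino_acid=seq[i], start=i + 1, end=j + 1))
        i = j + 1
    return out


def aar_totals(aars: Iterable[AAR]) -> dict[str, int]:
    """Total AAR length per amino acid (sum of individual repeat lengths);
    zero for amino acids without repeats."""
    totals = {aa: 0 for aa in CANONICAL_AA}
    for r in aars:
        totals[r.amino_acid] += r.length
    return totals


def composition_profile(record: ProteinRecord | str, min_aar_len: int = 4) -> CompositionProfile:
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    return CompositionProfile(
        percents=aa_percentages(seq),
        aar_totals=aar_totals(find_aars(seq, min_aar_len)),
        length=len(seq),
    )


def proteome_baseline(
    records: Sequence[ProteinRecord],
    mode: Literal["mean_of_percents", "pooled"] = "mean_of_percents",
) -> dict[str, float]:
    """Baseline composition over a protein set.

    Default is the unweighted mean over proteins of per-protein percent
    occurrences (the mean occurrence across all proteins); ``pooled``
    computes residue frequencies over the concatenated set instead and is
    provided for sensitivity analysis — the two differ whenever protein
    lengths vary.
    """
    if not records:
        raise ValueError("empty record set")
    if mode == "mean_of_percents":
        per = np.array(
            [[aa_percentages(r)[aa] for aa in CANONICAL_AA] for r in records]
        )
        means = per.mean(axis=0)
        return dict(zip(CANONICAL_AA, means.tolist()))
    if mode == "pooled":
        total = sum(len(r) for r in records)
        counts = {aa: 0 for aa in CANONICAL_AA}
        for r in records:
            for aa in CANONICAL_AA:
                counts[aa] += r.sequence.count(aa)
        return {aa: counts[aa] / total * 100.0 for aa in CANONICAL_AA}
    raise ValueError(f"unknown baseline mode {mode!r}")


def enrichment_report(
    observed: dict[str, float],
    baseline: dict[str, float],
    threshold: float = 20.0,
) -> EnrichmentReport:
    """Flag amino acids enriched (> +threshold%) or depleted (< -threshold%)
    relative to a baseline; baseline-zero entries are ``undefined``."""
    deviation: dict[str, float] = {}
    flags: dict[str, Flag] = {}
    for aa in CANONICAL_AA:
        base = baseline[aa]
        obs = observed[aa]
        if base == 0:
            deviation[aa] = float("nan")
            flags[aa] = "undefined"
            continue
        dev = (obs - base) / base * 100.0
        deviation[aa] = dev
        if dev > threshold:
            flags[aa] = "enriched"
        elif dev < -threshold:
            flags[aa] = "depleted"
        else:
            flags[aa] = "neutral"
    return EnrichmentReport(
        baseline=dict(baseline), observed=dict(observed),
        deviation=deviation, flags=flags, threshold=threshold,
    )


def write_aar_bed(aars_by_protein: dict[str, list[AAR]], path: str | Path) -> None:
    """Export AARs as BED-like TSV: 0-based half-open (start-1, end) columns
    plus amino acid and length."""
    rows = [
        {"protein_id": pid, "start": r.start - 1, "end": r.end,
         "amino_acid": r.amino_acid, "length": r.length}
        for pid, aars in aars_by_protein.items()
        for r in aars
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "amino_acid", "length"]) \
        .to_csv(path, sep="\t", index=False)
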