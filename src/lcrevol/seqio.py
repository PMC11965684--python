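"""Sequence, metadata and score-table I/O plus sequence quality control.

Protein sequences travel as :class:`ProteinRecord` objects annotated with
species, clade and paralog. Clade stem ages live in a :class:`CladeRegistry`.
Per-protein or per-residue scores produced by external predictors (LLPS
propensity, prion-likeness) are ingested from TSV as :class:`ExternalScoreSet`.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical one-letter order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes accepted on input but excluded from counts.
AMBIGUOUS_AA = "BJOUXZ"

VALID_AA = set(CANONICAL_AA) | set(AMBIGUOUS_AA)

_HEADER_TAG = re.compile(r"(\w+)=(\S+)")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One ortholog protein sequence with its evolutionary annotations.

    ``sequence`` is an uppercase amino-acid string over the canonical 20
    letters plus the permitted ambiguity codes B/J/O/U/X/Z.
    """

    id: str
    sequence: str
    species: str = ""
    clade: str = ""
    paralog: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal character(s) "
                f"{', '.join(sorted(repr(c) for c in bad))} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_AA for c in self.sequence)


@dataclass(frozen=True)
class CladeEntry:
    name: str
    stem_age_mya: float
    n_species: int = 0


@dataclass
class CladeRegistry:
    """Ordered clade list with stem ages (Mya) and a reference clade.

    The reference clade (default: the oldest) is the normalization anchor
    for reporting clade-mean trajectories.
    """

    clades: list[CladeEntry]
    reference: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.clades]
        if len(names) != len(set(names)):
            raise ValueError("duplicate clade names in registry")
        for c in self.clades:
            if c.stem_age_mya <= 0:
                raise ValueError(f"clade {c.name!r}: stem age must be > 0")
        if not self.reference:
            self.reference = max(self.clades, key=lambda c: c.stem_age_mya).name
        elif self.reference not in names:
            raise ValueError(f"reference clade {self.reference!r} not in registry")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.clades)

    def __iter__(self):
        return iter(self.clades)

    def __len__(self) -> int:
        return len(self.clades)

    def stem_age(self, name: str) -> float:
        for c in self.clades:
            if c.name == name:
                return c.stem_age_mya
        raise KeyError(f"clade {name!r} not in registry")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.clades]


@dataclass
class ExternalScoreSet:
    """Scores from an external predictor for one protein.

    Either a single per-protein ``value`` or a per-residue ``track`` (list
    ordered by position); exactly one of the two is set.
    """

    protein_id: str
    score_name: str
    value: float | None = None
    track: list[float] | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.track is None):
            raise ValueError(
                f"{self.protein_id}/{self.score_name}: exactly one of "
                "per-protein value and per-residue track must be given"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and validated. Optional ``key=value`` tags in
    the description (``species=``, ``clade=``, ``paralog=``) are honored;
    anything else is left for :func:`join_metadata`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        digits = sorted(set(seq) & set("0123456789"))
        if digits:
            raise SequenceError(
                f"record {rec.id!r}: illegal character {digits[0]!r} in sequence"
            )
        tags = dict(_HEADER_TAG.findall(rec.description))
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                species=tags.get("species", ""),
                clade=tags.get("clade", ""),
                paralog=tags.get("paralog", ""),
            )
        )
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, embedding annotations as header tags."""
    out = []
    for r in records:
        desc = []
        if r.species:
            desc.append(f"species={r.species}")
        if r.clade:
            desc.append(f"clade={r.clade}")
        if r.paralog:
            desc.append(f"paralog={r.paralog}")
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(desc)))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar metadata TSV (columns: id, species, clade, paralog)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"clade", "paralog"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks column(s): {sorted(missing)}")
    if "id" not in df.columns and "species" not in df.columns:
        raise ValueError("metadata table needs an 'id' or 'species' column")
    return df


def join_metadata(
    records: Sequence[ProteinRecord],
    metadata: pd.DataFrame,
    registry: CladeRegistry,
) -> list[ProteinRecord]:
    """Annotate records from a metadata table, dropping unknown clades.

    Rows are matched on ``id`` when present, else on ``species``. Records
    whose clade is absent from ``registry`` are excluded with a warning.
    Duplicate (species, paralog) rows are an error.
    """
    key = "id" if "id" in metadata.columns else "species"
    if "species" in metadata.columns and "paralog" in metadata.columns:
        dup = metadata.duplicated(subset=["species", "paralog"], keep=False)
        if dup.any():
            pairs = metadata.loc[dup, ["species", "paralog"]].drop_duplicates()
            raise ValueError(
                "duplicate (species, paralog) metadata rows: "
                + "; ".join(f"({r.species}, {r.paralog})" for r in pairs.itertuples())
            )
    table = metadata.set_index(key)
    annotated: list[ProteinRecord] = []
    for rec in records:
        lookup = rec.id if key == "id" else rec.species
        if lookup not in table.index:
            logger.warning("record %s: no metadata row, excluded", rec.id)
            continue
        row = table.loc[lookup]
        clade = row["clade"]
        if clade not in registry:
            logger.warning(
                "record %s: clade %r not in registry, excluded", rec.id, clade
            )
            continue
        annotated.append(
            replace(
                rec,
                species=row.get("species", rec.species) or rec.species,
                clade=clade,
                paralog=row["paralog"],
            )
        )
    seen: set[tuple[str, str]] = set()
    for rec in annotated:
        pair = (rec.species, rec.paralog)
        if pair in seen:
            raise ValueError(f"duplicate (species, paralog) pair {pair}")
        seen.add(pair)
    return annotated


# ---------------------------------------------------------------------------
# QC filter


def qc_filter(
    records: Sequence[ProteinRecord],
    length_deficit_threshold: int = 50,
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Discard obviously incomplete sequences.

    A record is discarded when (i) its first residue is not methionine, or
    (ii) it is more than ``length_deficit_threshold`` residues shorter than
    the median length of its (clade, paralog) group — a stand-in for visual
    alignment inspection flagging large deletions. Groups of size 1 skip
    rule (ii).

    Returns ``(kept, discarded)`` where each discarded entry carries its
    reason string.
    """
    kept: list[ProteinRecord] = []
    discarded: list[tuple[ProteinRecord, str]] = []

    no_met = [r for r in records if not r.sequence.startswith("M")]
    candidates = [r for r in records if r.sequence.startswith("M")]
    for r in no_met:
        discarded.append((r, "no initial methionine"))

    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for r in candidates:
        groups.setdefault((r.clade, r.paralog), []).append(r)
    for members in groups.values():
        if len(members) == 1:
            kept.extend(members)
            continue
        median = statistics.median(len(m) for m in members)
        for m in members:
            deficit = median - len(m)
            if deficit > length_deficit_threshold:
                discarded.append(
                    (m, f"length deficit {deficit:g} > {length_deficit_threshold} "
                        f"vs clade/paralog median {median:g}")
                )
            else:
                kept.append(m)
    kept.sort(key=lambda r: [x.id for x in records].index(r.id))
    return kept, discarded


# ---------------------------------------------------------------------------
# External scores


def read_external_scores(path: str | Path) -> list[ExternalScoreSet]:
    """Read external predictor scores from TSV.

    Columns: ``protein_id``, ``score_name``, ``position`` (1-based; empty or
    ``-`` for a per-protein value), ``value``. Per-residue rows for one
    (protein, score) must form a contiguous 1..L block.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "score_name": str})
    required = {"protein_id", "score_name", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"score table lacks column(s): {sorted(required - set(df.columns))}")
    if "position" not in df.columns:
        df["position"] = None
    df["position"] = pd.to_numeric(
        df["position"].replace({"-": None, "": None}), errors="coerce"
    )

    out: list[ExternalScoreSet] = []
    for (pid, name), grp in df.groupby(["protein_id", "score_name"], sort=False):
        has_pos = grp["position"].notna()
        if has_pos.any() and (~has_pos).any():
            raise ValueError(
                f"{pid}/{name}: mixed per-residue and per-protein rows"
            )
        if has_pos.any():
            grp = grp.sort_values("position")
            positions = grp["position"].astype(int).tolist()
            expected = list(range(1, len(positions) + 1))
            if positions != expected:
                gaps = sorted(set(expected) - set(positions))
                raise ValueError(
                    f"{pid}/{name}: non-contiguous positions, missing {gaps}"
                )
            out.append(
                ExternalScoreSet(pid, name, track=grp["value"].astype(float).tolist())
            )
        else:
            if len(grp) != 1:
                raise ValueError(f"{pid}/{name}: multiple per-protein rows")
            out.append(
                ExternalScoreSet(pid, name, value=float(grp["value"].iloc[0]))
            )
    return out


def validate_scores_against_records(
    scores: Iterable[ExternalScoreSet], records: Sequence[ProteinRecord]
) -> None:
    """Check per-residue tracks match sequence lengths."""
    lengths = {r.id: len(r) for r in records}
    for s in scores:
        if s.track is not None and s.protein_id in lengths:
            if len(s.track) != lengths[s.protein_id]:
                raise ValueError(
                    f"{s.protein_id}/{s.score_name}: track length {len(s.track)} "
                    f"!= sequence length {lengths[s.protein_id]}"
                )


# ---------------------------------------------------------------------------
# Result tables


def write_parameter_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write per-protein parameter rows as a deterministic TSV.

    Rows carry (protein_id, species, clade, paralog, parameter, value);
    output is sorted by (clade, species, paralog, parameter) and written at
    full floating precision so re-runs are byte-identical.
    """
    cols = ["protein_id", "species", "clade", "paralog", "parameter", "value"]
    df = pd.DataFrame(list(rows), columns=cols)
    if len(df):
        df = df.sort_values(["clade", "species", "paralog", "parameter"],
                            kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return df
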