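"""Synthetic ortholog-family generator with clade-age-dependent repeats.

Each simulated protein is ``"M" + NTR + CTR``: a variable N-terminal region
carrying planted homorepeat runs whose lengths drift linearly with clade age
offset, and a conserved C-terminal block shared across all species up to
per-site substitution noise. This emulates the statistical structure the
evolutionary analysis assumes — clade-mean trends against stem age with
intraclade variability — without modelling real phylogenetic sequence
evolution (no trees, no indels beyond repeat-length jitter).

Age offsets are ``oldest stem age − clade stem age``, so a positive planted
slope means the repeat grows toward younger clades, which the correlation
stage reports as a negative r against stem age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .seqio import CANONICAL_AA, CladeEntry, CladeRegistry, ProteinRecord


def default_registry() -> CladeRegistry:
    """The nine major vertebrate clades with TimeTree-median stem ages (Mya)
    and the species counts of the reference ortholog collection."""
    return CladeRegistry(clades=[
        CladeEntry("Cho", 462, 12),   # Chondrichthyes
        CladeEntry("Act", 429, 175),  # Actinopterygii
        CladeEntry("Amp", 352, 11),   # Amphibia/Lissamphibia
        CladeEntry("Sau", 319, 159),  # Sauropsida
        CladeEntry("Mar", 160, 8),    # Marsupialia
        CladeEntry("Atl", 99, 9),     # Atlantogenata
        CladeEntry("Lau", 94, 119),   # Laurasiatheria
        CladeEntry("Gli", 87, 45),    # Glires
        CladeEntry("Pri", 87, 34),    # Primates (ties with Glires allowed)
    ], reference="Cho")


def results_variant_registry() -> CladeRegistry:
    """Alternative stem-age set (and 11 Chondrichthyes species) as quoted in
    some result summaries; kept as a second fixture for sensitivity checks.
    The primary fixture is :func:`default_registry`."""
    return CladeRegistry(clades=[
        CladeEntry("Cho", 462, 11),
        CladeEntry("Act", 429, 175),
        CladeEntry("Amp", 319, 11),
        CladeEntry("Sau", 180, 159),
        CladeEntry("Mar", 99, 8),
        CladeEntry("Atl", 94, 9),
        CladeEntry("Lau", 94, 119),
        CladeEntry("Gli", 87, 45),
        CladeEntry("Pri", 87, 34),
    ], reference="Cho")


def actinopterygii_registry() -> CladeRegistry:
    """The 21 ray-finned-fish subclades with stem ages (Mya)."""
    return CladeRegistry(clades=[
        CladeEntry("Cladistia", 396, 2),
        CladeEntry("Holostei", 321, 1),
        CladeEntry("Osteoglossocephala", 263, 2),
        CladeEntry("Elopocephala", 250, 3),
        CladeEntry("Otomorpha", 224, 31),
        CladeEntry("Protacanthopterygii", 219, 1),
        CladeEntry("Lampridacea", 134, 1),
        CladeEntry("Holocentrinomorphaceae", 127, 1),
        CladeEntry("Batrachoidaria", 120, 1),
        CladeEntry("Syngnathiaria", 109, 9),
        CladeEntry("Gobiaria", 108, 3),
        CladeEntry("Eupercaria", 113, 28),
        CladeEntry("Carangaria", 104, 16),
        CladeEntry("Pomacentridae", 87, 7),
        CladeEntry("Cichlomorphae", 91, 9),
        CladeEntry("Atheriniformes", 80, 1),
        CladeEntry("Beloniformes", 89, 1),
        CladeEntry("Aplocheiloidei", 74, 4),
        CladeEntry("Cyprinodontoidei", 46, 4),
        CladeEntry("Poecilinae", 18.9, 4),
        CladeEntry("Poeciliinae", 18.9, 5),
    ], reference="Cladistia")


@dataclass(frozen=True)
class RepeatEffect:
    """One planted homorepeat: run length = base + slope * age_offset + noise,
    rounded and clipped at 0. ``slope`` is residues per Mya of age offset."""

    base: float
    slope: float


@dataclass
class SimConfig:
    """Configuration of one synthetic ortholog family.

    Defaults reflect a mid-size protein family: nine vertebrate clades,
    eight species per clade, a 150-residue variable NTR, a 120-residue
    conserved CTR with 2% per-site substitution noise, uniform background
    composition, repeat-length jitter SD of 1 residue. The seed is
    mandatory: every realization is reproducible.
    """

    seed: int
    registry: CladeRegistry = field(default_factory=default_registry)
    species_per_clade: int = 8
    ntr_length: int = 150
    ctr_length: int = 120
    ctr_substitution_rate: float = 0.02
    background: Mapping[str, float] | None = None  # None = uniform over 20
    repeat_effects: Mapping[str, RepeatEffect] = field(default_factory=dict)
    repeat_noise_sd: float = 1.0
    paralog: str = "SYN1"

    def __post_init__(self) -> None:
        if self.species_per_clade < 1:
            raise ValueError("species_per_clade must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    slopes: dict[str, float]                      # parameter -> planted slope
    expected_clade_means: dict[str, dict[str, float]]  # clade -> param -> mean
    realized_runs: dict[str, dict[str, int]]      # protein id -> aa -> run length
    null_model: bool


def _background_probs(config: SimConfig) -> tuple[np.ndarray, str]:
    if config.background is None:
        p = np.full(20, 1 / 20)
    else:
        p = np.array([config.background.get(aa, 0.0) for aa in CANONICAL_AA], float)
        if p.sum() <= 0:
            raise ValueError("background frequencies sum to 0")
        p = p / p.sum()
    return p, CANONICAL_AA


def _draw(rng: np.random.Generator, n: int, probs: np.ndarray) -> list[str]:
    idx = rng.choice(20, size=n, p=probs)
    return [CANONICAL_AA[i] for i in idx]


def _build_ntr(rng: np.random.Generator, length: int, probs: np.ndarray,
               runs: dict[str, int]) -> str:
    """Random background NTR with planted runs kept maximal: runs are
    separated (and flanked) by at least one residue differing from the
    run's amino acid."""
    planted = [(aa, n) for aa, n in runs.items() if n >= 2]
    rng.shuffle(planted)
    total_run = sum(n for _, n in planted)
    n_spacers = len(planted) + 1
    free = length - total_run
    if free < n_spacers:
        raise ValueError(
            f"infeasible config: planted runs total {total_run} residues + "
            f"{n_spacers} spacers exceed NTR length {length}"
        )
    # distribute free residues over spacers, each >= 1
    cuts = rng.choice(np.arange(1, free), size=n_spacers - 1, replace=False) \
        if n_spacers > 1 else np.array([], dtype=int)
    cuts = np.sort(cuts)
    spacer_lens = np.diff(np.concatenate(([0], cuts, [free]))).astype(int)

    parts: list[str] = []
    for i, slen in enumerate(spacer_lens):
        spacer = _draw(rng, int(slen), probs)
        # keep planted runs maximal: boundary spacer residues must differ
        # from the adjacent run's amino acid
        if i > 0 and spacer and spacer[0] == planted[i - 1][0]:
            spacer[0] = _redraw_not(rng, probs, planted[i - 1][0])
        if i < len(planted) and spacer and spacer[-1] == planted[i][0]:
            spacer[-1] = _redraw_not(rng, probs, planted[i][0])
        parts.append("".join(spacer))
        if i < len(planted):
            aa, n = planted[i]
            parts.append(aa * n)
    return "".join(parts)


def _redraw_not(rng: np.random.Generator, probs: np.ndarray, avoid: str) -> str:
    p = probs.copy()
    p[CANONICAL_AA.index(avoid)] = 0.0
    if p.sum() == 0:
        raise ValueError("background admits only the run amino acid; cannot flank runs")
    return CANONICAL_AA[rng.choice(20, p=p / p.sum())]


def simulate_family(config: SimConfig) -> tuple[list[ProteinRecord], pd.DataFrame, SimTruth]:
    """Generate one ortholog family across the configured clades.

    Returns the records, a metadata table (id, species, clade, paralog) and
    the :class:`SimTruth` ground truth. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    probs, _ = _background_probs(config)
    oldest = max(c.stem_age_mya for c in config.registry)

    master_ctr = "".join(_draw(rng, config.ctr_length, probs))

    records: list[ProteinRecord] = []
    meta_rows = []
    realized: dict[str, dict[str, int]] = {}
    expected: dict[str, dict[str, float]] = {}
    for entry in config.registry:
        offset = oldest - entry.stem_age_mya
        expected[entry.name] = {
            f"aar_{aa}": eff.base + eff.slope * offset
            for aa, eff in config.repeat_effects.items()
        }
        for s in range(config.species_per_clade):
            pid = f"SYN-{entry.name}-{s + 1:02d}"
            species = f"{entry.name}_species_{s + 1}"
            runs: dict[str, int] = {}
            for aa, eff in config.repeat_effects.items():
                noise = rng.normal(0.0, config.repeat_noise_sd) \
                    if config.repeat_noise_sd > 0 else 0.0
                runs[aa] = max(0, round(eff.base + eff.slope * offset + noise))
            ntr = _build_ntr(rng, config.ntr_length, probs, runs)
            ctr = list(master_ctr)
            if config.ctr_substitution_rate > 0:
                hits = np.nonzero(
                    rng.random(config.ctr_length) < config.ctr_substitution_rate
                )[0]
                for h in hits:
                    ctr[h] = _redraw_not(rng, probs, ctr[h]) \
                        if probs[CANONICAL_AA.index(ctr[h])] < 1 else ctr[h]
            seq = "M" + ntr + "".join(ctr)
            records.append(ProteinRecord(
                id=pid, sequence=seq, species=species,
                clade=entry.name, paralog=config.paralog,
            ))
            meta_rows.append({"id": pid, "species": species,
                              "clade": entry.name, "paralog": config.paralog})
            realized[pid] = runs

    metadata = pd.DataFrame(meta_rows, columns=["id", "species", "clade", "paralog"])
    truth = SimTruth(
        slopes={f"aar_{aa}": eff.slope for aa, eff in config.repeat_effects.items()},
        expected_clade_means=expected,
        realized_runs=realized,
        null_model=all(e.slope == 0 for e in config.repeat_effects.values()),
    )
    return records, metadata, truth


def null_family(config: SimConfig) -> tuple[list[ProteinRecord], pd.DataFrame, SimTruth]:
    """Same generator with all planted slopes forced to zero (null model)."""
    null_effects = {aa: RepeatEffect(e.base, 0.0)
                    for aa, e in config.repeat_effects.items()}
    return simulate_family(replace(config, repeat_effects=null_effects))


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Persist ground truth as YAML."""
    payload = {
        "null_model": truth.null_model,
        "slopes": dict(truth.slopes),
        "expected_clade_means": {c: dict(v) for c, v in truth.expected_clade_means.items()},
        "realized_runs": {p: dict(v) for p, v in truth.realized_runs.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
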