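"""Evolutionary trend analysis: clade means of composition/complexity
parameters correlated with clade stem ages.

Per-protein parameters (20 amino-acid percent occurrences, 20 per-amino-acid
homorepeat total lengths, mean SIM and mean REP, plus any ingested external
per-protein scores) are averaged within clades — unweighted over the
orthologs available in each clade — and the clade means are correlated
against clade stem ages with Pearson's r. Significance is a two-tailed
t-test, t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom, with
p <= 0.05 considered significant; no multiple-testing correction is applied
(a deliberate caveat, documented in the methods note). Under this convention
a negative r means the parameter increases toward younger clades.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import ScoreTrack, mean_track, score_profile
from .composition import aa_percentages, aar_totals, find_aars
from .seqio import CANONICAL_AA, CladeRegistry, ExternalScoreSet, ProteinRecord

logger = logging.getLogger(__name__)

ANNOTATION_COLS = ["species", "clade", "paralog"]

PCT_PARAMS = [f"pct_{aa}" for aa in CANONICAL_AA]
AAR_PARAMS = [f"aar_{aa}" for aa in CANONICAL_AA]
BASE_PARAMS = PCT_PARAMS + AAR_PARAMS + ["mean_SIM", "mean_REP"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one parameter (or pair) with significance.

    ``r`` is NaN when either series has zero variance; such results are
    never significant.
    """

    parameter: str
    r: float
    n: int
    p: float
    significant: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass
class CladeSummary:
    """Per-clade parameter means with the clade's stem age."""

    clade: str
    stem_age_mya: float
    n_orthologs: int
    means: dict[str, float]
    n_per_parameter: dict[str, int] = field(default_factory=dict)


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n, via
    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def pearson_with_p(x: Sequence[float], y: Sequence[float],
                   parameter: str = "") -> CorrelationResult:
    """Pearson r with a two-tailed p from the t-transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 points for a defined p, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(parameter, float("nan"), n, float("nan"), False)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(parameter, r, n, p, p <= SIGNIFICANCE_LEVEL)


# ---------------------------------------------------------------------------
# Parameter assembly


def parameter_vectors(
    records: Sequence[ProteinRecord],
    tracks: Mapping[str, Mapping[str, ScoreTrack]] | None = None,
    external_scores: Iterable[ExternalScoreSet] = (),
    min_aar_len: int = 4,
) -> pd.DataFrame:
    """Per-protein parameter table, one row per protein.

    Columns: species/clade/paralog annotations, the 42 base parameters
    (pct_*, aar_*, mean_SIM, mean_REP) and one column per external
    per-protein score. ``tracks`` may supply precomputed SIM/REP tracks
    keyed ``tracks[protein_id]["SIM"|"REP"]``; otherwise profiles are
    computed here. Missing external scores are NaN (absent, never zero).
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "species": rec.species, "clade": rec.clade, "paralog": rec.paralog,
        }
        for aa, v in aa_percentages(rec).items():
            row[f"pct_{aa}"] = v
        for aa, v in aar_totals(find_aars(rec, min_aar_len)).items():
            row[f"aar_{aa}"] = float(v)
        rec_tracks = (tracks or {}).get(rec.id, {})
        for score in ("SIM", "REP"):
            track = rec_tracks.get(score) or score_profile(rec, score)
            row[f"mean_{score}"] = mean_track(track)
        rows.append(pd.Series(row, name=rec.id))
    df = pd.DataFrame(rows)
    df.index.name = "protein_id"

    for s in external_scores:
        if s.value is None:
            continue  # per-residue externals are aggregated upstream if wanted
        if s.score_name in BASE_PARAMS:
            raise ValueError(f"external score {s.score_name!r} collides with a base parameter")
        if s.score_name not in df.columns:
            df[s.score_name] = np.nan
        if s.protein_id in df.index:
            df.loc[s.protein_id, s.score_name] = s.value
    return df


def parameter_names(vectors: pd.DataFrame) -> list[str]:
    return [c for c in vectors.columns if c not in ANNOTATION_COLS]


def core_parameter_set(llps: str | None = None, prd: str | None = None) -> list[str]:
    """The conventional 24-parameter subset: the 20 percent occurrences plus
    mean SIM, mean REP and (when ingested) LLPS-propensity and prion-likeness
    scores."""
    extras = [s for s in (llps, prd) if s]
    return PCT_PARAMS + ["mean_SIM", "mean_REP"] + extras


def vectors_to_long(vectors: pd.DataFrame) -> list[dict]:
    """Wide per-protein parameter frame -> long rows for
    :func:`lcrevol.seqio.write_parameter_table`."""
    rows = []
    for pid, row in vectors.iterrows():
        for p in parameter_names(vectors):
            v = row[p]
            if pd.isna(v):
                continue
            rows.append({
                "protein_id": pid, "species": row["species"],
                "clade": row["clade"], "paralog": row["paralog"],
                "parameter": p, "value": float(v),
            })
    return rows


def long_to_vectors(table: pd.DataFrame) -> pd.DataFrame:
    """Long parameter table -> wide frame indexed by protein id."""
    annot = (table[["protein_id"] + ANNOTATION_COLS]
             .drop_duplicates("protein_id").set_index("protein_id"))
    wide = table.pivot(index="protein_id", columns="parameter", values="value")
    return annot.join(wide)


# ---------------------------------------------------------------------------
# Clade summaries


def clade_summaries(
    vectors: pd.DataFrame,
    registry: CladeRegistry,
    parameters: Sequence[str] | None = None,
) -> list[CladeSummary]:
    """Unweighted per-clade means of each parameter, ordered by descending
    stem age. Clades with no orthologs are omitted with a warning."""
    params = list(parameters) if parameters is not None else parameter_names(vectors)
    unknown = set(vectors["clade"]) - set(registry.names)
    if unknown:
        raise ValueError(f"clade(s) not in registry: {sorted(unknown)}")
    out: list[CladeSummary] = []
    grouped = vectors.groupby("clade")
    for entry in sorted(registry, key=lambda c: -c.stem_age_mya):
        if entry.name not in grouped.groups:
            logger.warning("clade %s has no orthologs; omitted", entry.name)
            continue
        grp = grouped.get_group(entry.name)
        means = {p: float(grp[p].mean()) for p in params}  # NaN-skipping mean
        n_per = {p: int(grp[p].notna().sum()) for p in params}
        out.append(CladeSummary(
            clade=entry.name, stem_age_mya=entry.stem_age_mya,
            n_orthologs=len(grp), means=means, n_per_parameter=n_per,
        ))
    return out


def summaries_frame(summaries: Sequence[CladeSummary]) -> pd.DataFrame:
    """Clade summaries as a DataFrame (index clade, stem_age_mya + params)."""
    rows = []
    for s in summaries:
        row = {"stem_age_mya": s.stem_age_mya, "n_orthologs": s.n_orthologs}
        row.update(s.means)
        rows.append(pd.Series(row, name=s.clade))
    df = pd.DataFrame(rows)
    df.index.name = "clade"
    return df


def normalize_to_reference(
    summaries: Sequence[CladeSummary], reference_clade: str
) -> tuple[list[CladeSummary], list[str]]:
    """Divide each clade mean by the reference clade's mean, per parameter.

    For reporting trajectories only — correlations always use unnormalized
    means (per-parameter rescaling cannot change r). Parameters whose
    reference value is 0 are non-normalizable: set to NaN and listed in the
    returned second element.
    """
    ref = next((s for s in summaries if s.clade == reference_clade), None)
    if ref is None:
        raise ValueError(f"reference clade {reference_clade!r} not in summaries")
    bad = sorted(p for p, v in ref.means.items() if v == 0 or math.isnan(v))
    out = []
    for s in summaries:
        means = {
            p: (s.means[p] / ref.means[p]) if p not in bad else float("nan")
            for p in s.means
        }
        out.append(CladeSummary(s.clade, s.stem_age_mya, s.n_orthologs,
                                means, dict(s.n_per_parameter)))
    return out, bad


# ---------------------------------------------------------------------------
# Correlations


def correlate_with_stem_age(
    summaries: Sequence[CladeSummary], parameter: str
) -> CorrelationResult:
    """Pearson r of clade means against clade stem ages.

    Clades where the parameter mean is undefined (no measured ortholog) are
    dropped pairwise; n reflects the clades actually used.
    """
    pts = [(s.means[parameter], s.stem_age_mya) for s in summaries
           if not math.isnan(s.means[parameter])]
    if len(pts) < 3:
        raise ValueError(f"{parameter}: only {len(pts)} clades with defined values")
    vals, ages = zip(*pts)
    return pearson_with_p(vals, ages, parameter=parameter)


def per_species_correlation(
    vectors: pd.DataFrame, registry: CladeRegistry, parameter: str
) -> CorrelationResult:
    """Stem-age correlation over individual orthologs rather than clade
    means: every protein inherits its clade's stem age; n = proteins."""
    ages = vectors["clade"].map(registry.stem_age)
    mask = vectors[parameter].notna()
    return pearson_with_p(vectors.loc[mask, parameter], ages[mask],
                          parameter=parameter)


def cross_series_correlation(
    series_x: Sequence[float], series_y: Sequence[float], label: str = ""
) -> CorrelationResult:
    """Pearson r between two clade-mean series over the same clade ordering
    (paralog-vs-paralog or parameter-vs-parameter comparisons)."""
    return pearson_with_p(series_x, series_y, parameter=label)


def correlation_table(
    summaries: Sequence[CladeSummary], parameters: Sequence[str]
) -> pd.DataFrame:
    """Stem-age correlations for many parameters as one tidy table."""
    rows = []
    for p in parameters:
        try:
            c = correlate_with_stem_age(summaries, p)
        except ValueError:
            c = CorrelationResult(p, float("nan"), 0, float("nan"), False)
        rows.append({"parameter": p, "r": c.r, "n": c.n, "p": c.p,
                     "significant": c.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subsampling robustness


def subsample_robustness(
    vectors: pd.DataFrame,
    registry: CladeRegistry,
    parameters: Sequence[str],
    k: int = 5,
    reps: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Robustness of stem-age correlations to even species sampling.

    Each repetition samples ``k`` species per clade without replacement
    (all of them when the clade has fewer than ``k``), recomputes clade
    means and stem-age correlations per parameter. The stability summary
    reports, per parameter, the fraction of repetitions preserving the
    full-data significance verdict and the fraction preserving the sign
    of r.

    Returns ``(per_rep_table, stability_summary)``; deterministic for a
    fixed seed (per-repetition seeds derive from one root seed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    full = {p: correlate_with_stem_age(clade_summaries(vectors, registry, parameters), p)
            for p in parameters}

    root = np.random.SeedSequence(seed)
    rep_rows = []
    for rep_i, child in enumerate(root.spawn(reps), start=1):
        rng = np.random.default_rng(child)
        picked = []
        for clade in registry.names:
            members = vectors.index[vectors["clade"] == clade]
            if len(members) == 0:
                continue
            if len(members) <= k:
                picked.extend(members)
            else:
                picked.extend(rng.choice(members, size=k, replace=False))
        sub = vectors.loc[picked]
        summaries = clade_summaries(sub, registry, parameters)
        for p in parameters:
            c = correlate_with_stem_age(summaries, p)
            rep_rows.append({"rep": rep_i, "parameter": p, "r": c.r, "n": c.n,
                             "p": c.p, "significant": c.significant})
    per_rep = pd.DataFrame(rep_rows)

    summary_rows = []
    for p in parameters:
        sub = per_rep[per_rep["parameter"] == p]
        f = full[p]
        keep_sig = float((sub["significant"] == f.significant).mean())
        if f.defined:
            same_sign = float((np.sign(sub["r"]) == np.sign(f.r)).mean())
        else:
            same_sign = float("nan")
        summary_rows.append({
            "parameter": p, "full_r": f.r, "full_p": f.p,
            "full_significant": f.significant,
            "frac_reps_same_significance": keep_sig,
            "frac_reps_same_sign": same_sign,
        })
    return per_rep, pd.DataFrame(summary_rows)
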