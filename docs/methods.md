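# Methods

## Problem

Low-complexity regions (LCRs) and homopolymeric amino-acid repeats (AARs)
in protein families — exemplified by the variable N-terminal regions of the
vertebrate CPEB translational regulators — expand and contract over
evolutionary time, with consequences for phase separation and prion-like
behaviour. `lcrevol` quantifies these features per residue and per protein,
aggregates them per clade, and asks whether clade means trend with clade
stem age.

## Window geometry

Both per-residue scores use a sliding window nominally 20 residues long,
centered on residue *i*: positions `[max(1, i−9), min(L, i+10)]` (9
upstream, 10 downstream). At the sequence edges the window clips: it grows
from 11 to 20 residues over the first ten positions and shrinks from 20
down to 10 over the last ten (19 at position L−9 through 10 at position L;
at position L−10 it is still 20). For sequences of 11 residues or fewer the
window is the whole sequence at every position. Symmetric clipping is the
only rule consistent with the stated 11→20 growth at the N-terminus, so it
is applied at both ends.

One consequence worth stating: even a 20-residue homopolymer has clipped
edge windows (lengths 11…20…10), so its **mean** per-residue REP is 15,
not 20; the single full window still scores 20.

## SIM — simplicity

For a window, let `a` be the 20-vector of occurrence counts of the
canonical amino acids and `b` the number of amino acids present at least
once. Then

    SIM = CV(a) / (1 + log b)

with CV the **population** (divide-by-n) coefficient of variation of `a`
and the natural logarithm by default (`log_base` is exposed for sensitivity
checks; both endpoints are base-independent because log 1 = 0). SIM ranges
from 0 (all 20 amino acids once: CV = 0) to √19 ≈ 4.3589 (homopolymer:
CV = √19, b = 1), conventionally printed as 0–4.35 after two-decimal
truncation.

Two alternative readings were rejected because they contradict the printed
endpoints: a *product* CV·(1 + log b) gives 3·(1+ln 2) ≈ 5.08 > 4.35 for a
two-amino-acid block window, and a *sample* (n−1) standard deviation gives
4.472 for the homopolymer. SIM depends only on window composition, so it is
invariant under any permutation of residues within the window.

## REP — repetitiveness

For the same window, identify maximal runs of ≥ 2 identical canonical
residues. With `a_total` the summed run length, `b_runs` the run count and
`c_distinct` the number of distinct run-forming amino acids,

    REP = a_total / (b_runs · c_distinct),    REP = 0 if no run exists.

Range 0–20; 20 is attained only by a pure homopolymer window. The grouping
a/(b·c) is adopted (rather than (a/b)·c) because it parallels the SIM
fraction and makes the homopolymer the unique maximum — (a/b)·c would also
assign 20 to a window of ten two-residue runs. The zero-run case is defined
as 0 to avoid 0/0. "Units" of a tandem repeat are read as residues: runs of
≥ 2 identical residues, not multi-residue motifs. Given fixed composition,
REP ranks arrangement: `AQAQ…` → 0, `AAAAAQQQQQAAAAAQQQQQ` → 2.5,
`AAAAAAAAAAQQQQQQQQQQ` → 5.

Ambiguity codes (B/J/O/U/X/Z) are accepted on input, occupy window
positions, join no count vector entry and break runs. A window containing
no canonical residue has undefined SIM (NaN in tracks) and REP 0.

Per-protein scores are the arithmetic means of the per-residue tracks. The
vectorized track implementation (cumulative counts for SIM, run clipping
for REP) is held equal, to 1e-12, to a naive per-window recomputation in
the test suite.

## Composition and homorepeats

Percent occurrence is `count(X)/length × 100` per canonical amino acid;
ambiguity codes count toward the length only. AARs are maximal runs of ≥ 4
identical canonical residues, reported 1-based inclusive (BED export uses
0-based half-open columns); per-amino-acid totals sum individual repeat
lengths. Enrichment against a proteome baseline flags relative deviations
strictly beyond ±20% — the worked 500-residue example (48 alanines, +20.0%
exactly) sits on the boundary and is deliberately neutral. The baseline is
the **unweighted mean of per-protein percentages** (matching "mean
occurrence across all proteins"); a pooled residue-frequency mode exists
behind a flag and differs whenever lengths vary.

## QC filter

Sequences lacking the initial methionine are discarded, as are sequences
more than 50 residues shorter than the median length of their
(clade, paralog) group. The original selection was done by eye on multiple
alignments; the median-deficit rule is an explicit, idempotent heuristic
stand-in and is logged as such. Singleton groups skip the length rule.

## Evolutionary analysis

Per-protein parameter vectors hold 42 base parameters (20 percents, 20 AAR
totals, mean SIM, mean REP) plus any ingested external per-protein scores
(e.g. LLPS propensity from FuzDrop/ParSe, prion-likeness from PLAAC —
ingested as TSV, never recomputed). The conventional 24-parameter subset is
the 20 percents + mean SIM + mean REP + LLPS + prion-likeness.

Clade means are unweighted over available orthologs regardless of clade
size (how single-sequence clades were weighted in the original analysis is
unstated; unweighted means are used throughout). Pearson's r is computed on
(clade mean, stem age) pairs; p is two-tailed from t = r√(n−2)/√(1−r²) on
n−2 df, which reproduces the reference significance bounds (r = −0.96,
n = 9 → p < 0.001; r = −0.76, n = 9 → p < 0.03). Tied stem ages (Glires and
Primates at 87 Mya) need no special casing. Zero-variance series yield an
undefined r, reported as NaN and never significant. No multiple-testing
correction is applied — matching the reference convention; with 42
parameters, ~2 significant null correlations are expected per family at
α = 0.05, which the null-calibration driver makes visible.

Normalization to the reference (oldest) clade is for reporting only;
correlations always use unnormalized means — a per-parameter positive
rescale cannot change r (asserted in tests). The per-species variant gives
every ortholog its clade's stem age. Subsampling robustness draws k = 5
species per clade without replacement (all, if a clade is smaller), 10
repetitions, per-repetition seeds spawned deterministically from one root
seed; the stability summary reports both the fraction of repetitions
preserving the full-data significance verdict and the fraction preserving
the sign of r, since a tally of "preserved instances" could mean either.

## Synthetic families

The generator emulates exactly the statistical structure the analysis
assumes: each protein is `M + NTR + CTR`, where the CTR is a conserved
block shared family-wide up to a 2% per-site substitution rate, and the NTR
is background sequence carrying planted homorepeat runs of length
`max(0, round(base + slope × age_offset + N(0, σ)))`, with
`age_offset = oldest stem age − clade stem age` so a positive slope means
growth toward younger clades (reported as negative r). Planted runs are
flanked by non-matching residues so they stay maximal and countable.
Defaults: the nine-clade vertebrate registry (stem ages 462, 429, 352, 319,
160, 99, 94, 87, 87 Mya), 8 species/clade, NTR 150, CTR 120, uniform
background over the 20 amino acids, repeat jitter σ = 1 residue. The seed
is mandatory and fully determines the output (integer-state NumPy
generator).

What the generator does **not** emulate: phylogenetic covariance (no tree,
no substitution model), indels beyond repeat-length jitter, realistic
amino-acid background (a uniform background is the default; real proteomes
are far from uniform), and correlated evolution among parameters. Passing
recovery/type-I tests therefore shows the *pipeline* is unbiased and
calibrated under its own assumptions — not that real ortholog data meet
those assumptions. Reproducing the biological correlation values would
require several hundred database orthologs per paralog and is supported as
a workflow, not tested.

Registry fixtures: the Methods-derived nine-clade set above is primary; a
variant with alternative stem ages quoted elsewhere in the source results
(Amp 319, Sau 180, Mar 99, Atl 94; 11 Chondrichthyes species) ships as
`results_variant_registry()` for sensitivity checks, and the 21
ray-finned-fish subclades (Cladistia 396 Mya … Poeciliinae 18.9 Mya) as
`actinopterygii_registry()`.

## Numerical and design choices

- Printed-value comparisons truncate to two decimals (4.35 for √19);
  stored values keep full precision.
- Result TSVs are written with `%.17g` floats and a fixed sort so re-runs
  are byte-identical.
- Metadata travels in a sidecar TSV rather than FASTA headers (headers are
  honored when they carry `key=value` tags).
- Simulation suite sizes: trend recovery uses 200 families (9 clades × 3
  species, 100+60-residue proteins, planted polyP slope 0.04 residues/Mya);
  type-I calibration uses 1000 null families (80+60-residue proteins) and
  pools the 22 composition/complexity parameters, excluding undefined
  correlations from the tally. These sizes give binomial standard errors
  well inside the asserted bands.
- The analysis drivers use seed 1 by default; every stochastic entry point
  requires an explicit seed.

## Known limitations

- Plain Pearson on clade means ignores phylogenetic non-independence;
  tree-aware regression is out of scope by design.
- The QC length rule needs ≥ 2 sequences per (clade, paralog) group to act.
- External predictor scores are taken at face value; threshold metadata
  (e.g. pDP ≥ 0.6) is carried but not enforced.
- Per-residue external tracks are ingested and validated but only
  per-protein values enter the parameter vectors; aggregate tracks upstream
  if needed.
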