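"""Clade means, stem-age correlations, normalization and subsampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lcrevol.evolution import (
    clade_summaries,
    core_parameter_set,
    correlate_with_stem_age,
    cross_series_correlation,
    long_to_vectors,
    normalize_to_reference,
    p_from_r,
    parameter_names,
    parameter_vectors,
    pearson_with_p,
    per_species_correlation,
    subsample_robustness,
    summaries_frame,
    vectors_to_long,
)
from lcrevol.seqio import CladeEntry, CladeRegistry, ExternalScoreSet, ProteinRecord
from lcrevol.synthetic import RepeatEffect, SimConfig, default_registry, simulate_family


@pytest.fixture(scope="module")
def family():
    config = SimConfig(seed=424243, species_per_clade=4, ntr_length=120,
                       ctr_length=80,
                       repeat_effects={"P": RepeatEffect(6.0, 0.04)})
    return simulate_family(config)


@pytest.fixture(scope="module")
def vectors(family):
    records, _, _ = family
    return parameter_vectors(records)


class TestPearson:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            got = pearson_with_p(x, y)
            r_ref, p_ref = sps.pearsonr(x, y)
            assert got.r == pytest.approx(r_ref, abs=1e-12)
            assert got.p == pytest.approx(p_ref, rel=1e-9)

    def test_direct_covariance_oracle(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r_naive = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson_with_p(x, y).r == pytest.approx(r_naive, abs=1e-12)

    @pytest.mark.parametrize("r,n,bound", [(-0.96, 9, 0.001), (-0.76, 9, 0.03)])
    def test_printed_significance_triples(self, r, n, bound):
        assert p_from_r(r, n) < bound

    def test_p_sign_invariant_and_monotone(self):
        for n in (5, 9, 30):
            rs = np.linspace(0.05, 0.95, 10)
            ps = [p_from_r(r, n) for r in rs]
            assert ps == sorted(ps, reverse=True)
            assert all(p_from_r(-r, n) == pytest.approx(p_from_r(r, n)) for r in rs)

    def test_perfect_correlation(self):
        ages = [462, 429, 352, 319, 160, 99, 94, 87, 80]
        vals = [2 - 0.001 * a for a in ages]
        res = pearson_with_p(vals, ages)
        assert res.r == pytest.approx(-1.0) and res.p == 0.0

    def test_zero_variance_undefined(self):
        res = pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.r) and not res.significant

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])


class TestParameterVectors:
    def test_homopolymer_protein(self):
        rec = ProteinRecord("H", "A" * 20, species="s_s", clade="Pri",
                            paralog="S")
        v = parameter_vectors([rec])
        assert v.loc["H", "pct_A"] == 100.0
        assert v.loc["H", "aar_A"] == 20.0
        assert v.loc["H", "mean_SIM"] == pytest.approx(math.sqrt(19))
        # edge windows clip, so per-residue REP averages 15 over L=20
        assert v.loc["H", "mean_REP"] == pytest.approx(15.0)

    def test_base_vector_has_42_entries(self, small_records):
        v = parameter_vectors(small_records)
        assert len(parameter_names(v)) == 42

    def test_external_passthrough_and_missing_nan(self, small_records):
        scores = [ExternalScoreSet("P1", "PLAAC_PRD", value=0.73)]
        v = parameter_vectors(small_records, external_scores=scores)
        assert v.loc["P1", "PLAAC_PRD"] == 0.73
        assert np.isnan(v.loc["P2", "PLAAC_PRD"])

    def test_core_24_subset(self):
        core = core_parameter_set(llps="ParSe_sum", prd="PLAAC_PRD")
        assert len(core) == 24
        assert "mean_SIM" in core and "pct_P" in core


class TestCladeSummaries:
    def test_means_and_order(self):
        reg = CladeRegistry([CladeEntry("Old", 400), CladeEntry("New", 90)])
        recs = [
            ProteinRecord("A1", "M" + "P" * 10 + "Q" * 89, species="a_a",
                          clade="New", paralog="S"),
            ProteinRecord("A2", "M" + "P" * 14 + "Q" * 85, species="b_b",
                          clade="New", paralog="S"),
            ProteinRecord("A3", "M" + "Q" * 99, species="c_c", clade="Old",
                          paralog="S"),
        ]
        summaries = clade_summaries(parameter_vectors(recs), reg)
        assert [s.clade for s in summaries] == ["Old", "New"]  # descending age
        new = summaries[1]
        assert new.means["pct_P"] == pytest.approx(12.0)
        assert new.n_orthologs == 2

    def test_groupwise_mean_oracle(self, vectors, family):
        _, _, _ = family
        summaries = clade_summaries(vectors, default_registry())
        df = vectors.groupby("clade")["pct_P"].mean()
        for s in summaries:
            assert s.means["pct_P"] == pytest.approx(df[s.clade], abs=1e-12)

    def test_empty_clade_omitted(self, caplog):
        reg = CladeRegistry([CladeEntry("A", 100), CladeEntry("B", 50)])
        recs = [ProteinRecord("P1", "MAAAQ", species="x_x", clade="A",
                              paralog="S")]
        summaries = clade_summaries(parameter_vectors(recs), reg)
        assert [s.clade for s in summaries] == ["A"]


class TestNormalize:
    def test_reference_maps_to_one(self, vectors):
        summaries = clade_summaries(vectors, default_registry())
        normed, bad = normalize_to_reference(summaries, "Cho")
        ref = next(s for s in normed if s.clade == "Cho")
        for p, v in ref.means.items():
            if p not in bad:
                assert v == pytest.approx(1.0)

    def test_simple_ratio(self):
        reg = CladeRegistry([CladeEntry("Cho", 462), CladeEntry("Pri", 87)])
        recs = [ProteinRecord("C", "M" + "P" * 5 + "Q" * 94, species="c_c",
                              clade="Cho", paralog="S"),
                ProteinRecord("P", "M" + "P" * 8 + "Q" * 91, species="p_p",
                              clade="Pri", paralog="S")]
        summaries = clade_summaries(parameter_vectors(recs), reg)
        normed, bad = normalize_to_reference(summaries, "Cho")
        pri = next(s for s in normed if s.clade == "Pri")
        assert pri.means["pct_P"] == pytest.approx(1.6)
        assert "pct_W" in bad  # reference has no tryptophan: flagged, not inf

    def test_normalization_does_not_change_r(self, vectors):
        """Normalization is a per-parameter positive rescale, so it cannot
        change the stem-age correlation."""
        summaries = clade_summaries(vectors, default_registry())
        normed, bad = normalize_to_reference(summaries, "Cho")
        for p in ("pct_P", "mean_SIM"):
            assert p not in bad
            r0 = correlate_with_stem_age(summaries, p).r
            r1 = correlate_with_stem_age(normed, p).r
            assert r1 == pytest.approx(r0, abs=1e-10)


class TestStemAgeCorrelation:
    def test_planted_trend_detected(self, vectors):
        summaries = clade_summaries(vectors, default_registry())
        res = correlate_with_stem_age(summaries, "aar_P")
        assert res.r < -0.9 and res.significant
        assert res.n == 9

    def test_linear_means_give_r_of_one(self):
        reg = default_registry()
        summaries = clade_summaries(
            _linear_vectors(reg, slope=-0.01), reg, ["pct_A"])
        res = correlate_with_stem_age(summaries, "pct_A")
        assert abs(res.r) == pytest.approx(1.0)

    def test_per_species_variant(self, vectors):
        res = per_species_correlation(vectors, default_registry(), "aar_P")
        assert res.n == len(vectors)
        assert res.r < -0.8 and res.significant

    def test_single_clade_zero_age_variance(self):
        reg = CladeRegistry([CladeEntry("A", 100)])
        recs = [ProteinRecord(f"P{i}", "M" + "A" * (10 + i), species=f"s{i}_x",
                              clade="A", paralog="S") for i in range(4)]
        res = per_species_correlation(parameter_vectors(recs), reg, "pct_A")
        assert not res.defined and not res.significant


class TestCrossSeries:
    def test_self_correlation(self):
        x = [1.0, 2.0, 3.5, 7.0]
        res = cross_series_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_printed_cross_paralog_triple(self):
        assert p_from_r(0.89, 9) < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_series_correlation([1, 2, 3], [1, 2])

    def test_type_one_rate_null_series(self, rng):
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            res = cross_series_correlation(rng.normal(size=9), rng.normal(size=9))
            hits += res.significant
        assert 0.02 <= hits / n_sim <= 0.09


class TestSubsampling:
    def test_k_at_clade_size_reproduces_full(self, vectors):
        reg = default_registry()
        params = ["pct_P", "aar_P", "mean_SIM"]
        full = {p: correlate_with_stem_age(clade_summaries(vectors, reg, params), p)
                for p in params}
        per_rep, _ = subsample_robustness(vectors, reg, params, k=4, reps=3,
                                          seed=7)
        for row in per_rep.itertuples():
            assert row.r == pytest.approx(full[row.parameter].r, abs=1e-12)

    def test_deterministic_given_seed(self, vectors):
        reg = default_registry()
        a = subsample_robustness(vectors, reg, ["aar_P"], k=2, reps=5, seed=11)
        b = subsample_robustness(vectors, reg, ["aar_P"], k=2, reps=5, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_strong_trend_survives_subsampling(self, vectors):
        per_rep, stability = subsample_robustness(
            vectors, default_registry(), ["aar_P"], k=2, reps=10, seed=3)
        row = stability.iloc[0]
        assert row.full_significant
        assert row.frac_reps_same_significance >= 0.9
        assert row.frac_reps_same_sign == 1.0

    def test_k_validation(self, vectors):
        with pytest.raises(ValueError):
            subsample_robustness(vectors, default_registry(), ["pct_A"], k=0)


class TestLongWideRoundtrip:
    def test_roundtrip(self, vectors):
        table = pd.DataFrame(vectors_to_long(vectors))
        back = long_to_vectors(table)
        for p in parameter_names(vectors):
            np.testing.assert_allclose(
                back[p].loc[vectors.index], vectors[p], atol=1e-12)


def _linear_vectors(registry, slope: float) -> pd.DataFrame:
    rows = []
    for entry in registry:
        for s in range(2):
            rows.append(pd.Series({
                "species": f"{entry.name}_s{s}", "clade": entry.name,
                "paralog": "S", "pct_A": 10 + slope * entry.stem_age_mya,
            }, name=f"{entry.name}{s}"))
    df = pd.DataFrame(rows)
    df.index.name = "protein_id"
    return df
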