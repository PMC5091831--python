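"""Screening rules, non-local-molt flagging, ANOVA, transfer-function bands."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plumage.fixtures import EXCLUDED_SPECIES, make_synthetic_records
from plumage.screening import (
    DEFAULT_NONLOCAL_BAND,
    TransferFunction,
    classify_species_mean,
    flag_nonlocal_molt,
    predict_feather_band,
    screen_records,
    year_species_anova,
)
from plumage.validation import anova_power_study


class TestScreenRecords:
    def test_identity_filter(self, records_toy):
        report, kept = screen_records(records_toy, min_n=1, exclusion_list=())
        assert report.retained_records == len(records_toy)
        assert not report.excluded_species

    def test_minimum_sample_rule(self, records_toy):
        report, kept = screen_records(records_toy, min_n=9)
        assert report.retained_records == 19
        assert report.retained_species == ["AAAA", "CCCC"]
        assert "BBBB" in report.excluded_species

    def test_non_asy_records_dropped(self, records_toy):
        df = records_toy.copy()
        df.loc[df.index[:2], "age"] = "SY"
        report, kept = screen_records(df, min_n=1)
        assert report.retained_records == len(df) - 2
        assert (kept["age"] == "ASY").all()

    def test_idempotent(self, records_toy):
        _, once = screen_records(records_toy, min_n=9)
        _, twice = screen_records(once, min_n=9)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_raises(self, records_toy):
        with pytest.raises(ValueError, match="no records"):
            screen_records(records_toy, min_n=99)

    def test_fixture_exclusion_arithmetic(self):
        records = make_synthetic_records(seed=0)
        report, kept = screen_records(
            records, min_n=9, exclusion_list=EXCLUDED_SPECIES
        )
        assert report.retained_records == 192
        assert len(report.retained_species) == 15
        assert set(report.excluded_species) == set(EXCLUDED_SPECIES)

    def test_report_json_round_trip(self, records_toy, tmp_path):
        import json

        report, _ = screen_records(records_toy, min_n=9)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["retained_records"] == 19


class TestFlagNonlocalMolt:
    def test_enriched_mean_is_flagged(self):
        flagged = flag_nonlocal_molt({"XXXX": -51.0}, band=(-170.0, -110.0))
        assert flagged == ["XXXX"]

    def test_all_inside_band_no_flags(self):
        means = {"AAAA": -150.0, "BBBB": -127.0}
        assert flag_nonlocal_molt(means, band=(-170.0, -110.0)) == []

    def test_boundary_mean_not_flagged(self):
        assert flag_nonlocal_molt({"EDGE": -110.0}, band=(-170.0, -110.0)) == []

    def test_fixture_reproduces_the_six_excluded_species(self):
        """The synthetic table flags exactly the six non-local molters."""
        records = make_synthetic_records(seed=0)
        means = records.groupby("species")["d2hf"].mean()
        flagged = flag_nonlocal_molt(means, band=DEFAULT_NONLOCAL_BAND)
        assert sorted(flagged) == sorted(EXCLUDED_SPECIES)


def _balanced_two_way(cell_means, n_per_cell, sigma, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for (year, sp), mu in cell_means.items():
        for v in rng.normal(mu, sigma, size=n_per_cell):
            rows.append({"year": year, "species": sp, "d2hf": v})
    return pd.DataFrame(rows)


class TestYearSpeciesAnova:
    def test_null_case_interaction_near_zero(self):
        pvals = []
        for seed in range(10):
            df = _balanced_two_way(
                {(y, s): -140.0 for y in (2011, 2013) for s in ("AAAA", "BBBB")},
                n_per_cell=10, sigma=1.0, seed=seed,
            )
            table = year_species_anova(df)
            p = table.loc[table["effect"] == "C(year):C(species)", "p"].iloc[0]
            pvals.append(float(p))
        assert np.median(pvals) > 0.05

    def test_hand_computed_sums_of_squares(self):
        """Balanced 2×2 with cell means (0,0,0,10): textbook SS decomposition."""
        df = _balanced_two_way(
            {(1, "A"): 0.0, (1, "B"): 0.0, (2, "A"): 0.0, (2, "B"): 10.0},
            n_per_cell=5, sigma=1.0, seed=3,
        )
        table = year_species_anova(df).set_index("effect")
        # oracle: balanced two-way SS from cell/marginal means
        piv = df.groupby(["year", "species"])["d2hf"].mean().unstack()
        grand = df["d2hf"].mean()
        n = 5
        ss_year = 2 * n * ((piv.mean(axis=1) - grand) ** 2).sum()
        ss_species = 2 * n * ((piv.mean(axis=0) - grand) ** 2).sum()
        interaction = piv.sub(piv.mean(axis=1), axis=0).sub(piv.mean(axis=0), axis=1) + grand
        ss_int = n * (interaction**2).to_numpy().sum()
        ss_resid = (
            df.groupby(["year", "species"])["d2hf"]
            .apply(lambda v: ((v - v.mean()) ** 2).sum())
            .sum()
        )
        f_oracle = (ss_int / 1) / (ss_resid / (20 - 4))
        assert table.loc["C(year)", "sum_sq"] == pytest.approx(ss_year, abs=1e-8)
        assert table.loc["C(species)", "sum_sq"] == pytest.approx(ss_species, abs=1e-8)
        assert table.loc["C(year):C(species)", "F"] == pytest.approx(f_oracle, abs=1e-8)

    def test_shift_invariance_of_F(self):
        df = _balanced_two_way(
            {(1, "A"): 0.0, (1, "B"): 2.0, (2, "A"): 1.0, (2, "B"): 5.0},
            n_per_cell=6, sigma=2.0, seed=4,
        )
        t1 = year_species_anova(df)
        df2 = df.assign(d2hf=df["d2hf"] + 1000.0)
        t2 = year_species_anova(df2)
        np.testing.assert_allclose(t1["F"][:3], t2["F"][:3], rtol=1e-10)

    def test_empty_cell_error_names_cell(self):
        df = _balanced_two_way(
            {(1, "A"): 0.0, (1, "B"): 0.0, (2, "A"): 0.0, (2, "B"): 0.0},
            n_per_cell=4, sigma=1.0, seed=5,
        )
        df = df[~((df["year"] == 2) & (df["species"] == "B"))]
        with pytest.raises(ValueError, match="year=2, species=B"):
            year_species_anova(df)

    def test_requires_exactly_two_years(self):
        df = _balanced_two_way(
            {(y, s): 0.0 for y in (1, 2, 3) for s in ("A", "B")},
            n_per_cell=3, sigma=1.0, seed=6,
        )
        with pytest.raises(ValueError, match="2 year"):
            year_species_anova(df)

    def test_power_at_observed_offsets_matches_noncentral_F(self):
        """Simulated detection rate agrees with the exact noncentral-F power."""
        res = anova_power_study(n_replicates=100, seed=0)
        offs = np.array([4.0, 9.0, 12.0, -6.0])
        d = offs - offs.mean()
        nc = 15 * np.sum((d / 2.0) ** 2) * 2 / 8.0**2
        df1, df2 = 3, 8 * 15 - 8
        crit = stats.f.ppf(1 - 0.001, df1, df2)
        exact = 1 - stats.ncf.cdf(crit, df1, df2, nc)
        assert abs(res["power"] - exact) < 0.1


class TestTransferFunction:
    def test_linear_band(self):
        tf = TransferFunction(intercept=-20.0, slope=1.0, resid_sd=10.0, label="ground")
        assert predict_feather_band(-120.0, [tf])["ground"] == (-150.0, -130.0)

    def test_zero_slope_band_constant(self):
        tf = TransferFunction(intercept=-140.0, slope=0.0, resid_sd=5.0, label="non-ground")
        assert tf.band(-120.0) == tf.band(-80.0)

    def test_species_mean_classification(self):
        assert classify_species_mean(-143.0, (-160.0, -130.0)) == "consistent with local molt"
        assert classify_species_mean(-100.0, (-160.0, -130.0)) == "outside predicted band"

    def test_missing_configuration_rejected(self):
        with pytest.raises(ValueError):
            predict_feather_band(-120.0, [])
        with pytest.raises(ValueError):
            TransferFunction(intercept=0.0, slope=1.0, resid_sd=0.0, label="x")
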