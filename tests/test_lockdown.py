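"""The lockdown loss factor F: labelling, period means, ratios, tables."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_force_factor,
    calendar_from_lck,
    random_factor_instance,
    records_to_flows,
)
from riverflux import (
    LockdownFactor,
    f_factor,
    factor_table,
    factor_table_by_window,
    label_period,
    site_period_means,
)
from riverflux.periods import default_calendar


CAL = default_calendar()


class TestLabelPeriod:
    @pytest.mark.parametrize(
        "month, expected",
        [
            ("2020-04", "LCK"),   # inside the first lockdown window
            ("2020-07", "OOL"),   # the summer between the windows
            ("2021-01", "LCK"),   # inside the second window
            ("2020-10", "OOL"),   # window opens only late October
            ("2020-01", "OOL"),
            ("2021-03", "LCK"),
        ],
    )
    def test_default_calendar_labels(self, month, expected):
        assert label_period(month, CAL) == expected

    def test_month_outside_campaign_is_an_error(self):
        with pytest.raises(ValueError, match="outside campaign"):
            label_period("2019-12", CAL)

    def test_lockdown_strata_sizes(self):
        labels = [CAL.label(m) for m in CAL.campaign_months()]
        assert labels.count("LCK") == 8 and labels.count("OOL") == 8


def site_frame(ool_values, lck_values):
    ool_months = [m for m in CAL.campaign_months() if CAL.label(m) == "OOL"]
    lck_months = [m for m in CAL.campaign_months() if CAL.label(m) == "LCK"]
    rows = [(m, v) for m, v in zip(ool_months, ool_values)]
    rows += [(m, v) for m, v in zip(lck_months, lck_values)]
    return pd.DataFrame(rows, columns=["month", "mass_flow_ug_s"])


class TestSitePeriodMeans:
    @pytest.mark.parametrize(
        "ool, lck, expected",
        [
            ([2, 4], [1, 3], (3.0, 2.0)),
            ([7, 7, 7], [7, 7], (7.0, 7.0)),
            ([10, 20, 30], [5], (20.0, 5.0)),
        ],
    )
    def test_arithmetic_means_per_period(self, ool, lck, expected):
        assert site_period_means(site_frame(ool, lck), CAL) == pytest.approx(expected)

    def test_empty_period_yields_nan(self):
        l_ool, l_lck = site_period_means(site_frame([1.0], []), CAL)
        assert l_ool == 1.0 and np.isnan(l_lck)


class TestFFactor:
    def test_single_site(self):
        flows = records_to_flows(
            [("s1", pd.Period("2020-01", "M"), 4.0), ("s1", pd.Period("2020-04", "M"), 2.0)]
        )
        res = f_factor(flows, CAL)
        assert res.f == pytest.approx(2.0)
        assert res.stdev == 0.0
        assert res.n_sites == 1

    def test_two_sites_hand_computed(self):
        """Per-site (L_OOL, L_LCK) of (4,1) and (2,2): ratios {4, 1}, so
        F = 2.5 and the n-1 standard deviation is sqrt(4.5) = 2.1213."""
        rows = [
            ("s1", pd.Period("2020-01", "M"), 4.0),
            ("s1", pd.Period("2020-04", "M"), 1.0),
            ("s2", pd.Period("2020-01", "M"), 2.0),
            ("s2", pd.Period("2020-04", "M"), 2.0),
        ]
        res = f_factor(records_to_flows(rows), CAL)
        assert res.f == pytest.approx(2.5)
        assert res.stdev == pytest.approx(2.1213, abs=1e-4)
        assert res.n_sites == 2
        assert res.substantial_loss and res.halved

    def test_site_without_lockdown_samples_is_excluded(self, caplog):
        rows = [
            ("s1", pd.Period("2020-01", "M"), 4.0),
            ("s1", pd.Period("2020-04", "M"), 2.0),
            ("s2", pd.Period("2020-01", "M"), 9.0),  # no LCK month at s2
        ]
        with caplog.at_level("WARNING"):
            res = f_factor(records_to_flows(rows), CAL)
        assert res.n_sites == 1
        assert any("excluded" in r.message for r in caplog.records)

    def test_no_eligible_site_is_an_error(self):
        rows = [("s1", pd.Period("2020-01", "M"), 4.0)]
        with pytest.raises(ValueError, match="eligible"):
            f_factor(records_to_flows(rows), CAL)

    def test_oracle_equivalence_on_random_instances(self):
        """F, its dispersion and the site count match a brute-force
        double-loop reference on small random instances."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            records, lck = random_factor_instance(rng)
            oracle = brute_force_factor(records, lck)
            flows = records_to_flows(records)
            cal = calendar_from_lck(lck)
            res = f_factor(flows, cal)
            f_ref, sd_ref, n_ref = oracle
            assert res.n_sites == n_ref
            assert res.f == pytest.approx(f_ref, rel=1e-12)
            assert res.stdev == pytest.approx(sd_ref, rel=1e-12, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        records, lck = random_factor_instance(rng)
        flows = records_to_flows(records)
        cal = calendar_from_lck(lck)
        base = f_factor(flows, cal)
        scaled = flows.assign(mass_flow_ug_s=flows["mass_flow_ug_s"] * 1234.5)
        res = f_factor(scaled, cal)
        assert res.f == pytest.approx(base.f, rel=1e-12)
        assert res.stdev / res.f == pytest.approx(
            base.stdev / base.f if base.f else 0.0, rel=1e-9, abs=1e-12
        )

    def test_period_swap_inverts_site_ratios(self):
        """Exchanging the LCK and OOL labels maps each per-site ratio to its
        reciprocal."""
        rng = np.random.default_rng(11)
        records, lck = random_factor_instance(rng)
        flows = records_to_flows(records)
        months = set(flows["month"])
        swapped = months - lck
        if not swapped or not (months & lck):
            pytest.skip("degenerate draw")
        est = LockdownFactor(calendar=calendar_from_lck(lck)).fit(flows)
        est_swapped = LockdownFactor(calendar=calendar_from_lck(swapped)).fit(flows)
        a = est.site_ratios_.set_index("site_code")["ratio"]
        b = est_swapped.site_ratios_.set_index("site_code")["ratio"]
        common = a.index.intersection(b.index)
        assert len(common) > 0
        np.testing.assert_allclose(a[common], 1.0 / b[common], rtol=1e-12)


class TestFactorTable:
    def test_null_dataset_gives_unit_factors(self):
        rows = []
        for s in ["s1", "s2"]:
            for m in CAL.campaign_months():
                rows.append((s, "a", m, 5.0, "R"))
        df = pd.DataFrame(rows, columns=["site_code", "analyte", "month", "mass_flow_ug_s", "river"])
        table = factor_table(df, CAL)
        assert (table["f"] == 1.0).all()
        assert not table["substantial_loss"].any()
        assert not table["halved"].any()

    def test_sorted_descending_with_threshold_flags(self, default_flows):
        table = factor_table(default_flows, CAL)
        assert (table["f"].diff().dropna() <= 1e-12).all()
        assert table["substantial_loss"].equals(table["f"] >= 1.5)
        assert table["halved"].equals(table["f"] >= 2.0)
        assert (table["halved"] <= table["substantial_loss"]).all()

    def test_builtin_panels_row_counts(self, default_flows):
        table = factor_table(default_flows, CAL)
        counts = table.groupby("river").size()
        assert counts["Sava"] == 17
        assert counts["Drava"] == 7

    def test_per_window_table_has_both_lockdowns(self, default_flows):
        win = factor_table_by_window(default_flows, CAL)
        assert set(win["window"]) == {"LCK1", "LCK2"}
        pooled = factor_table(default_flows, CAL)
        assert len(win) == 2 * len(pooled)

    def test_time_axis_stdev_is_a_flagged_alternative(self, default_flows):
        sites_axis = LockdownFactor(calendar=CAL, stdev_axis="sites").fit(default_flows)
        time_axis = LockdownFactor(calendar=CAL, stdev_axis="time").fit(default_flows)
        pd.testing.assert_series_equal(
            sites_axis.factor_table_["f"], time_axis.factor_table_["f"]
        )
        assert not sites_axis.factor_table_["stdev"].equals(time_axis.factor_table_["stdev"])
        with pytest.raises(ValueError, match="stdev_axis"):
            LockdownFactor(stdev_axis="bogus").fit(default_flows)
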