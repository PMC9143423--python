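"""Lockdown-effect ratio statistic on contaminant mass flows.

For one analyte on one river, each monitoring site *i* contributes the
ratio of its average mass flow outside lockdowns to its average mass flow
during lockdowns,

    r_i = L_i(OOL) / L_i(LCK),

with both averages taken over the site's *sampled* months in each period
(missing months are never interpolated).  The factor

    F = (1/N) Σ_i r_i

is the mean of the per-site ratios over the N eligible sites, and its
dispersion is the sample (n−1) standard deviation of the r_i (0 when
N = 1).  F > 1 means the analyte's flux dropped during lockdowns; F ≥ 1.5
is flagged a substantial loss and F ≥ 2 means the flux more than halved.

A site is eligible only if it has at least one sampled month in each
period and a non-zero lockdown average; ineligible sites are excluded with
a logged warning, never silently.  Both lockdown windows are pooled into
one LCK stratum for F; per-window factors are available as supplementary
output because the two lockdowns differed in strictness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .periods import OOL, PeriodCalendar, default_calendar

__all__ = [
    "FactorResult",
    "LockdownFactor",
    "site_period_means",
    "f_factor",
    "factor_table",
    "factor_table_by_window",
]

logger = logging.getLogger(__name__)

SUBSTANTIAL_LOSS_THRESHOLD = 1.5
HALVED_THRESHOLD = 2.0


@dataclass(frozen=True)
class FactorResult:
    """One analyte × river row of the lockdown-loss table."""

    analyte: str
    river: str
    f: float
    stdev: float
    n_sites: int
    substantial_loss: bool
    halved: bool

    def __post_init__(self):
        if not self.f > 0:
            raise ValueError(f"F must be positive, got {self.f}")
        if self.stdev < 0 or self.n_sites < 1:
            raise ValueError("stdev must be >= 0 and n_sites >= 1")
        if self.halved and not self.substantial_loss:
            raise ValueError("halved implies substantial_loss")


def site_period_means(site_flows: pd.DataFrame, calendar: PeriodCalendar) -> tuple[float, float]:
    """Arithmetic mean mass flow (µg/s) per period for one site × analyte.

    ``site_flows`` needs columns ``month`` and ``mass_flow_ug_s``.  Returns
    ``(L_OOL, L_LCK)``; a period with no sampled month yields NaN there (the
    caller decides eligibility).
    """
    labels = site_flows["month"].map(calendar.label)
    values = site_flows["mass_flow_ug_s"]
    ool = values[labels == OOL]
    lck = values[labels != OOL]
    l_ool = float(ool.mean()) if len(ool) else float("nan")
    l_lck = float(lck.mean()) if len(lck) else float("nan")
    return l_ool, l_lck


def _site_ratios(flows: pd.DataFrame, calendar: PeriodCalendar,
                 analyte: str, river: str) -> pd.Series:
    """Per-site OOL/LCK ratios for one analyte × river, excluding ineligible sites."""
    ratios: dict[str, float] = {}
    for site, sub in flows.groupby("site_code", observed=True, sort=True):
        l_ool, l_lck = site_period_means(sub, calendar)
        if np.isnan(l_ool) or np.isnan(l_lck):
            logger.warning(
                "site %s excluded for %s (%s): no sampled month in one period", site, analyte, river
            )
            continue
        if l_lck == 0:
            logger.warning(
                "site %s excluded for %s (%s): zero lockdown mass flow makes the ratio undefined",
                site, analyte, river,
            )
            continue
        ratios[site] = l_ool / l_lck
    return pd.Series(ratios, dtype=float)


def _result_from_ratios(analyte: str, river: str, ratios: pd.Series) -> FactorResult:
    f = float(ratios.mean())
    stdev = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return FactorResult(
        analyte=analyte,
        river=river,
        f=f,
        stdev=stdev,
        n_sites=int(len(ratios)),
        substantial_loss=bool(f >= SUBSTANTIAL_LOSS_THRESHOLD),
        halved=bool(f >= HALVED_THRESHOLD),
    )


def f_factor(flows: pd.DataFrame, calendar: PeriodCalendar | None = None,
             analyte: str | None = None, river: str | None = None) -> FactorResult:
    """The factor F for one analyte on one river.

    ``flows`` is the per-(site, analyte, month) mass-flow table; if it holds
    several analytes/rivers, name the one wanted via ``analyte``/``river``.

    Raises ``ValueError`` when no site is eligible.
    """
    calendar = calendar or default_calendar()
    sub = flows
    if analyte is not None:
        sub = sub[sub["analyte"] == analyte]
    if river is not None and "river" in sub.columns:
        sub = sub[sub["river"] == river]
    names = sub["analyte"].unique() if "analyte" in sub.columns else [analyte or "?"]
    if len(names) != 1:
        raise ValueError(f"f_factor needs exactly one analyte, got {sorted(names)}")
    a = str(names[0])
    r = river if river is not None else str(sub["river"].iloc[0]) if "river" in sub.columns else ""
    ratios = _site_ratios(sub, calendar, a, r)
    if ratios.empty:
        raise ValueError(f"no eligible site for {a!r} on {r!r}")
    return _result_from_ratios(a, r, ratios)


class LockdownFactor(BaseEstimator):
    """Estimate the per-analyte lockdown loss factor F across sites.

    scikit-learn style estimator: ``fit`` consumes the long-format
    mass-flow table (columns ``site_code, river, analyte, month,
    mass_flow_ug_s``) and computes

    ``factor_table_``
        one row per (analyte, river) sorted by F descending, with the
        sample standard deviation of the per-site ratios, the eligible-site
        count and the threshold flags;
    ``site_ratios_``
        tidy per-site ratios behind each row;
    ``window_table_``
        supplementary per-lockdown-window factors (each window vs OOL).

    Parameters
    ----------
    calendar:
        PeriodCalendar; None uses the packaged default study calendar.
    stdev_axis:
        "sites" (default): dispersion across the per-site ratios, matching
        the factor's definition.  "time": dispersion across OOL months of
        the monthly cross-site mean of L_i(month)/L_i(LCK) — an alternative
        reading kept behind this flag.
    """

    def __init__(self, calendar: PeriodCalendar | None = None, stdev_axis: str = "sites"):
        self.calendar = calendar
        self.stdev_axis = stdev_axis

    def fit(self, X: pd.DataFrame, y=None):
        if self.stdev_axis not in ("sites", "time"):
            raise ValueError(f"stdev_axis must be 'sites' or 'time', got {self.stdev_axis!r}")
        calendar = self.calendar or default_calendar()
        results: list[FactorResult] = []
        ratio_rows = []
        for (river, analyte), sub in X.groupby(["river", "analyte"], observed=True, sort=True):
            ratios = _site_ratios(sub, calendar, analyte, river)
            if ratios.empty:
                logger.warning("no eligible site for %s (%s); row omitted", analyte, river)
                continue
            res = _result_from_ratios(analyte, river, ratios)
            if self.stdev_axis == "time":
                res = FactorResult(
                    analyte=res.analyte, river=res.river, f=res.f,
                    stdev=self._time_stdev(sub, calendar),
                    n_sites=res.n_sites,
                    substantial_loss=res.substantial_loss, halved=res.halved,
                )
            results.append(res)
            for site, r in ratios.items():
                ratio_rows.append((analyte, river, site, r))

        table = pd.DataFrame([vars(r) for r in results])
        if not table.empty:
            table = table.sort_values(
                ["f", "analyte"], ascending=[False, True], kind="stable"
            ).reset_index(drop=True)
        self.factor_table_ = table
        self.site_ratios_ = pd.DataFrame(
            ratio_rows, columns=["analyte", "river", "site_code", "ratio"]
        )
        self.window_table_ = self._window_table(X, calendar)
        return self

    @staticmethod
    def _time_stdev(sub: pd.DataFrame, calendar: PeriodCalendar) -> float:
        """Across-time dispersion: sd over OOL months of the cross-site mean
        of L_i(month)/L_i(LCK)."""
        monthly = []
        lck_means = {}
        for site, s in sub.groupby("site_code", observed=True):
            _, l_lck = site_period_means(s, calendar)
            if not np.isnan(l_lck) and l_lck != 0:
                lck_means[site] = l_lck
        ool = sub[sub["month"].map(calendar.label) == OOL]
        for month, s in ool.groupby("month", observed=True):
            vals = [
                row.mass_flow_ug_s / lck_means[row.site_code]
                for row in s.itertuples()
                if row.site_code in lck_means
            ]
            if vals:
                monthly.append(float(np.mean(vals)))
        return float(np.std(monthly, ddof=1)) if len(monthly) > 1 else 0.0

    def _window_table(self, X: pd.DataFrame, calendar: PeriodCalendar) -> pd.DataFrame:
        """Per-window factors: each lockdown window separately vs OOL."""
        rows = []
        for window in calendar.windows:
            single = PeriodCalendar(
                calendar.campaign_start, calendar.campaign_end, (window,)
            )
            # Months of other windows must not leak into OOL: drop them.
            other = [m for w in calendar.windows if w is not window for m in w.months()]
            keep = ~X["month"].isin(other)
            for (river, analyte), sub in X[keep].groupby(
                ["river", "analyte"], observed=True, sort=True
            ):
                ratios = _site_ratios(sub, single, analyte, river)
                if ratios.empty:
                    continue
                res = _result_from_ratios(analyte, river, ratios)
                rows.append((window.label, analyte, river, res.f, res.stdev, res.n_sites))
        return pd.DataFrame(
            rows, columns=["window", "analyte", "river", "f", "stdev", "n_sites"]
        )


def factor_table(flows: pd.DataFrame, calendar: PeriodCalendar | None = None,
                 stdev_axis: str = "sites") -> pd.DataFrame:
    """Per-(analyte, river) factor table sorted by F descending."""
    return LockdownFactor(calendar=calendar, stdev_axis=stdev_axis).fit(flows).factor_table_


def factor_table_by_window(flows: pd.DataFrame,
                           calendar: PeriodCalendar | None = None) -> pd.DataFrame:
    """Supplementary per-lockdown-window factor table."""
    return LockdownFactor(calendar=calendar).fit(flows).window_table_
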