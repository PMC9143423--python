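"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (plain Python
loops, direct eigendecomposition) kept free of any package code so they can
serve as independent references for the pipeline's statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riverflux import SimulationConfig, align, compute_mass_flows, simulate
from riverflux.periods import PeriodCalendar, default_calendar


# ---------------------------------------------------------------------------
# Oracles


def brute_force_factor(records, lck_months):
    """Reference lockdown factor: plain double loop over (site, month, value).

    ``records`` is an iterable of (site, month, value); ``lck_months`` the
    set of lockdown months.  Returns (F, sd, n_sites) with sites lacking a
    period or with zero lockdown mean excluded — mirroring the definition,
    not the implementation.
    """
    records = list(records)
    sites = sorted({s for s, _, _ in records})
    ratios = []
    for site in sites:
        ool = [v for s, m, v in records if s == site and m not in lck_months]
        lck = [v for s, m, v in records if s == site and m in lck_months]
        if not ool or not lck:
            continue
        lck_mean = sum(lck) / len(lck)
        if lck_mean == 0:
            continue
        ratios.append((sum(ool) / len(ool)) / lck_mean)
    if not ratios:
        return None
    n = len(ratios)
    f = sum(ratios) / n
    sd = (sum((r - f) ** 2 for r in ratios) / (n - 1)) ** 0.5 if n > 1 else 0.0
    return f, sd, n


def eig_pca(matrix, n_components, standardize=False):
    """Reference PCA via direct eigendecomposition of the covariance matrix.

    Returns (explained_fractions, scores) with each score column oriented so
    its largest-magnitude loading is positive (the package's convention).
    """
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / Xc.std(axis=0, ddof=0)
    n = X.shape[0]
    cov = Xc.T @ Xc / (n - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0, None)
    fractions = w / w.sum()
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] *= -1
    scores = Xc @ v[:, :n_components]
    return fractions[:n_components], scores


def random_factor_instance(rng, max_sites=5, max_months=16):
    """A random small instance for the factor oracle: sparse site-month grid.

    Returns (records, lck_months) guaranteed to leave >= 1 eligible site.
    """
    calendar = default_calendar()
    months = calendar.campaign_months()[: rng.integers(4, max_months + 1)]
    lck = {m for m in months if calendar.label(m) == "LCK"}
    if not lck or len(lck) == len(months):
        lck = set(months[: max(1, len(months) // 2)])
    n_sites = int(rng.integers(1, max_sites + 1))
    cells: dict = {}
    for s in range(n_sites):
        for m in months:
            if rng.random() < 0.75:  # sparse sampling
                cells[(f"s{s}", m)] = float(rng.lognormal(1.0, 1.0))
    # Guarantee one eligible site (one sample in each period).
    cells.setdefault(("s0", sorted(lck)[0]), float(rng.lognormal(1.0, 1.0)))
    ool_months = [m for m in months if m not in lck]
    if ool_months:
        cells.setdefault(("s0", ool_months[0]), float(rng.lognormal(1.0, 1.0)))
    records = [(s, m, v) for (s, m), v in cells.items()]
    return records, lck


def records_to_flows(records, analyte="x", river="R"):
    """Long-format mass-flow table from (site, month, value) records."""
    df = pd.DataFrame(records, columns=["site_code", "month", "mass_flow_ug_s"])
    df = df.groupby(["site_code", "month"], as_index=False).first()  # dedupe guard rows
    df["analyte"] = analyte
    df["river"] = river
    return df


def calendar_from_lck(lck_months) -> PeriodCalendar:
    """Calendar whose pooled LCK stratum is exactly ``lck_months``."""
    from riverflux.periods import CalendarWindow

    base = default_calendar()
    months = sorted(lck_months)
    windows = []
    start = prev = months[0]
    for m in months[1:]:
        if m != prev + 1:
            windows.append(CalendarWindow(f"W{len(windows) + 1}", start, prev))
            start = m
        prev = m
    windows.append(CalendarWindow(f"W{len(windows) + 1}", start, prev))
    return PeriodCalendar(base.campaign_start, base.campaign_end, tuple(windows))


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign (study-shaped: 12 sites, 16 months)."""
    dataset, truth = simulate(SimulationConfig(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def default_flows(default_campaign):
    dataset, _ = default_campaign
    return compute_mass_flows(align(dataset))


@pytest.fixture()
def tiny_csv_campaign(tmp_path):
    """Write a hand-sized CSV fixture: 2 sites x 2 analytes x 3 months.

    Returns (paths dict, edit) where ``edit(name, mutate)`` rewrites one CSV
    through a mutating function for invalid-input tests.
    """
    import csv

    months = ["2020-01", "2020-02", "2020-03"]
    sites = [("A1", "Sava", 45.8, 15.9, 1), ("A2", "Sava", 45.7, 16.2, 2)]
    analytes = [("alpha", "STM", 0.5), ("beta", "ATD", 0.2)]
    paths = {
        "conc": tmp_path / "concentrations.csv",
        "flows": tmp_path / "flows.csv",
        "analytes": tmp_path / "analytes.csv",
        "sites": tmp_path / "sites.csv",
    }
    with open(paths["conc"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_code", "analyte", "month", "value_ng_L"])
        value = iter(range(1, 100))
        for code, *_ in sites:
            for name, *_ in analytes:
                for m in months:
                    w.writerow([code, name, m, next(value)])
    with open(paths["flows"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_code", "month", "discharge_m3_s"])
        for code, *_ in sites:
            for m in months:
                w.writerow([code, m, 100.0])
    with open(paths["analytes"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "category", "loq_ng_L"])
        w.writerows(analytes)
    with open(paths["sites"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "river", "lat", "lon", "downstream_rank"])
        w.writerows(sites)

    def edit(name, mutate):
        lines = paths[name].read_text().splitlines()
        paths[name].write_text("\n".join(mutate(lines)) + "\n")

    return paths, edit
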