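"""Contaminant mass flow (flux) and its site/category aggregates.

The central derived quantity is the mass of a contaminant passing a river
station per unit time: concentration × discharge.  With concentrations in
ng/L and discharge in m³/s the numeric product is already in µg/s
(1 ng/L × 1 m³/s = 1000 ng/s = 1 µg/s), which is the unit used throughout;
reports may relabel to mg/s (÷1000) where a legacy unit is wanted.

Aggregates are plain sums: over the sites of a river per time point (total
river flux) and over the member analytes of a therapeutic category across
sites (category flux).  Site-months that were never sampled contribute 0 to
summed aggregates and are accounted for by a completeness fraction, so that
total-series plots remain comparable across months; they are *excluded*
(not zero-filled) from period averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AnalyteRegistry, ValidationError

__all__ = [
    "mass_flow",
    "MassFlowTransformer",
    "compute_mass_flows",
    "aggregate_over_sites",
    "aggregate_by_category",
    "UNIT_FACTORS",
]

#: Multiplicative factors from the native µg/s to report units.
UNIT_FACTORS = {"ug_s": 1.0, "mg_s": 1e-3}


def mass_flow(concentration, discharge):
    """Mass flow in µg/s from concentration (ng/L) and discharge (m³/s).

    Accepts scalars or aligned arrays.  The unit identity
    ng/L · m³/s = µg/s makes the plain product the answer.
    """
    c = np.asarray(concentration, dtype=float)
    q = np.asarray(discharge, dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration")
    if (q <= 0).any():
        raise ValueError("discharge must be positive")
    out = c * q
    return float(out) if out.ndim == 0 else out


class MassFlowTransformer(BaseEstimator, TransformerMixin):
    """Append the mass-flow column to an aligned concentration–discharge table.

    Stateless scikit-learn transformer: input is the table produced by
    :func:`riverflux.preprocess.align`; output adds ``mass_flow_ug_s``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["mass_flow_ug_s"] = mass_flow(
            out["conc_ng_L"].to_numpy(), out["discharge_m3_s"].to_numpy()
        )
        return out


def compute_mass_flows(aligned: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :class:`MassFlowTransformer`."""
    return MassFlowTransformer().fit_transform(aligned)


def _monthly_sum(df: pd.DataFrame, key_name: str, key_value: str,
                 expected_per_month: int) -> pd.DataFrame:
    """Sum mass flow per month with a completeness fraction.

    ``expected_per_month`` is the number of member series that would report
    in a fully sampled month; absent members contribute 0 and lower the
    completeness.
    """
    grouped = df.groupby("month", observed=True).agg(
        total_ug_s=("mass_flow_ug_s", "sum"),
        n_series=("mass_flow_ug_s", "size"),
    )
    grouped = grouped.sort_index().reset_index()
    grouped.insert(0, "key", key_value)
    grouped["completeness"] = grouped.pop("n_series") / expected_per_month
    grouped.rename(columns={"key": key_name}, inplace=True)
    return grouped


def aggregate_over_sites(flows: pd.DataFrame, site_codes, key: str = "aggregate") -> pd.DataFrame:
    """Total mass flow per month summed over the selected sites.

    ``flows`` is the per-(site, analyte, month) mass-flow table.  Returns
    columns ``key, month, total_ug_s, completeness`` where completeness is
    the fraction of expected (site, analyte) series present that month.
    """
    site_codes = list(site_codes)
    if not site_codes:
        raise ValueError("empty site subset")
    sub = flows[flows["site_code"].isin(site_codes)]
    expected = max(
        sub.groupby("site_code", observed=True)["analyte"].nunique().reindex(site_codes)
        .fillna(0).sum(),
        1,
    )
    return _monthly_sum(sub, "key", key, int(expected))


def aggregate_by_category(flows: pd.DataFrame, registry: AnalyteRegistry) -> pd.DataFrame:
    """Total mass flow per therapeutic category per month, across all sites.

    Categories with no measured member are absent.  The grand total over the
    returned categories equals the all-analyte total at every month
    (conservation), since the categories partition the analytes.
    """
    unmapped = sorted(set(flows["analyte"]) - set(registry.keys()))
    if unmapped:
        raise ValidationError(f"analytes without a category mapping: {unmapped}")
    cat_of = {a.name: a.category for a in registry}
    tagged = flows.assign(category=flows["analyte"].map(cat_of))
    pieces = []
    for cat, sub in tagged.groupby("category", observed=True, sort=False):
        expected = sub.groupby("site_code", observed=True)["analyte"].nunique().sum()
        pieces.append(_monthly_sum(sub, "category", cat, int(max(expected, 1))))
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["category", "month", "total_ug_s", "completeness"]
    )
    return out.sort_values(["category", "month"], kind="stable").reset_index(drop=True)
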