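"""Left-censored concentration substitution and concentration–discharge alignment.

Observations below an analyte's limit of quantification (LOQ) are
left-censored: the true concentration is known only to lie in (0, LOQ).
The pipeline substitutes a fixed fraction of the LOQ — by default 1/10 —
which is the conventional simple-substitution rule for monitoring data of
this kind.  Distributional censored-data estimators (Kaplan–Meier, censored
MLE) are a documented extension point, not implemented here.

The substitution is a visible, flag-carrying step: every imputed row keeps
``imputed=True`` downstream so reports can state per-analyte imputed
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CENSORED, AnalyteRecord, AnalyteRegistry, ConcentrationObservation, Dataset

__all__ = ["ImputationPolicy", "CensoredImputer", "impute_censored", "align"]


@dataclass(frozen=True)
class ImputationPolicy:
    """Substitution rule for below-LOQ values: ``fraction × LOQ``."""

    censored_fraction_of_loq: float = 0.1

    def __post_init__(self):
        f = self.censored_fraction_of_loq
        if not 0 < f <= 1:
            raise ValueError(f"censored_fraction_of_loq must be in (0, 1], got {f}")


def impute_censored(obs: ConcentrationObservation, analyte: AnalyteRecord,
                    policy: ImputationPolicy = ImputationPolicy()) -> float:
    """Concentration in ng/L with the censoring substitution applied.

    Quantified values pass through unchanged; a censored observation becomes
    ``policy.censored_fraction_of_loq × analyte.loq``.
    """
    if not obs.is_censored:
        return float(obs.value)
    if analyte.loq is None or not np.isfinite(analyte.loq):
        raise ValueError(f"censored observation for {obs.analyte!r} but analyte LOQ is missing")
    return policy.censored_fraction_of_loq * analyte.loq


class CensoredImputer(BaseEstimator, TransformerMixin):
    """Substitute below-LOQ concentrations by a fixed fraction of the LOQ.

    A scikit-learn style transformer over the long-format concentration
    table (columns ``analyte``, ``value_ng_L``, ``censored``).  ``fit``
    captures the per-analyte LOQ map from the registry; ``transform``
    returns a copy with censored cells replaced by ``fraction × LOQ`` and an
    ``imputed`` flag column.

    Parameters
    ----------
    censored_fraction_of_loq:
        Substituted fraction of the analyte LOQ, in (0, 1]; default 0.1.
    """

    def __init__(self, censored_fraction_of_loq: float = 0.1):
        self.censored_fraction_of_loq = censored_fraction_of_loq

    def fit(self, X: pd.DataFrame, y=None, *, analytes: AnalyteRegistry | None = None):
        ImputationPolicy(self.censored_fraction_of_loq)  # validate
        if analytes is None:
            raise ValueError("CensoredImputer.fit requires the analyte registry (analytes=...)")
        self.loq_map_ = {a.name: a.loq for a in analytes}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "loq_map_"):
            raise RuntimeError("CensoredImputer is not fitted")
        out = X.copy()
        censored = out["censored"].to_numpy(dtype=bool)
        if censored.any():
            loqs = out.loc[censored, "analyte"].map(self.loq_map_)
            if loqs.isna().any():
                missing = sorted(out.loc[censored, "analyte"][loqs.isna()].unique())
                raise ValueError(f"censored observations for analytes without LOQ: {missing}")
            out.loc[censored, "value_ng_L"] = self.censored_fraction_of_loq * loqs.astype(float)
        out["imputed"] = censored
        return out


def align(dataset: Dataset, policy: ImputationPolicy = ImputationPolicy()) -> pd.DataFrame:
    """Join imputed concentrations with discharges into the analysis table.

    Returns one row per observed (site, analyte, month) restricted to each
    site's river panel, with columns ``site_code, river, analyte, month,
    conc_ng_L, discharge_m3_s, imputed``.  Months without a sampling event
    are simply absent — they are never interpolated, so downstream period
    averages run over available samples only.
    """
    imputer = CensoredImputer(policy.censored_fraction_of_loq).fit(
        dataset.concentrations, analytes=dataset.analytes
    )
    conc = imputer.transform(dataset.concentrations)

    river_of = {s.code: s.river for s in dataset.sites}
    conc["river"] = conc["site_code"].map(river_of)
    panel_ok = pd.Series(
        [a in dataset.panel(r) for a, r in zip(conc["analyte"], conc["river"])],
        index=conc.index,
    )
    conc = conc[panel_ok]

    merged = conc.merge(dataset.flows, on=["site_code", "month"], how="left", validate="m:1")
    # Dataset validation guarantees a discharge for every concentration row.
    assert not merged["discharge_m3_s"].isna().any()
    out = merged.rename(columns={"value_ng_L": "conc_ng_L"})[
        ["site_code", "river", "analyte", "month", "conc_ng_L", "discharge_m3_s", "imputed"]
    ]
    return out.sort_values(["site_code", "analyte", "month"], kind="stable").reset_index(drop=True)
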