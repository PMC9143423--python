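"""Domain model and tabular I/O for river contaminant monitoring campaigns.

The data model is deliberately small: an analyte registry (compound name,
therapeutic category, limit of quantification), a site registry (station
code, river, coordinates, downstream order), long-format monthly
concentration and discharge tables, and a period calendar.  Concentrations
below the analytical limit of quantification (LOQ) are *left-censored*; they
are carried through the model as an explicit :data:`CENSORED` marker — never
as zero or blank — so that substitution happens in exactly one documented
place (:mod:`riverflux.preprocess`).

CSV schemas (comma-separated, UTF-8, header row; months as ISO ``YYYY-MM``):

* ``concentrations(site_code,analyte,month,value_ng_L)`` — censored cells
  hold the literal token ``<LOQ``
* ``flows(site_code,month,discharge_m3_s)``
* ``analytes(name,category,loq_ng_L)``
* ``sites(code,river,lat,lon,downstream_rank)``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .periods import PeriodCalendar, default_calendar, read_calendar, to_month, write_calendar

#: Closed set of therapeutic categories partitioning the analytes.
CATEGORIES = ("ATB", "ATD", "ATE", "IDRG", "CAR", "DIUR", "STM", "AID")

#: Literal CSV token marking a below-LOQ (left-censored) concentration cell.
CENSORED_TOKEN = "<LOQ"


class _Censored:
    """Singleton marker for a left-censored (below-LOQ) observation."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "CENSORED"


#: Sentinel carried in place of a numeric value for below-LOQ observations.
CENSORED = _Censored()


class ValidationError(ValueError):
    """A dataset or registry violates an invariant; the message names rows."""


@dataclass(frozen=True)
class AnalyteRecord:
    """One measured compound: name, therapeutic category, LOQ in ng/L."""

    name: str
    category: str
    loq: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"analyte {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )
        if not self.loq > 0:
            raise ValidationError(f"analyte {self.name!r}: loq must be > 0, got {self.loq}")


@dataclass(frozen=True)
class SiteRecord:
    """One monitoring station: code, river, coordinates, downstream order."""

    code: str
    river: str
    latitude: float
    longitude: float
    downstream_rank: int

    def __post_init__(self):
        if not -90 <= self.latitude <= 90:
            raise ValidationError(f"site {self.code!r}: latitude {self.latitude} outside [-90, 90]")
        if not -180 <= self.longitude <= 180:
            raise ValidationError(
                f"site {self.code!r}: longitude {self.longitude} outside [-180, 180]"
            )


class _Registry:
    """Ordered, name-keyed record collection with uniqueness enforcement."""

    key_attr: str = "name"

    def __init__(self, records=()):
        self._records: dict[str, object] = {}
        for rec in records:
            self.add(rec)

    def add(self, record):
        key = getattr(record, self.key_attr)
        if key in self._records:
            raise ValidationError(f"duplicate {self.key_attr} {key!r} in registry")
        self._records[key] = record

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, key):
        return key in self._records

    def __getitem__(self, key):
        try:
            return self._records[key]
        except KeyError:
            raise KeyError(f"unknown {self.key_attr} {key!r}") from None

    def keys(self):
        return list(self._records)

    def __eq__(self, other):
        return type(other) is type(self) and self._records == other._records


class AnalyteRegistry(_Registry):
    key_attr = "name"

    def categories(self) -> dict[str, list[str]]:
        """Mapping category → member analyte names (insertion order)."""
        out: dict[str, list[str]] = {}
        for rec in self:
            out.setdefault(rec.category, []).append(rec.name)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.name, a.category, a.loq) for a in self],
            columns=["name", "category", "loq_ng_L"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnalyteRegistry":
        _require_columns(df, ["name", "category", "loq_ng_L"], "analytes")
        return cls(
            AnalyteRecord(str(r.name), str(r.category), float(r.loq_ng_L))
            for r in df.itertuples(index=False)
        )


class SiteRegistry(_Registry):
    key_attr = "code"

    def __init__(self, records=()):
        super().__init__(records)
        self._check_ranks()
        self._warn_coordinate_outliers()

    def _check_ranks(self):
        by_river: dict[str, set[int]] = {}
        for s in self:
            ranks = by_river.setdefault(s.river, set())
            if s.downstream_rank in ranks:
                raise ValidationError(
                    f"site {s.code!r}: downstream_rank {s.downstream_rank} "
                    f"duplicated within river {s.river!r}"
                )
            ranks.add(s.downstream_rank)

    def _warn_coordinate_outliers(self):
        # Stations on one river lie within a few degrees of each other; a
        # latitude far from the river's median is almost certainly a
        # transcription error in the source table.  Warn, never correct.
        for river in {s.river for s in self}:
            group = [s for s in self if s.river == river]
            if len(group) < 3:
                continue
            med = float(np.median([s.latitude for s in group]))
            for s in group:
                if abs(s.latitude - med) > 5:
                    warnings.warn(
                        f"site {s.code!r}: latitude {s.latitude} is {abs(s.latitude - med):.1f}deg "
                        f"from the {river} median ({med:.2f}); likely a transcription error "
                        "in the source — kept as given, supply an override to correct it",
                        UserWarning,
                        stacklevel=3,
                    )

    def rivers(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self:
            seen.setdefault(s.river)
        return list(seen)

    def by_river(self, river: str) -> list[SiteRecord]:
        out = [s for s in self if s.river == river]
        return sorted(out, key=lambda s: s.downstream_rank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.code, s.river, s.latitude, s.longitude, s.downstream_rank) for s in self],
            columns=["code", "river", "lat", "lon", "downstream_rank"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteRegistry":
        _require_columns(df, ["code", "river", "lat", "lon", "downstream_rank"], "sites")
        return cls(
            SiteRecord(str(r.code), str(r.river), float(r.lat), float(r.lon), int(r.downstream_rank))
            for r in df.itertuples(index=False)
        )


@dataclass(frozen=True)
class ConcentrationObservation:
    """One (site, analyte, month) concentration in ng/L, possibly censored."""

    site_code: str
    analyte: str
    month: pd.Period
    value: object  # float or CENSORED

    def __post_init__(self):
        object.__setattr__(self, "month", to_month(self.month))
        if not self.is_censored and float(self.value) < 0:
            raise ValidationError(
                f"concentration for ({self.site_code}, {self.analyte}, {self.month}) "
                f"is negative: {self.value}"
            )

    @property
    def is_censored(self) -> bool:
        return self.value is CENSORED


@dataclass(frozen=True)
class FlowObservation:
    """River discharge at one site in one month, m³/s."""

    site_code: str
    month: pd.Period
    discharge: float

    def __post_init__(self):
        object.__setattr__(self, "month", to_month(self.month))
        if not self.discharge > 0:
            raise ValidationError(
                f"discharge for ({self.site_code}, {self.month}) must be > 0, got {self.discharge}"
            )


@dataclass
class Dataset:
    """A validated monitoring campaign ready for analysis.

    ``concentrations`` columns: site_code, analyte, month (Period[M]),
    value_ng_L (float, NaN when censored), censored (bool).
    ``flows`` columns: site_code, month, discharge_m3_s.
    ``panels`` maps river → tuple of analyte names measured on that river;
    when None the panel is inferred from the observations present.
    """

    analytes: AnalyteRegistry
    sites: SiteRegistry
    concentrations: pd.DataFrame
    flows: pd.DataFrame
    calendar: PeriodCalendar
    panels: dict | None = None

    def __post_init__(self):
        self.validate()

    def panel(self, river: str) -> tuple[str, ...]:
        if self.panels and river in self.panels:
            return tuple(self.panels[river])
        codes = [s.code for s in self.sites.by_river(river)]
        obs = self.concentrations[self.concentrations["site_code"].isin(codes)]
        return tuple(dict.fromkeys(obs["analyte"]))

    def validate(self) -> None:
        conc, flows = self.concentrations, self.flows
        _require_columns(conc, ["site_code", "analyte", "month", "value_ng_L", "censored"],
                         "concentrations")
        _require_columns(flows, ["site_code", "month", "discharge_m3_s"], "flows")

        bad_site = ~conc["site_code"].isin(self.sites.keys())
        if bad_site.any():
            rows = conc.index[bad_site][:5].tolist()
            raise ValidationError(
                f"concentration rows {rows} reference unknown site codes "
                f"{sorted(conc.loc[bad_site, 'site_code'].unique())}"
            )
        bad_analyte = ~conc["analyte"].isin(self.analytes.keys())
        if bad_analyte.any():
            rows = conc.index[bad_analyte][:5].tolist()
            raise ValidationError(
                f"concentration rows {rows} reference unknown analytes "
                f"{sorted(conc.loc[bad_analyte, 'analyte'].unique())}"
            )
        bad_flow_site = ~flows["site_code"].isin(self.sites.keys())
        if bad_flow_site.any():
            rows = flows.index[bad_flow_site][:5].tolist()
            raise ValidationError(f"flow rows {rows} reference unknown site codes")

        dup = conc.duplicated(subset=["site_code", "analyte", "month"])
        if dup.any():
            raise ValidationError(
                f"duplicate (site, analyte, month) concentration rows at index "
                f"{conc.index[dup][:5].tolist()}"
            )
        dupf = flows.duplicated(subset=["site_code", "month"])
        if dupf.any():
            raise ValidationError(
                f"duplicate (site, month) flow rows at index {flows.index[dupf][:5].tolist()}"
            )

        neg = conc["value_ng_L"].lt(0) & ~conc["censored"]
        if neg.any():
            raise ValidationError(
                f"negative concentrations at rows {conc.index[neg][:5].tolist()}"
            )
        nonpos = ~flows["discharge_m3_s"].gt(0)
        if nonpos.any():
            raise ValidationError(
                f"non-positive discharge at rows {flows.index[nonpos][:5].tolist()}"
            )

        for col_df, name in ((conc, "concentration"), (flows, "flow")):
            outside = ~col_df["month"].map(lambda m: m in self.calendar)
            if outside.any():
                raise ValidationError(
                    f"{name} rows {col_df.index[outside][:5].tolist()} fall outside the "
                    f"campaign span {self.calendar.campaign_start}..{self.calendar.campaign_end}"
                )

        have_flow = set(zip(flows["site_code"], flows["month"]))
        conc_keys = list(zip(conc["site_code"], conc["month"]))
        missing = [i for i, k in zip(conc.index, conc_keys) if k not in have_flow]
        if missing:
            raise ValidationError(
                f"concentration rows {missing[:5]} have no matching (site, month) discharge"
            )

    def equals(self, other: "Dataset") -> bool:
        return (
            self.analytes == other.analytes
            and self.sites == other.sites
            and self.calendar == other.calendar
            and self.panels == other.panels
            and _frames_equal(self.concentrations, other.concentrations,
                              ["site_code", "analyte", "month"])
            and _frames_equal(self.flows, other.flows, ["site_code", "month"])
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame, keys) -> bool:
    a = a.sort_values(keys).reset_index(drop=True)
    b = b.sort_values(keys).reset_index(drop=True)
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    return a.equals(b)


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{table} table missing columns {missing}; has {list(df.columns)}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_concentrations(path, censored_token: str = CENSORED_TOKEN) -> pd.DataFrame:
    """Read the long-format concentration CSV; censored cells become NaN+flag."""
    df = pd.read_csv(
        path, dtype={"site_code": str, "analyte": str, "month": str, "value_ng_L": str}
    )
    _require_columns(df, ["site_code", "analyte", "month", "value_ng_L"], "concentrations")
    raw = df["value_ng_L"].astype(str).str.strip()
    censored = raw == censored_token

    def parse(s):  # Python float() round-trips exactly, unlike the fast C parser
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    values = raw.where(~censored).map(parse)
    bad = values.isna() & ~censored
    if bad.any():
        raise ValidationError(
            f"concentrations rows {df.index[bad][:5].tolist()} have values that are neither "
            f"numeric nor the censored token {censored_token!r}"
        )
    out = df[["site_code", "analyte"]].copy()
    out["month"] = df["month"].map(to_month)
    out["value_ng_L"] = values.astype(float)
    out["censored"] = censored.to_numpy()
    return out


def read_flows(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_code": str, "month": str}, float_precision="round_trip")
    _require_columns(df, ["site_code", "month", "discharge_m3_s"], "flows")
    out = df[["site_code"]].copy()
    out["month"] = df["month"].map(to_month)
    out["discharge_m3_s"] = pd.to_numeric(df["discharge_m3_s"]).astype(float)
    return out


def read_dataset(conc_path, flow_path, analyte_path, site_path, calendar_path=None,
                 censored_token: str = CENSORED_TOKEN, panels: dict | None = None) -> Dataset:
    """Read and validate a full campaign from its CSV/YAML parts.

    ``calendar_path`` may be omitted, in which case the packaged default
    study calendar is used.
    """
    analytes = AnalyteRegistry.from_frame(pd.read_csv(analyte_path))
    sites = SiteRegistry.from_frame(pd.read_csv(site_path))
    calendar = read_calendar(calendar_path) if calendar_path else default_calendar()
    conc = read_concentrations(conc_path, censored_token=censored_token)
    flows = read_flows(flow_path)
    return Dataset(analytes, sites, conc, flows, calendar, panels=panels)


def write_dataset(dataset: Dataset, directory, censored_token: str = CENSORED_TOKEN) -> dict:
    """Write a Dataset back to its CSV/YAML parts; returns the path map."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "concentrations": directory / "concentrations.csv",
        "flows": directory / "flows.csv",
        "analytes": directory / "analytes.csv",
        "sites": directory / "sites.csv",
        "calendar": directory / "calendar.yaml",
    }
    conc = dataset.concentrations.copy()
    value = conc["value_ng_L"].map(lambda v: format(v, ".17g") if pd.notna(v) else "")
    value = value.where(~conc["censored"], censored_token)
    out = pd.DataFrame(
        {
            "site_code": conc["site_code"],
            "analyte": conc["analyte"],
            "month": conc["month"].astype(str),
            "value_ng_L": value,
        }
    )
    out.to_csv(paths["concentrations"], index=False)

    flows = dataset.flows.copy()
    flows["month"] = flows["month"].astype(str)
    flows["discharge_m3_s"] = flows["discharge_m3_s"].map(lambda v: format(v, ".17g"))
    flows.to_csv(paths["flows"], index=False)

    dataset.analytes.to_frame().to_csv(paths["analytes"], index=False)
    dataset.sites.to_frame().to_csv(paths["sites"], index=False)
    write_calendar(dataset.calendar, paths["calendar"])
    return paths


# ---------------------------------------------------------------------------
# Built-in study configuration

# Table-ordered catalogue: (name, category).  Eighteen compounds in eight
# therapeutic categories.
_BUILTIN_ANALYTES = (
    ("Azithromycin", "ATB"),
    ("O-Desmethylvenlafaxine", "ATD"),
    ("Venlafaxine", "ATD"),
    ("10-Hydroxycarbazepine", "ATE"),
    ("Amisulpride", "ATE"),
    ("Carbamazepine", "ATE"),
    ("Lamotrigine", "ATE"),
    ("Benzoylecgonine", "IDRG"),
    ("Cocaine", "IDRG"),
    ("MDMA-3,4", "IDRG"),
    ("Bisoprolol", "CAR"),
    ("Metoprolol", "CAR"),
    ("Torasemide", "DIUR"),
    ("Caffeine", "STM"),
    ("Cotinine", "STM"),
    ("4-Acetylaminoantipyrine", "AID"),
    ("4-Formylaminoantipyrine", "AID"),
    ("Dexamethasone", "AID"),
)

# Stations as printed in the source table: (code, river, lat, lon, rank).
# The Jankomir latitude is reproduced as printed even though it is
# geographically impossible (it duplicates Jesenice's longitude); the
# registry warns about it and accepts an override instead of silently
# correcting published values.
_BUILTIN_SITES = (
    ("S|Jes", "Sava", 45.860595, 15.692357, 1),
    ("S|Jnk", "Sava", 15.692357, 15.852741, 2),
    ("S|Rug", "Sava", 45.743684, 16.228377, 3),
    ("S|Jas", "Sava", 45.268587, 16.915962, 4),
    ("S|SBr", "Sava", 45.141268, 18.070956, 5),
    ("S|Zup", "Sava", 45.039882, 18.703391, 6),
    ("S|Rac", "Sava", 44.851851, 18.959196, 7),
    ("D|Leg", "Drava", 46.297943, 16.880991, 1),
    ("D|Bot", "Drava", 46.241223, 16.937914, 2),
    ("D|TeP", "Drava", 45.944342, 17.462874, 3),
    ("D|DoM", "Drava", 45.782751, 18.20062, 4),
    ("D|Bel", "Drava", 45.69049, 18.416862, 5),
)

#: The seven compounds measured on both rivers.
DRAVA_PANEL = (
    "Caffeine",
    "Cotinine",
    "Carbamazepine",
    "Lamotrigine",
    "10-Hydroxycarbazepine",
    "Venlafaxine",
    "O-Desmethylvenlafaxine",
)

#: Default compound dropped from the Sava panel to match the reported
#: 17-compound panel; the exclusion is configurable because the source never
#: names it (its own counts disagree: 18 catalogued, 17 reported measured).
DEFAULT_SAVA_EXCLUDED = "Amisulpride"


def builtin_registries(sava_excluded: str | None = DEFAULT_SAVA_EXCLUDED,
                       site_overrides: dict | None = None):
    """The packaged study configuration.

    Returns ``(analytes, sites, calendar, panels)``: the 18-compound
    catalogue with its 8 therapeutic categories, the 12 stations (7 Sava, 5
    Drava) with coordinates as printed, the default lockdown calendar, and
    the per-river analyte panels (17 Sava / 7 Drava by default).

    Per-compound LOQs are not published — only the method's 0.2–0.9 ng/L
    range — so the registry assigns deterministic, evenly spaced values
    across that range in catalogue order.

    Parameters
    ----------
    sava_excluded:
        Compound excluded from the Sava panel (None keeps all 18).
    site_overrides:
        Mapping ``code -> (lat, lon)`` replacing printed coordinates, e.g.
        to repair the impossible Jankomir latitude.
    """
    loqs = np.round(np.linspace(0.2, 0.9, len(_BUILTIN_ANALYTES)), 3)
    analytes = AnalyteRegistry(
        AnalyteRecord(name, cat, float(q))
        for (name, cat), q in zip(_BUILTIN_ANALYTES, loqs)
    )
    overrides = site_overrides or {}
    records = []
    for code, river, lat, lon, rank in _BUILTIN_SITES:
        if code in overrides:
            lat, lon = overrides[code]
        records.append(SiteRecord(code, river, lat, lon, rank))
    sites = SiteRegistry(records)

    sava_panel = tuple(n for n, _ in _BUILTIN_ANALYTES if n != sava_excluded)
    panels = {"Sava": sava_panel, "Drava": DRAVA_PANEL}
    return analytes, sites, default_calendar(), panels
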