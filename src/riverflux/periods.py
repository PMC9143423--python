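"""Campaign calendar: lockdown windows and month labelling.

The monitoring campaign is a run of consecutive calendar months, some of
which fall inside intervention (lockdown) windows.  For the ratio statistic
all lockdown windows are pooled into a single ``LCK`` stratum; every other
campaign month is out-of-lockdown (``OOL``).  Sampling is monthly and no
day-of-month is available, so windows are resolved to whole months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

LCK = "LCK"
OOL = "OOL"

__all__ = [
    "LCK",
    "OOL",
    "CalendarWindow",
    "PeriodCalendar",
    "label_period",
    "read_calendar",
    "write_calendar",
    "default_calendar",
]


def to_month(value) -> pd.Period:
    """Coerce an ISO 'YYYY-MM' string (or Period/Timestamp) to a monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr not in ("M", "ME"):
            return value.asfreq("M")
        return value
    return pd.Period(value, freq="M")


@dataclass(frozen=True)
class CalendarWindow:
    """One labelled lockdown window, inclusive on both ends."""

    label: str
    start: pd.Period
    end: pd.Period

    def __post_init__(self):
        object.__setattr__(self, "start", to_month(self.start))
        object.__setattr__(self, "end", to_month(self.end))
        if self.end < self.start:
            raise ValueError(f"window {self.label!r}: end {self.end} before start {self.start}")

    def __contains__(self, month) -> bool:
        m = to_month(month)
        return self.start <= m <= self.end

    def months(self) -> list[pd.Period]:
        return list(pd.period_range(self.start, self.end, freq="M"))


@dataclass(frozen=True)
class PeriodCalendar:
    """Campaign span plus non-overlapping lockdown windows.

    Months inside any window are labelled ``LCK``; all other campaign months
    are ``OOL``.  Months outside the campaign are rejected.
    """

    campaign_start: pd.Period
    campaign_end: pd.Period
    windows: tuple[CalendarWindow, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "campaign_start", to_month(self.campaign_start))
        object.__setattr__(self, "campaign_end", to_month(self.campaign_end))
        object.__setattr__(self, "windows", tuple(self.windows))
        if self.campaign_end < self.campaign_start:
            raise ValueError("campaign end precedes campaign start")
        seen: set[pd.Period] = set()
        for w in self.windows:
            if w.start < self.campaign_start or w.end > self.campaign_end:
                raise ValueError(f"window {w.label!r} extends outside the campaign span")
            overlap = seen.intersection(w.months())
            if overlap:
                raise ValueError(f"window {w.label!r} overlaps another window at {sorted(overlap)}")
            seen.update(w.months())

    def campaign_months(self) -> list[pd.Period]:
        return list(pd.period_range(self.campaign_start, self.campaign_end, freq="M"))

    def __contains__(self, month) -> bool:
        m = to_month(month)
        return self.campaign_start <= m <= self.campaign_end

    def label(self, month) -> str:
        """Pooled period label, ``LCK`` or ``OOL``."""
        m = to_month(month)
        if m not in self:
            raise ValueError(f"month {m} outside campaign {self.campaign_start}..{self.campaign_end}")
        return LCK if any(m in w for w in self.windows) else OOL

    def window_label(self, month) -> str | None:
        """Which named window a month belongs to, or None for OOL months."""
        m = to_month(month)
        if m not in self:
            raise ValueError(f"month {m} outside campaign {self.campaign_start}..{self.campaign_end}")
        for w in self.windows:
            if m in w:
                return w.label
        return None

    def labels(self, months) -> pd.Series:
        """Vectorised :meth:`label` over an iterable of months."""
        return pd.Series([self.label(m) for m in months], index=getattr(months, "index", None))


def label_period(month, calendar: PeriodCalendar) -> str:
    """Label a campaign month ``LCK`` (inside any lockdown window) or ``OOL``."""
    return calendar.label(month)


def default_calendar() -> PeriodCalendar:
    """The 16-month study calendar: Jan 2020 – Apr 2021 with two lockdowns.

    The first lockdown ran mid-March to mid-May 2020 and is resolved to the
    months 2020-03..2020-05.  The second ran from late October 2020 to March
    2021; because the window opens only late in October and the within-month
    sampling date is unknown, 2020-10 is kept out-of-lockdown and the window
    is 2020-11..2021-03.
    """
    return PeriodCalendar(
        campaign_start=pd.Period("2020-01", "M"),
        campaign_end=pd.Period("2021-04", "M"),
        windows=(
            CalendarWindow("LCK1", pd.Period("2020-03", "M"), pd.Period("2020-05", "M")),
            CalendarWindow("LCK2", pd.Period("2020-11", "M"), pd.Period("2021-03", "M")),
        ),
    )


def read_calendar(path) -> PeriodCalendar:
    """Read a calendar from YAML.

    Accepts either a mapping ``{campaign: {start_month, end_month},
    windows: [{label, start_month, end_month}, ...]}`` or a bare list of
    window mappings, in which case the campaign span must be supplied by the
    caller later (here it defaults to the hull of the windows).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        windows = [
            CalendarWindow(w["label"], to_month(w["start_month"]), to_month(w["end_month"]))
            for w in raw.get("windows", [])
        ]
        camp = raw.get("campaign", {})
        start = to_month(camp["start_month"])
        end = to_month(camp["end_month"])
    elif isinstance(raw, list):
        windows = [
            CalendarWindow(w["label"], to_month(w["start_month"]), to_month(w["end_month"]))
            for w in raw
        ]
        if not windows:
            raise ValueError("calendar YAML list contains no windows")
        start = min(w.start for w in windows)
        end = max(w.end for w in windows)
    else:
        raise ValueError(f"unrecognised calendar YAML structure in {path}")
    return PeriodCalendar(start, end, tuple(windows))


def write_calendar(calendar: PeriodCalendar, path) -> None:
    doc = {
        "campaign": {
            "start_month": str(calendar.campaign_start),
            "end_month": str(calendar.campaign_end),
        },
        "windows": [
            {"label": w.label, "start_month": str(w.start), "end_month": str(w.end)}
            for w in calendar.windows
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
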