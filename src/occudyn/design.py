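"""Survey design: sites, primary periods (seasons) and secondary occasions.

A camera-trap survey is organised as ``n_sites`` stations sampled over a
sequence of primary periods ("seasons", e.g. wet/dry blocks) between which
the occupancy state of a site may change.  Within a season, continuous-time
detections are discretised into consecutive fixed-length occasions (default
5 days, 13 per season) during which occupancy is assumed closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Season", "SurveyDesign", "default_seasons"]


@dataclass(frozen=True)
class Season:
    """A primary period with a label and calendar interval [start, end)."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end <= self.start:
            raise ValueError(f"season {self.label!r}: end must be after start")

    @property
    def span_days(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(days=1))


@dataclass(frozen=True)
class SurveyDesign:
    """Layout of a multi-season camera-trap survey.

    Parameters
    ----------
    n_sites : int
        Number of camera-trap stations.
    seasons : tuple of Season
        Chronologically ordered, non-overlapping primary periods.
    occasion_days : int
        Length of one secondary occasion in days (default 5).
    n_occasions : int
        Secondary occasions per season (default 13).
    """

    n_sites: int
    seasons: tuple[Season, ...]
    occasion_days: int = 5
    n_occasions: int = 13

    def __post_init__(self):
        object.__setattr__(self, "seasons", tuple(self.seasons))
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.occasion_days <= 0 or self.n_occasions <= 0:
            raise ValueError("occasion_days and n_occasions must be positive")
        labels = [s.label for s in self.seasons]
        if len(set(labels)) != len(labels):
            raise ValueError("season labels must be unique")
        for a, b in zip(self.seasons, self.seasons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"seasons {a.label!r} and {b.label!r} overlap or are out of order"
                )
        need = self.occasion_days * self.n_occasions
        for s in self.seasons:
            if need > s.span_days:
                raise ValueError(
                    f"season {s.label!r} spans {s.span_days} days; "
                    f"{self.n_occasions} x {self.occasion_days}-day occasions need {need}"
                )

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)

    @property
    def season_labels(self) -> list[str]:
        return [s.label for s in self.seasons]

    def season_index(self, label: str) -> int:
        try:
            return self.season_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown season label {label!r}") from None

    def subset(self, labels) -> "SurveyDesign":
        idx = [self.season_index(l) for l in labels]
        if idx != sorted(idx):
            raise ValueError("season subset must preserve chronological order")
        return SurveyDesign(
            n_sites=self.n_sites,
            seasons=tuple(self.seasons[i] for i in idx),
            occasion_days=self.occasion_days,
            n_occasions=self.n_occasions,
        )


def default_seasons() -> tuple[Season, ...]:
    """Two wet (Oct-Dec) and two dry (Jun-Aug) survey blocks over two years.

    Each season spans exactly 65 days so that thirteen 5-day occasions tile
    it with no remainder.
    """
    spans = [
        ("W20", "2020-10-15"),
        ("D21", "2021-06-15"),
        ("W21", "2021-10-15"),
        ("D22", "2022-06-15"),
    ]
    out = []
    for label, start in spans:
        t0 = pd.Timestamp(start)
        out.append(Season(label, t0, t0 + pd.Timedelta(days=65)))
    return tuple(out)
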