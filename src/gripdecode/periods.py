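"""Trial-period definitions shared across the pipeline.

The 12 modelled 1.5-s time-bins of a trial are grouped into four periods:
cue (C, bins 1-2), early delay (ED, bins 3-5), late delay (LD, bins 6-8)
and motor execution (ME, bins 9-11). Bin 12 is left unassigned by default.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PeriodDef", "DEFAULT_PERIODS", "periods_by_name"]


@dataclass(frozen=True)
class PeriodDef:
    name: str
    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError(f"period {self.name!r} has no bins")


DEFAULT_PERIODS: tuple[PeriodDef, ...] = (
    PeriodDef("C", (1, 2)),
    PeriodDef("ED", (3, 4, 5)),
    PeriodDef("LD", (6, 7, 8)),
    PeriodDef("ME", (9, 10, 11)),
)


def periods_by_name(periods=DEFAULT_PERIODS) -> dict[str, PeriodDef]:
    seen: set[int] = set()
    for p in periods:
        if seen.intersection(p.bins):
            raise ValueError("period bin sets must be disjoint")
        seen.update(p.bins)
    return {p.name: p for p in periods}
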