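"""Read classification and run accounting.

Every read falls into exactly one category: Spike (matches a spike
reference), one of four M13 classes keyed by the length of the observed
barcode (6 / 5 / 4 / <4 bases), or Unmatched.  The tally mirrors the
standard run-accounting report: per-class counts, the derived "M13 detected"
and "Munged" sums (munged = the three repairable classes), and per-class
percentages of the M13-detected reads at one decimal place.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .barcode_engine import BarcodeObservation, detect_barcode, repair_barcode
from .panel_io import (
    BarcodeSet,
    ReadRecord,
    RunConfig,
    iupac_matches,
)

__all__ = ["ReadCategory", "DemuxTally", "classify_read", "tally", "is_spike_read"]


class ReadCategory(enum.Enum):
    SPIKE = "Spike"
    UNMATCHED = "Unmatched"
    M13_6BP = "6 bp BAT"
    M13_5BP = "5 bp BAT"
    M13_4BP = "4 bp BAT"
    M13_LT4BP = "<4 bp BAT"


_M13_CLASSES = (
    ReadCategory.M13_6BP,
    ReadCategory.M13_5BP,
    ReadCategory.M13_4BP,
    ReadCategory.M13_LT4BP,
)
_MUNGEABLE = (ReadCategory.M13_6BP, ReadCategory.M13_5BP, ReadCategory.M13_4BP)

_LEN_TO_CLASS = {6: ReadCategory.M13_6BP, 5: ReadCategory.M13_5BP,
                 4: ReadCategory.M13_4BP}


def is_spike_read(read: ReadRecord, spikes: Sequence[str], budget: int) -> bool:
    """Ungapped IUPAC-aware comparison of the read against each spike reference.

    Spike molecules carry degenerate prefixes, so spike references may contain
    IUPAC letters; a reference letter matches any base in its set.  The read
    is spike if some reference matches with <= ``budget`` mismatches over the
    aligned (offset-0) window.
    """
    for ref in spikes:
        w = min(len(read.seq), len(ref))
        mm = 0
        for a, b in zip(read.seq[:w], ref[:w]):
            if a != b and not iupac_matches(a, b):
                mm += 1
                if mm > budget:
                    break
        else:
            return True
    return False


def classify_read(
    read: ReadRecord,
    bset: BarcodeSet,
    spikes: Sequence[str],
    m13: str,
    cfg: RunConfig,
):
    """Assign one read to its category; returns (category, observation|None).

    Precedence is Spike > M13 > Unmatched by default (``cfg.spike_first``
    switches spike testing to after M13 detection).  For M13 reads the
    observation carries the repaired barcode when repair succeeds.
    """
    obs: Optional[BarcodeObservation] = None

    def spike() -> bool:
        return bool(spikes) and is_spike_read(read, spikes, cfg.max_map_mismatches)

    if cfg.spike_first and spike():
        return ReadCategory.SPIKE, None
    obs = detect_barcode(read, m13)
    if obs is None:
        if not cfg.spike_first and spike():
            return ReadCategory.SPIKE, None
        return ReadCategory.UNMATCHED, None
    obs.repaired = repair_barcode(obs, bset)
    cat = _LEN_TO_CLASS.get(len(obs.observed), ReadCategory.M13_LT4BP)
    return cat, obs


@dataclass
class DemuxTally:
    """Per-category read counts and the derived accounting quantities."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in ReadCategory})

    def add(self, category: ReadCategory, n: int = 1) -> None:
        self.counts[category] = self.counts.get(category, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def m13_detected(self) -> int:
        return sum(self.counts.get(c, 0) for c in _M13_CLASSES)

    @property
    def munged(self) -> int:
        """Reads usable for munging: intact plus repairable (6/5/4 bp) classes."""
        return sum(self.counts.get(c, 0) for c in _MUNGEABLE)

    def percent_of_m13(self, category: ReadCategory) -> float:
        """Category share of M13-detected reads, one decimal place."""
        m13 = self.m13_detected
        if m13 == 0:
            return 0.0
        return round(100.0 * self.counts.get(category, 0) / m13, 1)

    @property
    def usable_percent(self) -> float:
        """Munged (repair-usable) share of M13-detected reads, one decimal."""
        m13 = self.m13_detected
        return round(100.0 * self.munged / m13, 1) if m13 else 0.0

    def to_rows(self, called: Optional[int] = None) -> list:
        """Run-accounting rows (Total/Spike/Unmatched/M13/.../Munged[/Called])."""
        rows = [
            {"category": "Total", "reads": self.total},
            {"category": "Spike", "reads": self.counts.get(ReadCategory.SPIKE, 0)},
            {"category": "Unmatched",
             "reads": self.counts.get(ReadCategory.UNMATCHED, 0)},
            {"category": "M13 detected", "reads": self.m13_detected},
        ]
        for cat in _M13_CLASSES:
            rows.append({"category": cat.value, "reads": self.counts.get(cat, 0)})
        rows.append({"category": "Munged", "reads": self.munged})
        if called is not None:
            rows.append({"category": "Called", "reads": called})
        return rows

    @classmethod
    def from_counts(cls, spike=0, unmatched=0, bp6=0, bp5=0, bp4=0, lt4=0):
        t = cls()
        t.add(ReadCategory.SPIKE, spike)
        t.add(ReadCategory.UNMATCHED, unmatched)
        t.add(ReadCategory.M13_6BP, bp6)
        t.add(ReadCategory.M13_5BP, bp5)
        t.add(ReadCategory.M13_4BP, bp4)
        t.add(ReadCategory.M13_LT4BP, lt4)
        return t


def tally(classifications: Iterable) -> DemuxTally:
    """Exact per-category counts from a stream of classify_read results."""
    t = DemuxTally()
    for item in classifications:
        cat = item[0] if isinstance(item, tuple) else item
        t.add(cat)
    return t
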