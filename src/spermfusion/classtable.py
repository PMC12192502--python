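"""Class tables: ordered class names with sample counts and percentage shares.

The reference fixture is the published 18-class sperm-morphology class
distribution (Hi-LabSpermMorpho): 18 head/neck/tail abnormality classes plus
``Normal``, with severe imbalance (largest class ~19% of the data, smallest
~0.2%).  Shares are recomputed from counts with round-half-up to two decimals;
the printed source table's counts sum to 18,446 while the stated image total
is 18,456, so the denominator is configurable and defaults to the stated
total (see docs/methods.md for the discrepancy notes).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "ClassTable",
    "make_class_table",
    "HI_LAB_CLASS_COUNTS",
    "HI_LAB_STATED_TOTAL",
    "hi_lab_class_table",
]

#: Published per-class sample counts of the 18-class sperm-morphology dataset,
#: in its (alphabetical) listing order.
HI_LAB_CLASS_COUNTS: dict[str, int] = {
    "AmorphHead": 3572,
    "AsymmetricNeck": 366,
    "CurlyTail": 1443,
    "DoubleHead": 48,
    "DoubleTail": 200,
    "LongTail": 42,
    "NarrowAcrosome": 2054,
    "Normal": 598,
    "PinHead": 782,
    "PyriformHead": 978,
    "RoundHead": 247,
    "ShortTail": 991,
    "TaperedHead": 1399,
    "ThickNeck": 1977,
    "ThinNeck": 192,
    "TwistedNeck": 1154,
    "TwistedTail": 706,
    "VacuolatedHead": 1697,
}

#: Stated size of the annotated image collection (the printed counts above sum
#: to 18,446; shares in the source table are mostly consistent with 18,456).
HI_LAB_STATED_TOTAL = 18456


def _share_percent(count: int, total: int) -> float:
    """100*count/total, rounded half-up to two decimals (as printed tables do)."""
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassTable:
    """Ordered class labels with counts and two-decimal percentage shares."""

    names: tuple[str, ...]
    counts: tuple[int, ...]
    shares: tuple[float, ...]
    total: int

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def share_of(self, name: str) -> float:
        return self.shares[self.names.index(name)]

    def count_of(self, name: str) -> int:
        return self.counts[self.names.index(name)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"class": self.names, "count": self.counts, "share_percent": self.shares}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, total: int | None = None) -> "ClassTable":
        df = pd.read_csv(path)
        return make_class_table(
            df["class"].astype(str).tolist(),
            df["count"].astype(int).tolist(),
            total=total,
        )


def make_class_table(
    names: list[str], counts: list[int], total: int | None = None
) -> ClassTable:
    """Build a :class:`ClassTable`, deriving shares from counts.

    Parameters
    ----------
    names, counts
        Parallel lists of class labels and nonnegative sample counts.
    total
        Denominator for the percentage shares.  Defaults to ``sum(counts)``;
        passing an explicit total supports tables whose printed counts do not
        sum to the stated dataset size.
    """
    if len(names) != len(counts):
        raise ValueError("names and counts must have the same length")
    if len(names) == 0:
        raise ValueError("class table needs at least one class")
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if total is None:
        total = sum(counts)
    total = int(total)
    if total < max(counts):
        raise ValueError("total is smaller than the largest class count")
    if total <= 0:
        raise ValueError("total must be positive")
    shares = tuple(_share_percent(c, total) for c in counts)
    return ClassTable(tuple(names), tuple(counts), shares, total)


def hi_lab_class_table(total: int | None = HI_LAB_STATED_TOTAL) -> ClassTable:
    """The 18-class imbalanced reference table (pass ``total=None`` to use the
    sum of the printed counts, 18,446, as the denominator instead)."""
    return make_class_table(
        list(HI_LAB_CLASS_COUNTS), list(HI_LAB_CLASS_COUNTS.values()), total=total
    )
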