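"""Collagen-yield arithmetic from extraction masses.

The reference values the calibration regresses on come from wet-chemistry
extraction: a bone aliquot is demineralised, gelatinised and (usually)
ultrafiltered at a 30 kDa cut-off, splitting long collagen chains
(>30 kDa, the fraction used for dating) from short ones. The yield of a
fraction is simply ``100 x extracted mass / starting mass``. A yield of
at least 1 % is the conventional datability threshold.

Stored values are never rounded; rendering rounds half-up at display
time only, since published tables mix integer and two-decimal renderings
inconsistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

__all__ = [
    "ExtractionRecord",
    "fraction_yield_pct",
    "total_yield_pct",
    "report_yield",
    "YieldReport",
    "read_extraction_csv",
    "write_extraction_csv",
]


@dataclass
class ExtractionRecord:
    """Masses from one collagen extraction.

    ``collagen_hi_mg`` is the >30 kDa (long-chain) fraction and
    ``collagen_lo_mg`` the <30 kDa one. Records pretreated without the
    ultrafiltration step carry their single combined mass in
    ``collagen_hi_mg`` with ``collagen_lo_mg == 0`` and the flag False.
    """

    sample_id: str
    sample_taken_mg: float
    collagen_hi_mg: float
    collagen_lo_mg: float = 0.0
    ultrafiltered: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sample_taken_mg) and self.sample_taken_mg > 0):
            raise ValueError("sample_taken_mg must be > 0")
        if self.collagen_hi_mg < 0 or self.collagen_lo_mg < 0:
            raise ValueError("extracted masses must be >= 0")
        if self.collagen_hi_mg + self.collagen_lo_mg > self.sample_taken_mg:
            raise ValueError("extracted mass exceeds the starting sample mass")
        if not self.ultrafiltered and self.collagen_lo_mg != 0:
            raise ValueError(
                "non-ultrafiltered records carry a single combined mass in "
                "collagen_hi_mg with collagen_lo_mg = 0"
            )


def fraction_yield_pct(mass_mg: float, sample_taken_mg: float) -> float:
    """Yield of one fraction: ``100 x mass / sample mass``, unrounded."""
    if not (math.isfinite(sample_taken_mg) and sample_taken_mg > 0):
        raise ValueError("sample_taken_mg must be > 0")
    if not (0 <= mass_mg <= sample_taken_mg):
        raise ValueError(
            f"extracted mass {mass_mg} outside [0, {sample_taken_mg}]"
        )
    return 100.0 * mass_mg / sample_taken_mg


def total_yield_pct(record: ExtractionRecord) -> float:
    """Total yield over both fractions; equals the sum of fraction yields."""
    return fraction_yield_pct(
        record.collagen_hi_mg + record.collagen_lo_mg, record.sample_taken_mg
    )


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class YieldReport:
    """Display-rounded yields (half-up) at a requested precision."""

    sample_id: str
    decimals: int
    hi_pct: float
    lo_pct: float
    total_pct: float


def report_yield(record: ExtractionRecord, decimals: int = 0) -> YieldReport:
    """Half-up rounding of the fraction and total yields for display."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    hi = fraction_yield_pct(record.collagen_hi_mg, record.sample_taken_mg)
    lo = fraction_yield_pct(record.collagen_lo_mg, record.sample_taken_mg)
    total = total_yield_pct(record)
    return YieldReport(
        sample_id=record.sample_id,
        decimals=decimals,
        hi_pct=_round_half_up(hi, decimals),
        lo_pct=_round_half_up(lo, decimals),
        total_pct=_round_half_up(total, decimals),
    )


_CSV_COLUMNS = [
    "sample_id",
    "sample_taken_mg",
    "collagen_hi_mg",
    "collagen_lo_mg",
    "ultrafiltered",
]


def read_extraction_csv(path: str | Path) -> list[ExtractionRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"extraction CSV missing columns: {sorted(missing)}")
    return [
        ExtractionRecord(
            sample_id=str(row.sample_id),
            sample_taken_mg=float(row.sample_taken_mg),
            collagen_hi_mg=float(row.collagen_hi_mg),
            collagen_lo_mg=float(row.collagen_lo_mg),
            ultrafiltered=bool(row.ultrafiltered),
        )
        for row in df.itertuples()
    ]


def write_extraction_csv(records: list[ExtractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "sample_taken_mg": r.sample_taken_mg,
                "collagen_hi_mg": r.collagen_hi_mg,
                "collagen_lo_mg": r.collagen_lo_mg,
                "ultrafiltered": r.ultrafiltered,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
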