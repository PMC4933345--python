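"""Effluent-based donor-cell retention after intracoronary injection.

In an ex-vivo Langendorff-perfused heart every injected cell either lodges
in the coronary microvasculature or exits with the coronary effluent, so
counting cells in the timed effluent fractions measures retention directly:

    effluent cell number (cells/min) = mean concentration (cells/ml) x flow (ml/min)
    total effluent cells             = sum over the first W minutes (default 5)
    retention rate (%)               = (injected - total effluent) / injected x 100

Concentrations are read in triplicate on an automated counter; the mean of
the reads is used by default (median available for robustness).
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal, Sequence

import numpy as np

from .sizes import SizeHistogram

logger = logging.getLogger(__name__)

__all__ = [
    "EffluentRecord",
    "CellPopulation",
    "PerfusionRun",
    "RetentionResult",
    "DoseConversion",
    "effluent_cell_number",
    "total_effluent",
    "retention_rate",
    "first_minute_fraction",
    "convert_clinical_dose",
    "analyze_run",
]

DEFAULT_WINDOW_MINUTES = 5


@dataclasses.dataclass(frozen=True)
class EffluentRecord:
    """One timed coronary-effluent fraction.

    ``minute_index`` is 1-based: minute 1 covers [0, 60) s after injection
    start, so the 20-s injection lies entirely within minute 1.
    ``flow_volume`` is the effluent volume collected during that minute
    (ml/min).  ``background_rbc`` optionally records residual red-blood-cell
    carryover (cells/min) for subtraction.
    """

    minute_index: int
    flow_volume: float
    concentration_reads: tuple[float, ...]
    background_rbc: float | None = None

    def __post_init__(self) -> None:
        if self.minute_index < 1:
            raise ValueError(f"minute_index must be >= 1, got {self.minute_index}")
        if self.flow_volume < 0:
            raise ValueError(f"flow_volume must be >= 0, got {self.flow_volume}")
        reads = tuple(float(r) for r in self.concentration_reads)
        if len(reads) == 0:
            raise ValueError("concentration_reads must contain at least one read")
        if any(r < 0 for r in reads):
            raise ValueError("concentration reads must be non-negative")
        if self.background_rbc is not None and self.background_rbc < 0:
            raise ValueError("background_rbc must be non-negative")
        object.__setattr__(self, "concentration_reads", reads)


@dataclasses.dataclass(frozen=True)
class CellPopulation:
    """A donor-cell sample: count, viability and 1-um size histogram."""

    total_count: float
    viability: float = 1.0
    size_histogram: SizeHistogram | None = None

    def __post_init__(self) -> None:
        if self.total_count < 0:
            raise ValueError("total_count must be non-negative")
        if not 0.0 <= self.viability <= 1.0:
            raise ValueError(f"viability must lie in [0,1], got {self.viability}")
        if self.size_histogram is not None and not self.size_histogram.normalized:
            if not math.isclose(self.size_histogram.total(), self.total_count,
                                rel_tol=1e-9, abs_tol=0.5):
                raise ValueError(
                    "size histogram counts must sum to total_count "
                    f"({self.size_histogram.total()} vs {self.total_count})"
                )


@dataclasses.dataclass(frozen=True)
class PerfusionRun:
    """One Langendorff heart experiment: dose, effluent series, metadata."""

    injected_dose: float
    cell_type: str
    effluent_series: tuple[EffluentRecord, ...]
    pre_injection_population: CellPopulation | None = None
    effluent_size_histogram: SizeHistogram | None = None
    baseline_flow: float | None = None
    injection_volume: float = 3.0
    injection_duration: float = 20.0
    run_id: str = "run"

    def __post_init__(self) -> None:
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        series = tuple(sorted(self.effluent_series, key=lambda r: r.minute_index))
        minutes = [r.minute_index for r in series]
        if len(set(minutes)) != len(minutes):
            dup = sorted({m for m in minutes if minutes.count(m) > 1})
            raise ValueError(f"duplicate minute indices in effluent series: {dup}")
        object.__setattr__(self, "effluent_series", series)

    def record(self, minute: int) -> EffluentRecord:
        for r in self.effluent_series:
            if r.minute_index == minute:
                return r
        raise KeyError(f"no effluent record for minute {minute}")

    @property
    def n_minutes(self) -> int:
        return max(r.minute_index for r in self.effluent_series)


@dataclasses.dataclass(frozen=True)
class RetentionResult:
    """Derived retention quantities for one perfusion run."""

    per_minute_cell_number: dict[int, float]
    total_effluent: float
    retention_pct: float           # clamped to [0, 100]
    retention_pct_raw: float       # unclamped; negative if effluent > dose
    first_minute_pct: float        # NaN when total_effluent == 0
    window_minutes: int
    injected_dose: float
    clamped: bool = False


@dataclasses.dataclass(frozen=True)
class DoseConversion:
    """Allometric clinical-to-animal dose conversion (raw and reported)."""

    per_artery: float          # rounded to 2 significant figures
    total: float               # rounded to 1 significant figure
    per_artery_raw: float
    total_raw: float


def effluent_cell_number(
    record: EffluentRecord,
    aggregator: Literal["mean", "median"] = "mean",
    subtract_background: bool = False,
) -> float:
    """Cells leaving the heart during one minute (cells/min).

    Mean (default) or median of the replicate concentration reads times the
    minute's effluent volume; optional red-cell background subtraction,
    floored at zero.
    """
    reads = np.asarray(record.concentration_reads)
    conc = float(np.median(reads)) if aggregator == "median" else float(np.mean(reads))
    cells = conc * record.flow_volume
    if subtract_background and record.background_rbc is not None:
        logger.warning(
            "minute %d: subtracting red-cell background %.3g cells/min",
            record.minute_index, record.background_rbc,
        )
        cells -= record.background_rbc
    return max(cells, 0.0)


def total_effluent(
    series: Sequence[EffluentRecord],
    window_minutes: int = DEFAULT_WINDOW_MINUTES,
    aggregator: Literal["mean", "median"] = "mean",
    subtract_background: bool = False,
) -> float:
    """Total cells lost to the effluent over minutes 1..window_minutes."""
    by_minute = {r.minute_index: r for r in series}
    missing = [m for m in range(1, window_minutes + 1) if m not in by_minute]
    if missing:
        raise ValueError(
            f"effluent series is missing minute(s) {missing} of the "
            f"{window_minutes}-minute window"
        )
    return sum(
        effluent_cell_number(by_minute[m], aggregator, subtract_background)
        for m in range(1, window_minutes + 1)
    )


def retention_rate(
    injected_dose: float,
    total_effluent_cells: float,
    clamp: bool = True,
) -> float:
    """Donor-cell retention rate (%) = (injected - effluent) / injected x 100.

    If counting noise makes the effluent total exceed the dose the raw value
    is negative; by default it is clamped to 0% with a logged warning (use
    ``clamp=False`` for the raw value).
    """
    if injected_dose <= 0:
        raise ValueError("injected_dose must be positive")
    if total_effluent_cells < 0:
        raise ValueError("total effluent cell count must be non-negative")
    raw = (injected_dose - total_effluent_cells) / injected_dose * 100.0
    if raw < 0 and clamp:
        logger.warning(
            "effluent total %.4g exceeds injected dose %.4g "
            "(raw retention %.2f%%); clamping to 0%%",
            total_effluent_cells, injected_dose, raw,
        )
        return 0.0
    return raw


def first_minute_fraction(result: RetentionResult) -> float:
    """Percent of all exited cells that left during minute 1.

    Undefined when nothing exited; returns NaN (flagged missing) in that
    case rather than raising.
    """
    if result.total_effluent <= 0:
        return float("nan")
    return result.per_minute_cell_number[1] / result.total_effluent * 100.0


def _round_sig(x: float, n_sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n_sig - 1))


def convert_clinical_dose(
    human_dose: float,
    human_mass_kg: float,
    animal_mass_kg: float,
    n_arteries: int = 3,
) -> DoseConversion:
    """Scale a single-artery clinical cell dose to an animal by body mass.

    ``per_artery = human_dose * animal_mass / human_mass`` (reported to 2
    significant figures); ``total = per_artery * n_arteries`` (reported to
    1 significant figure).  Raw unrounded values are kept alongside.
    """
    if human_dose <= 0:
        raise ValueError("human_dose must be positive")
    if human_mass_kg <= 0 or animal_mass_kg <= 0:
        raise ValueError("masses must be positive")
    if n_arteries < 1:
        raise ValueError("n_arteries must be >= 1")
    per_artery_raw = human_dose * animal_mass_kg / human_mass_kg
    total_raw = per_artery_raw * n_arteries
    return DoseConversion(
        per_artery=_round_sig(per_artery_raw, 2),
        total=_round_sig(total_raw, 1),
        per_artery_raw=per_artery_raw,
        total_raw=total_raw,
    )


def analyze_run(
    run: PerfusionRun,
    window_minutes: int = DEFAULT_WINDOW_MINUTES,
    aggregator: Literal["mean", "median"] = "mean",
    subtract_background: bool = False,
    clamp: bool = True,
) -> RetentionResult:
    """Full effluent analysis of one run: per-minute numbers, totals, rate."""
    per_minute = {
        r.minute_index: effluent_cell_number(r, aggregator, subtract_background)
        for r in run.effluent_series
    }
    total = total_effluent(run.effluent_series, window_minutes, aggregator,
                           subtract_background)
    raw = retention_rate(run.injected_dose, total, clamp=False)
    pct = max(raw, 0.0) if clamp else raw
    if raw < 0 and clamp:
        logger.warning("run %s: retention clamped from %.2f%% to 0%%",
                       run.run_id, raw)
    result = RetentionResult(
        per_minute_cell_number=per_minute,
        total_effluent=total,
        retention_pct=pct,
        retention_pct_raw=raw,
        first_minute_pct=float("nan"),
        window_minutes=window_minutes,
        injected_dose=run.injected_dose,
        clamped=raw < 0 and clamp,
    )
    fmf = first_minute_fraction(result)
    return dataclasses.replace(result, first_minute_pct=fmf)
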