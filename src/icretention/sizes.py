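"""Cell-size histograms on 1-micrometre bins and size-stratified retention.

Automated cell counters report diameter distributions as counts per 1-um
subdivision.  Comparing the pre-injection distribution (scaled to the
injected dose) with the distribution of cells recovered in the coronary
effluent gives a retention rate per diameter bin: cells missing from the
effluent in a bin were retained in the heart.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SizeHistogram",
    "BinRetention",
    "summarize_sizes",
    "per_bin_retention",
    "pooled_retention",
    "bins_to_frame",
]


@dataclasses.dataclass(frozen=True, eq=False)
class SizeHistogram:
    """Diameter histogram on consecutive half-open 1-um bins [d, d+1).

    Parameters
    ----------
    lower_edges
        Integer lower edges in um, strictly consecutive (d, d+1, ...).
    counts
        Cell count (or fraction, if ``normalized``) per bin, all >= 0.
    normalized
        If True, ``counts`` are fractions and must sum to 1 (tol 1e-9).
    """

    lower_edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        edges = np.asarray(self.lower_edges, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.shape != edges.shape or edges.size == 0:
            raise ValueError("lower_edges and counts must be equal-length 1-D arrays")
        if edges.size > 1 and not np.all(np.diff(edges) == 1):
            raise ValueError("bin lower edges must be consecutive integers (um)")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if self.normalized and abs(counts.sum() - 1.0) > 1e-9:
            raise ValueError("normalized histogram must sum to 1 within 1e-9")
        object.__setattr__(self, "lower_edges", edges)
        object.__setattr__(self, "counts", counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeHistogram):
            return NotImplemented
        return (
            self.normalized == other.normalized
            and np.array_equal(self.lower_edges, other.lower_edges)
            and np.array_equal(self.counts, other.counts)
        )

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dict(cls, bins: Mapping[int, float], normalized: bool = False) -> "SizeHistogram":
        """Build from a mapping {lower edge um -> count}; gaps filled with 0."""
        if not bins:
            raise ValueError("empty histogram")
        lo, hi = min(bins), max(bins)
        edges = np.arange(lo, hi + 1)
        counts = np.array([float(bins.get(int(d), 0.0)) for d in edges])
        return cls(edges, counts, normalized=normalized)

    @classmethod
    def from_diameters(
        cls,
        diameters: np.ndarray,
        lo: int | None = None,
        hi: int | None = None,
    ) -> "SizeHistogram":
        """Bin raw diameters (um) to 1-um bins labelled by ``floor(d)``.

        ``lo``/``hi`` force the edge range (inclusive of bin [hi, hi+1)),
        so that two samples can be binned onto identical edges.
        """
        d = np.asarray(diameters, dtype=float)
        if d.size == 0:
            raise ValueError("empty diameter sample")
        if np.any(d < 0):
            raise ValueError("diameters must be non-negative")
        flo = int(np.floor(d.min())) if lo is None else int(lo)
        fhi = int(np.floor(d.max())) if hi is None else int(hi)
        idx = np.floor(d).astype(int) - flo
        if np.any(idx < 0) or np.any(idx > fhi - flo):
            raise ValueError("diameters fall outside the forced bin range")
        counts = np.bincount(idx, minlength=fhi - flo + 1).astype(float)
        return cls(np.arange(flo, fhi + 1), counts)

    # -- basic queries ---------------------------------------------------
    @property
    def midpoints(self) -> np.ndarray:
        return self.lower_edges + 0.5

    def total(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "SizeHistogram":
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero histogram")
        return SizeHistogram(self.lower_edges, self.counts / tot, normalized=True)

    def scale(self, total: float) -> "SizeHistogram":
        """Rescale counts so they sum to ``total`` (e.g. the injected dose)."""
        return SizeHistogram(self.lower_edges, self.counts / self.total() * total)

    def fraction_at_least(self, cutoff_um: float) -> float:
        """Fraction of cells in bins whose lower edge is >= cutoff."""
        mask = self.lower_edges >= cutoff_um
        return float(self.counts[mask].sum() / self.counts.sum())

    def to_dict(self) -> dict[int, float]:
        return {int(d): float(c) for d, c in zip(self.lower_edges, self.counts)}

    def __add__(self, other: "SizeHistogram") -> "SizeHistogram":
        """Count-wise sum, union-aligned on bin edges (both unnormalized)."""
        if self.normalized or other.normalized:
            raise ValueError("cannot add normalized histograms")
        lo = min(self.lower_edges[0], other.lower_edges[0])
        hi = max(self.lower_edges[-1], other.lower_edges[-1])
        edges = np.arange(lo, hi + 1)
        counts = np.zeros(edges.size)
        counts[self.lower_edges[0] - lo : self.lower_edges[-1] - lo + 1] += self.counts
        counts[other.lower_edges[0] - lo : other.lower_edges[-1] - lo + 1] += other.counts
        return SizeHistogram(edges, counts)


@dataclasses.dataclass(frozen=True)
class BinRetention:
    """Retention of one 1-um diameter subpopulation."""

    bin_lower: int
    injected_in_bin: float
    effluent_in_bin: float
    retention_pct: float          # clamped to [0, 100]; NaN if no injected cells
    retention_pct_raw: float      # unclamped value (can be negative)
    clamped: bool
    low_support: bool


def summarize_sizes(hist: SizeHistogram) -> tuple[float, float]:
    """Median and mean diameter (um) of a binned population.

    The mean is the count-weighted average of bin midpoints.  The median is
    interpolated linearly inside the bin containing the 50th percentile:
    ``lower + (N/2 - cum_below) / count_in_bin``; a single-bin histogram
    therefore has median at its midpoint.

    Returns
    -------
    (median_um, mean_um)
    """
    counts = hist.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot summarize an empty histogram")
    mean = float(np.sum(hist.midpoints * counts) / total)
    half = total / 2.0
    cum = np.cumsum(counts)
    i = int(np.searchsorted(cum, half))
    below = cum[i - 1] if i > 0 else 0.0
    median = float(hist.lower_edges[i] + (half - below) / counts[i])
    return median, mean


def per_bin_retention(
    pre: SizeHistogram,
    effluent: SizeHistogram,
    clamp: bool = True,
    min_support: float = 100.0,
) -> list[BinRetention]:
    """Retention rate per 1-um bin from pre-injection vs effluent counts.

    ``pre`` must be scaled to the injected dose (absolute cell counts) and
    both histograms must share identical bin edges.  Per bin,
    ``retention = (injected - effluent) / injected * 100``; where counting
    noise makes effluent exceed injected, the value is clamped to 0 (raw
    value kept) when ``clamp`` is set.  Bins with fewer than ``min_support``
    injected cells are flagged ``low_support``.

    Bins with zero injected cells get ``retention_pct = NaN`` (flagged
    missing) rather than raising.
    """
    if pre.lower_edges.shape != effluent.lower_edges.shape or np.any(
        pre.lower_edges != effluent.lower_edges
    ):
        raise ValueError(
            "pre-injection and effluent histograms must share identical bin edges; "
            f"got {pre.lower_edges[[0, -1]].tolist()} vs "
            f"{effluent.lower_edges[[0, -1]].tolist()}"
        )
    out: list[BinRetention] = []
    for d, inj, eff in zip(pre.lower_edges, pre.counts, effluent.counts):
        if inj <= 0:
            out.append(
                BinRetention(int(d), float(inj), float(eff), float("nan"),
                             float("nan"), False, True)
            )
            continue
        raw = (inj - eff) / inj * 100.0
        clamped = clamp and raw < 0.0
        if clamped:
            logger.warning(
                "bin [%d,%d) um: effluent count %.0f exceeds injected %.0f; "
                "retention clamped to 0%%", d, d + 1, eff, inj
            )
        out.append(
            BinRetention(
                bin_lower=int(d),
                injected_in_bin=float(inj),
                effluent_in_bin=float(eff),
                retention_pct=max(raw, 0.0) if clamp else raw,
                retention_pct_raw=raw,
                clamped=clamped,
                low_support=inj < min_support,
            )
        )
    return out


def pooled_retention(bins: Iterable[BinRetention], lower_cutoff: float, clamp: bool = True) -> float:
    """Retention (%) of all cells in bins at or above ``lower_cutoff`` um.

    Pools injected and effluent *counts* over the tail and applies the
    retention formula once — not the mean of per-bin percentages.
    """
    tail = [b for b in bins if b.bin_lower >= lower_cutoff]
    if not tail:
        raise ValueError(f"no bins at or above {lower_cutoff} um")
    inj = sum(b.injected_in_bin for b in tail)
    eff = sum(b.effluent_in_bin for b in tail)
    if inj <= 0:
        raise ValueError(f"no injected cells in bins at or above {lower_cutoff} um")
    raw = (inj - eff) / inj * 100.0
    return max(raw, 0.0) if clamp else raw


def bins_to_frame(bins: Iterable[BinRetention]) -> pd.DataFrame:
    """Tabulate per-bin retention (columns match the CSV output schema)."""
    return pd.DataFrame(
        [
            {
                "bin_lower_um": b.bin_lower,
                "injected": b.injected_in_bin,
                "effluent": b.effluent_in_bin,
                "retention_pct": b.retention_pct,
                "clamped": b.clamped,
                "low_support": b.low_support,
            }
            for b in bins
        ]
    )
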