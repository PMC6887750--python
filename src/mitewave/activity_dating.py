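"""Substitution-rate calibration and activity dating via T = D/s.

The triple (T, D, s) — event time in years, divergence in
substitutions/site and rate in substitutions/site/year — is closed under
the relation ``T = D / s``: any two members determine the third.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .consensus_divergence import DivergenceSummary

__all__ = [
    "DatingModel",
    "WaveReport",
    "calibrate_rate",
    "date_event",
    "wave_report",
    "years_to_mya",
]


@dataclass(frozen=True)
class DatingModel:
    """A consistent (T, D, s) triple."""

    T: float  # years
    D: float  # substitutions/site
    s: float  # substitutions/site/year

    def __post_init__(self) -> None:
        if self.T < 0 or self.D < 0 or self.s < 0:
            raise ValueError("T, D and s must all be >= 0")
        if self.s > 0 and not math.isclose(self.T, self.D / self.s, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("T, D, s do not satisfy T = D/s")


def calibrate_rate(d_mean: float, t_split: float) -> float:
    """Substitution rate from a mean divergence and a known split time: ``s = D / T``."""
    if t_split <= 0:
        raise ValueError("t_split must be > 0")
    if d_mean < 0:
        raise ValueError("d_mean must be >= 0")
    return d_mean / t_split


def date_event(d: float, s: float) -> float:
    """Age in years of an event with divergence ``d`` at rate ``s``: ``T = D / s``."""
    if s <= 0:
        raise ValueError("substitution rate must be > 0")
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return d / s


def years_to_mya(years: float) -> float:
    """Years -> millions of years, one decimal (report precision)."""
    return round(years / 1e6, 1)


@dataclass(frozen=True)
class WaveReport:
    """Dated summary of an amplification wave from its divergence landscape."""

    rate_s: float
    wave_end_years: float  # age of the youngest (min-divergence) copy
    wave_mid_years: float  # age at the mean divergence
    active_recently: bool
    n_copies: int

    @property
    def wave_end_mya(self) -> float:
        return years_to_mya(self.wave_end_years)

    @property
    def wave_mid_mya(self) -> float:
        return years_to_mya(self.wave_mid_years)


def wave_report(
    landscape: DivergenceSummary, s: float, recent_threshold: float = 0.02
) -> WaveReport:
    """Date the end and midpoint of a wave from its divergence landscape.

    ``active_recently`` flags a minimum divergence below
    ``recent_threshold`` (a reporting convenience, not an inference claim).
    """
    if s <= 0:
        raise ValueError("substitution rate must be > 0")
    if not landscape.ids:
        raise ValueError("empty divergence landscape")
    if math.isnan(landscape.min):
        raise ValueError("landscape has no finite divergences")
    return WaveReport(
        rate_s=s,
        wave_end_years=date_event(landscape.min, s),
        wave_mid_years=date_event(landscape.mean, s),
        active_recently=landscape.min < recent_threshold,
        n_copies=len(landscape.ids),
    )
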