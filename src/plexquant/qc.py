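"""PSM filtering against detector saturation and low signal.

High-intensity reporter ions (~1e6 detector units) saturate the detector
and the 13C/15N isotopolog peaks of a channel pair coalesce into one
distorted peak, which both corrupts the two channels' intensities and
drops the apparent resolving power below the ~45,000 needed to separate
the 0.006 Da pair spacing.  Low-intensity scans also fail the resolution
gate, for the opposite reason: too few ions to profile the peak.  The
filter therefore removes a PSM when (a) any matched reporter ion has
resolving power below ``resolution_min``, or (b) the total S/N summed
over the 18 channels is below ``total_sn_min``.  Either reason alone
removes — the two criteria flag largely different populations (saturated
high-S/N scans vs dim low-S/N scans), visible as a bimodal total-S/N
distribution among low-resolution scans.

Filtering removes; it never attempts to correct coalesced intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import yaml

from plexquant.extraction import Ms2Scan, PsmQuantRecord
from plexquant.reference import isotopolog_pairs

__all__ = [
    "QcConfig",
    "FilterReason",
    "FilterDecision",
    "CoalescenceEvent",
    "flag_psm",
    "filter_table",
    "FilterSummary",
    "low_resolution_sn_profile",
    "SnProfile",
    "detect_coalescence",
]


class FilterReason(str, Enum):
    LOW_RESOLUTION = "LOW_RESOLUTION"
    LOW_SN = "LOW_SN"


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for PSM-level reporter QC.

    resolution_min
        Minimum resolving power (FWHM) required of every matched
        reporter ion; 45,000 separates the 0.006 Da isotopolog spacing
        at reporter m/z.
    total_sn_min
        Minimum summed S/N across the 18 channels.  The default 1440
        corresponds to an average S/N of 80 per channel over 18 channels
        (an interpretation of the constant, not an instrument fact).
    pmt_quant, pmt_wide
        Narrow (quantitation) and wide (diagnostic) peak-match
        tolerances in Da.
    saturation_intensity
        Detector units at which ion saturation sets in; used by the
        simulator and by documentation, not by the filter itself.
    """

    resolution_min: float = 45000.0
    total_sn_min: float = 1440.0
    pmt_quant: float = 0.001
    pmt_wide: float = 0.003
    saturation_intensity: float = 1e6

    def __post_init__(self):
        for name in (
            "resolution_min",
            "total_sn_min",
            "pmt_quant",
            "pmt_wide",
            "saturation_intensity",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"QcConfig.{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "QcConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class FilterDecision:
    """Retain/remove decision for one PSM with machine-readable reasons."""

    psm_id: str
    retained: bool
    reasons: frozenset[FilterReason]

    def __post_init__(self):
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must hold exactly when reasons is empty")


@dataclass(frozen=True)
class CoalescenceEvent:
    """One isotopolog pair merged into a single peak.

    The merged peak sits strictly between the pair's theoretical m/z
    values; offsets are positive and sum to the pair spacing.
    """

    nominal_mass: int
    low_label: str
    high_label: str
    merged_mz: float
    offset_to_low: float
    offset_to_high: float


def flag_psm(record: PsmQuantRecord, config: QcConfig | None = None) -> FilterDecision:
    """Apply the resolution and total-S/N gates to one PSM.

    LOW_RESOLUTION is raised iff any *matched* observation reports a
    resolving power strictly below ``resolution_min`` (channels absent
    from the scan cannot fail resolution; they already contribute zero
    S/N).  LOW_SN is raised iff total S/N is strictly below
    ``total_sn_min`` — removal thresholds are strict, so equality passes.
    """
    config = config or QcConfig()
    reasons = set()
    for obs in record.observations:
        if obs.matched and obs.resolution is not None and obs.resolution < config.resolution_min:
            reasons.add(FilterReason.LOW_RESOLUTION)
            break
    if record.total_sn < config.total_sn_min:
        reasons.add(FilterReason.LOW_SN)
    return FilterDecision(
        psm_id=record.psm_id,
        retained=not reasons,
        reasons=frozenset(reasons),
    )


@dataclass
class FilterSummary:
    n_input: int
    n_retained: int
    n_low_resolution: int
    n_low_sn: int


def filter_table(
    records: Sequence[PsmQuantRecord], config: QcConfig | None = None
) -> tuple[list[PsmQuantRecord], list[FilterDecision], FilterSummary]:
    """Filter a PSM table; returns (retained records, all decisions, summary).

    Decisions cover every input record in order; the retained list is a
    subsequence of the input.
    """
    config = config or QcConfig()
    decisions = [flag_psm(rec, config) for rec in records]
    retained = [rec for rec, dec in zip(records, decisions) if dec.retained]
    summary = FilterSummary(
        n_input=len(records),
        n_retained=len(retained),
        n_low_resolution=sum(
            FilterReason.LOW_RESOLUTION in d.reasons for d in decisions
        ),
        n_low_sn=sum(FilterReason.LOW_SN in d.reasons for d in decisions),
    )
    return retained, decisions, summary


@dataclass
class SnProfile:
    """Diagnostic summary of log10 total S/N among low-resolution PSMs."""

    log10_total_sn: np.ndarray
    low_mode_mean: Optional[float]
    high_mode_mean: Optional[float]
    threshold: Optional[float]
    assignments: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    degenerate: bool = False

    @property
    def separation(self) -> Optional[float]:
        if self.low_mode_mean is None or self.high_mode_mean is None:
            return None
        return self.high_mode_mean - self.low_mode_mean


def low_resolution_sn_profile(
    records: Sequence[PsmQuantRecord], config: QcConfig | None = None
) -> SnProfile:
    """log10 total S/N of PSMs with any matched resolution below the gate.

    Low-resolution scans split bimodally: a low-S/N mode (dim ions, too
    few to profile a peak) and a high-S/N mode (saturated, coalesced
    ions).  The split reported here is a 1-D two-means partition over
    log10 total S/N — a reporting diagnostic only; the filter never
    depends on it.
    """
    config = config or QcConfig()
    values = []
    for rec in records:
        is_low = any(
            o.matched and o.resolution is not None and o.resolution < config.resolution_min
            for o in rec.observations
        )
        if is_low and rec.total_sn > 0:
            values.append(np.log10(rec.total_sn))
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return SnProfile(arr, None, None, None, degenerate=True)
    if np.allclose(arr, arr[0]):
        return SnProfile(
            arr, float(arr[0]), float(arr[0]), None,
            assignments=np.zeros(arr.size, dtype=int), degenerate=True,
        )
    assign = _two_means_1d(arr)
    low_mean = float(arr[assign == 0].mean())
    high_mean = float(arr[assign == 1].mean())
    return SnProfile(
        log10_total_sn=arr,
        low_mode_mean=low_mean,
        high_mode_mean=high_mean,
        threshold=0.5 * (low_mean + high_mean),
        assignments=assign,
    )


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Exact-ish 1-D 2-means via Lloyd iterations from min/max seeds."""
    lo, hi = float(x.min()), float(x.max())
    for _ in range(max_iter):
        cut = 0.5 * (lo + hi)
        assign = (x > cut).astype(int)
        if assign.all() or not assign.any():
            break
        new_lo, new_hi = float(x[assign == 0].mean()), float(x[assign == 1].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return (x > 0.5 * (lo + hi)).astype(int)


def detect_coalescence(
    scan: Ms2Scan, config: QcConfig | None = None
) -> list[CoalescenceEvent]:
    """Find isotopolog pairs merged into a single in-between peak.

    A pair is flagged when no peak lies within ``pmt_quant`` of either
    member's theoretical m/z but exactly one peak lies strictly between
    the two theoretical values.  The event records the merged centroid
    and its positive offsets to both members.
    """
    config = config or QcConfig()
    mzs = np.array([p.mz for p in scan.peaks])
    events = []
    for n_member, c_member in isotopolog_pairs():
        lo, hi = n_member.exact_mz, c_member.exact_mz
        near_member = np.any(np.abs(mzs - lo) <= config.pmt_quant) or np.any(
            np.abs(mzs - hi) <= config.pmt_quant
        )
        if near_member:
            continue
        between = mzs[(mzs > lo) & (mzs < hi)]
        if between.size != 1:
            continue
        merged = float(between[0])
        events.append(
            CoalescenceEvent(
                nominal_mass=n_member.nominal_mass,
                low_label=n_member.label,
                high_label=c_member.label,
                merged_mz=merged,
                offset_to_low=merged - lo,
                offset_to_high=hi - merged,
            )
        )
    return events
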