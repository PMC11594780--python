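"""The five quantitative CZE-IS graphic indexes.

For an electrophoretic peak in zone z (gamma or beta2) located at the apex x
of the reference curve P within the zone:

* sharpness index  s(x) = -[P(x+1) + P(x-1) - 2 P(x)], the negated central
  second finite difference of P; positive at peaks, and larger for sharper
  (narrower) peaks, so a high value flags a possible monoclonal spike.
* light chain index  Q(x) = (P(x) - K(x)) / (P(x) - L(x)), the ratio of the
  kappa- to the lambda-subtraction signal; reflects the kappa/lambda balance
  of the immunoglobulins under the peak.
* immunoglobulin indexes  dG(x) = P(x) - G(x), dA(x) = P(x) - A(x),
  dM(x) = P(x) - M(x); the absorbance removed by each antiserum, a proxy for
  the isotype's concentration at the peak.  Negative values are possible when
  immunoglobulin levels are low (two noisy overlapping curves are subtracted)
  and are reported unclamped.

All five indexes are evaluated at the REF apex within the zone; a ``max``
mode is provided for the sharpness index only, taking the maximum of the
second-difference expression over interior zone points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .trace_model import TraceSet, ZoneMap, DEFAULT_ZONE_MAP

__all__ = [
    "INDEX_NAMES",
    "EVAL_ZONES",
    "DENOMINATOR_FLOOR",
    "PeakLocation",
    "UndefinedIndex",
    "ReportingPolicy",
    "ZonePanel",
    "IndexPanel",
    "locate_peak",
    "sharpness_index",
    "light_chain_index",
    "immunoglobulin_index",
    "compute_panel",
    "panels_to_frame",
]

INDEX_NAMES = ("sharpness", "light_chain", "igg", "iga", "igm")
EVAL_ZONES = ("gamma", "beta2")

#: Floor on |P - L| below which the light chain index is reported undefined.
DENOMINATOR_FLOOR = 1e-9

_ISO_CHANNEL = {"igg": "IgG", "iga": "IgA", "igm": "IgM"}


class ZoneEvaluationError(ValueError):
    """Raised when an index cannot be evaluated in the requested zone."""


@dataclass(frozen=True)
class UndefinedIndex:
    """Marker for an index value that cannot be computed (e.g. Q with a
    vanishing denominator); carries a human-readable reason."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class PeakLocation:
    """Evaluation point of a zone: the apex of the REF curve within it.

    ``prominence`` is the apex absorbance minus the larger of the two
    zone-edge REF values; it may be <= 0 for a flat or monotone zone, which
    callers can use to gate interpretation.
    """

    zone: str
    apex_index: int
    apex_absorbance: float
    prominence: float


@dataclass(frozen=True)
class ReportingPolicy:
    """Display rounding: the light chain index to ``light_chain_decimals``,
    all other indexes to ``other_decimals`` (integers by default, matching
    how such intervals are conventionally printed).  Stored values always
    keep full precision."""

    light_chain_decimals: int = 2
    other_decimals: int = 0

    def round_value(self, index: str, value: float | None):
        if value is None or isinstance(value, UndefinedIndex):
            return value
        nd = self.light_chain_decimals if index == "light_chain" else self.other_decimals
        rounded = round(float(value), nd)
        return rounded if nd > 0 else int(rounded)


def _smooth(p: np.ndarray, window: int | None) -> np.ndarray:
    """Optional centered moving average with an odd window (edges reflected)."""
    if window is None or window <= 1:
        return p
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    padded = np.pad(p, half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def locate_peak(
    ts: TraceSet,
    zones: ZoneMap | None = None,
    zone: str = "gamma",
    smooth_window: int | None = None,
) -> PeakLocation:
    """Locate the REF apex within a zone (ties broken to the smallest index).

    A flat zone yields the zone start with prominence 0; an apex at a zone
    boundary point is returned as-is and shows up as low prominence.
    """
    zones = zones or DEFAULT_ZONE_MAP
    start, end = zones.interval(zone)
    if end - start < 3:
        raise ZoneEvaluationError(
            f"zone {zone!r} is narrower than 3 points ([{start}, {end}))"
        )
    p = _smooth(ts.ref, smooth_window)
    segment = p[start:end]
    apex = start + int(np.argmax(segment))
    apex_val = float(p[apex])
    prominence = apex_val - max(float(p[start]), float(p[end - 1]))
    return PeakLocation(
        zone=zone, apex_index=apex, apex_absorbance=apex_val, prominence=prominence
    )


def _second_difference(p: np.ndarray, x: int) -> float:
    return -(float(p[x + 1]) + float(p[x - 1]) - 2.0 * float(p[x]))


def sharpness_index(
    ts: TraceSet,
    zones: ZoneMap | None = None,
    zone: str = "gamma",
    mode: str = "apex",
    smooth_window: int | None = None,
) -> float:
    """Negated central second difference of REF at the zone apex.

    ``mode="max"`` instead returns the maximum of the expression over all
    interior zone points (points with both neighbours on the axis).
    """
    zones = zones or DEFAULT_ZONE_MAP
    if mode not in ("apex", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    start, end = zones.interval(zone)
    p = _smooth(ts.ref, smooth_window)
    n = p.shape[0]
    if mode == "max":
        lo = max(start, 1)
        hi = min(end, n - 1)
        xs = np.arange(lo, hi)
        if xs.size == 0:
            raise ZoneEvaluationError(f"zone {zone!r} has no interior points")
        vals = -(p[xs + 1] + p[xs - 1] - 2.0 * p[xs])
        return float(np.max(vals))
    loc = locate_peak(ts, zones, zone, smooth_window=smooth_window)
    x = loc.apex_index
    if x <= 0 or x >= n - 1:
        raise ZoneEvaluationError(
            f"apex of zone {zone!r} lies at the axis boundary (x={x}); "
            "the central difference has no neighbour there"
        )
    return _second_difference(p, x)


def light_chain_index(
    ts: TraceSet,
    zones: ZoneMap | None = None,
    zone: str = "gamma",
    floor: float = DENOMINATOR_FLOOR,
) -> float | UndefinedIndex:
    """Q = (P - K) / (P - L) at the zone apex.

    Returns an :class:`UndefinedIndex` marker when |P - L| underflows the
    denominator floor (Q would be unbounded or 0/0), never +-infinity.
    """
    zones = zones or DEFAULT_ZONE_MAP
    loc = locate_peak(ts, zones, zone)
    x = loc.apex_index
    num = float(ts.ref[x] - ts["K"][x])
    den = float(ts.ref[x] - ts["L"][x])
    if abs(den) < floor:
        return UndefinedIndex(
            reason=f"denominator P-L = {den:.3g} below floor {floor:g} at x={x}"
        )
    return num / den


def immunoglobulin_index(
    ts: TraceSet,
    zones: ZoneMap | None = None,
    zone: str = "gamma",
    isotype: str = "IgG",
) -> float:
    """P - (isotype channel) at the zone apex; negative values are permitted
    and returned unclamped."""
    if isotype not in ("IgG", "IgA", "IgM"):
        raise ValueError(f"unknown isotype {isotype!r}")
    zones = zones or DEFAULT_ZONE_MAP
    loc = locate_peak(ts, zones, zone)
    x = loc.apex_index
    return float(ts.ref[x] - ts[isotype][x])


@dataclass(frozen=True)
class ZonePanel:
    zone: str
    peak: PeakLocation
    sharpness: float
    light_chain: float | UndefinedIndex
    igg: float
    iga: float
    igm: float

    def value(self, index: str) -> float | UndefinedIndex:
        return getattr(self, index)


@dataclass(frozen=True)
class IndexPanel:
    """The ten index values (five indexes x gamma/beta2) for one case,
    stored at full precision together with the evaluation points used."""

    case_id: str
    zones: dict[str, ZonePanel]
    policy: ReportingPolicy = ReportingPolicy()

    def value(self, index: str, zone: str) -> float | UndefinedIndex:
        return self.zones[zone].value(index)

    def rounded(self) -> dict[str, dict[str, float | int | UndefinedIndex]]:
        """Values rounded per the reporting policy (display only)."""
        return {
            zone: {
                index: self.policy.round_value(index, zp.value(index))
                for index in INDEX_NAMES
            }
            for zone, zp in self.zones.items()
        }


def compute_panel(
    ts: TraceSet,
    zones: ZoneMap | None = None,
    reporting: ReportingPolicy | None = None,
    smooth_window: int | None = None,
) -> IndexPanel:
    """Compute all ten indexes for one case at each zone's REF apex."""
    zones = zones or DEFAULT_ZONE_MAP
    reporting = reporting or ReportingPolicy()
    zone_panels: dict[str, ZonePanel] = {}
    for zone in EVAL_ZONES:
        peak = locate_peak(ts, zones, zone, smooth_window=smooth_window)
        zone_panels[zone] = ZonePanel(
            zone=zone,
            peak=peak,
            sharpness=sharpness_index(ts, zones, zone, smooth_window=smooth_window),
            light_chain=light_chain_index(ts, zones, zone),
            igg=immunoglobulin_index(ts, zones, zone, "IgG"),
            iga=immunoglobulin_index(ts, zones, zone, "IgA"),
            igm=immunoglobulin_index(ts, zones, zone, "IgM"),
        )
    return IndexPanel(case_id=ts.case_id, zones=zone_panels, policy=reporting)


def panels_to_frame(panels: Iterable[IndexPanel]) -> pd.DataFrame:
    """Long-format panel table: one row per case and zone.

    Columns: case_id, zone, sharpness, light_chain, igg, iga, igm,
    apex_index, prominence, flags.  Undefined light-chain values become NaN
    with the reason recorded in ``flags``.
    """
    rows = []
    for panel in panels:
        for zone in EVAL_ZONES:
            zp = panel.zones[zone]
            flags = []
            lc = zp.light_chain
            if isinstance(lc, UndefinedIndex):
                flags.append("light_chain_undefined")
                lc_value = np.nan
            else:
                lc_value = lc
            if zp.peak.prominence <= 0:
                flags.append("flat_zone")
            rows.append(
                {
                    "case_id": panel.case_id,
                    "zone": zone,
                    "sharpness": zp.sharpness,
                    "light_chain": lc_value,
                    "igg": zp.igg,
                    "iga": zp.iga,
                    "igm": zp.igm,
                    "apex_index": zp.peak.apex_index,
                    "prominence": zp.peak.prominence,
                    "flags": ";".join(flags),
                }
            )
    columns = [
        "case_id", "zone", "sharpness", "light_chain", "igg", "iga", "igm",
        "apex_index", "prominence", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)
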