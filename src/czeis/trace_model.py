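"""Data model and CSV I/O for capillary electrophoresis immunosubtraction traces.

A CZE-IS case consists of six aligned ultraviolet-absorbance curves recorded
over the same migration-time axis: one electrophoresis run without antisera
(the reference curve, ``REF``) and five runs in which anti-IgG, anti-IgA,
anti-IgM, anti-kappa (``K``) or anti-lambda (``L``) antiserum has depleted the
corresponding immunoglobulin fraction.  Each curve is a fixed-length vector of
absorbance values (instrument arbitrary units), 300 points by default, so one
case is a 6 x 300 matrix.

The electrophoretic axis is partitioned into the classical serum protein
fractions (albumin, alpha1, alpha2, beta1, beta2, gamma) by a :class:`ZoneMap`
of half-open index intervals.  Downstream index computations only require the
beta2 and gamma zones, where immunoglobulins migrate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "ZONE_NAMES",
    "DEFAULT_ZONE_FRACTIONS",
    "TraceSet",
    "ZoneMap",
    "TraceParseError",
    "read_traces",
    "write_traces",
    "validate_traceset",
]

#: The six channels of a CZE-IS case, in canonical order.  ``REF`` is the run
#: without antisera; the others are named after the antiserum applied.
CHANNELS: tuple[str, ...] = ("REF", "IgG", "IgA", "IgM", "K", "L")

#: Serum protein fractions in migration order (albumin-first orientation).
ZONE_NAMES: tuple[str, ...] = ("albumin", "alpha1", "alpha2", "beta1", "beta2", "gamma")

#: Default zone boundaries as fractions of the axis length.  These follow the
#: typical serum protein electrophoresis fraction layout and are fully
#: overridable via :meth:`ZoneMap.from_fractions` / :meth:`ZoneMap.from_config`.
DEFAULT_ZONE_FRACTIONS: dict[str, tuple[float, float]] = {
    "albumin": (0.05, 0.25),
    "alpha1": (0.25, 0.35),
    "alpha2": (0.35, 0.48),
    "beta1": (0.48, 0.58),
    "beta2": (0.58, 0.70),
    "gamma": (0.70, 0.98),
}


class TraceParseError(ValueError):
    """Raised when a trace CSV cannot be parsed into valid trace sets."""


@dataclass
class TraceSet:
    """One case's six aligned absorbance curves.

    Parameters
    ----------
    case_id:
        Opaque case identifier.
    channels:
        Mapping from channel name (one of :data:`CHANNELS`) to a vector of
        ``n_points`` absorbance values in instrument arbitrary units.
    n_points:
        Number of points per curve; derived from the first channel when not
        given.  The instrument export is 300 points over a 300 s window.
    axis_unit:
        Seconds per point (informational only).
    clipped:
        When true, values are expected to be nonnegative (the instrument
        clips at zero); when false, negative values are permitted, e.g. for
        unclipped synthetic traces.
    """

    case_id: str
    channels: dict[str, np.ndarray]
    n_points: int | None = None
    axis_unit: float = 1.0
    clipped: bool = True

    def __post_init__(self) -> None:
        self.channels = {
            name: np.asarray(values, dtype=float)
            for name, values in self.channels.items()
        }
        if self.n_points is None:
            first = next(iter(self.channels.values()), None)
            self.n_points = 0 if first is None else int(first.shape[0])

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    @property
    def ref(self) -> np.ndarray:
        """The reference curve P(x) (run without antisera)."""
        return self.channels["REF"]

    def as_matrix(self) -> np.ndarray:
        """Return the case as a (6, n_points) matrix in canonical channel order."""
        return np.vstack([self.channels[c] for c in CHANNELS])


def validate_traceset(ts: TraceSet) -> list[str]:
    """Check a trace set against its structural invariants.

    Returns a list of human-readable violation descriptions; an empty list
    means the trace set is valid.  This function is total: it reports problems
    instead of raising.
    """
    violations: list[str] = []
    present = list(ts.channels.keys())
    for name in CHANNELS:
        if name not in present:
            violations.append(f"missing channel: {name}")
    for name in present:
        if name not in CHANNELS:
            violations.append(f"unexpected channel: {name}")
    n = ts.n_points if ts.n_points is not None else 0
    for name, values in ts.channels.items():
        if values.ndim != 1:
            violations.append(f"channel {name} is not one-dimensional")
            continue
        if values.shape[0] != n:
            violations.append(
                f"ragged length: channel {name} has {values.shape[0]} points, expected {n}"
            )
        bad = ~np.isfinite(values)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            violations.append(
                f"non-finite value: channel {name} at point {idx}"
            )
        elif ts.clipped and (values < 0).any():
            idx = int(np.flatnonzero(values < 0)[0])
            violations.append(
                f"negative value in clipped trace: channel {name} at point {idx}"
            )
    return violations


@dataclass(frozen=True)
class ZoneMap:
    """Named half-open index intervals [start, end) on the trace axis.

    ``zones`` preserves ascending index order.  Zone indexing is 0-based and
    intervals are half-open, so a zone ``(start, end)`` covers points
    ``start .. end-1``.
    """

    zones: dict[str, tuple[int, int]]
    n_points: int = 300
    orientation: str = "albumin_first"

    def __post_init__(self) -> None:
        problems = self.violations()
        if problems:
            raise ValueError("invalid zone map: " + "; ".join(problems))

    def violations(self) -> list[str]:
        out: list[str] = []
        prev_end = 0
        for name, (start, end) in self.zones.items():
            if name not in ZONE_NAMES:
                out.append(f"unknown zone {name!r}")
            if not (0 <= start < end <= self.n_points):
                out.append(f"zone {name} interval [{start}, {end}) outside [0, {self.n_points})")
            if start < prev_end:
                out.append(f"zone {name} overlaps or is out of order")
            prev_end = max(prev_end, end)
        for required in ("beta2", "gamma"):
            if required not in self.zones:
                out.append(f"required zone {required} missing")
        return out

    def __contains__(self, zone: str) -> bool:
        return zone in self.zones

    def __getitem__(self, zone: str) -> tuple[int, int]:
        return self.zones[zone]

    def interval(self, zone: str) -> tuple[int, int]:
        if zone not in self.zones:
            raise KeyError(f"zone {zone!r} not defined in zone map")
        return self.zones[zone]

    @classmethod
    def from_fractions(
        cls,
        fractions: Mapping[str, Sequence[float]] | None = None,
        n_points: int = 300,
        orientation: str = "albumin_first",
    ) -> "ZoneMap":
        """Build a zone map from fractional boundaries of the axis length.

        With ``orientation="gamma_first"`` the axis is mirrored: a fraction
        interval [a, b) maps to index interval [n - round(b*n), n - round(a*n))
        and zones are emitted in the mirrored (ascending-index) order.
        """
        if orientation not in ("albumin_first", "gamma_first"):
            raise ValueError(f"unknown orientation {orientation!r}")
        fractions = dict(fractions or DEFAULT_ZONE_FRACTIONS)
        items: list[tuple[str, tuple[int, int]]] = []
        for name, (lo, hi) in fractions.items():
            start = int(round(lo * n_points))
            end = int(round(hi * n_points))
            if orientation == "gamma_first":
                start, end = n_points - end, n_points - start
            items.append((name, (start, end)))
        items.sort(key=lambda kv: kv[1][0])
        return cls(zones=dict(items), n_points=n_points, orientation=orientation)

    @classmethod
    def from_config(cls, path: str | Path, n_points: int = 300) -> "ZoneMap":
        """Load a zone map from a YAML or JSON config file.

        The config maps ``zones: {name: [start_fraction, end_fraction]}`` plus
        an optional ``orientation`` key.
        """
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            cfg = json.loads(text)
        else:
            import yaml

            cfg = yaml.safe_load(text)
        return cls.from_fractions(
            cfg.get("zones", None),
            n_points=n_points,
            orientation=cfg.get("orientation", "albumin_first"),
        )


#: Zone map used throughout when none is supplied.
DEFAULT_ZONE_MAP = ZoneMap.from_fractions()


# ---------------------------------------------------------------------------
# CSV dialects
#
# long: columns case_id, channel, t, absorbance      (one row per point)
# wide: columns case_id, channel, v0 .. v{n-1}       (one row per channel)
# ---------------------------------------------------------------------------


def _read_frame(source: str | Path | IO[str]) -> pd.DataFrame:
    try:
        # round_trip parsing so write->read reproduces doubles bit-for-bit
        return pd.read_csv(source, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceParseError(f"cannot parse CSV: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TraceParseError(f"missing required columns: {', '.join(missing)}")


def _finish_case(case_id: str, chans: dict[str, np.ndarray], clipped: bool) -> TraceSet:
    for name in CHANNELS:
        if name not in chans:
            raise TraceParseError(f"case {case_id}: missing channel {name}")
    lengths = {name: arr.shape[0] for name, arr in chans.items()}
    if len(set(lengths.values())) != 1:
        raise TraceParseError(f"case {case_id}: ragged channel lengths {lengths}")
    ts = TraceSet(case_id=case_id, channels=chans, clipped=clipped)
    problems = validate_traceset(ts)
    if problems:
        raise TraceParseError(f"case {case_id}: " + "; ".join(problems))
    return ts


def read_traces(
    source: str | Path | IO[str],
    dialect: str = "long",
    clipped: bool = False,
) -> list[TraceSet]:
    """Read trace sets from a CSV file or stream in the named dialect.

    Cases are returned in file order.  Any structural problem (missing or
    duplicate channel, ragged lengths, non-numeric cells) raises
    :class:`TraceParseError` naming the offending case.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_frame(source)
    cases: list[TraceSet] = []
    if dialect == "long":
        _require_columns(df, ("case_id", "channel", "t", "absorbance"))
        if df.empty:
            return []
        if not np.issubdtype(np.asarray(df["absorbance"]).dtype, np.number):
            bad = df[pd.to_numeric(df["absorbance"], errors="coerce").isna()]
            row = bad.iloc[0]
            raise TraceParseError(
                f"case {row['case_id']}: non-numeric absorbance at channel "
                f"{row['channel']} t={row['t']}"
            )
        for case_id, group in df.groupby("case_id", sort=False):
            chans: dict[str, np.ndarray] = {}
            for channel, sub in group.groupby("channel", sort=False):
                t = np.asarray(sub["t"], dtype=int)
                if len(np.unique(t)) != len(t):
                    raise TraceParseError(
                        f"case {case_id}: duplicate rows for channel {channel}"
                    )
                order = np.argsort(t)
                t = t[order]
                if t[0] != 0 or not np.array_equal(t, np.arange(len(t))):
                    raise TraceParseError(
                        f"case {case_id}: channel {channel} time index is not 0..n-1"
                    )
                chans[str(channel)] = np.asarray(sub["absorbance"], dtype=float)[order]
            cases.append(_finish_case(str(case_id), chans, clipped))
    else:
        _require_columns(df, ("case_id", "channel"))
        vcols = sorted(
            (c for c in df.columns if re.fullmatch(r"v\d+", c)),
            key=lambda c: int(c[1:]),
        )
        if df.empty:
            return []
        if not vcols:
            raise TraceParseError("wide dialect requires v0..v{n-1} columns")
        values = df[vcols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        df = df.reset_index(drop=True)
        for case_id, group in df.groupby("case_id", sort=False):
            chans = {}
            for pos in group.index:
                channel = str(df.at[pos, "channel"])
                if channel in chans:
                    raise TraceParseError(
                        f"case {case_id}: duplicate channel {channel}"
                    )
                vec = values[pos]
                if np.isnan(vec).any():
                    raise TraceParseError(
                        f"case {case_id}: non-numeric or missing value in channel {channel}"
                    )
                chans[channel] = vec
            cases.append(_finish_case(str(case_id), chans, clipped))
    return cases


def write_traces(
    cases: Sequence[TraceSet],
    sink: str | Path | IO[str],
    dialect: str = "long",
    header_comment: str | None = None,
) -> None:
    """Write trace sets as CSV in the named dialect.

    Values are written with Python's shortest round-trip float representation,
    so ``read_traces(write_traces(...))`` reproduces them exactly.  An optional
    ``header_comment`` is emitted as leading ``#`` lines.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "long":
        frames = []
        for ts in cases:
            n = ts.n_points or 0
            for channel in CHANNELS:
                frames.append(
                    pd.DataFrame(
                        {
                            "case_id": ts.case_id,
                            "channel": channel,
                            "t": np.arange(n),
                            "absorbance": ts.channels[channel],
                        }
                    )
                )
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame(columns=["case_id", "channel", "t", "absorbance"])
    else:
        n = cases[0].n_points if cases else 0
        vcols = [f"v{i}" for i in range(n or 0)]
        rows = []
        for ts in cases:
            for channel in CHANNELS:
                rows.append(
                    {"case_id": ts.case_id, "channel": channel}
                    | dict(zip(vcols, ts.channels[channel]))
                )
        df = pd.DataFrame(rows, columns=["case_id", "channel", *vcols])

    def _dump(fh: IO[str]) -> None:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")

    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            _dump(fh)
    else:
        _dump(sink)
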