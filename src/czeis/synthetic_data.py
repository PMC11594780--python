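"""Seeded generator of synthetic CZE-IS trace sets with ground-truth labels.

The generator emulates the structure the index pipeline assumes: each case is
a 6 x n_points matrix of absorbance curves built from Gaussian-shaped protein
fractions.  The reference curve is

    REF(x) = sum(non-immunoglobulin fractions) + sum(immunoglobulin mass) [+ spike] + noise

and each antiserum channel removes a fraction ``epsilon`` (the subtraction
efficiency) of the targeted mass:

    channel_T(x) = REF_clean(x) - epsilon * mass_T(x) + independent noise

Isotype channels (IgG/IgA/IgM) subtract that isotype's mass; the anti-kappa
channel subtracts the kappa-bearing portion of *all* immunoglobulin mass
(polyclonal mass is split by the per-case ``kappa_fraction``; a monoclonal
spike contributes entirely to its own light chain), and anti-lambda
analogously.  Noise-free, the three isotype subtraction deltas and the two
light-chain deltas therefore both sum to ``epsilon *`` (total immunoglobulin
curve) at every point — a conservation law the tests exercise.

Case types:

* ``normal`` — polyclonal immunoglobulin humps with log-normal per-case
  amplitudes and a Beta-distributed kappa fraction.
* ``monoclonal`` — a normal background plus one tall, narrow Gaussian spike
  in the gamma or beta2 zone, attributed to a single isotype and light chain.
* ``polyclonal`` — all isotype amplitudes scaled by ``polyclonal_scale > 1``
  (a diffuse, broad-based elevation; no spike).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_model import CHANNELS, DEFAULT_ZONE_FRACTIONS, TraceSet

__all__ = [
    "GaussianComponent",
    "IsotypeSpec",
    "SpikeSpec",
    "SimConfig",
    "SimCase",
    "simulate_trace",
    "simulate_cohort",
    "write_labels",
]

CASE_TYPES = ("normal", "monoclonal", "polyclonal")
ISOTYPES = ("IgG", "IgA", "IgM")
LIGHT_CHAINS = ("kappa", "lambda")


@dataclass(frozen=True)
class GaussianComponent:
    """A Gaussian protein fraction: amplitude (a.u.), center as an axis
    fraction, and width as the Gaussian standard deviation in points."""

    amplitude: float
    center_frac: float
    width_pts: float

    def curve(self, n_points: int, amplitude: float | None = None) -> np.ndarray:
        a = self.amplitude if amplitude is None else amplitude
        x = np.arange(n_points, dtype=float)
        c = self.center_frac * (n_points - 1)
        return a * np.exp(-((x - c) ** 2) / (2.0 * self.width_pts**2))


@dataclass(frozen=True)
class IsotypeSpec:
    """Per-isotype immunoglobulin hump.

    The per-case amplitude is drawn from a log-normal with median
    ``amp_median`` and log-space standard deviation ``amp_sigma``
    (``amp_sigma = 0`` fixes the amplitude at the median).
    """

    center_frac: float
    width_pts: float
    amp_median: float
    amp_sigma: float

    def curve(self, n_points: int, amplitude: float) -> np.ndarray:
        return GaussianComponent(amplitude, self.center_frac, self.width_pts).curve(
            n_points
        )


@dataclass(frozen=True)
class SpikeSpec:
    """A monoclonal spike: one narrow Gaussian attributed to a single isotype
    and light chain.

    ``amplitude`` is in absorbance units unless ``relative`` is true, in which
    case it is a multiple of the noise-free local hump apex (background plus
    polyclonal immunoglobulin) within the spike's zone; the realized absolute
    amplitude is recorded in the case label.
    """

    zone: str
    isotype: str
    light_chain: str
    amplitude: float
    width_pts: float
    center_frac: float
    relative: bool = False


# Defaults calibrated once so that a normal cohort yields index magnitudes of
# the same order as published gamma/beta2 reference intervals (gamma IgG index
# in the tens-to-hundreds, light-chain index between ~1 and ~2.7) and so that
# narrow spikes separate cleanly from broad polyclonal humps in the sharpness
# index.  The beta2 entry is the non-immunoglobulin beta2 peak (complement
# C3/transferrin band); without it the zone's apex would sit on the zone edge
# under the rising gamma tail.  See docs/methods.md for the calibration
# rationale.
_DEFAULT_BACKGROUND = {
    "albumin": GaussianComponent(1200.0, 0.15, 9.0),
    "alpha1": GaussianComponent(180.0, 0.30, 5.0),
    "alpha2": GaussianComponent(280.0, 0.42, 6.0),
    "beta1": GaussianComponent(260.0, 0.52, 5.0),
    "beta2": GaussianComponent(130.0, 0.615, 5.0),
}
_DEFAULT_ISOTYPES = {
    "IgG": IsotypeSpec(0.82, 28.0, 220.0, 0.45),
    "IgA": IsotypeSpec(0.63, 15.0, 60.0, 0.50),
    "IgM": IsotypeSpec(0.66, 17.0, 30.0, 0.50),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic CZE-IS generator.

    Besides the shape parameters, the config carries the case type and, for
    monoclonal cases, the spike; ``simulate_cohort`` draws per-case spikes and
    polyclonal scales from the ``*_range``/``*_probs`` fields.
    """

    n_points: int = 300
    background: Mapping[str, GaussianComponent] = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND)
    )
    isotypes: Mapping[str, IsotypeSpec] = field(
        default_factory=lambda: dict(_DEFAULT_ISOTYPES)
    )
    kappa_fraction: float | None = None  # fixed value; None -> Beta draw
    kappa_mean: float = 0.62
    kappa_concentration: float = 80.0
    epsilon: float = 0.95  # subtraction efficiency in [0, 1]; 0 = no subtraction
    noise_sd: float = 1.5  # additive i.i.d. Gaussian noise per channel, a.u.
    clip_negative: bool = False
    case_type: str = "normal"
    spike: SpikeSpec | None = None
    polyclonal_scale: float = 3.0
    zone_fractions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_FRACTIONS)
    )
    # cohort-level sampling of per-case parameters
    spike_zone_probs: Mapping[str, float] = field(
        default_factory=lambda: {"gamma": 0.7, "beta2": 0.3}
    )
    spike_isotype_probs: Mapping[str, float] = field(
        default_factory=lambda: {"IgG": 0.6, "IgA": 0.2, "IgM": 0.2}
    )
    spike_light_chain_probs: Mapping[str, float] = field(
        default_factory=lambda: {"kappa": 0.6, "lambda": 0.4}
    )
    spike_rel_amp_range: tuple[float, float] = (5.0, 12.0)
    spike_width_range: tuple[float, float] = (1.5, 3.0)
    spike_center_margin: float = 0.2  # spike center drawn in central 1-2*m of zone
    polyclonal_scale_range: tuple[float, float] = (3.0, 5.0)

    def validate(self) -> None:
        if self.n_points < 10:
            raise ValueError("n_points must be at least 10")
        for name, comp in self.background.items():
            if comp.amplitude < 0 or comp.width_pts <= 0:
                raise ValueError(f"invalid background component {name}")
        for name, iso in self.isotypes.items():
            if iso.amp_median < 0 or iso.amp_sigma < 0 or iso.width_pts <= 0:
                raise ValueError(f"invalid isotype component {name}")
        if self.kappa_fraction is not None and not (0.0 < self.kappa_fraction < 1.0):
            raise ValueError("kappa_fraction must lie in (0, 1)")
        if not (0.0 <= self.epsilon <= 1.0):
            # 0 means no subtraction at all (all six channels coincide);
            # useful as a degenerate control even if unphysical for antisera
            raise ValueError("epsilon must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.case_type not in CASE_TYPES:
            raise ValueError(f"unknown case_type {self.case_type!r}")
        if (self.spike is not None) != (self.case_type == "monoclonal"):
            raise ValueError("spike must be present iff case_type is monoclonal")
        if self.spike is not None:
            s = self.spike
            if s.zone not in ("gamma", "beta2"):
                raise ValueError("spike zone must be gamma or beta2")
            if s.isotype not in ISOTYPES or s.light_chain not in LIGHT_CHAINS:
                raise ValueError("invalid spike isotype or light chain")
            if s.amplitude < 0 or s.width_pts <= 0:
                raise ValueError("spike amplitude must be >= 0 and width > 0")
        if self.case_type == "polyclonal" and self.polyclonal_scale <= 1.0:
            raise ValueError("polyclonal_scale must exceed 1")


@dataclass(frozen=True)
class SimLabel:
    """Ground truth of one simulated case."""

    case_type: str
    amplitudes: dict[str, float]
    kappa_fraction: float
    spike: SpikeSpec | None = None
    spike_amplitude_abs: float | None = None
    polyclonal_scale: float | None = None


@dataclass(frozen=True)
class SimCase:
    traceset: TraceSet
    label: SimLabel


def _zone_interval(config: SimConfig, zone: str) -> tuple[int, int]:
    lo, hi = config.zone_fractions[zone]
    return int(round(lo * config.n_points)), int(round(hi * config.n_points))


def simulate_trace(config: SimConfig, seed: int, case_id: str | None = None) -> SimCase:
    """Simulate one case; identical (config, seed) gives bitwise-identical output.

    Per-case randomness (isotype amplitudes, kappa fraction, channel noise) is
    drawn from ``numpy.random.default_rng(seed)`` in a fixed order, so two
    configs that differ only in the spike share the same polyclonal draws.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_points

    # per-case draws, fixed order: isotype amplitudes then kappa fraction
    amps: dict[str, float] = {}
    for iso in ISOTYPES:
        spec = config.isotypes[iso]
        if spec.amp_sigma > 0:
            amps[iso] = float(
                spec.amp_median * math.exp(spec.amp_sigma * rng.standard_normal())
            )
        else:
            amps[iso] = float(spec.amp_median)
    if config.kappa_fraction is not None:
        kappa = float(config.kappa_fraction)
    else:
        m, c = config.kappa_mean, config.kappa_concentration
        if config.case_type == "polyclonal":
            # a polyclonal flare pools many more clones, so the aggregate
            # kappa fraction regresses toward the mean with smaller variance
            c = c * config.polyclonal_scale
        kappa = float(rng.beta(m * c, (1.0 - m) * c))

    scale = None
    if config.case_type == "polyclonal":
        scale = float(config.polyclonal_scale)
        amps = {iso: a * scale for iso, a in amps.items()}

    background = np.zeros(n)
    for comp in config.background.values():
        background += comp.curve(n)
    iso_curves = {
        iso: config.isotypes[iso].curve(n, amplitude=amps[iso]) for iso in ISOTYPES
    }
    poly_ig = sum(iso_curves.values())

    spike_curve = np.zeros(n)
    spike_amp_abs = None
    spike = config.spike
    if spike is not None:
        if spike.relative:
            lo, hi = _zone_interval(config, spike.zone)
            hump_apex = float(np.max((background + poly_ig)[lo:hi]))
            spike_amp_abs = spike.amplitude * hump_apex
        else:
            spike_amp_abs = spike.amplitude
        spike_curve = GaussianComponent(
            spike_amp_abs, spike.center_frac, spike.width_pts
        ).curve(n)

    # mass removed by each antiserum
    mass = {iso: iso_curves[iso].copy() for iso in ISOTYPES}
    kappa_mass = kappa * poly_ig
    lambda_mass = (1.0 - kappa) * poly_ig
    if spike is not None:
        mass[spike.isotype] = mass[spike.isotype] + spike_curve
        if spike.light_chain == "kappa":
            kappa_mass = kappa_mass + spike_curve
        else:
            lambda_mass = lambda_mass + spike_curve
    mass["K"] = kappa_mass
    mass["L"] = lambda_mass

    ref_clean = background + poly_ig + spike_curve
    eps = config.epsilon
    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:  # fixed order keeps noise draws deterministic
        clean = ref_clean if name == "REF" else ref_clean - eps * mass[name]
        if config.noise_sd > 0:
            clean = clean + rng.normal(0.0, config.noise_sd, n)
        channels[name] = clean
    if config.clip_negative:
        channels = {k: np.maximum(v, 0.0) for k, v in channels.items()}

    ts = TraceSet(
        case_id=case_id or f"sim-{seed}",
        channels=channels,
        n_points=n,
        clipped=config.clip_negative,
    )
    label = SimLabel(
        case_type=config.case_type,
        amplitudes=amps,
        kappa_fraction=kappa,
        spike=spike,
        spike_amplitude_abs=spike_amp_abs,
        polyclonal_scale=scale,
    )
    return SimCase(traceset=ts, label=label)


def _draw_choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs.keys())
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _draw_spike(rng: np.random.Generator, config: SimConfig) -> SpikeSpec:
    zone = _draw_choice(rng, config.spike_zone_probs)
    isotype = _draw_choice(rng, config.spike_isotype_probs)
    light_chain = _draw_choice(rng, config.spike_light_chain_probs)
    amp = float(rng.uniform(*config.spike_rel_amp_range))
    width = float(rng.uniform(*config.spike_width_range))
    zlo, zhi = config.zone_fractions[zone]
    m = config.spike_center_margin * (zhi - zlo)
    center = float(rng.uniform(zlo + m, zhi - m))
    return SpikeSpec(
        zone=zone,
        isotype=isotype,
        light_chain=light_chain,
        amplitude=amp,
        width_pts=width,
        center_frac=center,
        relative=True,
    )


def simulate_cohort(
    n: int,
    mixture: Mapping[str, float],
    config: SimConfig | None = None,
    seed: int = 0,
    id_prefix: str = "sim",
) -> list[SimCase]:
    """Simulate ``n`` labeled cases with case types drawn from ``mixture``.

    ``mixture`` maps case types to proportions summing to 1.  All case-level
    randomness (type, spike parameters, polyclonal scale, and the per-case
    draws inside :func:`simulate_trace`) is reproducible under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    config = config or SimConfig()
    unknown = set(mixture) - set(CASE_TYPES)
    if unknown:
        raise ValueError(f"unknown case types in mixture: {sorted(unknown)}")
    total = float(sum(mixture.values()))
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"mixture proportions must sum to 1 (got {total})")

    rng = np.random.default_rng(seed)
    types = list(mixture.keys())
    probs = np.asarray([mixture[t] for t in types], dtype=float)
    cases: list[SimCase] = []
    width = max(4, len(str(max(n - 1, 0))))
    for i in range(n):
        case_type = types[int(rng.choice(len(types), p=probs))]
        case_cfg = replace(config, case_type=case_type, spike=None)
        if case_type == "monoclonal":
            case_cfg = replace(case_cfg, spike=_draw_spike(rng, config))
        elif case_type == "polyclonal":
            case_cfg = replace(
                case_cfg,
                polyclonal_scale=float(rng.uniform(*config.polyclonal_scale_range)),
            )
        child_seed = int(rng.integers(0, 2**31 - 1))
        cases.append(
            simulate_trace(case_cfg, child_seed, case_id=f"{id_prefix}-{i:0{width}d}")
        )
    return cases


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file mirroring its fields.

    ``background`` entries are ``[amplitude, center_frac, width_pts]``;
    ``isotypes`` entries are ``[center_frac, width_pts, amp_median,
    amp_sigma]``; ``spike`` is a mapping of :class:`SpikeSpec` fields.
    Omitted fields keep their defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "background" in raw:
        kwargs["background"] = {
            name: GaussianComponent(*vals) for name, vals in raw.pop("background").items()
        }
    if "isotypes" in raw:
        kwargs["isotypes"] = {
            name: IsotypeSpec(*vals) for name, vals in raw.pop("isotypes").items()
        }
    if raw.get("spike") is not None:
        kwargs["spike"] = SpikeSpec(**raw.pop("spike"))
    elif "spike" in raw:
        raw.pop("spike")
    for tup in (
        "spike_rel_amp_range",
        "spike_width_range",
        "polyclonal_scale_range",
    ):
        if tup in raw:
            raw[tup] = tuple(raw[tup])
    if "zone_fractions" in raw:
        raw["zone_fractions"] = {
            k: tuple(v) for k, v in raw["zone_fractions"].items()
        }
    kwargs.update(raw)
    config = SimConfig(**kwargs)
    config.validate()
    return config


def write_labels(
    cases: Sequence[SimCase],
    sink: str | Path | IO[str],
    header_comment: str | None = None,
) -> None:
    """Write ground-truth labels of a simulated cohort as CSV."""
    rows = []
    for case in cases:
        lab = case.label
        spike = lab.spike
        rows.append(
            {
                "case_id": case.traceset.case_id,
                "case_type": lab.case_type,
                "spike_zone": spike.zone if spike else "",
                "spike_isotype": spike.isotype if spike else "",
                "spike_light_chain": spike.light_chain if spike else "",
                "spike_amplitude": lab.spike_amplitude_abs if spike else "",
                "spike_width_pts": spike.width_pts if spike else "",
                "spike_center_frac": spike.center_frac if spike else "",
                "kappa_fraction": lab.kappa_fraction,
                "amp_igg": lab.amplitudes["IgG"],
                "amp_iga": lab.amplitudes["IgA"],
                "amp_igm": lab.amplitudes["IgM"],
                "polyclonal_scale": lab.polyclonal_scale if lab.polyclonal_scale else "",
            }
        )
    columns = [
        "case_id", "case_type", "spike_zone", "spike_isotype", "spike_light_chain",
        "spike_amplitude", "spike_width_pts", "spike_center_frac", "kappa_fraction",
        "amp_igg", "amp_iga", "amp_igm", "polyclonal_scale",
    ]
    df = pd.DataFrame(rows, columns=columns)

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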