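import numpy as np
import pytest

from czeis import TraceSet, ZoneMap
from czeis.trace_model import CHANNELS


def make_traceset(ref, case_id="t", clipped=False, **channels):
    """Build a TraceSet from a REF vector; unspecified channels copy REF.

    Channel overrides may be vectors or scalars (broadcast to full length).
    """
    ref = np.asarray(ref, dtype=float)
    chans = {"REF": ref}
    for name in CHANNELS[1:]:
        v = channels.get(name)
        if v is None:
            chans[name] = ref.copy()
        elif np.isscalar(v):
            chans[name] = np.full_like(ref, float(v))
        else:
            chans[name] = np.asarray(v, dtype=float)
    return TraceSet(case_id=case_id, channels=chans, clipped=clipped)


@pytest.fixture
def small_zones():
    """An 8-point axis with both required zones (for formula arithmetic)."""
    return ZoneMap(zones={"beta2": (0, 3), "gamma": (3, 8)}, n_points=8)


def impulse(value=1.0, at=5, n=8):
    ref = np.zeros(n)
    ref[at] = value
    return ref


@pytest.fixture
def default_zones():
    return ZoneMap.from_fractions()
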