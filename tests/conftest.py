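"""Shared fixtures: small meshes for unit tests, full-scale shared runs,
and the independent brute-force oracle for the lumped VKR model."""

from __future__ import annotations

import numpy as np
import pytest

from phloempart.lumped_models import vkr_resistance
from phloempart.params_geometry import (
    MeshSpec,
    ScenarioConfig,
    SinkSpec,
    SourceSpec,
)

SMALL_MESH = MeshSpec(n_source=4, source_element_length=0.025,
                      n_pathway=6, n_sink=4, sink_element_length=0.025)


@pytest.fixture
def small_config() -> ScenarioConfig:
    """Symmetric two-sink phloem-only scenario on a coarse mesh."""
    return ScenarioConfig(mesh_spec=SMALL_MESH, name="small")


@pytest.fixture
def small_single_sink() -> ScenarioConfig:
    return ScenarioConfig(
        mesh_spec=SMALL_MESH,
        sinks=[SinkSpec(v_max=25e-9)],
        source=SourceSpec(v0=10e-9),
        name="small_single",
    )


# ---------------------------------------------------------------------------
# Independent VKR oracle: nested bisection over (c0, (c1, c2)).
# ---------------------------------------------------------------------------

def _inner_root(c0, vmax, km, r_ref):
    """Sink concentration solving c0(c0-c)/r((c0+c)/2) = vmax*c/(km+c).

    The left side decreases and the right side increases in c, so the root
    in (0, c0) is unique and plain bisection finds it.
    """
    def h(c):
        r = vkr_resistance((c0 + c) / 2 / 1000.0, r_ref, out_of_range="clamp")
        return c0 * (c0 - c) / r - vmax * c / (km + c)

    lo, hi = 0.0, c0
    if h(hi) > 0:  # delivery exceeds unloading even at c = c0 (no root below)
        return c0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def vkr_oracle(v0, sinks, r_refs, c0_hi=1e6):
    """Brute-force steady state of the lumped resistance model.

    Outer bisection on the source concentration c0 (total unloading is
    increasing in c0), inner bisections for the sink concentrations.
    Entirely independent of the package's multi-start Newton solver.
    """
    def total(c0):
        cs = [_inner_root(c0, vm, km, r)
              for (vm, km), r in zip(sinks, r_refs)]
        return sum(vm * c / (km + c) for (vm, km), c in zip(sinks, cs)), cs

    lo, hi = 1e-12, c0_hi
    assert total(hi)[0] > v0, "oracle bracket too small"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid)[0] < v0:
            lo = mid
        else:
            hi = mid
    c0 = 0.5 * (lo + hi)
    u, cs = total(c0)
    return c0, cs[0], cs[1]
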