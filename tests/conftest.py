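import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from nmdashunt import cable


CABLE_GRID = np.arange(0, 37, 4)
CABLE_KW = dict(ampa_g_peak=6.0, nmda_ampa_ratio=1.0, record_sites_um=(0.0, 125.0))


@pytest.fixture(scope="session")
def cable_setup():
    """Ball-and-stick surrogate used across cable tests.

    300 µm dendrite so that inhibition can be placed 80 µm distal to the
    excitation at 125 µm, as in the placement protocols.
    """
    morph = cable.build_ball_and_stick(dend_length=300.0)
    mem = cable.MembraneParams()
    return morph, mem


@pytest.fixture(scope="session")
def cable_curves(cable_setup):
    """Soma + dendrite i/o curves for the standard inhibition placements."""
    morph, mem = cable_setup
    out = {}
    out["control"] = cable.cable_io_curve(morph, mem, CABLE_GRID, **CABLE_KW)
    for label, loc, g in [
        ("dendritic", 125.0, 4.0),
        ("somatic", 0.0, 90.0),
        ("onpath", 45.0, 8.0),
    ]:
        inh = cable.inhibitory_population(g_peak_total=g, location_um=loc)
        out[label] = cable.cable_io_curve(morph, mem, CABLE_GRID, inhibition=inh, **CABLE_KW)
    return out


@pytest.fixture(scope="session")
def cable_curves_passive(cable_setup):
    """Same placements with voltage-gated Na+/K+ channels zeroed."""
    morph, mem = cable_setup
    mem = mem.passive()
    out = {}
    out["control"] = cable.cable_io_curve(morph, mem, CABLE_GRID, **CABLE_KW)
    for label, loc, g in [("dendritic", 125.0, 4.0), ("somatic", 0.0, 90.0)]:
        inh = cable.inhibitory_population(g_peak_total=g, location_um=loc)
        out[label] = cable.cable_io_curve(morph, mem, CABLE_GRID, inhibition=inh, **CABLE_KW)
    return out
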