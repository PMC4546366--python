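import numpy as np
import pytest

from rfackit import PhantomSpec, generate_lv_phantom, sector_areas
from rfackit.rfac import compute_rfac, detect_ed_es


@pytest.fixture(scope="session")
def uniform_phantom():
    """Jitterless phantom with uniform contraction 0.2 (closed-form RFAC 36%)."""
    spec = PhantomSpec(contraction_field=0.2, matrix_px=96, jitter_px=0.0, seed=0)
    return generate_lv_phantom(spec)


@pytest.fixture(scope="session")
def sectorwise_phantom():
    """Jitterless 128-px phantom with distinct per-sector amplitudes, no taper."""
    c = np.tile(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]), (7, 1))
    spec = PhantomSpec(
        contraction_field=c, matrix_px=128, jitter_px=0.0, transition_deg=0.0, seed=0
    )
    return generate_lv_phantom(spec)


@pytest.fixture(scope="session")
def measured_sectorwise(sectorwise_phantom):
    table = sector_areas(sectorwise_phantom)
    ed, es, _ = detect_ed_es(table)
    return table, compute_rfac(table, ed, es)
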