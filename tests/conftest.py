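"""Shared fixtures: simulated cohorts are expensive, so the FS
current-clamp cohorts and the layer-6 step families are built once per
session and reused by the detector, feature and acceptance tests."""

import numpy as np
import pytest

from ephysepi import synthetic as sd


def brute_force_spike_count(v: np.ndarray) -> int:
    """Independent spike-count oracle: local maxima above 0 mV separated
    by a dip below -20 mV."""
    count, armed = 0, True
    for s in v:
        if armed and s >= 0:
            count += 1
            armed = False
        elif not armed and s < -20.0:
            armed = True
    return count


@pytest.fixture(scope="session")
def fs_cohorts():
    """11 wild-type and 11 null fast-spiking cells, full step families."""
    out = {}
    for group, preset, seed in (("wt", sd.get_preset("FS"), 11),
                                ("null", sd.knockout_preset("FS"), 22)):
        cells = sd.cohort_presets(preset, 11, seed)
        out[group] = [
            sd.simulate_current_clamp(c, sd.FS_PROTOCOL, seed=seed + j,
                                      group=group, cell_id=f"fs-{group}-{j}")
            for j, c in enumerate(cells)
        ]
    return out


@pytest.fixture(scope="session")
def l6_families():
    """Wild-type and null layer-6 pyramidal step families (one cell each)."""
    return {
        "wt": sd.simulate_current_clamp(
            sd.get_preset("RS-layer6"), sd.PYRAMIDAL_PROTOCOL, seed=5),
        "null": sd.simulate_current_clamp(
            sd.knockout_preset("RS-layer6"), sd.PYRAMIDAL_PROTOCOL, seed=6),
    }


@pytest.fixture(scope="session")
def detector_sweep_bank(fs_cohorts, l6_families):
    """>= 200 sweeps spanning both presets and both genotype scales."""
    sweeps = []
    for rec in fs_cohorts["wt"][:3] + fs_cohorts["null"][:3]:
        sweeps.extend(rec.sweeps)
    sweeps.extend(l6_families["wt"].sweeps)
    sweeps.extend(l6_families["null"].sweeps)
    assert len(sweeps) >= 200
    return sweeps
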