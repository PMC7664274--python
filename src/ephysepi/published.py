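"""Printed group-level values from the source study, used as inputs.

These are the published per-group summary statistics (means over cells)
that several desk-scale derived quantities are computed from — e.g. the
percent reduction in sodium-current density between genotypes, or the
fold change in synaptic event frequency.  They are inputs to arithmetic,
never substitutes for quantities the pipeline measures.
"""

from __future__ import annotations

__all__ = [
    "PEAK_INA_DENSITY_DISSOCIATED", "PEAK_INA_DENSITY_PATCH",
    "PERSISTENT_INA_DENSITY_RAMP", "SIPSC_FREQUENCY_HZ",
    "SIPSC_AMPLITUDE_PA", "SURVIVAL_MEDIAN_DAYS", "SURVIVAL_N",
    "percent_reduction", "fold_change",
]

# Peak sodium-current density (pA/pF); dissociated PV+ interneurons at
# -25 mV, layer-6 nucleated patches at -20 mV, persistent ramps at -20 mV.
PEAK_INA_DENSITY_DISSOCIATED = {"wt": -399.52, "null": -280.39}
PEAK_INA_DENSITY_PATCH = {"wt": -218.33, "null": -134.36}
PERSISTENT_INA_DENSITY_RAMP = {"wt": -10.30, "null": -6.70}

# Spontaneous IPSCs in layer-6 pyramidal neurons (per-cell means).
SIPSC_FREQUENCY_HZ = {"wt": 3.81, "null": 1.38}
SIPSC_AMPLITUDE_PA = {"wt": 36.90, "null": 34.54}

# Survival cohorts: constitutive null vs PV-restricted deletion.
SURVIVAL_MEDIAN_DAYS = {"null": 18, "pv_cre": 25}
SURVIVAL_N = {"null": 60, "pv_cre": 62}


def percent_reduction(reference: float, reduced: float) -> float:
    """Percent loss of magnitude relative to the reference value."""
    return (1.0 - abs(reduced) / abs(reference)) * 100.0


def fold_change(reference: float, reduced: float) -> float:
    """Fold difference of the reference over the reduced value."""
    return abs(reference) / abs(reduced)
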