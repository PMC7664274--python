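"""Liquid junction potentials from pipette/bath solution recipes.

Whole-cell voltages are offset by the liquid junction potential (LJP) that
forms between the pipette filling solution and the bath.  The LJP is
estimated with the Henderson equation, which assumes a linear mixing
profile across the junction and ideal (activity-coefficient-free)
electrodiffusion:

    V_bath - V_pipette = -(RT/F) * (S1/S2) * ln(Sb/Sp)

    S1 = sum_i z_i u_i (c_i^bath - c_i^pip)
    S2 = sum_i z_i^2 u_i (c_i^bath - c_i^pip)
    Sp = sum_i z_i^2 u_i c_i^pip ,  Sb likewise for the bath

where u_i is the absolute mobility of species i, proportional to its
limiting equivalent conductivity (lambda_i / |z_i| of the molar value).
The sign convention matches the usual offline correction: the reported
LJP is positive for a K-gluconate pipette in a NaCl-rich bath, and true
membrane potentials are obtained as V_recorded - LJP
(see :func:`ephysepi.trace_io.apply_junction_correction`).

Recipes are entered the way Methods sections print them ("140 K-Gluconate,
4 NaCl, 0.5 CaCl2, ..."); :func:`dissociate_recipe` expands supported salts
into ionic species, handles the pH-dependent fraction of weak acids
(HEPES), and closes electroneutrality with the stated pH counter-ion
(KOH or CsOH), mimicking what a bench scientist enters into a junction
potential calculator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "IonSpecies",
    "SolutionComposition",
    "henderson_ljp",
    "dissociate_recipe",
    "LIMITING_EQUIV_CONDUCTIVITY",
    "ION_VALENCE",
    "KGLUCONATE_INTERNAL",
    "ACSF_BATH",
    "CSCL_NA_INTERNAL",
    "NA30_EXTERNAL",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

# Limiting equivalent conductivities at 25 C, S cm^2 / equiv.
# Inorganic ions: CRC Handbook.  Organic/buffer ions: values used by
# common junction-potential calculators (Barry & Lynch 1991 relative
# mobilities, rescaled by lambda(K+) = 73.5; divalent entries converted
# from their per-charge convention).
LIMITING_EQUIV_CONDUCTIVITY: dict[str, float] = {
    "H": 349.65,
    "K": 73.48,
    "Na": 50.08,
    "Li": 38.66,
    "Cs": 77.26,
    "NH4": 73.5,
    "TEA": 32.66,
    "Tris": 29.5,
    "Ca": 59.47,
    "Mg": 53.0,
    "Ba": 63.63,
    "Cd": 54.0,
    "OH": 198.0,
    "Cl": 76.31,
    "Br": 78.1,
    "F": 55.4,
    "NO3": 71.42,
    "HCO3": 44.5,
    "H2PO4": 33.0,
    "SO4": 80.0,
    "acetate": 40.9,
    "gluconate": 24.3,
    "glutamate": 19.1,
    "isethionate": 38.2,
    "methanesulfonate": 48.8,
    "HEPES": 22.05,
    "MES": 26.5,
    "EGTA": 35.3,
    "phosphocreatine": 35.3,
    "ATP": 35.3,
    "GTP": 35.3,
}

ION_VALENCE: dict[str, int] = {
    "H": 1, "K": 1, "Na": 1, "Li": 1, "Cs": 1, "NH4": 1, "TEA": 1,
    "Tris": 1, "Ca": 2, "Mg": 2, "Ba": 2, "Cd": 2,
    "OH": -1, "Cl": -1, "Br": -1, "F": -1, "NO3": -1, "HCO3": -1,
    "H2PO4": -1, "SO4": -2, "acetate": -1, "gluconate": -1,
    "glutamate": -1, "isethionate": -1, "methanesulfonate": -1,
    "HEPES": -1, "MES": -1, "EGTA": -2, "phosphocreatine": -2,
    "ATP": -4, "GTP": -4,
}

# pKa of the titratable buffer handled fractionally (25 C).
HEPES_PKA = 7.55


class UnknownSpeciesError(KeyError):
    """A species has no tabulated mobility or valence."""


class UnknownSaltError(KeyError):
    """A recipe component is not in the supported salt table."""


@dataclass(frozen=True)
class IonSpecies:
    name: str
    valence: int
    concentration_mm: float
    mobility: float  # relative to K+, dimensionless

    def __post_init__(self):
        if self.concentration_mm < 0:
            raise ValueError(f"negative concentration for {self.name}")


@dataclass
class SolutionComposition:
    """A fully dissociated ionic composition (concentrations in mM)."""

    species: list[IonSpecies] = field(default_factory=list)
    name: str = ""

    def concentration(self, ion: str) -> float:
        return sum(s.concentration_mm for s in self.species if s.name == ion)

    def charge_imbalance(self) -> float:
        """Net charge (mM of elementary charge); ~0 for a valid solution."""
        return sum(s.valence * s.concentration_mm for s in self.species)

    def ionic_strength_equiv(self) -> float:
        return sum(abs(s.valence) * s.concentration_mm for s in self.species)

    def validate(self) -> None:
        tot = self.ionic_strength_equiv()
        if tot > 0 and abs(self.charge_imbalance()) > 0.05 * tot:
            raise ValueError(
                f"solution {self.name!r} charge imbalance "
                f"{self.charge_imbalance():.2f} mM exceeds 5% of ionic strength"
            )

    @classmethod
    def from_dict(cls, conc_mm: dict[str, float], name: str = "") -> "SolutionComposition":
        species = []
        for ion, c in conc_mm.items():
            if ion not in ION_VALENCE or ion not in LIMITING_EQUIV_CONDUCTIVITY:
                raise UnknownSpeciesError(
                    f"no tabulated mobility/valence for species {ion!r}"
                )
            lam = LIMITING_EQUIV_CONDUCTIVITY[ion]
            z = ION_VALENCE[ion]
            species.append(IonSpecies(ion, z, float(c), lam / LIMITING_EQUIV_CONDUCTIVITY["K"]))
        return cls(species, name)


def henderson_ljp(
    internal: SolutionComposition,
    external: SolutionComposition,
    temperature_k: float = 295.0,
) -> float:
    """Liquid junction potential (mV) of the bath relative to the pipette.

    Positive values mean the pipette is negative with respect to the bath;
    recorded voltages are corrected by subtracting the returned value.

    Raises
    ------
    UnknownSpeciesError
        if any species lacks a tabulated mobility (lists the species).
    ValueError
        for empty solutions.
    """
    if not internal.species or not external.species:
        raise ValueError("both solutions must contain at least one species")
    internal.validate()
    external.validate()

    ions = sorted(
        {s.name for s in internal.species} | {s.name for s in external.species}
    )
    missing = [i for i in ions if i not in LIMITING_EQUIV_CONDUCTIVITY]
    if missing:
        raise UnknownSpeciesError(
            f"species without tabulated mobility: {', '.join(missing)}"
        )

    s1 = s2 = sp = sb = 0.0
    for ion in ions:
        z = ION_VALENCE[ion]
        u = LIMITING_EQUIV_CONDUCTIVITY[ion]  # absolute mobility ~ lambda_eq
        a = internal.concentration(ion)
        b = external.concentration(ion)
        d = b - a
        s1 += z * u * d
        s2 += z * z * u * d
        sp += z * z * u * a
        sb += z * z * u * b
    if sp <= 0 or sb <= 0:
        raise ValueError("degenerate solution (no ionic conductivity)")
    log_term = math.log(sb / sp)
    if s2 == 0.0:
        if log_term != 0.0:  # pragma: no cover - pathological composition
            raise ValueError("Henderson denominator vanished")
        return 0.0
    rt_f_mv = GAS_CONSTANT * temperature_k / FARADAY * 1e3
    return -rt_f_mv * (s1 / s2) * log_term


# --- recipe parsing -------------------------------------------------------

# salt name -> {ion: stoichiometry}
_SALTS: dict[str, dict[str, float]] = {
    "NACL": {"Na": 1, "Cl": 1},
    "KCL": {"K": 1, "Cl": 1},
    "CSCL": {"Cs": 1, "Cl": 1},
    "LICL": {"Li": 1, "Cl": 1},
    "CACL2": {"Ca": 1, "Cl": 2},
    "MGCL2": {"Mg": 1, "Cl": 2},
    "BACL2": {"Ba": 1, "Cl": 2},
    "CDCL2": {"Cd": 1, "Cl": 2},
    "KH2PO4": {"K": 1, "H2PO4": 1},
    "NAHCO3": {"Na": 1, "HCO3": 1},
    "K-GLUCONATE": {"K": 1, "gluconate": 1},
    "KGLUCONATE": {"K": 1, "gluconate": 1},
    "NA-ISETHIONATE": {"Na": 1, "isethionate": 1},
    "TEA-CL": {"TEA": 1, "Cl": 1},
    "TEACL": {"TEA": 1, "Cl": 1},
    # bare "TEA" in Na-channel internals is the chloride salt
    "TEA": {"TEA": 1, "Cl": 1},
    "HEPES": {"HEPES": 1},            # weak acid, pH-fractionated
    "EGTA": {"EGTA": 1},              # fully deprotonated pair at pH 7.2-7.4
    "EGTA:CSOH": {"EGTA": 1, "Cs": 2},
    "EGTA:KOH": {"EGTA": 1, "K": 2},
    "PHOSPHOCREATINE": {"phosphocreatine": 1},
    "NA2PHOSPHOCREATINE": {"phosphocreatine": 1, "Na": 2},
    "NA2-PHOSPHOCREATINE": {"phosphocreatine": 1, "Na": 2},
    "MG-ATP": {"Mg": 1, "ATP": 1},
    "MGATP": {"Mg": 1, "ATP": 1},
    "NA2-ATP": {"Na": 2, "ATP": 1},
    "GTP": {"GTP": 1},
    "NA-GTP": {"Na": 1, "GTP": 1},
    # neutral osmolytes contribute nothing to the junction
    "GLUCOSE": {},
    "D-GLUCOSE": {},
    "SUCROSE": {},
}

_COMPONENT_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(.+?)\s*$")


def dissociate_recipe(
    components: dict[str, float] | str,
    ph: float = 7.3,
    ph_counter_ion: str = "K",
    name: str = "",
) -> SolutionComposition:
    """Expand a printed recipe into a dissociated :class:`SolutionComposition`.

    Parameters
    ----------
    components
        Either a mapping ``{"NaCl": 125, "KCl": 2.5, ...}`` (mM) or a
        comma-separated recipe string ``"125 NaCl, 2.5 KCl"``.
    ph
        Working pH; controls the protonation state of HEPES.
    ph_counter_ion
        Cation of the base used to titrate the solution ("K" for KOH,
        "Cs" for CsOH, "Na" for NaOH).  Added to close electroneutrality,
        as the pH-adjustment step does on the bench.

    Raises
    ------
    UnknownSaltError
        for a component not in the supported salt table.
    """
    if isinstance(components, str):
        parsed: dict[str, float] = {}
        for token in components.split(","):
            token = token.strip()
            if not token:
                continue
            m = _COMPONENT_RE.match(token)
            if not m:
                raise UnknownSaltError(f"cannot parse recipe component {token!r}")
            parsed[m.group(2)] = parsed.get(m.group(2), 0.0) + float(m.group(1))
        components = parsed

    conc: dict[str, float] = {}
    for salt, mm in components.items():
        key = salt.strip().upper().replace("‐", "-").replace("_", "")
        key = re.sub(r"\s+", "-", key)
        if key not in _SALTS:
            key2 = key.replace("-", "")
            if key2 in _SALTS:
                key = key2
            else:
                raise UnknownSaltError(f"unsupported salt {salt!r}")
        for ion, stoich in _SALTS[key].items():
            amount = stoich * float(mm)
            if ion == "HEPES":
                amount *= 1.0 / (1.0 + 10 ** (HEPES_PKA - ph))
            conc[ion] = conc.get(ion, 0.0) + amount

    # close electroneutrality with the titration counter-ion
    charge = sum(ION_VALENCE[i] * c for i, c in conc.items())
    if charge < 0:
        z = ION_VALENCE[ph_counter_ion]
        conc[ph_counter_ion] = conc.get(ph_counter_ion, 0.0) + (-charge) / z
    elif charge > 0:
        # acid titration (HCl) closes a cation excess
        conc["Cl"] = conc.get("Cl", 0.0) + charge

    return SolutionComposition.from_dict(conc, name=name)


# --- the study's printed recipes ------------------------------------------

#: Current-clamp pipette solution (pH 7.2-7.3 with KOH).
KGLUCONATE_INTERNAL = dissociate_recipe(
    {
        "K-gluconate": 140, "NaCl": 4, "CaCl2": 0.5, "HEPES": 10,
        "EGTA": 5, "phosphocreatine": 5, "Mg-ATP": 2, "GTP": 0.4,
    },
    ph=7.25, ph_counter_ion="K", name="K-gluconate internal",
)

#: Artificial cerebrospinal fluid bath (pH 7.35-7.40 aerated).
ACSF_BATH = dissociate_recipe(
    {
        "NaCl": 125, "KCl": 2.5, "MgCl2": 1, "KH2PO4": 1.25,
        "NaHCO3": 26, "CaCl2": 2, "D-glucose": 20,
    },
    ph=7.38, ph_counter_ion="Na", name="ACSF",
)

#: Sodium-channel pipette solution (pH 7.2-7.3 with CsOH).
CSCL_NA_INTERNAL = dissociate_recipe(
    {
        "CsCl": 115, "CaCl2": 0.5, "EGTA:CsOH": 5, "HEPES": 10,
        "Na2-phosphocreatine": 5, "TEA": 20, "Mg-ATP": 2, "GTP": 0.4,
    },
    ph=7.25, ph_counter_ion="Cs", name="CsCl Na-channel internal",
)

#: Reduced-sodium external recording solution (pH 7.35 with CsOH).
NA30_EXTERNAL = dissociate_recipe(
    {
        "NaCl": 30, "BaCl2": 1, "MgCl2": 2, "CsCl": 45, "CdCl2": 0.2,
        "CaCl2": 1, "HEPES": 10, "TEA-Cl": 20, "D-glucose": 100,
    },
    ph=7.35, ph_counter_ion="Cs", name="30 mM Na external",
)
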