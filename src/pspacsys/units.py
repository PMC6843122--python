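"""Unit conversions between field bookkeeping and rhizosphere-solver scales.

Soil pool state is carried as areal mass density (kg P ha-1 per layer);
the radial uptake solver works in solution concentration (umol cm-3).
Conversions go through the labile-pool/buffer-power convention: the
soluble pool per unit soil volume equals b * Cl, where b is the
dimensionless buffer power (which subsumes the volumetric water content,
b ~ theta + rho*k for a linear isotherm).
"""

from __future__ import annotations

#: molar mass of phosphorus, g mol-1
P_MOLAR_MASS = 30.97

#: 1 kg ha-1 expressed as g m-2
KG_HA_TO_G_M2 = 0.1
G_M2_TO_KG_HA = 10.0

#: 1 kg ha-1 expressed as ug cm-2 (1e9 ug over 1e8 cm2)
KG_HA_TO_UG_CM2 = 10.0


def mg_kg_to_kg_ha(conc_mg_kg: float, bulk_density: float, thickness_cm: float) -> float:
    """Convert a soil concentration (mg kg-1) to areal mass (kg ha-1) for one layer.

    bulk_density in g cm-3, thickness in cm.
    """
    return conc_mg_kg * bulk_density * thickness_cm * 0.1


def kg_ha_to_mg_kg(mass_kg_ha: float, bulk_density: float, thickness_cm: float) -> float:
    return mass_kg_ha / (bulk_density * thickness_cm * 0.1)


def pool_to_solution_conc(mass_kg_ha: float, thickness_cm: float, buffer_power: float) -> float:
    """Solution concentration Cl (umol cm-3) for a labile pool of mass_kg_ha.

    The labile pool per soil volume is b*Cl (Barber convention), so
    Cl = pool / (b * V_soil) with everything per cm3 of bulk soil.
    """
    if thickness_cm <= 0 or buffer_power <= 0:
        raise ValueError("thickness and buffer power must be positive")
    ug_per_cm3_soil = mass_kg_ha * KG_HA_TO_UG_CM2 / thickness_cm
    umol_per_cm3_soil = ug_per_cm3_soil / P_MOLAR_MASS
    return umol_per_cm3_soil / buffer_power


def solution_conc_to_pool(cl_umol_cm3: float, thickness_cm: float, buffer_power: float) -> float:
    """Inverse of :func:`pool_to_solution_conc` (kg P ha-1)."""
    umol_per_cm3_soil = cl_umol_cm3 * buffer_power
    ug_per_cm3_soil = umol_per_cm3_soil * P_MOLAR_MASS
    return ug_per_cm3_soil * thickness_cm / KG_HA_TO_UG_CM2


def umol_per_cm_root_to_kg_ha(
    uptake_umol_cm: float, root_length_density: float, thickness_cm: float
) -> float:
    """Convert cumulative uptake per unit root length to areal mass.

    uptake_umol_cm : umol per cm of root
    root_length_density : cm root per cm3 soil
    """
    umol_per_cm2_ground = uptake_umol_cm * root_length_density * thickness_cm
    ug_per_cm2 = umol_per_cm2_ground * P_MOLAR_MASS
    return ug_per_cm2 / KG_HA_TO_UG_CM2
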