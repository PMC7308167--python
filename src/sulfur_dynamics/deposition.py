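"""Aboveground sulfur inputs and solute routing.

Occult (fog) deposition and dry (stomatal) deposition are the only two
explicitly modeled aboveground processes; everything else — canopy
interception, snow dynamics, infiltration, bypass flow — moves S
passively with the water fluxes of the hydrologic driver.  Solute in any
aboveground water pool changes in proportion to the pool's water change
(:func:`route_solute`): outflowing water exports solute at the pool's
current concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AbovegroundSolute",
    "occult_deposition",
    "dry_deposition",
    "route_solute",
]


@dataclass
class AbovegroundSolute:
    """Solute held in aboveground water stores (mg SO4-S/m2)."""

    canopy_store: float = 0.0
    snow_store: float = 0.0

    def __post_init__(self) -> None:
        if self.canopy_store < 0 or self.snow_store < 0:
            raise ValueError("aboveground solute stores must be nonnegative")


def occult_deposition(so2_air: float, f_occult: float, fog_precip: float) -> float:
    """Fog (occult) S deposition, mg SO4-S m-2 d-1.

    The SO4-S concentration of fog water is taken proportional to the
    ambient SO2-S concentration (mg/m3) via the enrichment factor
    ``f_occult``; multiplying by fog precipitation (mm) yields the areal
    flux.
    """
    if so2_air < 0 or f_occult < 0 or fog_precip < 0:
        raise ValueError("occult_deposition inputs must be nonnegative")
    return so2_air * f_occult * fog_precip


def dry_deposition(so2_air: float, f_dry: float, kc_stress: float,
                   kc_lai: float, wind_u2: float) -> float:
    """Stomatal (dry) SO2-S uptake by the canopy, mg SO4-S m-2 d-1.

    Product of air concentration, enrichment factor, stomatal openness
    ``kc_stress``, relative leaf area ``kc_lai`` and 2-m wind speed.  The
    flux feeds the foliage pool directly (no canopy wash-off).
    """
    if min(so2_air, f_dry, kc_stress, kc_lai, wind_u2) < 0:
        raise ValueError("dry_deposition inputs must be nonnegative")
    if kc_stress > 1 or kc_lai > 1:
        raise ValueError("kc_stress and kc_lai must lie in [0, 1]")
    return so2_air * f_dry * kc_stress * kc_lai * wind_u2


def route_solute(store: float, water_before: float,
                 outflow: float) -> tuple[float, float]:
    """Move solute with water out of an aboveground pool.

    The relative solute change equals the relative water change, i.e.
    the outflow carries the pool's current concentration.  Returns
    ``(updated_store, exported_flux)`` in mg/m2; mass is conserved
    between the two.
    """
    if store < 0 or outflow < 0:
        raise ValueError("store and outflow must be nonnegative")
    if store == 0.0:
        return 0.0, 0.0
    if water_before <= 0.0:
        raise ValueError("positive solute store with no water: "
                         "concentration undefined")
    frac = min(outflow / water_before, 1.0)
    exported = store * frac
    return store - exported, exported
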