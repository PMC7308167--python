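"""Belowground rate laws for the sulfur dynamics model.

All process rates are expressed in mg SO4-S per m2 ground area per day.
Concentrations are mg SO4-S per litre of soil solution; with rooting
depth ``z_r`` in mm and storages in mg/m2 the conversion in
:func:`solution_concentration` is unit-exact (1 mm over 1 m2 = 1 L).

The module deliberately exposes each rate law as a plain scalar
function: the integrator composes them into the coupled ODE system, and
the test-suite checks every law against closed-form identities
(half-saturation points, half-life semantics, Q10 doubling) in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import IO

__all__ = [
    "ParameterSet",
    "SoilState",
    "DAYS_PER_YEAR",
    "T_BASE",
    "solution_concentration",
    "temperature_response",
    "moisture_response",
    "adsorption_equilibrium",
    "adsorption_rate",
    "immobilization_rate",
    "mineralization_stable",
    "mineralization_labile",
    "plant_uptake",
    "smoothstep",
    "litterfall_fraction",
    "litterfall",
    "load_parameters",
    "save_parameters",
    "load_site_parameters",
]

#: Mean Gregorian year length, used to convert half-lives given in years.
DAYS_PER_YEAR = 365.25

#: Base temperature (deg C) of the Q10 response; chosen to resemble the
#: annual mean soil temperature of temperate beech stands.
T_BASE = 8.0

LN2 = math.log(2.0)


@dataclass
class ParameterSet:
    """Site parameter set: deposition factors, microbial kinetics,
    plant-uptake demand curve, sorption isotherm and pool half-lives.

    Moisture thresholds ``theta0 <= theta1 <= theta2 <= theta3`` define a
    trapezoidal response (zero outside, optimal plateau in the middle),
    one quadruple per microbial process.  Reference values for the two
    calibrated beech stands ship with the package
    (:func:`load_site_parameters`).
    """

    # aboveground deposition enrichment factors (dimensionless)
    f_occult: float = 0.0
    f_dry: float = 0.0

    # trapezoidal soil-moisture response thresholds (L/L)
    theta0_mineral: float = 0.05
    theta1_mineral: float = 0.15
    theta2_mineral: float = 0.25
    theta3_mineral: float = 0.40
    theta0_immobil: float = 0.05
    theta1_immobil: float = 0.15
    theta2_immobil: float = 0.25
    theta3_immobil: float = 0.40

    # organic pool half-lives at optimal conditions
    hl_stable_yr: float = 50.0      # years
    hl_labile_d: float = 20.0       # days

    # microbial immobilization (Michaelis-Menten)
    k_m_immobil: float = 1.0        # mg/L
    v_coeff_immobil: float = 2.0    # mg m-2 d-1 at optimal conditions
    f_q10_immobil: float = 2.0
    f_q10_mineral: float = 2.0

    # plant uptake (Michaelis-Menten with annual demand throttling)
    v_starve_plant: float = 0.1     # mg m-2 d-1, S-starved canopy
    v_sat_plant: float = 0.0        # mg m-2 d-1, demand saturated
    k_m_plant: float = 1.0          # mg/L
    acu_starve: float = 1000.0      # mg m-2 yr-1, demand throttling onset
    acu_sat: float = 1500.0         # mg m-2 yr-1, uptake shutdown

    # routing fractions
    f_labile: float = 0.2           # organic input fraction to labile pool
    f_fol: float = 0.7              # uptake fraction routed to foliage

    # Langmuir sorption with first-order kinetics
    hl_ads_d: float = 100.0         # days
    k_l_ads: float = 10.0           # mg/L half-saturation concentration
    k_max_ads: float = 5000.0       # mg/m2 maximum charge

    # fixed constants
    t_base: float = T_BASE          # deg C
    resp_min: float = 0.0
    resp_opt: float = 1.0
    z_r: float = 500.0              # rooting/soil depth, mm

    # optional concentration-dependent labile half-life (sulfatase effect)
    sulfatase_enabled: bool = False
    hl_sulfatase_0: float = 10.0    # days at 0 mg/L
    hl_sulfatase_10: float = 30.0   # days at 10 mg/L

    # 1770 pool initializations (site calibration results)
    init_labile: float = 0.0        # mg/m2
    init_stable: float = 0.0        # mg/m2

    def __post_init__(self) -> None:
        for proc in ("mineral", "immobil"):
            ts = [getattr(self, f"theta{i}_{proc}") for i in range(4)]
            if not (ts[0] <= ts[1] <= ts[2] <= ts[3]):
                raise ValueError(f"moisture thresholds for {proc} not ordered: {ts}")
        for name in ("hl_stable_yr", "hl_labile_d", "hl_ads_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("f_labile", "f_fol"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.k_max_ads < 0:
            raise ValueError("k_max_ads must be nonnegative")
        if not self.acu_starve < self.acu_sat:
            raise ValueError("acu_starve must be below acu_sat")
        if self.f_q10_immobil <= 0 or self.f_q10_mineral <= 0:
            raise ValueError("Q10 factors must be positive")
        if self.z_r <= 0:
            raise ValueError("rooting depth z_r must be positive")

    def with_values(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    # -- serialization: flat ``key = value`` text files --------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def save(self, path_or_file) -> None:
        save_parameters(self, path_or_file)


@dataclass
class SoilState:
    """Instantaneous S storages (mg/m2).

    ``acu`` is the calendar-year accumulated plant uptake used by the
    demand-throttling curve; ``canopy_store`` and ``snow_store`` hold
    solute in aboveground water pools awaiting transfer to the soil.
    """

    sol: float = 0.0
    fol: float = 0.0
    labile: float = 0.0
    stable: float = 0.0
    ads: float = 0.0
    acu: float = 0.0
    canopy_store: float = 0.0
    snow_store: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sol", "fol", "labile", "stable", "ads", "acu",
                     "canopy_store", "snow_store"):
            if getattr(self, name) < 0:
                raise ValueError(f"SoilState.{name} must be nonnegative")

    def total(self) -> float:
        """Total system S including aboveground solute stores (mg/m2)."""
        return (self.sol + self.fol + self.labile + self.stable + self.ads
                + self.canopy_store + self.snow_store)

    def soil_total(self) -> float:
        """Total soil S: solution + organic + adsorbed (mg/m2)."""
        return self.sol + self.labile + self.stable + self.ads


def solution_concentration(sol: float, z_r: float, theta: float) -> float:
    """SO4-S concentration (mg/L) of the soil solution.

    Storage per unit area divided by the water column ``z_r * theta``;
    with ``z_r`` in mm this is mg/L directly.
    """
    if z_r <= 0:
        raise ValueError("z_r must be positive")
    if theta <= 0:
        raise ValueError("theta must be positive (concentration undefined)")
    if sol < 0:
        raise ValueError("sol must be nonnegative")
    return sol / (z_r * theta)


def temperature_response(t_soil: float, f_q10: float, t_base: float = T_BASE) -> float:
    """Q10 temperature multiplier: 1 at the base temperature, times
    ``f_q10`` for every 10 deg C above it."""
    if f_q10 <= 0:
        raise ValueError("f_q10 must be positive")
    return math.exp(math.log(f_q10) / 10.0 * (t_soil - t_base))


def moisture_response(theta: float, theta0: float, theta1: float,
                      theta2: float, theta3: float,
                      resp_min: float = 0.0, resp_opt: float = 1.0) -> float:
    """Trapezoidal soil-moisture response.

    ``resp_min`` outside [theta0, theta3], linear ramps on the flanks and
    the ``resp_opt`` plateau on [theta1, theta2]; continuous everywhere.
    """
    if not (theta0 <= theta1 <= theta2 <= theta3):
        raise ValueError("moisture thresholds must be ordered")
    if theta <= theta0 or theta >= theta3:
        # degenerate equal thresholds fall through to resp_min
        if theta1 <= theta <= theta2:
            return resp_opt
        return resp_min
    if theta <= theta1:
        frac = (theta - theta0) / (theta1 - theta0)
    elif theta <= theta2:
        frac = 1.0
    else:
        frac = 1.0 - (theta - theta2) / (theta3 - theta2)
    return resp_min + (resp_opt - resp_min) * frac


def adsorption_equilibrium(conc: float, k_max_ads: float, k_l_ads: float) -> float:
    """Langmuir equilibrium charge (mg/m2) at the given solution
    concentration, in half-saturation form ``K_max * C / (K_L + C)``."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    if conc == 0.0:
        return 0.0
    return k_max_ads * conc / (k_l_ads + conc)


def adsorption_rate(ads: float, ads_eq: float, hl_ads_d: float) -> float:
    """First-order relaxation of the adsorbed pool toward its Langmuir
    equilibrium: the gap halves every ``hl_ads_d`` days.  Signed
    (positive = net adsorption)."""
    if hl_ads_d <= 0:
        raise ValueError("hl_ads_d must be positive")
    return LN2 / hl_ads_d * (ads_eq - ads)


def immobilization_rate(conc: float, params: ParameterSet,
                        t_soil: float, theta: float) -> float:
    """Microbial S immobilization (mg m-2 d-1): Michaelis-Menten in the
    solution concentration with temperature/moisture-scaled V_max."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    v_max = (params.v_coeff_immobil
             * temperature_response(t_soil, params.f_q10_immobil, params.t_base)
             * moisture_response(theta, params.theta0_immobil,
                                 params.theta1_immobil, params.theta2_immobil,
                                 params.theta3_immobil,
                                 params.resp_min, params.resp_opt))
    return v_max * conc / (params.k_m_immobil + conc)


def _mineral_resp(params: ParameterSet, t_soil: float, theta: float) -> float:
    return (temperature_response(t_soil, params.f_q10_mineral, params.t_base)
            * moisture_response(theta, params.theta0_mineral,
                                params.theta1_mineral, params.theta2_mineral,
                                params.theta3_mineral,
                                params.resp_min, params.resp_opt))


def mineralization_stable(stable: float, params: ParameterSet,
                          t_soil: float, theta: float) -> float:
    """First-order mineralization of the stable (carbon-bonded) organic
    pool, environment-scaled; half-life is given in years."""
    if stable < 0:
        raise ValueError("stable pool must be nonnegative")
    lam = LN2 / (params.hl_stable_yr * DAYS_PER_YEAR)
    return stable * lam * _mineral_resp(params, t_soil, theta)


def labile_half_life(conc: float, params: ParameterSet) -> float:
    """Effective half-life (days) of the labile organic pool.

    Constant ``hl_labile_d`` by default.  With the sulfatase module
    enabled the half-life depends linearly on the solution concentration:
    S-starved microbes release sulfatase, shortening the half-life at low
    concentrations.  The line is pinned at 0 and 10 mg/L.
    """
    if not params.sulfatase_enabled:
        return params.hl_labile_d
    k = (params.hl_sulfatase_10 - params.hl_sulfatase_0) / 10.0
    hl = k * conc + params.hl_sulfatase_0
    if hl <= 0:
        raise ValueError(f"nonpositive labile half-life at conc={conc} mg/L")
    return hl


def mineralization_labile(labile: float, conc: float, params: ParameterSet,
                          t_soil: float, theta: float) -> float:
    """First-order mineralization of the labile (ester-sulfate) organic
    pool, environment-scaled, optionally concentration-dependent."""
    if labile < 0:
        raise ValueError("labile pool must be nonnegative")
    lam = LN2 / labile_half_life(conc, params)
    return labile * lam * _mineral_resp(params, t_soil, theta)


def smoothstep(x: float, e0: float, e1: float, y0: float, y1: float) -> float:
    """Cubic Hermite step from ``y0`` (x <= e0) to ``y1`` (x >= e1) with
    zero slope at both edges."""
    if e0 >= e1:
        raise ValueError("smoothstep requires e0 < e1")
    if x <= e0:
        return y0
    if x >= e1:
        return y1
    t = (x - e0) / (e1 - e0)
    return y0 + (y1 - y0) * t * t * (3.0 - 2.0 * t)


def plant_uptake(conc: float, kc_lai: float, acu: float,
                 params: ParameterSet) -> float:
    """Root S uptake (mg m-2 d-1).

    Michaelis-Menten in the solution concentration during the growing
    season (``kc_lai > 0``), zero otherwise.  The maximum rate declines
    smoothly from ``v_starve_plant`` to ``v_sat_plant`` as the calendar
    year's accumulated uptake ``acu`` crosses [acu_starve, acu_sat]:
    trees throttle uptake once the annual demand is met.
    """
    if conc < 0 or kc_lai < 0 or acu < 0:
        raise ValueError("plant_uptake inputs must be nonnegative")
    if kc_lai == 0.0:
        return 0.0
    v_max = smoothstep(acu, params.acu_starve, params.acu_sat,
                       params.v_starve_plant, params.v_sat_plant)
    return v_max * conc / (params.k_m_plant + conc)


def litterfall_fraction(doy: int, doy_lc: int, doy_le: int,
                        kc_lai_today: float, kc_lai_yesterday: float) -> float:
    """Fraction of the foliage S pool shed today.

    Zero before the autumn decline window, the relative daily leaf-area
    loss inside it, and 1 on the last day (the whole remaining pool
    falls).  Days after the window carry no foliage, fraction 0.  A
    canopy that is bare on both days inside the window sheds nothing;
    a nonzero leaf area appearing after a bare day is inconsistent
    forcing and raises.
    """
    if doy < doy_lc or doy > doy_le:
        return 0.0
    if doy == doy_le:
        return 1.0
    if kc_lai_yesterday <= 0.0:
        if kc_lai_today <= 0.0:
            return 0.0
        raise ValueError("zero leaf area inside the litterfall window")
    frac = 1.0 - kc_lai_today / kc_lai_yesterday
    return min(max(frac, 0.0), 1.0)


def litterfall(fol: float, kc_lai_today: float, kc_lai_yesterday: float,
               doy: int, doy_lc: int, doy_le: int) -> float:
    """Litterfall S flux (mg m-2 d-1) from the foliage pool."""
    if fol < 0:
        raise ValueError("foliage pool must be nonnegative")
    return litterfall_fraction(doy, doy_lc, doy_le,
                               kc_lai_today, kc_lai_yesterday) * fol


# ---------------------------------------------------------------------------
# parameter file round-tripping (flat ``key = value`` text)

def save_parameters(params: ParameterSet, path_or_file) -> None:
    lines = []
    for name, value in params.to_dict().items():
        if isinstance(value, bool):
            lines.append(f"{name} = {'true' if value else 'false'}")
        else:
            lines.append(f"{name} = {value!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w") as fh:
            fh.write(text)


def _parse_param_text(text: str, source: str = "<string>") -> ParameterSet:
    valid = {f.name for f in fields(ParameterSet)}
    values: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{source}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in valid:
            raise ValueError(f"{source}:{lineno}: unknown parameter {key!r}")
        if val.lower() in ("true", "false"):
            values[key] = val.lower() == "true"
        else:
            values[key] = float(val)
    return ParameterSet(**values)


def load_parameters(path_or_file: "str | IO[str]") -> ParameterSet:
    """Read a :class:`ParameterSet` from a flat key/value text file."""
    if hasattr(path_or_file, "read"):
        return _parse_param_text(path_or_file.read())
    with open(path_or_file) as fh:
        return _parse_param_text(fh.read(), source=str(path_or_file))


def load_site_parameters(site: str) -> ParameterSet:
    """Load one of the packaged reference parameter sets.

    ``site`` is ``"exelberg"`` or ``"jubilaeumswarte"`` — the calibration
    results for the two monitored beech stands.
    """
    from importlib.resources import files

    name = site.strip().lower()
    resource = files("sulfur_dynamics.data").joinpath(f"{name}.params")
    if not resource.is_file():
        raise ValueError(f"unknown site {site!r}")
    return _parse_param_text(resource.read_text(), source=f"{name}.params")
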