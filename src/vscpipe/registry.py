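"""Registry of environmental explanatory variables.

Thirteen candidate drivers of community vertical structure are used
throughout the pipeline, split into two classes:

* **resource** variables describe an area's capacity to supply water, heat
  and soil nutrients for plant growth (precipitation, aridity, temperature,
  soil fertility and acidity);
* **non-resource limiting** variables constrain growth and reproduction
  without supplying a resource (extreme cold, large diurnal/annual
  temperature swings, low oxygen and carbon-dioxide partial pressure at
  altitude, ultraviolet load, wind shear).
"""

from __future__ import annotations

#: Resource-availability variables.
RESOURCE_VARS: tuple[str, ...] = ("MAT", "MAP", "AI", "pH", "SOC", "TN")

#: Non-resource limiting variables.
NONRESOURCE_VARS: tuple[str, ...] = (
    "T_coldest",
    "T_diurnal",
    "T_annual",
    "PO2",
    "PCO2",
    "UR",
    "Wind",
)

#: All 13 candidate explanatory variables, in canonical order.
ALL_VARS: tuple[str, ...] = RESOURCE_VARS + NONRESOURCE_VARS

#: Variables retained by the default Pearson screening rules (see
#: :func:`vscpipe.drivers.screen_variables`): PCO2 drops as collinear with
#: PO2, MAP drops as collinear with AI, and of the three cold/temperature-
#: range variables only the one least correlated with MAT survives.
DEFAULT_SCREENED_VARS: tuple[str, ...] = (
    "MAT",
    "AI",
    "pH",
    "SOC",
    "TN",
    "T_diurnal",
    "PO2",
    "UR",
    "Wind",
)

#: Recognised vegetation types, ordered from the most favorable regime
#: (subtropical forest) to the most extreme (alpine desert grassland).
VEG_TYPES: tuple[str, ...] = ("forest", "shrubland", "meadow", "steppe", "desert")

#: Types whose plant records carry a stem diameter (basal area weighting).
WOODY_TYPES: frozenset[str] = frozenset({"forest", "shrubland"})

#: Types whose plant records carry fractional coverage.
GRASSLAND_TYPES: frozenset[str] = frozenset({"meadow", "steppe", "desert"})

#: Height-class width in metres used by the Shannon-evenness metric,
#: per vegetation type (1 m for forests, 10 cm for shrublands, 1 cm for
#: grasslands).
CLASS_WIDTHS: dict[str, float] = {
    "forest": 1.0,
    "shrubland": 0.10,
    "meadow": 0.01,
    "steppe": 0.01,
    "desert": 0.01,
}

#: O2 and CO2 volume mixing ratios of dry air, used when converting total
#: barometric pressure to partial pressures.
O2_MIXING_RATIO = 0.20946
CO2_MIXING_RATIO = 4.0e-4


def classify(var: str) -> str:
    """Return ``"resource"`` or ``"nonresource"`` for a registry variable.

    Raises
    ------
    KeyError
        If *var* is not one of the 13 registry variables.
    """
    if var in RESOURCE_VARS:
        return "resource"
    if var in NONRESOURCE_VARS:
        return "nonresource"
    raise KeyError(f"unknown environmental variable: {var!r}")


def validate_registry_names(names) -> None:
    """Raise ``ValueError`` if any name is not a registry variable."""
    bad = [n for n in names if n not in ALL_VARS]
    if bad:
        raise ValueError(f"unknown environmental variable(s): {bad}")
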