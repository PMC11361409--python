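"""Unit conversions used throughout the package."""

FT_TO_M = 0.3048
FT3_TO_M3 = FT_TO_M**3
#: 1 cubic foot per minute in m^3/h (0.3048^3 * 60, rounded as conventionally quoted).
CFM_TO_M3H = 1.699011
MILE_TO_M = 1609.344
EARTH_RADIUS_M = 6371_008.8


def ft3_to_m3(volume_ft3: float) -> float:
    """Convert a room volume from cubic feet to cubic metres."""
    return volume_ft3 * FT3_TO_M3


def cfm_to_m3h(flow_cfm: float) -> float:
    """Convert an air-cleaner flow rate from CFM to m^3/h (500 CFM -> 849.5)."""
    return flow_cfm * CFM_TO_M3H


def miles_to_m(miles: float) -> float:
    return miles * MILE_TO_M
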