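"""Fixed digitization catalogs and default layout maps for the CASAS Aruba
testbed (a single-resident apartment instrumented with 31 ceiling motion
sensors M001–M031 and four door sensors D001–D004).

Motion sensors digitize to indices 1–31, door sensors to 32–35; the eleven
activity classes (ten annotated ADLs plus the catch-all) map to 1–11.
Functional areas cluster into five groups — Kitchen+Dining, Bedroom+Bathroom,
Living, Office, Home Entrance — and each annotated activity has a home area.

The per-sensor area map below is an approximation reconstructed from the
published floorplan (the exact assignment is layout knowledge, not part of
the data format); override it for a different home or a more precise map.
"""

from __future__ import annotations

from .correlation import CorrelationConfig
from .events import OTHER_ACTIVITY, Catalog

MOTION_SENSORS = [f"M{i:03d}" for i in range(1, 32)]
DOOR_SENSORS = [f"D{i:03d}" for i in range(1, 5)]

ACTIVITIES = [
    "Meal_Preparation",
    "Relax",
    "Eating",
    "Work",
    "Sleeping",
    "Wash_Dishes",
    "Bed_to_Toilet",
    "Enter_Home",
    "Leave_Home",
    "Housekeeping",
    OTHER_ACTIVITY,
]

KITCHEN_DINING, BEDROOM_BATHROOM, LIVING, OFFICE, HOME_ENTRANCE = 1, 2, 3, 4, 5

AREA_NAMES = {
    KITCHEN_DINING: "Kitchen+Dining",
    BEDROOM_BATHROOM: "Bedroom+Bathroom",
    LIVING: "Living",
    OFFICE: "Office",
    HOME_ENTRANCE: "Home Entrance",
}

#: Home area of each annotated activity; Housekeeping and the catch-all are
#: deliberately unmapped and resolve by the majority-event-area rule.
ACTIVITY_AREA = {
    "Meal_Preparation": KITCHEN_DINING,
    "Eating": KITCHEN_DINING,
    "Wash_Dishes": KITCHEN_DINING,
    "Sleeping": BEDROOM_BATHROOM,
    "Bed_to_Toilet": BEDROOM_BATHROOM,
    "Relax": LIVING,
    "Work": OFFICE,
    "Enter_Home": HOME_ENTRANCE,
    "Leave_Home": HOME_ENTRANCE,
}

#: Approximate sensor -> area map (see module docstring); indices 1–31 are
#: M001–M031 and 32–35 are D001–D004.
SENSOR_AREA = {
    # bedrooms and bathroom corridor
    **{i: BEDROOM_BATHROOM for i in (1, 2, 3, 4, 5, 6, 7, 23, 24, 29, 30, 31)},
    # living room
    **{i: LIVING for i in (8, 9, 10, 11, 12, 13, 20)},
    # kitchen and dining
    **{i: KITCHEN_DINING for i in (14, 15, 16, 17, 18, 19, 22)},
    # office
    **{i: OFFICE for i in (25, 26, 27, 28)},
    # entrance and doors
    **{i: HOME_ENTRANCE for i in (21, 32, 33, 34, 35)},
}


def sensor_catalog() -> Catalog:
    """Frozen Aruba sensor catalog (unknown sensors, e.g. temperature lines,
    are skipped on read)."""
    return Catalog(MOTION_SENSORS + DOOR_SENSORS, frozen=True)


def activity_catalog() -> Catalog:
    return Catalog(ACTIVITIES, frozen=True)


def correlation_config(**overrides) -> CorrelationConfig:
    """Default offline-phase configuration for Aruba-format streams."""
    base = dict(
        sensor_area=dict(SENSOR_AREA),
        activity_area=dict(ACTIVITY_AREA),
        scm_window=15,
        sct_rank=2,
    )
    base.update(overrides)
    return CorrelationConfig(**base)
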