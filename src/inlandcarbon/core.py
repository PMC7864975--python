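"""Shared domain vocabulary: permafrost zones, water-body classes, units.

Everything downstream is stratified by permafrost zone (five classes of
frozen-ground coverage, ordered south to north) and by water-body class
(flowing vs standing waters, split at the observation cutoffs of the
underlying hydrography databases: 90 m width for lotic systems, 0.01 km2
surface area for lentic ones).

Unit discipline at module boundaries: surface areas in km2, widths in m,
daily emission rates in g C m-2 d-1, season lengths in days, annual budget
totals in Pg C yr-1.  Conversions happen only inside operations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

# --- unit constants -------------------------------------------------------

KM2_TO_M2 = 1.0e6
G_TO_PG = 1.0e-15
C_MOLAR_MASS = 12.011  # g mol-1

# class boundaries (database observation limits and physical minima)
RIVER_MIN_WIDTH_M = 90.0        # lotic bodies narrower than this are streams
STREAM_MIN_WIDTH_M = 0.32       # minimum width of first-order streams
LAKE_MIN_AREA_KM2 = 0.01        # lentic bodies smaller than this are ponds
POND_MIN_AREA_KM2 = 0.000115    # smallest measured pond


class PermafrostZone(enum.Enum):
    """Permafrost extent classes, ordered south -> north."""

    ABSENT = "absent"
    ISOLATED = "isolated"
    SPORADIC = "sporadic"
    DISCONTINUOUS = "discontinuous"
    CONTINUOUS = "continuous"

    @property
    def order(self) -> int:
        return ZONE_ORDER.index(self)

    def __lt__(self, other: "PermafrostZone") -> bool:
        if not isinstance(other, PermafrostZone):
            return NotImplemented
        return self.order < other.order


ZONE_ORDER: tuple[PermafrostZone, ...] = (
    PermafrostZone.ABSENT,
    PermafrostZone.ISOLATED,
    PermafrostZone.SPORADIC,
    PermafrostZone.DISCONTINUOUS,
    PermafrostZone.CONTINUOUS,
)

#: accepted spellings -> canonical zone (case-insensitive lookup applied on top)
_ZONE_ALIASES = {
    "absent": PermafrostZone.ABSENT,
    "permafrost-free": PermafrostZone.ABSENT,
    "permafrost_free": PermafrostZone.ABSENT,
    "free": PermafrostZone.ABSENT,
    "none": PermafrostZone.ABSENT,
    "isolated": PermafrostZone.ISOLATED,
    "sporadic": PermafrostZone.SPORADIC,
    "discontinuous": PermafrostZone.DISCONTINUOUS,
    "continuous": PermafrostZone.CONTINUOUS,
}


def normalize_zone(label: "str | PermafrostZone") -> PermafrostZone:
    """Map a free-form zone label (any case, a few synonyms) to its enum."""
    if isinstance(label, PermafrostZone):
        return label
    key = str(label).strip().lower().replace(" ", "_")
    try:
        return _ZONE_ALIASES[key]
    except KeyError:
        raise InputError(f"unknown permafrost zone label: {label!r}") from None


class BodyClass(enum.Enum):
    MAIN_CHANNEL = "main_channel"
    RIVER = "river"
    STREAM = "stream"
    LAKE = "lake"
    POND = "pond"


LOTIC_CLASSES = (BodyClass.MAIN_CHANNEL, BodyClass.RIVER, BodyClass.STREAM)
LENTIC_CLASSES = (BodyClass.LAKE, BodyClass.POND)


def normalize_body_class(label: "str | BodyClass") -> BodyClass:
    if isinstance(label, BodyClass):
        return label
    key = str(label).strip().lower()
    try:
        return BodyClass(key)
    except ValueError:
        raise InputError(f"unknown water-body class: {label!r}") from None


@dataclass(frozen=True)
class ZoneInfo:
    """Static attributes of one permafrost zone used for upscaling."""

    zone: PermafrostZone
    land_area_km2: float
    latitude_band: tuple[float, float]  # (south, north), degrees N

    def __post_init__(self) -> None:
        if self.land_area_km2 <= 0:
            raise ConfigurationError(
                f"land area must be strictly positive for zone {self.zone.value}"
            )
        lo, hi = self.latitude_band
        if not (lo < hi):
            raise ConfigurationError(
                f"latitude band must satisfy south < north for {self.zone.value}"
            )


# --- errors ---------------------------------------------------------------


class InlandCarbonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InlandCarbonError, ValueError):
    """Invalid generator or pipeline configuration."""


class InputError(InlandCarbonError, ValueError):
    """Malformed or out-of-contract input data."""


class DomainError(InlandCarbonError, ValueError):
    """Argument outside an operation's physical/mathematical domain."""


class FittingError(InlandCarbonError, RuntimeError):
    """Degenerate or underdetermined statistical fit."""
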