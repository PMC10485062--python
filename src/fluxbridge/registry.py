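"""Registry of the daily covariates ("factors") that drive the flux models.

The registry fixes a single canonical ordering of factors. Distance vectors
and transferability-regression coefficients index into this ordering, so it
must be identical at training time and at transfer time.

Factors fall into three groups:

* ``meteorological`` — station-observed weather (air/dew-point temperature,
  vapour pressure deficit, downward shortwave radiation); available in every
  scenario.
* ``remote_sensing`` — satellite vegetation/surface variables (fPAR, EVI,
  LSWI, seven surface-reflectance bands); only used in the RS scenario.
* ``static`` — terrain and soil attributes, constant in time.

Two feature scenarios are supported: ``RS`` (all factors) and ``WRS``
(remote-sensing factors withheld), mirroring model variants built with and
without satellite predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SCENARIOS = ("RS", "WRS")
TARGETS = ("NEE", "WF")

#: Canonical category ordering. Used for reporting and deterministic
#: tie-breaking when two transfer candidates score identically.
CATEGORIES = (
    "Wetland",
    "Cropland",
    "Grassland",
    "Forest",
    "Asia",
    "Europe",
    "Arid",
    "NonArid",
    "Overall",
)


@dataclass(frozen=True)
class Factor:
    """One covariate: its name, physical units and availability group."""

    name: str
    units: str
    group: str  # "meteorological" | "remote_sensing" | "static"

    def __post_init__(self) -> None:
        if self.group not in ("meteorological", "remote_sensing", "static"):
            raise ValueError(f"unknown factor group: {self.group!r}")

    @property
    def is_static(self) -> bool:
        return self.group == "static"


@dataclass(frozen=True)
class FactorRegistry:
    """Ordered, immutable collection of factors.

    The ordering is load-bearing: distance vectors d1..dw and the
    transferability-regression coefficients a1..aw are aligned with it.
    """

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def get(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def for_scenario(self, scenario: str) -> tuple[Factor, ...]:
        """Factors available under a scenario (WRS drops remote sensing)."""
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario: {scenario!r}")
        if scenario == "WRS":
            return tuple(f for f in self.factors if f.group != "remote_sensing")
        return self.factors

    def feature_names(self, scenario: str) -> tuple[str, ...]:
        return tuple(f.name for f in self.for_scenario(scenario))

    def daily_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if not f.is_static)

    def static_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.is_static)

    def rs_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.group == "remote_sensing")


_REFLECTANCE_BANDS = tuple(f"b{i}" for i in range(1, 8))


def default_registry() -> FactorRegistry:
    """The default 19-factor set.

    Four meteorological factors, eleven remote-sensing factors (fPAR, EVI,
    LSWI and reflectance bands 1–7) and four static terrain/soil factors.
    This is a representative reconstruction of a typical flux-upscaling
    covariate set, not a copy of any particular archive's variable list.
    """
    mets = (
        Factor("ta", "degC", "meteorological"),
        Factor("td", "degC", "meteorological"),
        Factor("vpd", "kPa", "meteorological"),
        Factor("dsr", "W m-2", "meteorological"),
    )
    rs = (
        Factor("fpar", "-", "remote_sensing"),
        Factor("evi", "-", "remote_sensing"),
        Factor("lswi", "-", "remote_sensing"),
    ) + tuple(Factor(b, "-", "remote_sensing") for b in _REFLECTANCE_BANDS)
    static = (
        Factor("elevation", "m", "static"),
        Factor("slope", "deg", "static"),
        Factor("sand_frac", "%", "static"),
        Factor("clay_frac", "%", "static"),
    )
    return FactorRegistry(mets + rs + static)
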