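"""Flat key-value run configuration with schema validation.

The config dialect is one ``key = value`` per line, SI units, ``#`` comments.
Unknown keys are an error, not a warning: misspelling a parameter must never
silently run the default study configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .bioheat import (LaserSource, SigmaConvention, SimGrid, ThermalProperties,
                      TissueGeometry)

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config_text",
           "SCHEMA"]


class ConfigError(ValueError):
    pass


def _positive(v: float) -> bool:
    return v > 0


def _non_negative(v: float) -> bool:
    return v >= 0


def _fraction_limit(v: float) -> bool:
    return 0 < v < 1


# key -> (default, parser, validator, unit, description)
SCHEMA: dict[str, tuple] = {
    # tissue / blood (ThermalProperties)
    "conductivity": (0.5, float, _non_negative, "W/m/K",
                     "tissue thermal conductivity k"),
    "density": (1090.0, float, _positive, "kg/m^3", "tissue density rho"),
    "specific_heat": (3400.0, float, _positive, "J/kg/K",
                      "tissue specific heat cp"),
    "blood_density": (1050.0, float, _positive, "kg/m^3", "blood density"),
    "blood_specific_heat": (3617.0, float, _positive, "J/kg/K",
                            "blood specific heat"),
    "perfusion_rate": (1.0e-3, float, _non_negative, "1/s",
                       "blood perfusion rate omega_b"),
    "blood_temperature": (37.0, float, lambda v: True, "degC",
                          "arterial blood / baseline temperature"),
    "metabolic_heat": (420.0, float, _non_negative, "W/m^3",
                       "metabolic heat generation Q_m"),
    # geometry
    "radius": (5.0e-3, float, _positive, "m", "tissue cylinder radius"),
    "thickness": (500.0e-6, float, _positive, "m", "tissue slab thickness h"),
    # laser source
    "power": (0.035, float, _non_negative, "W", "laser power P"),
    "beam_diameter": (200.0e-6, float, _positive, "m", "beam diameter d"),
    "sigma_convention": ("d/6", str, lambda v: v in ("d/6", "d/3"), "-",
                         "Gaussian width: sigma = d/6 (default) or d/3"),
    "on_time": (2.0, float, _positive, "s", "irradiation duration t_on"),
    # mesh / time stepping
    "dr_core": (1.5e-6, float, _positive, "m", "radial spacing in the core"),
    "core_radius": (300.0e-6, float, _positive, "m",
                    "radius of the uniformly meshed core"),
    "dz_surface": (0.5e-6, float, _positive, "m",
                   "axial spacing at the irradiated surface"),
    "radial_stretch": (1.06, float, lambda v: v >= 1, "-",
                       "geometric stretch of the outer radial mesh"),
    "axial_stretch": (1.08, float, lambda v: v >= 1, "-",
                      "geometric stretch of the axial mesh"),
    "dt": (5.0e-3, float, _positive, "s", "time step"),
    "t_end": (10.0, float, _positive, "s", "total simulated time"),
    "theta": (1.0, float, lambda v: 0.5 <= v <= 1.0, "-",
              "implicit scheme weight (1 = backward Euler, 0.5 = CN)"),
    "output_interval": (0.05, float, _positive, "s",
                        "spacing of recorded snapshots"),
    # analysis
    "extent_threshold": (40.0, float, lambda v: True, "degC",
                         "threshold for the super-threshold extent"),
    "return_band": (1.0, float, _positive, "degC",
                    "band around baseline counted as 'returned'"),
    # synthesis / stats
    "seed": (0, int, lambda v: 0 <= v < 2 ** 31, "-",
             "master seed for every random generator"),
    "alternative": ("less", str,
                    lambda v: v in ("less", "greater", "two-sided"), "-",
                    "Mann-Whitney alternative for irradiated vs control"),
    "grade1_max_fraction": (0.02, float, _fraction_limit, "-",
                            "largest circumference fraction scored grade 1"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter map; builders hand out the typed domain objects."""

    values: dict

    def __getitem__(self, key: str):
        return self.values[key]

    def thermal_properties(self) -> ThermalProperties:
        v = self.values
        return ThermalProperties(
            conductivity=v["conductivity"], density=v["density"],
            specific_heat=v["specific_heat"],
            blood_density=v["blood_density"],
            blood_specific_heat=v["blood_specific_heat"],
            perfusion_rate=v["perfusion_rate"],
            blood_temperature=v["blood_temperature"],
            metabolic_heat=v["metabolic_heat"])

    def geometry(self) -> TissueGeometry:
        return TissueGeometry(radius=self.values["radius"],
                              thickness=self.values["thickness"])

    def laser_source(self) -> LaserSource:
        conv = (SigmaConvention.DIAMETER_IS_6_SIGMA
                if self.values["sigma_convention"] == "d/6"
                else SigmaConvention.DIAMETER_IS_3_SIGMA)
        return LaserSource(power=self.values["power"],
                           beam_diameter=self.values["beam_diameter"],
                           sigma_convention=conv,
                           on_time=self.values["on_time"])

    def sim_grid(self) -> SimGrid:
        v = self.values
        return SimGrid.build(self.geometry(), dr_core=v["dr_core"],
                             core_radius=v["core_radius"],
                             dz_surface=v["dz_surface"],
                             radial_stretch=v["radial_stretch"],
                             axial_stretch=v["axial_stretch"],
                             dt=v["dt"], t_end=v["t_end"])


def parse_config_text(text: str, source: str = "<config>") -> RunConfig:
    values = {key: spec[0] for key, spec in SCHEMA.items()}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(
                f"{source}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (part.strip() for part in line.partition("="))
        if key not in SCHEMA:
            raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
        default, parser, validator, unit, desc = SCHEMA[key]
        try:
            parsed = parser(val)
        except ValueError as exc:
            raise ConfigError(
                f"{source}:{lineno}: key {key!r} expects "
                f"{parser.__name__} ({unit}): {exc}") from None
        if not validator(parsed):
            raise ConfigError(
                f"{source}:{lineno}: invalid value {parsed!r} for key "
                f"{key!r} ({desc}, {unit})")
        values[key] = parsed
    return RunConfig(values=values)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse and validate a config file; with no path, return all defaults
    (the thin-slab study configuration)."""
    if path is None:
        return RunConfig(values={k: s[0] for k, s in SCHEMA.items()})
    path = Path(path)
    return parse_config_text(path.read_text(), source=str(path))
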