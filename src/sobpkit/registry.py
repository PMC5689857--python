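"""The 24-configuration registry of a Mevion S250-class delivery system.

The double-scattering system offers 24 beam configurations in three
groups — large (12 configurations, 25 cm nozzle), deep (5, 14 cm
nozzle) and small (7, 14 cm nozzle) — with group-wise limits on range
and modulation width:

    large: range 5–25 cm,    modulation 2–20 cm
    deep:  range 20.1–32 cm, modulation 2–10 cm
    small: range 5–20 cm,    modulation 2–20 cm

Per-configuration nominal ranges are taken from the measured distal-90%
depths of the system's commissioning dataset (see ``commissioning``).
``validate_configuration`` checks *requested* range/modulation strictly
against the group limits; nominal ranges themselves are allowed a
0.15 cm grace because a measured D90 can sit slightly past the nominal
group maximum (configuration 1 measures 25.10 cm in a 25 cm group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = [
    "BeamConfiguration",
    "GROUP_LIMITS",
    "REGISTRY",
    "get_configuration",
    "configurations_in_group",
    "validate_configuration",
]

#: group -> dict of (min_range, max_range, min_modulation, max_modulation), cm
GROUP_LIMITS: dict[str, dict[str, float]] = {
    "large": {"min_range": 5.0, "max_range": 25.0, "min_mod": 2.0, "max_mod": 20.0},
    "deep": {"min_range": 20.1, "max_range": 32.0, "min_mod": 2.0, "max_mod": 10.0},
    "small": {"min_range": 5.0, "max_range": 20.0, "min_mod": 2.0, "max_mod": 20.0},
}

#: tolerance on *nominal* range vs the group limit, cm
_NOMINAL_GRACE = 0.15


@dataclass(frozen=True)
class BeamConfiguration:
    """One of the 24 delivery configurations."""

    id: int
    group: str
    nominal_range: float
    nozzle_field_diameter: float
    max_modulation: float
    min_modulation: float = 2.0
    aperture: str | None = None
    airgap: float = 10.0

    def __post_init__(self) -> None:
        if self.group not in GROUP_LIMITS:
            raise ValueError(f"unknown group {self.group!r}")
        lim = GROUP_LIMITS[self.group]
        if not (
            lim["min_range"] - _NOMINAL_GRACE
            <= self.nominal_range
            <= lim["max_range"] + _NOMINAL_GRACE
        ):
            raise ValueError(
                f"config {self.id}: nominal range {self.nominal_range} outside "
                f"{self.group} limits"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _mk(cid: int, group: str, rng: float) -> BeamConfiguration:
    nozzle = 25.0 if group == "large" else 14.0
    max_mod = 10.0 if group == "deep" else 20.0
    return BeamConfiguration(
        id=cid,
        group=group,
        nominal_range=rng,
        nozzle_field_diameter=nozzle,
        max_modulation=max_mod,
    )


#: nominal ranges = measured D90 of the commissioning dataset, cm
_NOMINAL_RANGES = {
    # large group, configurations 1-12
    1: 25.10, 2: 22.59, 3: 20.92, 4: 18.78, 5: 16.80, 6: 14.94,
    7: 13.24, 8: 11.52, 9: 10.07, 10: 8.72, 11: 7.39, 12: 6.67,
    # deep group, configurations 13-17
    13: 31.88, 14: 29.51, 15: 27.08, 16: 24.55, 17: 22.06,
    # small group, configurations 18-24
    18: 20.05, 19: 17.81, 20: 15.39, 21: 13.32, 22: 11.28, 23: 9.18, 24: 7.12,
}


def _group_of(cid: int) -> str:
    if 1 <= cid <= 12:
        return "large"
    if 13 <= cid <= 17:
        return "deep"
    if 18 <= cid <= 24:
        return "small"
    raise KeyError(f"configuration id {cid} outside 1-24")


REGISTRY: dict[int, BeamConfiguration] = {
    cid: _mk(cid, _group_of(cid), rng) for cid, rng in _NOMINAL_RANGES.items()
}


def get_configuration(cid: int) -> BeamConfiguration:
    if cid not in REGISTRY:
        raise KeyError(f"configuration id {cid} outside 1-24")
    return REGISTRY[cid]


def configurations_in_group(group: str) -> list[BeamConfiguration]:
    if group not in GROUP_LIMITS:
        raise ValueError(f"unknown group {group!r}")
    return [c for c in REGISTRY.values() if c.group == group]


def validate_configuration(
    config: BeamConfiguration, requested_range: float, requested_modulation: float
) -> list[str]:
    """Check a requested (range, modulation) against the group limits.

    Returns a list of violation messages naming the breached bound;
    empty list means the request is deliverable by the group.
    """
    lim = GROUP_LIMITS[config.group]
    violations = []
    if requested_range > lim["max_range"]:
        violations.append(
            f"range {requested_range} > {config.group} max range {lim['max_range']}"
        )
    if requested_range < lim["min_range"]:
        violations.append(
            f"range {requested_range} < {config.group} min range {lim['min_range']}"
        )
    if requested_modulation > lim["max_mod"]:
        violations.append(
            f"modulation {requested_modulation} > {config.group} max modulation "
            f"{lim['max_mod']}"
        )
    if requested_modulation < lim["min_mod"]:
        violations.append(
            f"modulation {requested_modulation} < {config.group} min modulation "
            f"{lim['min_mod']}"
        )
    if requested_modulation > requested_range:
        violations.append(
            f"modulation {requested_modulation} > range {requested_range}"
        )
    return violations
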