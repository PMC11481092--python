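"""Shipped presets: design spaces, rig constants and calibrated kinetics.

The numeric variable bounds and reactor constants are documented working
assumptions chosen to be consistent with the reported optima (high step-1
temperature, anhydride equivalents above 2, sub-minute step-2 residence
times feasible, 100 degC reachable); override them via config files where a
different rig is being emulated.  The ``paper`` kinetic preset is the
frozen output of :func:`flowopt.virtual_rig.calibrate` against the three
study optima (65 / 97 / 85 %).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .design_space import DesignSpace, VariableSpec
from .virtual_rig import KineticParams, RigPreset

__all__ = [
    "design_space_preset",
    "rig_preset",
    "kinetic_preset",
    "available_presets",
    "DESIGN_SPACE_FOR_MODE",
    "RIG_FOR_MODE",
]

#: rig mode -> design-space preset name
DESIGN_SPACE_FOR_MODE = {
    "step1": "step1",
    "step2": "step2",
    "step2_im": "step2-im",
    "telescoped": "telescoped",
}

#: rig mode -> rig preset name
RIG_FOR_MODE = {
    "step1": "osat",
    "step2": "osat",
    "step2_im": "osat",
    "telescoped": "telescoped",
}


def _load(name: str) -> dict:
    text = resources.files("flowopt").joinpath("data", name).read_text()
    return yaml.safe_load(text)


def available_presets() -> dict[str, list[str]]:
    return {
        "design_space": sorted(_load("design_spaces.yaml")),
        "rig": sorted(_load("rigs.yaml")),
        "kinetics": sorted(_load("kinetics.yaml")),
    }


def design_space_preset(name: str) -> DesignSpace:
    """Load a named design space (step1, step2, step2-im, telescoped)."""
    spaces = _load("design_spaces.yaml")
    if name not in spaces:
        raise KeyError(f"unknown design-space preset {name!r}; "
                       f"available: {sorted(spaces)}")
    return DesignSpace(VariableSpec(**v) for v in spaces[name])


def rig_preset(name: str) -> RigPreset:
    """Load a named rig preset (osat, telescoped)."""
    rigs = _load("rigs.yaml")
    if name not in rigs:
        raise KeyError(f"unknown rig preset {name!r}; available: "
                       f"{sorted(rigs)}")
    return RigPreset(**rigs[name])


def kinetic_preset(name: str = "paper") -> KineticParams:
    """Load a named kinetic preset (default: the calibrated ``paper`` set)."""
    kins = _load("kinetics.yaml")
    if name not in kins:
        raise KeyError(f"unknown kinetic preset {name!r}; available: "
                       f"{sorted(kins)}")
    return KineticParams(**kins[name])
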