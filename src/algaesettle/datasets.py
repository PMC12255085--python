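"""Packaged reference data: the 14-run sedimentation CCD and cost defaults.

``load_ccd_table()`` returns the complete blocked central-composite dataset
for both species (pH and salinity as factors; settling efficiency in % and
settling time in hours as responses).  The module also exposes the published
uncoded regression surfaces for each response, usable as ground truth for the
response-surface generator.
"""

from __future__ import annotations

import json
from importlib import resources

from .rsm import DEFAULT_FACTORS, DesignTable

__all__ = [
    "load_ccd_table",
    "load_cost_defaults",
    "CS_EFFICIENCY_SURFACE",
    "CS_TIME_SURFACE",
    "MC_EFFICIENCY_SURFACE",
    "MC_TIME_SURFACE",
    "RESPONSES",
]

#: response columns of the packaged CCD table
RESPONSES = ["cs_efficiency_pct", "cs_time_h", "mc_efficiency_pct", "mc_time_h"]

# Published uncoded regression equations (blocks-averaged intercepts).
CS_EFFICIENCY_SURFACE = {
    "b0": 191.18, "pH": -33.79, "salinity": 0.531,
    "pH^2": 2.365, "salinity^2": -0.01581, "pH*salinity": 0.00544,
}
CS_TIME_SURFACE = {
    "b0": -102.57, "pH": 44.68, "salinity": -1.522,
    "pH^2": -3.121, "salinity^2": 0.04334, "pH*salinity": -0.01156,
}
MC_EFFICIENCY_SURFACE = {
    "b0": 208.10, "pH": -42.79, "salinity": 1.076,
    "pH^2": 2.9757, "salinity^2": -0.03137, "pH*salinity": -0.00411,
}
MC_TIME_SURFACE = {
    "b0": -124.83, "pH": 57.49, "salinity": -1.423,
    "pH^2": -4.014, "salinity^2": 0.03794, "pH*salinity": 0.00600,
}


def load_ccd_table() -> DesignTable:
    """The 14-run, two-block CCD with observed responses for both species."""
    from .io import read_design_csv

    with resources.as_file(
        resources.files("algaesettle.data") / "table2.csv"
    ) as path:
        return read_design_csv(path, factors=DEFAULT_FACTORS)


def load_cost_defaults() -> dict:
    """Default harvesting cost parameters (energy, consumables, recoveries)."""
    text = (resources.files("algaesettle.data") / "costs_default.json").read_text()
    return json.loads(text)
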