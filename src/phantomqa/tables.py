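"""Packaged measurement tables and the default criteria configuration.

The CSVs under ``phantomqa/data`` are the published scorecard measurements of
a ring-gantry linac CBCT system benchmarked against the ACR accreditation
phantom (per-protocol metric rows for the head and body phantoms, the
exposure-stability series, and the four-machine comparison).  They are the
inputs to the criteria-only scoring path and to the reproduction analyses.

Note: one published body-phantom uniformity entry contains the typographical
value "8.7r5"; it is stored here as 8.75 (it classifies as a major deviation
either way).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .criteria import CriteriaConfig

METRIC_COLUMNS = [
    "contrast_resolution",
    "spatial_resolution",
    "acrylic",
    "air",
    "bone",
    "polyethylene",
    "water",
    "image_scaling",
    "hu_uniformity",
]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("phantomqa.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_protocol_scorecards() -> pd.DataFrame:
    """Per-protocol metrics for the head and body phantoms (11 protocols each)."""
    return _read_csv("table2_protocols.csv")


def load_exposure_series() -> pd.DataFrame:
    """Pediatric head/abdomen protocols rescanned at four exposure settings."""
    return _read_csv("table3_exposure.csv")


def load_machine_comparison() -> pd.DataFrame:
    """Six protocols compared across four imaging systems."""
    return _read_csv("table4_machines.csv")


def load_default_config() -> CriteriaConfig:
    with resources.files("phantomqa.data").joinpath("acr_criteria.yaml").open("r") as fh:
        return CriteriaConfig.from_dict(yaml.safe_load(fh))
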