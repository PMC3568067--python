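"""Bundled reference datasets.

Two small criteria tables from published cardiomyocyte substrate-supply
studies ship with the package so the efficiency index can be exercised and
cross-checked without running any simulation:

* ``load_baseline_scan_criteria`` — 16 substrate compositions over glucose,
  oleate, acetoacetate and lactate with their oxygen demand (vO2) and total
  substrate uptake (vs) at a 21.6 mmol·min⁻¹·(l cell)⁻¹ ATP demand.
* ``load_perfusion_comparison`` — nine perfused-working-heart substrate
  settings with simulated and experimentally measured (vO2, vs) pairs.

Also bundled: a starter function-test battery targeting the generated core
network (schema-compatible with user-transcribed batteries).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .funtest import FunctionTest


def _data_path(name: str):
    return resources.files(__package__) / "data" / name


def load_baseline_scan_criteria() -> pd.DataFrame:
    """16-row criteria table (β shares, vO2, vs) for the four-substrate scan."""
    with resources.as_file(_data_path("baseline_scan_criteria.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_perfusion_comparison() -> pd.DataFrame:
    """Nine perfusion settings with simulated and experimental (vO2, vs) pairs."""
    with resources.as_file(_data_path("perfusion_comparison.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_core_battery() -> list[FunctionTest]:
    """Starter function-test battery for the generated core network."""
    import json

    text = _data_path("core_function_battery.json").read_text()
    return [FunctionTest(**t) for t in json.loads(text)]
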