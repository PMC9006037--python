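"""Plain-text (YAML) configuration files for runs and custom sweeps.

A run config is a flat key-value file mirroring the CLI flags::

    n_males0: 30
    n_females0: 30
    male_mortality: 0.4
    female_mortality: 0.1
    trait_mode: fixed_proportion
    trait_level: 1/3          # fractions may be quoted strings

A sweep config replaces the scalar mortality/level with grids::

    scenario_label: my_sweep
    male_mortalities: [0.1, 0.4, 0.7]
    female_mortality: equal   # or a number
    trait_mode: fixed_number
    trait_levels: [3, 6, 9]

All values are echoed into every output for provenance.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Union

import yaml

from .cohort import ScenarioConfig
from .sweep import SweepSpec

__all__ = ["parse_level", "load_run_config", "load_sweep_config"]


def parse_level(value) -> Union[int, float, Fraction]:
    """Parse a trait level: int, float, or a fraction string like '1/3'."""
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, (int, float, Fraction)):
        return value
    raise ValueError(f"cannot parse trait level {value!r}")


def _load(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return data


def load_run_config(path, **overrides) -> ScenarioConfig:
    """Read a single-run config file; keyword overrides win over the file."""
    data = _load(path)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return ScenarioConfig(
        n_males0=int(data.get("n_males0", 30)),
        n_females0=int(data.get("n_females0", 30)),
        male_mortality=float(data["male_mortality"]),
        female_mortality=float(data["female_mortality"]),
        trait_mode=str(data["trait_mode"]),
        trait_level=parse_level(data["trait_level"]),
        scenario_label=str(data.get("scenario_label", Path(path).stem)),
    )


def load_sweep_config(path) -> SweepSpec:
    """Read a custom-grid sweep config file."""
    data = _load(path)
    fem = data.get("female_mortality", "equal")
    return SweepSpec(
        scenario_label=str(data.get("scenario_label", Path(path).stem)),
        male_mortalities=tuple(float(m) for m in data["male_mortalities"]),
        trait_mode=str(data["trait_mode"]),
        trait_levels=tuple(parse_level(v) for v in data["trait_levels"]),
        female_mortality=None if fem == "equal" else float(fem),
        n_males0=int(data.get("n_males0", 30)),
        n_females0=int(data.get("n_females0", 30)),
    )
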