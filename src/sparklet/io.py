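"""Tables and configuration files.

Event tables and FOV summaries are plain CSV with units embedded in the
column names (``amplitude_dff``, ``attack_ms``, ``spread_um2``);
configuration is YAML mirroring :class:`~sparklet.simulate.SimConfig`
and the pipeline parameters.  Both round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig

__all__ = [
    "write_table",
    "read_table",
    "load_sim_config",
    "save_sim_config",
    "load_yaml",
]


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML config {path}: {exc}") from exc
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    return doc


def load_sim_config(path: str | Path, **overrides) -> SimConfig:
    """Read a simulation config; keyword overrides win over the file."""
    doc = load_yaml(path)
    doc.update(overrides)
    return SimConfig.from_dict(doc)


def save_sim_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
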