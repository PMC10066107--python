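"""Product presets: release + disposition parameter sets keyed by product name.

The presets ship as a human-readable YAML file (``presets.yaml``) so that the
parameter provenance is inspectable and users can point the loaders at their
own files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .convolve import DispositionParams
from .release import ReleaseParams

__all__ = ["ProductPreset", "load_presets", "get_preset", "PRESET_NAMES"]

PRESET_NAMES = ("ER", "PP1M", "PP3M", "PP12M")


@dataclass(frozen=True)
class ProductPreset:
    """A named product: release function, disposition, study doses, interval."""

    name: str
    release: ReleaseParams
    disposition: DispositionParams
    doses_mg: tuple[float, ...]
    interval_h: float
    schedule_h: tuple[float, ...]


def _parse(name: str, raw: dict) -> ProductPreset:
    rel = ReleaseParams(**raw["release"])
    disp = DispositionParams(**raw["disposition"])
    return ProductPreset(
        name=name,
        release=rel,
        disposition=disp,
        doses_mg=tuple(float(x) for x in raw["doses_mg"]),
        interval_h=float(raw["interval_h"]),
        schedule_h=tuple(float(x) for x in raw["schedule_h"]),
    )


def load_presets(path: str | Path | None = None) -> dict[str, ProductPreset]:
    """Load all product presets from YAML (the packaged file by default)."""
    if path is None:
        text = resources.files("convopk").joinpath("presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: _parse(name, entry) for name, entry in raw.items()}


def get_preset(name: str, path: str | Path | None = None) -> ProductPreset:
    """Look up one preset by (case-insensitive) product name."""
    presets = load_presets(path)
    for key, preset in presets.items():
        if key.lower() == name.lower():
            return preset
    raise KeyError(f"unknown product preset {name!r}; available: {sorted(presets)}")
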