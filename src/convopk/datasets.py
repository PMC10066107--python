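"""Concentration-time datasets: container, CSV I/O and synthetic generation.

The on-disk format is a plain CSV with the required header columns
``PRODUCT, OCC, DOSE_MG, TIME_H, CONC_NG_ML`` (extra columns are preserved
untouched).  Each occasion (``OCC``) maps to exactly one dose history — by
default a single dose of ``DOSE_MG`` mg at t = 0.

Synthetic datasets emulate the mean concentration curves per dose group of
the product studies: noise-free profiles are simulated from a product preset
through the convolution engine and multiplied by ``1 + eps`` with
``eps ~ N(0, CV^2)`` (proportional error), deterministically per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .convolve import DoseEvent, simulate_ode
from .presets import ProductPreset, get_preset

__all__ = [
    "REQUIRED_COLUMNS",
    "PKDataset",
    "SynthSpec",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("PRODUCT", "OCC", "DOSE_MG", "TIME_H", "CONC_NG_ML")


@dataclass
class PKDataset:
    """Long-format concentration-time records grouped by product and occasion.

    Parameters
    ----------
    frame : pandas.DataFrame
        Must carry the :data:`REQUIRED_COLUMNS`; extra columns ride along.
    regimens : dict, optional
        Optional per-occasion dose histories as ``{occ: [DoseEvent, ...]}``.
        Occasions without an entry are single doses of ``DOSE_MG`` at t = 0.
    metadata : dict
        Free-form provenance (preset, seed, CV, ...).
    """

    frame: pd.DataFrame
    regimens: dict[object, list[DoseEvent]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing required column(s): {missing}")
        if (self.frame["TIME_H"] < 0).any():
            raise ValueError("TIME_H must be >= 0")
        if (self.frame["CONC_NG_ML"] < 0).any():
            raise ValueError("CONC_NG_ML must be >= 0")
        ndose = self.frame.groupby("OCC")["DOSE_MG"].nunique()
        bad = ndose[ndose > 1]
        if len(bad):
            raise ValueError(
                f"each occasion must map to one dose amount; violated by OCC {list(bad.index)}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_occasions(self) -> int:
        return self.frame["OCC"].nunique()

    def doses_for(self, occ: object) -> list[DoseEvent]:
        """Dose history of an occasion (single dose at t = 0 unless overridden)."""
        if occ in self.regimens:
            return list(self.regimens[occ])
        amount = float(self.frame.loc[self.frame["OCC"] == occ, "DOSE_MG"].iloc[0])
        return [DoseEvent(time=0.0, amount=amount)]

    def drop_predose_zeros(self) -> "PKDataset":
        """Remove rows with conc <= 0 before the first dose of their occasion."""
        keep = np.ones(len(self.frame), dtype=bool)
        for occ, g in self.frame.groupby("OCC"):
            first = min(e.time for e in self.doses_for(occ))
            bad = (g["CONC_NG_ML"] <= 0) & (g["TIME_H"] <= first)
            keep[g.index[bad]] = False
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d pre-dose zero-concentration record(s)", n_drop)
        return PKDataset(
            self.frame.loc[keep].reset_index(drop=True),
            regimens=self.regimens,
            metadata=self.metadata,
        )


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic mean-profile dataset.

    Defaults mirror the source study designs: the preset's published dose
    groups, its product-appropriate sampling schedule, 5 % proportional
    noise, one occasion per dose group.
    """

    preset: str
    doses_mg: tuple[float, ...] | None = None
    schedule_h: tuple[float, ...] | None = None
    cv: float = 0.05
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"CV must be >= 0, got {self.cv}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_dataset(spec: SynthSpec, preset: ProductPreset | None = None) -> PKDataset:
    """Simulate a noisy mean-profile dataset from a product preset.

    One simulation per unit dose is scaled across dose groups (the system is
    linear in dose), then proportional Gaussian noise is applied.
    """
    if preset is None:
        preset = get_preset(spec.preset)
    doses = spec.doses_mg if spec.doses_mg is not None else preset.doses_mg
    schedule = np.asarray(
        spec.schedule_h if spec.schedule_h is not None else preset.schedule_h, float
    )
    if np.any(schedule < 0):
        raise ValueError("sampling schedule must not contain times before t = 0")

    unit = simulate_ode(
        DoseEvent(0.0, 1.0), preset.release, preset.disposition, schedule
    )
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        for dose in doses:
            pred = dose * unit.conc
            eps = rng.normal(0.0, spec.cv, size=pred.shape) if spec.cv > 0 else 0.0
            conc = pred * (1.0 + eps)
            occ = f"{preset.name}-{dose:g}mg" + (f"-rep{rep}" if spec.n_replicates > 1 else "")
            for t, c in zip(schedule, conc):
                rows.append((preset.name, occ, dose, t, max(c, 0.0)))
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    meta = {
        "preset": preset.name,
        "seed": spec.seed,
        "cv": spec.cv,
        "doses_mg": list(doses),
        "n_replicates": spec.n_replicates,
    }
    return PKDataset(frame, metadata=meta)


def read_dataset(path: str | Path) -> PKDataset:
    """Read a dataset CSV, validating columns, numeric cells and duplicates.

    Parse problems are reported with 1-based data line numbers (header is
    line 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in ("DOSE_MG", "TIME_H", "CONC_NG_ML"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric value in column {col} at data line(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        frame[col] = coerced
    dup = frame.duplicated(subset=["OCC", "TIME_H"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in frame.index[dup][:5]]
        raise ValueError(
            f"{path.name}: duplicated (OCC, TIME_H) rows at data line(s) {lines}"
        )
    return PKDataset(frame)


def write_dataset(ds: PKDataset, path: str | Path) -> None:
    """Write a dataset to CSV (metadata as '#' comment lines, full precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in ds.metadata.items():
            fh.write(f"# {k}: {v}\n")
        ds.frame.to_csv(fh, index=False, float_format="%.17g")
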