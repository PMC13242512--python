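"""Reading and writing assay event tables, spectra and fit results.

File formats
------------
Event CSV: one row per droplet per cycle, columns ``droplet_id``,
``cycle``, ``volume_uL``, ``concentration_mg_per_mL``,
``freezing_temp_C``, ``frozen`` (0/1).  Volumes are µL on disk and mL
in memory.  Spectra: CSV with ``temperature_C`` and ``value``.  Fit
results: flat ``key = value`` text files.  Temperatures are written
with 3 decimals; in-memory computation is unrounded.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from icespec.assay import DropletAssay
from icespec.hub import (
    GaussianComponent,
    HUBFitResult,
    UnderlyingDistribution,
)

__all__ = [
    "read_events",
    "write_events",
    "write_spectrum",
    "read_spectrum",
    "write_fit_result",
    "read_fit_result",
    "load_config",
]

EVENT_FILE_COLUMNS = (
    "droplet_id",
    "cycle",
    "volume_uL",
    "concentration_mg_per_mL",
    "freezing_temp_C",
    "frozen",
)


def read_events(path: str | Path) -> DropletAssay:
    """Load and validate an event CSV into a :class:`DropletAssay`.

    Malformed rows are reported with their line numbers (header is
    line 1).  Droplet volume and concentration must be constant within
    a file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in EVENT_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")

    bad_rows = []
    temps = pd.to_numeric(df["freezing_temp_C"], errors="coerce")
    for idx in df.index[temps.isna() & df["frozen"].astype(bool)]:
        bad_rows.append(idx + 2)  # +1 header, +1 zero-based
    if bad_rows:
        raise ValueError(
            f"{path.name}: non-numeric freezing_temp_C on lines {bad_rows}"
        )
    df["freezing_temp_C"] = temps

    dup = df.duplicated(subset=["droplet_id", "cycle"])
    if dup.any():
        lines = [i + 2 for i in df.index[dup]]
        raise ValueError(
            f"{path.name}: duplicate (droplet_id, cycle) on lines {lines}"
        )

    for col in ("volume_uL", "concentration_mg_per_mL"):
        if df[col].nunique() != 1:
            raise ValueError(f"{path.name}: column {col} must be constant")

    volume_mL = float(df["volume_uL"].iloc[0]) / 1000.0
    concentration = float(df["concentration_mg_per_mL"].iloc[0])

    frozen_temps = df.loc[df["frozen"].astype(bool), "freezing_temp_C"]
    ramp_start = max(0.0, float(np.ceil(frozen_temps.max())) if len(frozen_temps) else 0.0)
    ramp_end = min(-30.0, float(np.floor(frozen_temps.min())) if len(frozen_temps) else -30.0)

    events = df[["droplet_id", "cycle", "freezing_temp_C", "frozen"]].copy()
    return DropletAssay(
        events=events,
        droplet_volume=volume_mL,
        mass_concentration=concentration,
        ramp_start=ramp_start,
        ramp_end=ramp_end,
    )


def write_events(assay: DropletAssay, path: str | Path) -> None:
    """Write an assay back to the event CSV schema (3-decimal temps)."""
    df = assay.events.copy()
    df["volume_uL"] = assay.droplet_volume * 1000.0
    df["concentration_mg_per_mL"] = assay.mass_concentration
    df = df[list(EVENT_FILE_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.3f")


def write_spectrum(
    path: str | Path, temperatures: np.ndarray, values: np.ndarray
) -> None:
    """Write a (temperature, value) spectrum CSV."""
    pd.DataFrame(
        {"temperature_C": np.round(temperatures, 3), "value": values}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["temperature_C"].to_numpy(float), df["value"].to_numpy(float)


def write_fit_result(result: HUBFitResult, path: str | Path) -> None:
    """Serialize a fit result as a flat key-value text file."""
    lines = []
    for i, comp in enumerate(result.distribution.components, start=1):
        lines.append(f"component_{i}_weight = {comp.weight!r}")
        lines.append(f"component_{i}_mode_C = {comp.t_mode!r}")
        lines.append(f"component_{i}_spread_C = {comp.spread!r}")
    lines.append(f"n_tot_per_mg = {result.distribution.n_tot!r}")
    lines.append(f"mse = {result.mse!r}")
    lines.append(f"p = {result.p}")
    lines.append(f"seed = {result.seed}")
    lines.append(f"n_restarts = {result.n_restarts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fit_result(path: str | Path) -> HUBFitResult:
    """Inverse of :func:`write_fit_result`."""
    kv: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = float(value.strip())
    p = int(kv["p"])
    comps = tuple(
        GaussianComponent(
            weight=kv[f"component_{i}_weight"],
            t_mode=kv[f"component_{i}_mode_C"],
            spread=kv[f"component_{i}_spread_C"],
        )
        for i in range(1, p + 1)
    )
    dist = UnderlyingDistribution(components=comps, n_tot=kv["n_tot_per_mg"])
    return HUBFitResult(
        distribution=dist,
        mse=kv["mse"],
        p=p,
        seed=int(kv["seed"]),
        n_restarts=int(kv["n_restarts"]),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a TOML configuration file into a plain dict."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
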