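"""CSV / JSON / YAML plumbing shared by the library and the CLI.

Schemas
-------
dose-response CSV   effector,conc_uM,response,response_kind,replicate
time-course CSV     time_min,analyte,conc_uM   (long format; s0 and enzyme
                    concentration travel in a sidecar config)
isotherm CSV        injection,volume_uL,heat_uJ
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay_rates import TimeCourse
from .itc_binding import Isotherm, ITCProtocol
from .kinetic_model import DoseResponseTable

__all__ = [
    "read_dose_response",
    "write_dose_response",
    "read_time_course",
    "write_time_course",
    "read_isotherm",
    "write_isotherm",
    "protocol_from_config",
    "load_config",
    "write_json",
]

DOSE_COLUMNS = ["effector", "conc_uM", "response", "response_kind", "replicate"]


def read_dose_response(path: str | Path) -> DoseResponseTable:
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns and c != "replicate"]
    if missing or df.empty:
        raise ValueError(
            f"dose-response CSV {path} missing columns {missing}"
            if missing else f"dose-response CSV {path} is empty"
        )
    return DoseResponseTable.from_frame(df)


def write_dose_response(table: DoseResponseTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_time_course(path: str | Path, s0: float, enzyme: float) -> TimeCourse:
    df = pd.read_csv(path)
    need = {"time_min", "analyte", "conc_uM"}
    if not need.issubset(df.columns) or df.empty:
        raise ValueError(f"time-course CSV {path} must have columns {sorted(need)}")
    wide = df.pivot_table(index="time_min", columns="analyte", values="conc_uM")
    wide = wide.sort_index()
    return TimeCourse(
        times=wide.index.to_numpy(float),
        products={c: wide[c].to_numpy(float) for c in wide.columns},
        s0=s0,
        enzyme_conc=enzyme,
    )


def write_time_course(tc: TimeCourse, path: str | Path) -> None:
    rows = []
    for analyte, series in tc.products.items():
        for t, c in zip(tc.times, series):
            rows.append({"time_min": t, "analyte": analyte, "conc_uM": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_isotherm(path: str | Path) -> tuple[Isotherm, np.ndarray]:
    """Returns the isotherm (molar ratios filled later from the protocol)
    together with the per-injection volumes."""
    df = pd.read_csv(path)
    need = {"injection", "volume_uL", "heat_uJ"}
    if not need.issubset(df.columns) or df.empty:
        raise ValueError(f"isotherm CSV {path} must have columns {sorted(need)}")
    df = df.sort_values("injection")
    iso = Isotherm(
        heats=df["heat_uJ"].to_numpy(float),
        molar_ratios=np.zeros(len(df)),
    )
    return iso, df["volume_uL"].to_numpy(float)


def write_isotherm(iso: Isotherm, protocol: ITCProtocol, path: str | Path) -> None:
    vols = protocol.injection_volumes
    if protocol.discard_first:
        vols = vols[1:]
    pd.DataFrame(
        {
            "injection": np.arange(1, len(iso.heats) + 1),
            "volume_uL": vols[: len(iso.heats)],
            "heat_uJ": iso.heats,
        }
    ).to_csv(path, index=False)


def protocol_from_config(cfg: dict) -> ITCProtocol:
    n = int(cfg.get("n_injections", 25))
    vol = float(cfg.get("injection_volume_uL", 1.96))
    return ITCProtocol(
        cell_volume=float(cfg.get("cell_volume_uL", 170.0)),
        cell_conc=float(cfg.get("cell_conc_uM", 45.0)),
        syringe_conc=float(cfg.get("syringe_conc_uM", 600.0)),
        injection_volumes=tuple(cfg["injection_volumes_uL"])
        if "injection_volumes_uL" in cfg
        else (vol,) * n,
        discard_first=bool(cfg.get("discard_first", False)),
    )


def load_config(path: str | Path) -> dict:
    """YAML (JSON is a YAML subset) config loader."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_json(obj: dict, path: str | Path | None) -> str:
    text = json.dumps(obj, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
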