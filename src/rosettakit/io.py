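"""Readers, writers and run manifests shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

import rosettakit
from rosettakit.descriptors import DESCRIPTOR_NAMES
from rosettakit.segmentation import BinaryMask

REQUIRED_TABLE_COLUMNS = ("plant_id", "ecotype", "das")


def read_descriptor_table(path: str | Path, require_descriptors: bool = True) -> pd.DataFrame:
    """Load and validate a long-format descriptor CSV.

    Requires ``plant_id``, ``ecotype``, ``das`` and (by default) all 20
    descriptor columns; ``das`` is coerced to numeric days, unknown
    columns are preserved, and duplicate (plant_id, das) rows are an
    error.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in table.columns]
    if require_descriptors:
        missing += [c for c in DESCRIPTOR_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    table["das"] = pd.to_numeric(table["das"], errors="raise")
    dup = table.duplicated(subset=["plant_id", "das"])
    if dup.any():
        first = table.loc[dup.idxmax(), ["plant_id", "das"]].tolist()
        raise ValueError(f"duplicate (plant_id, das) rows, e.g. {first}")
    eco_per_plant = table.groupby("plant_id")["ecotype"].nunique()
    if (eco_per_plant > 1).any():
        bad = eco_per_plant[eco_per_plant > 1].index.tolist()
        raise ValueError(f"plant(s) with inconsistent ecotype label: {bad}")
    return table


def write_results(obj, path: str | Path, force: bool = False) -> Path:
    """Write a DataFrame as CSV or a mapping as JSON; refuses to overwrite.

    CSV output keeps the frame's column order and omits the index so the
    file round-trips losslessly through :func:`read_descriptor_table`.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True / --force to overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_mask(path: str | Path, scale_factor: float = 1.0) -> BinaryMask:
    """Read an 8-bit mask image (non-zero = foreground)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(grid=arr > 0, scale_factor=scale_factor)


def write_mask(mask: BinaryMask, path: str | Path, force: bool = False) -> Path:
    """Write a mask as an 8-bit PNG (foreground 255, background 0)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists (pass force=True / --force to overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def read_colour_samples(path: str | Path) -> np.ndarray:
    """CSV of R,G,B rows (optional header) to an (n, 3) float array."""
    frame = pd.read_csv(path, header=None)
    if frame.iloc[0].astype(str).str.contains("[A-Za-z]").any():
        frame = frame.iloc[1:]
    arr = frame.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{path}: expected rows of R,G,B values")
    return arr


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    started: str = ""
    finished: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = rosettakit.__version__
    python: str = platform.python_version()

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def record_file(self, role: str, path: str | Path, output: bool = False) -> None:
        path = Path(path)
        digest = ""
        if path.exists():
            digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        (self.outputs if output else self.inputs)[role] = {
            "path": str(path),
            "sha256_16": digest,
        }

    def write(self, path: str | Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path
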