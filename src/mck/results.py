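"""Writing stage outputs with provenance sidecars.

Tabular outputs go to CSV, summaries to JSON, image outputs to TIFF. Every
artifact set carries a provenance record (run-config hash, seed, package
version) so a rerun with the same inputs is byte-identical and traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contact import ContactSeries
from .linescan import ColocResult, ShiftCurve
from .tracking import Kymograph, MsdFit, Track, tracks_to_csv


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_collision(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")


def write_provenance(out_dir: Path, name: str, config_dict: dict,
                     seed: int) -> Path:
    from . import __version__
    path = out_dir / f"{name}.provenance.json"
    with open(path, "w") as fh:
        json.dump({"config_hash": config_hash(config_dict), "seed": seed,
                   "mck_version": __version__}, fh, indent=2, sort_keys=True)
    return path


def write_results(result, out_dir: str | Path, name: str | None = None,
                  config_dict: dict | None = None, seed: int = 0,
                  overwrite: bool = False) -> dict[str, Path]:
    """Write a stage output to ``out_dir``; returns the written paths.

    Dispatches on the result type: ShiftCurve and ContactSeries become CSV +
    JSON summary; ColocResult and MsdFit become JSON; track lists become
    CSV; Kymographs become TIFF + CSV; DataFrames become CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def target(stem, suffix):
        path = out_dir / f"{stem}{suffix}"
        _check_collision(path, overwrite)
        return path

    if isinstance(result, ShiftCurve):
        stem = name or "shiftcurve"
        csv = target(stem, ".csv")
        result.to_dataframe().to_csv(csv, index=False)
        js = target(stem, ".json")
        with open(js, "w") as fh:
            json.dump({"step_nm": result.step,
                       "n_linescans": result.n_linescans,
                       "confidence": result.confidence,
                       "threshold_nm": result.threshold_distance,
                       "n_excluded": len(result.exclusions)},
                      fh, indent=2, sort_keys=True)
        files = {"csv": csv, "json": js}
    elif isinstance(result, ContactSeries):
        stem = name or "contact"
        csv = target(stem, ".csv")
        result.to_dataframe().to_csv(csv, index=False)
        js = target(stem, ".json")
        with open(js, "w") as fh:
            json.dump(result.summary(), fh, indent=2, sort_keys=True)
        files = {"csv": csv, "json": js}
    elif isinstance(result, ColocResult):
        stem = name or "coloc"
        js = target(stem, ".json")
        with open(js, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        files = {"json": js}
    elif isinstance(result, MsdFit):
        stem = name or "msd_fit"
        csv = target(stem, ".csv")
        pd.DataFrame({"lag_s": result.lags,
                      "msd_nm2": result.msd}).to_csv(csv, index=False)
        js = target(stem, ".json")
        with open(js, "w") as fh:
            json.dump(result.summary(), fh, indent=2, sort_keys=True)
        files = {"csv": csv, "json": js}
    elif isinstance(result, Kymograph):
        stem = name or "kymograph"
        tif = target(stem, ".tiff")
        tifffile.imwrite(tif, result.values.astype(np.float32))
        csv = target(stem, ".csv")
        result.to_dataframe().to_csv(csv, index=False)
        files = {"tiff": tif, "csv": csv}
    elif isinstance(result, (list, tuple)) and result \
            and isinstance(result[0], Track):
        stem = name or "tracks"
        csv = target(stem, ".csv")
        tracks_to_csv(list(result), csv)
        files = {"csv": csv}
    elif isinstance(result, pd.DataFrame):
        stem = name or "table"
        csv = target(stem, ".csv")
        result.to_csv(csv, index=False)
        files = {"csv": csv}
    elif isinstance(result, dict):
        stem = name or "summary"
        js = target(stem, ".json")
        with open(js, "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, default=float)
        files = {"json": js}
    else:
        raise TypeError(f"no writer for result type {type(result).__name__}")

    if config_dict is not None:
        files["provenance"] = write_provenance(out_dir, stem, config_dict,
                                               seed)
    return files
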