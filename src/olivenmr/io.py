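"""File I/O: two-column spectrum text files and bucket-table CSVs.

A spectrum file is two whitespace- or tab-separated numeric columns
(ppm, intensity); it is stored descending but read in either order. A bucket
table is a CSV with the metadata columns sample_id, cultivar, harvest,
plant_id followed by bucket columns headed by the 2-decimal center shifts,
plus a JSON sidecar recording scheme, state and normalization constant.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import BucketScheme, BucketTable, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_bucket_table",
    "write_bucket_table",
]

METADATA_COLUMNS = ["sample_id", "cultivar", "harvest", "plant_id"]


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (ppm, intensity) text file.

    Ascending input is re-sorted to descending ppm; the sample id is the
    filename stem.
    """
    path = Path(path)
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path.name}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path.name}: line {lineno}: non-numeric value") from exc
    if len(ppm) < 2:
        raise ValueError(f"{path.name}: fewer than 2 data points")
    ppm_arr = np.asarray(ppm)
    inten_arr = np.asarray(intensity)
    order = np.argsort(ppm_arr)[::-1]
    return Spectrum(ppm=ppm_arr[order], intensity=inten_arr[order], sample_id=path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as tab-separated (ppm, intensity), descending ppm."""
    data = np.column_stack([spectrum.ppm, spectrum.intensity])
    np.savetxt(path, data, delimiter="\t", fmt="%.10g")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_bucket_table(table: BucketTable, path: str | Path) -> None:
    """Write a bucket table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    meta = {
        "state": table.state,
        "normalization_target": table.normalization_target,
        "scheme": (
            {
                "region_high": table.scheme.region_high,
                "region_low": table.scheme.region_low,
                "width": table.scheme.width,
                "exclusions": [list(e) for e in table.scheme.exclusions],
            }
            if table.scheme is not None
            else None
        ),
        "scaling_params": (
            {k: v.tolist() for k, v in table.scaling_params.items()}
            if table.scaling_params is not None
            else None
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_bucket_table(path: str | Path) -> BucketTable:
    """Read a bucket-table CSV (and its sidecar, when present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing metadata column(s) {missing}")
    bucket_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    try:
        centers = np.array([float(c) for c in bucket_cols])
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric bucket column header") from exc
    if centers.size >= 2 and not np.all(np.diff(centers) < 0):
        raise ValueError(f"{path.name}: bucket labels are not strictly decreasing")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path.name}: duplicate sample_id {dup.iloc[0]!r}")
    state = "raw"
    target = None
    scheme = None
    scaling = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        state = meta.get("state", "raw")
        target = meta.get("normalization_target")
        if meta.get("scheme"):
            s = meta["scheme"]
            scheme = BucketScheme(
                region_high=s["region_high"],
                region_low=s["region_low"],
                width=s["width"],
                exclusions=tuple(tuple(e) for e in s["exclusions"]),
            )
        if meta.get("scaling_params"):
            scaling = {k: np.asarray(v) for k, v in meta["scaling_params"].items()}
    return BucketTable(
        values=df[bucket_cols].to_numpy(dtype=float),
        centers=centers,
        metadata=df[METADATA_COLUMNS].copy(),
        state=state,
        normalization_target=target,
        scaling_params=scaling,
        scheme=scheme,
    )
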