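"""Readers and writers for the pipeline's plain-text artifacts.

All tables travel as CSV (grids with a shape header comment, occurrences
as sparse species/cell triplets), model summaries and truth records as
JSON.  A manifest lists every artifact with its SHA-256 checksum so a run
can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from climspace.grid import GeoGrid
from climspace.diversity import PresenceAbsence

logger = logging.getLogger(__name__)


def load_variable_stack(paths: list) -> GeoGrid:
    """Assemble a GeoGrid from per-variable cell tables sharing one grid.

    Each CSV needs columns ``cell_id, row, col, lon, lat, area_km2`` plus
    exactly one variable column; files must agree cell-for-cell on the
    grid columns (mismatches fail naming the offending file).  Cells
    missing from any file (no valid value for that variable) are dropped,
    so the result holds only cells where every variable is valid.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    core = ["cell_id", "row", "col", "lon", "lat", "area_km2"]
    merged = None
    shape = None
    var_names = []
    for p in paths:
        meta, df = _read_with_header(p)
        var_cols = [c for c in df.columns if c not in core]
        if len(var_cols) != 1:
            raise ValueError(f"{p}: expected exactly one variable column, got {var_cols}")
        var_names.append(var_cols[0])
        df = df.dropna(subset=var_cols)
        this_shape = (int(meta["n_rows"]), int(meta["n_cols"]))
        if shape is None:
            shape = this_shape
            merged = df
        else:
            if this_shape != shape:
                raise ValueError(
                    f"grid mismatch: {p} is {this_shape}, expected {shape} "
                    f"(from {paths[0]})"
                )
            common = merged.merge(df[["cell_id"] + var_cols], on="cell_id", how="inner")
            check = merged.set_index("cell_id").loc[common["cell_id"], core[1:]]
            other = df.set_index("cell_id").loc[common["cell_id"], core[1:]]
            if not np.allclose(check.to_numpy(), other.to_numpy()):
                raise ValueError(f"grid coordinate mismatch between {paths[0]} and {p}")
            merged = common
    return GeoGrid(
        table=merged.reset_index(drop=True),
        n_rows=shape[0],
        n_cols=shape[1],
        var_names=var_names,
    )


def _read_with_header(path: Path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "n_rows" not in meta or "n_cols" not in meta:
        raise ValueError(f"{path}: missing grid-shape header comment")
    return meta, df


def load_pam(path, grid: GeoGrid | None = None, strict: bool = True) -> PresenceAbsence:
    """Read a sparse triplet occurrence CSV (species_id, cell_id).

    Duplicates are collapsed (count logged).  With a grid given,
    occurrences in unknown cells either fail (strict) or are dropped with
    a warning (lenient).
    """
    pam = PresenceAbsence.from_csv(path)
    if grid is not None:
        known = set(int(c) for c in grid.cell_ids)
        mask = pam.triplets["cell_id"].isin(known)
        if not mask.all():
            bad = pam.triplets.loc[~mask, "cell_id"].unique()
            if strict:
                raise ValueError(
                    f"{path}: occurrences in unknown cells: {bad[:10].tolist()}"
                )
            logger.warning("dropping %d occurrences in unknown cells", (~mask).sum())
            pam = PresenceAbsence(triplets=pam.triplets[mask].reset_index(drop=True))
    return pam


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config_dict: dict, extra: dict | None = None) -> Path:
    """List every artifact in the output directory with its checksum."""
    import climspace

    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": climspace.__version__,
        "config": config_dict,
        "files": {
            str(p.relative_to(outdir)): sha256_of(p) for p in files
        },
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    write_json(manifest, path)
    return path
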