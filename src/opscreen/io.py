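"""Shared file formats.

Images travel as OME-TIFF (cycle/channel axes tagged), label masks as 16-bit
integer TIFF, barcode lookups as TSV, tabular outputs as Parquet with CSV
mirrors, and ground truth / reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stitching import TileImage


def write_stack(path, stack: np.ndarray, axes: str = "CTYX" ) -> None:
    """OME-TIFF with tagged axes; ``stack`` is (cycle, channel, H, W)."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     ome=True, metadata={"axes": "TCYX"})


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[None]
    return arr


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def write_tiles(outdir, tiles: list[TileImage]) -> None:
    """One OME-TIFF per tile plus a stage-position TSV (tile_id, cycle, y, x)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tiles:
        name = f"tile_{t.tile_id}_cycle{t.cycle}.ome.tif"
        tifffile.imwrite(str(outdir / name), t.pixels.astype(np.float32),
                         ome=True, metadata={"axes": "CYX"})
        rows.append({"tile_id": t.tile_id, "cycle": t.cycle,
                     "y": t.stage_position[0], "x": t.stage_position[1],
                     "file": name})
    pd.DataFrame(rows).to_csv(outdir / "positions.tsv", sep="\t", index=False)


def read_tiles(indir) -> list[TileImage]:
    indir = Path(indir)
    pos = pd.read_csv(indir / "positions.tsv", sep="\t")
    tiles = []
    for _, r in pos.iterrows():
        px = tifffile.imread(str(indir / r["file"]))
        tiles.append(TileImage(pixels=px, tile_id=str(r["tile_id"]),
                               cycle=int(r["cycle"]),
                               stage_position=(float(r["y"]), float(r["x"]))))
    return tiles


def write_lookup(path, lookup: pd.DataFrame) -> None:
    lookup.to_csv(path, sep="\t", index=False)


def read_lookup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, table: pd.DataFrame, index: bool = False) -> None:
    """Parquet next to a CSV mirror with the same stem."""
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=index)
        table.to_csv(path.with_suffix(".csv"), index=index)
    else:
        table.to_csv(path, index=index)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_layout(path, layout) -> None:
    rows = [{"cycle": c, "tile_id": t, "y": p[0], "x": p[1]}
            for (c, t), p in sorted(layout.positions.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_report(path, graph) -> None:
    rows = []
    for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
        rows.append({"node_a": f"{u[0]}/{u[1]}", "node_b": f"{v[0]}/{v[1]}",
                     "dy": d["offset"][0], "dx": d["offset"][1],
                     "ncc": d.get("ncc", float("nan")), "kind": d["kind"]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
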