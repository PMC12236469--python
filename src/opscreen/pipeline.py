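"""End-to-end orchestration on synthetic screens.

``simulate_screen`` builds one coherent synthetic experiment — a tiled
multi-cycle, multi-channel acquisition of a field of cells whose rolonies
encode known variants — and ``run_pipeline`` pushes it through every stage:
stitch -> composite -> read calling -> cell genotyping -> population filters
-> feature table -> profiles -> scores -> clustering, writing artifacts and
a deterministic manifest.  Because the screen is synthetic the manifest can
also record accuracy against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .config import RunConfig
from .simulate import (GridTruth, RolonyTruth, FeatureTableTruth, make_barcode_lookup,
                       make_cell_mask, make_feature_table, make_rolony_stack,
                       lookup_read_strings, _textured_scene, DEFAULT_CHANNEL_MAP)
from .stitching import TileImage, stitch, composite_cycle, layout_rms_error
from .readcall import call_stack, reads_table
from .genotype import genotype_cells, apply_population_filters
from .profiles import build_profiles
from .scores import impact_scores, ks_feature_tests, landmark_calls
from .embedding import pca_reduce, knn_graph, louvain_cluster


@dataclass
class ScreenTruth:
    grid: GridTruth
    rolonies: RolonyTruth
    lookup: pd.DataFrame
    mask: np.ndarray
    cell_variant: dict[int, str]
    tiles: list[TileImage]
    feature_truth: FeatureTableTruth


def simulate_screen(n_rows: int = 3, n_cols: int = 3, n_cycles: int = 8,
                    n_variants: int = 12, n_synonymous: int = 3,
                    n_cells: int = 70, rolonies_per_cell: int = 3,
                    cell_radius: float = 11.0, snr: float = 8.0,
                    seed: int = 0, dual: bool = False) -> ScreenTruth:
    """One coherent synthetic screen with full generating truth.

    Cells are disks scattered over the stitched scene; each cell carries one
    variant barcode expressed by a handful of rolonies near its center.  The
    image stack is texture (cell bodies, in all channels) plus per-cycle
    rolony channel signal plus tile noise, cropped into a jittered grid.
    """
    rng = np.random.default_rng(seed)
    grid = GridTruth(n_rows=n_rows, n_cols=n_cols, n_cycles=n_cycles,
                     snr=min(snr, 6.0), seed=seed)
    H, W = grid.scene_shape
    length = n_cycles // 2 if dual else n_cycles
    lookup = make_barcode_lookup(n_variants, length, min_distance=3,
                                 n_barcodes_per_variant=1, seed=seed, dual=dual,
                                 n_synonymous=n_synonymous)
    read_strings = lookup_read_strings(lookup)

    # cells: rejection-sampled disk centers, one variant each
    centers = []
    margin = cell_radius + 6
    tries = 0
    while len(centers) < n_cells and tries < 100_000:
        tries += 1
        p = rng.uniform([margin, margin], [H - margin, W - margin])
        if all(np.hypot(*(p - q)) >= 2.3 * cell_radius for q in centers):
            centers.append(p)
    centers = np.array(centers)
    mask = make_cell_mask((H, W), centers, cell_radius)
    variant_idx = rng.integers(0, len(lookup), size=len(centers))
    cell_variant = {i + 1: lookup["variant"].iloc[v] for i, v in enumerate(variant_idx)}

    pos, codes, owner = [], [], []
    for i, c in enumerate(centers):
        for _ in range(rolonies_per_cell):
            for _try in range(50):
                off = rng.uniform(-cell_radius * 0.6, cell_radius * 0.6, size=2)
                p = c + off
                if all(np.hypot(*(p - q)) >= 4.0 for q in pos[-rolonies_per_cell:]):
                    break
            pos.append(p)
            codes.append(read_strings[variant_idx[i]])
            owner.append(i + 1)
    rolonies = RolonyTruth(positions=np.array(pos), barcodes=tuple(codes),
                           cell_of_rolony=tuple(owner), snr=snr)

    stack = make_rolony_stack(rolonies, n_cycles, (H, W), seed=seed + 1,
                              cell_background=0.0)
    # cell-body texture in every channel: registration features for stitching
    # and the all-channel background the second-max suppression removes
    texture = np.abs(_textured_scene((H, W), 3.0, np.random.default_rng(seed + 2),
                                     corr_sigma=4.0)) * (mask > 0)
    stack += texture[None, None]

    h, w = grid.tile_shape
    tiles = []
    for cycle in range(n_cycles):
        for tile_id, (y, x) in grid.true_positions.items():
            crop = stack[cycle, :, y:y + h, x:x + w].copy()
            crop += rng.normal(0.0, 0.3, size=crop.shape)
            jitter = rng.normal(0.0, grid.stage_jitter_sd, size=2)
            tiles.append(TileImage(pixels=crop.astype(np.float32), tile_id=tile_id,
                                   cycle=cycle,
                                   stage_position=(y + jitter[0], x + jitter[1])))

    # feature-table truth shares the lookup's variant naming (WT + syn_* + var_*)
    n_nonwt = n_variants - 1
    eff = np.zeros((n_nonwt, 40))
    rng2 = np.random.default_rng(seed + 3)
    for v in range(n_synonymous, n_nonwt):         # synonymous stay null
        feats = rng2.choice(40, size=5, replace=False)
        eff[v, feats] = rng2.normal(0, 2.5, size=5)
    ft = FeatureTableTruth(n_variants=n_nonwt, n_wt_cells=1500,
                           cells_per_variant=400, n_features=40,
                           n_synonymous=n_synonymous, effect_matrix=eff,
                           seed=seed + 4)
    return ScreenTruth(grid=grid, rolonies=rolonies, lookup=lookup, mask=mask,
                       cell_variant=cell_variant, tiles=tiles, feature_truth=ft)


def run_pipeline(screen: ScreenTruth, config: RunConfig | None = None,
                 outdir=None) -> dict:
    """Run every stage on a simulated screen; returns the manifest dict."""
    config = config or RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "dialect": config.dialect,
                      "stages": {}}

    # -- stitch ------------------------------------------------------------
    layout, graph = stitch(screen.tiles, min_overlap_px=config.min_overlap_px,
                           seed=config.seed)
    rms = layout_rms_error(layout, screen.grid.true_positions)
    manifest["stages"]["stitch"] = {
        "n_tiles": len(screen.tiles), "n_edges": graph.number_of_edges(),
        "rms_position_error_px": round(rms, 3),
    }
    if out is not None:
        oio.write_layout(out / "layout.tsv", layout)
        oio.write_edge_report(out / "edges.tsv", graph)

    # -- composite every cycle/channel ------------------------------------
    n_cycles = screen.grid.n_cycles
    n_channels = screen.tiles[0].pixels.shape[0]
    by_cycle = {c: [t for t in screen.tiles if t.cycle == c] for c in range(n_cycles)}
    th, tw = screen.tiles[0].shape
    ys = [p[0] for p in layout.positions.values()]
    xs = [p[1] for p in layout.positions.values()]
    origin = (min(ys), min(xs))
    shape = (int(np.ceil(max(ys) - origin[0])) + th,
             int(np.ceil(max(xs) - origin[1])) + tw)
    stacks = np.zeros((n_cycles, n_channels) + shape)
    for c in range(n_cycles):
        for ch in range(n_channels):
            img, _ = composite_cycle(by_cycle[c], layout, channel=ch,
                                     origin=origin, shape=shape)
            stacks[c, ch] = img

    # -- read calling ------------------------------------------------------
    positions, reads = call_stack(stacks, config.readcall)
    rt = reads_table(reads, screen.lookup)
    manifest["stages"]["readcall"] = {
        "n_reads": int(len(rt)),
        "n_called": int(rt["called_variant"].notna().sum()),
    }
    if out is not None:
        oio.write_table(out / "reads.parquet", rt)

    # -- genotyping --------------------------------------------------------
    cells = genotype_cells(rt, screen.mask, screen.lookup)
    filtered, report = apply_population_filters(cells, config.filters)
    truth_match = [screen.cell_variant.get(int(r.cell_label)) == r.variant
                   for r in filtered.itertuples()]
    manifest["stages"]["genotype"] = {
        "n_cells_with_reads": int(len(cells)),
        "n_cells_after_filters": int(len(filtered)),
        "genotype_accuracy": round(float(np.mean(truth_match)), 4) if truth_match else None,
        **{k: v for k, v in report.items() if k.startswith("removed")},
    }
    if out is not None:
        oio.write_table(out / "cells.parquet", filtered)
        oio.write_json(out / "filter_report.json", report)

    # -- feature table keyed by surviving genotypes ------------------------
    table = make_feature_table(screen.feature_truth)
    keep = set(filtered["variant"]) | {"WT"}
    table = table[table["variant"].isin(keep)].reset_index(drop=True)
    feats = [c for c in table.columns if c.startswith("f")]

    # -- profiles ----------------------------------------------------------
    syn = sorted(v for v in table["variant"].unique() if v.startswith("syn"))
    mode = config.normalize_mode if len(syn) >= 2 else "all"
    norm, prof_report = build_profiles(table, feats, wt_label="WT", mode=mode,
                                       synonymous_labels=syn,
                                       config=config.selection, seed=config.seed)
    manifest["stages"]["profiles"] = prof_report
    if out is not None:
        oio.write_table(out / "profiles.parquet", norm.reset_index())

    # -- scores ------------------------------------------------------------
    variants = [v for v in norm.index]
    imp = impact_scores(norm, syn) if syn else None
    ks_frames = {}
    family = len(feats) * len(variants)
    for v in variants:
        ks_frames[v] = ks_feature_tests(table[table["variant"] == v],
                                        table[table["variant"] == "WT"],
                                        feats, family_size=family, method="asymp")
    p_mat = pd.DataFrame({v: ks_frames[v]["p_bonferroni"] for v in variants}).T
    manifest["stages"]["scores"] = {
        "n_variants_scored": len(variants),
        "median_impact_score": round(float(imp.median()), 4) if imp is not None else None,
        "n_significant_tests": int((p_mat < 0.01).sum().sum()),
    }
    if out is not None and imp is not None:
        oio.write_table(out / "impact_scores.csv", imp.rename_axis("variant").reset_index())

    # -- embedding / clustering -------------------------------------------
    cols = [c for c in norm.columns if c != "n_cells"]
    emb = {}
    if len(norm) >= 4:
        scores_m, frac = pca_reduce(norm[cols].to_numpy(),
                                    config.variance_target)
        k = min(config.embed.knn_k, len(norm) - 1)
        g = knn_graph(scores_m, k=k)
        res = louvain_cluster(g, seed=config.embed.louvain_seed,
                              resolution=config.embed.louvain_resolution)
        emb = {"n_pcs": scores_m.shape[1], "knn_k": k,
               "n_clusters": res.n_clusters,
               "modularity": round(res.modularity, 4)}
        if out is not None:
            lab = pd.DataFrame({"variant": list(norm.index),
                                "cluster": [res.labels[i] for i in range(len(norm))]})
            lab.to_csv(out / "clusters.tsv", sep="\t", index=False)
    manifest["stages"]["embed"] = emb

    if out is not None:
        oio.write_json(out / "manifest.json", manifest)
    return manifest
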