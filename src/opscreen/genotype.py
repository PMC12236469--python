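"""Per-cell consensus genotypes from rolony reads, plus population filters.

Reads landing inside a segmented cell are combined into a consensus barcode
(per-position plurality vote across the cell's reads), matched to the
barcode->variant lookup by edit distance, and then filtered at the population
level: cells whose consensus is too far from any known barcode, cells
carrying two or more distinct barcodes (suspected doublets or segmentation
merges), barcodes seen in too few cells, and variants represented by too few
distinct barcodes are all removed.  The filter pipeline runs in a fixed,
documented order (edit-distance -> multibarcode -> cells-per-barcode ->
barcodes-per-variant) and is idempotent on its own output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readcall import RolonyRead, call_genotype


@dataclass
class FilterConfig:
    """Population-filter thresholds.

    ``max_edit`` is 1 for the single-barcode dialect and 2 for the
    dual-barcode dialect (two 8-mers tolerate one error each).
    """

    max_edit: int = 1
    min_cells_per_barcode: int = 10
    min_barcodes_per_variant: int = 5
    drop_multibarcode_cells: bool = True

    def __post_init__(self):
        if min(self.max_edit, self.min_cells_per_barcode,
               self.min_barcodes_per_variant) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CellGenotype:
    cell_label: int
    n_reads: int
    consensus_barcode: str | None
    consensus_edit_distance: int | None
    variant: str | None
    matched_barcode: str | None
    n_distinct_barcodes: int


def expand_nuclear_labels(nuclear_mask: np.ndarray, max_distance: float = 25.0
                          ) -> np.ndarray:
    """Grow nuclear labels into an estimated cell mask.

    Every background pixel within ``max_distance`` (Euclidean) of a label is
    assigned to the nearest label; labels never merge or overwrite each
    other.  ``max_distance=0`` returns the input unchanged.
    """
    from skimage.segmentation import expand_labels

    mask = np.asarray(nuclear_mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be an integer label image")
    if max_distance <= 0:
        return mask.copy()
    return expand_labels(mask, distance=max_distance)


def assign_reads_to_cells(reads: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Attach the cell label under each read position; background reads get 0."""
    y = reads["y"].round().astype(int).clip(0, mask.shape[0] - 1)
    x = reads["x"].round().astype(int).clip(0, mask.shape[1] - 1)
    out = reads.copy()
    out["cell_label"] = mask[y, x]
    return out


def _plurality_consensus(strings: list[str]) -> str | None:
    """Per-position plurality vote; positional ties fall back to the most
    common whole string, and a residual tie means no consensus."""
    if not strings:
        return None
    length = len(strings[0])
    if any(len(s) != length for s in strings):
        # mixed lengths cannot be voted position-wise; use whole-string mode
        return _mode_or_none(strings)
    consensus = []
    for i in range(length):
        counts = Counter(s[i] for s in strings).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            return _mode_or_none(strings)
        consensus.append(counts[0][0])
    return "".join(consensus)


def _mode_or_none(strings: list[str]) -> str | None:
    counts = Counter(strings).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def consensus_cell_genotype(cell_label: int, read_strings: list[str],
                            lookup: pd.DataFrame,
                            consensus: str = "per-position") -> CellGenotype:
    """Consensus barcode and genotype for the reads of one cell.

    ``n_distinct_barcodes`` counts the distinct lookup barcodes (or barcode
    pairs) that the cell's individual reads match — the doublet signal —
    counting only reads that resolve to a unique genotype.
    """
    if not read_strings:
        return CellGenotype(cell_label, 0, None, None, None, None, 0)
    if consensus == "per-position":
        cons = _plurality_consensus(read_strings)
    elif consensus == "whole-string":
        cons = _mode_or_none(read_strings)
    else:
        raise ValueError(f"unknown consensus mode {consensus!r}")
    distinct = set()
    for s in set(read_strings):
        v, _ = call_genotype(s, lookup)
        if v is not None:
            distinct.add(_matched_key(s, lookup))
    if cons is None:
        return CellGenotype(cell_label, len(read_strings), None, None, None,
                            None, len(distinct))
    variant, dist = call_genotype(cons, lookup)
    return CellGenotype(cell_label, len(read_strings), cons, dist, variant,
                        _matched_key(cons, lookup) if variant is not None else None,
                        len(distinct))


def _matched_key(read: str, lookup: pd.DataFrame) -> str | None:
    """The lookup barcode (or pair, joined by '+') nearest to ``read``."""
    from .readcall import _nearest
    if "barcode2" in lookup.columns:
        len1 = len(lookup["barcode"].iloc[0])
        _, h1 = _nearest(read[:len1], sorted(lookup["barcode"].unique()))
        _, h2 = _nearest(read[len1:], sorted(lookup["barcode2"].unique()))
        if len(h1) == 1 and len(h2) == 1:
            return h1[0] + "+" + h2[0]
        return None
    _, hits = _nearest(read, lookup["barcode"].tolist())
    return hits[0] if len(hits) == 1 else None


def genotype_cells(reads: pd.DataFrame, mask: np.ndarray, lookup: pd.DataFrame,
                   consensus: str = "per-position") -> pd.DataFrame:
    """Genotype every cell with at least one read; background reads are dropped."""
    assigned = assign_reads_to_cells(reads, mask)
    assigned = assigned[assigned["cell_label"] > 0]
    rows = []
    for label, grp in assigned.groupby("cell_label"):
        g = consensus_cell_genotype(int(label), grp["bases"].tolist(), lookup,
                                    consensus)
        rows.append({
            "cell_label": g.cell_label, "n_reads": g.n_reads,
            "consensus_barcode": g.consensus_barcode,
            "consensus_edit_distance": g.consensus_edit_distance,
            "variant": g.variant, "matched_barcode": g.matched_barcode,
            "n_distinct_barcodes": g.n_distinct_barcodes,
        })
    cols = ["cell_label", "n_reads", "consensus_barcode",
            "consensus_edit_distance", "variant", "matched_barcode",
            "n_distinct_barcodes"]
    return pd.DataFrame(rows, columns=cols)


def apply_population_filters(cells: pd.DataFrame, config: FilterConfig | None = None
                             ) -> tuple[pd.DataFrame, dict]:
    """Drop cells failing the edit-distance, doublet, and abundance rules.

    Fixed order: (1) consensus distance > max_edit or no variant called;
    (2) cells with >= 2 distinct barcodes; (3) barcodes present in fewer than
    ``min_cells_per_barcode`` cells (counted after the preceding steps);
    (4) variants represented by fewer than ``min_barcodes_per_variant``
    distinct barcodes.  Returns the surviving cells plus a per-rule report.
    """
    config = config or FilterConfig()
    report = {"input_cells": int(len(cells))}
    if len(cells) == 0:
        report.update(removed_edit_distance=0, removed_multibarcode=0,
                      removed_low_cell_barcodes=0, removed_low_barcode_variants=0,
                      output_cells=0)
        return cells.copy(), report

    keep = cells["variant"].notna() & (cells["consensus_edit_distance"] <= config.max_edit)
    report["removed_edit_distance"] = int((~keep).sum())
    cells = cells[keep]

    if config.drop_multibarcode_cells:
        keep = cells["n_distinct_barcodes"] < 2
        report["removed_multibarcode"] = int((~keep).sum())
        cells = cells[keep]
    else:
        report["removed_multibarcode"] = 0

    counts = cells["matched_barcode"].value_counts()
    good = counts[counts >= config.min_cells_per_barcode].index
    keep = cells["matched_barcode"].isin(good)
    report["removed_low_cell_barcodes"] = int((~keep).sum())
    cells = cells[keep]

    per_variant = cells.groupby("variant")["matched_barcode"].nunique()
    good_v = per_variant[per_variant >= config.min_barcodes_per_variant].index
    keep = cells["variant"].isin(good_v)
    report["removed_low_barcode_variants"] = int((~keep).sum())
    cells = cells[keep]

    report["output_cells"] = int(len(cells))
    return cells.reset_index(drop=True), report
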