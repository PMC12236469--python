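"""Synthetic fixtures with recorded ground truth.

Every generator in this module is a pure function of its configuration and an
explicit seed: no global RNG state is touched, and calling a generator twice
with the same arguments returns bit-identical output.  The fixtures emulate
the data an optical pooled screen produces — tiled multi-cycle microscope
images, rolony (rolling-circle amplification colony) signal stacks,
segmentation masks, barcode lookup tables, and single-cell feature tables —
with the generating truth recorded so downstream modules can be tested
against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .stitching import TileImage

BASES = "GTAC"
#: default base -> channel assignment (channel index of each base)
DEFAULT_CHANNEL_MAP = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# tile grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridTruth:
    """Ground truth for a simulated tile grid.

    ``true_positions`` maps ``tile_id`` (``"r{row}c{col}"``) to the global
    (y, x) pixel position of the tile's top-left corner.  Stage positions
    handed to the stitcher are these truths plus Gaussian jitter of SD
    ``stage_jitter_sd``.
    """

    n_rows: int
    n_cols: int
    tile_shape: tuple[int, int] = (128, 128)
    overlap_fraction: float = 0.2
    stage_jitter_sd: float = 2.0
    n_cycles: int = 2
    snr: float = 5.0
    seed: int = 0
    true_positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        h, w = self.tile_shape
        if h < 32 or w < 32:
            raise ValueError("tile_shape must be at least 32x32")
        if not 0.0 < self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must lie in (0, 0.5)")
        if self.overlap_fraction * min(h, w) < 8:
            raise ValueError(
                "overlap too small to register: need overlap_fraction*min(H,W) >= 8 px"
            )
        if not self.true_positions:
            step_y = int(round(h * (1 - self.overlap_fraction)))
            step_x = int(round(w * (1 - self.overlap_fraction)))
            pos = {
                f"r{r}c{c}": (r * step_y, c * step_x)
                for r in range(self.n_rows)
                for c in range(self.n_cols)
            }
            object.__setattr__(self, "true_positions", pos)
        if len(set(self.true_positions.values())) != len(self.true_positions):
            raise ValueError("true_positions must be unique")

    @property
    def scene_shape(self) -> tuple[int, int]:
        h, w = self.tile_shape
        ys = [p[0] for p in self.true_positions.values()]
        xs = [p[1] for p in self.true_positions.values()]
        return max(ys) + h, max(xs) + w

    def to_json(self) -> str:
        d = asdict(self)
        d["true_positions"] = {k: list(v) for k, v in self.true_positions.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "GridTruth":
        d = json.loads(s)
        d["tile_shape"] = tuple(d["tile_shape"])
        d["true_positions"] = {k: tuple(v) for k, v in d["true_positions"].items()}
        return cls(**d)


def _textured_scene(shape: tuple[int, int], amplitude: float, rng: np.random.Generator,
                    corr_sigma: float = 2.0) -> np.ndarray:
    """Spatially correlated random texture with SD ``amplitude``.

    Correlated (rather than white) texture is needed so phase correlation has
    structure to lock onto at subpixel shifts, like a field of cells does.
    """
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal(shape)
    tex = gaussian_filter(raw, corr_sigma)
    sd = tex.std()
    return tex * (amplitude / sd) if sd > 0 else tex


def make_tile_grid(truth: GridTruth) -> tuple[list[TileImage], GridTruth]:
    """Render a shared scene and crop jittered tiles from it.

    One static texture is shared by all cycles (the cells do not move between
    imaging cycles) plus a small per-cycle component, so inter-cycle edges are
    registrable.  Each tile is an exact crop at its true position with
    additive per-tile Gaussian read noise of SD 1; the texture SD is
    ``truth.snr`` so the signal-to-noise ratio is unambiguous.  Stage
    positions are the true positions plus N(0, stage_jitter_sd) jitter.
    """
    rng = np.random.default_rng(truth.seed)
    scene_shape = truth.scene_shape
    base = _textured_scene(scene_shape, truth.snr, rng)
    h, w = truth.tile_shape
    tiles: list[TileImage] = []
    for cycle in range(truth.n_cycles):
        # per-cycle variation at 20% of the static amplitude
        scene = base + _textured_scene(scene_shape, 0.2 * truth.snr, rng)
        for tile_id, (y, x) in truth.true_positions.items():
            crop = scene[y:y + h, x:x + w].copy()
            crop += rng.standard_normal((h, w))
            jitter = rng.normal(0.0, truth.stage_jitter_sd, size=2)
            tiles.append(TileImage(
                pixels=crop[None].astype(np.float32),
                tile_id=tile_id,
                cycle=cycle,
                stage_position=(y + jitter[0], x + jitter[1]),
            ))
    return tiles, truth


# ---------------------------------------------------------------------------
# rolony stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RolonyTruth:
    """Ground truth for a field of rolonies.

    Each rolony is a point source at ``positions[i]`` carrying barcode
    ``barcodes[i]``; at sequencing cycle c it lights up the channel encoding
    base c of its barcode with peak amplitude ``snr`` times the background
    noise SD.
    """

    positions: np.ndarray                     # (n, 2) float (y, x)
    barcodes: tuple[str, ...]
    cell_of_rolony: tuple[int, ...] = ()      # 0 = background
    psf_sigma: float = 1.5
    snr: float = 8.0
    channel_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self):
        if not 1.0 <= self.psf_sigma <= 3.0:
            raise ValueError("psf_sigma must lie in [1, 3]")
        if len(self.positions) != len(self.barcodes):
            raise ValueError("positions and barcodes must have equal length")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError("all barcodes must share one read length")


def random_rolony_positions(n: int, shape: tuple[int, int], min_spacing: float,
                            rng: np.random.Generator, margin: int = 8,
                            max_tries: int = 200_000) -> np.ndarray:
    """Rejection-sample ``n`` points with pairwise spacing >= ``min_spacing``."""
    h, w = shape
    cell = max(min_spacing, 1.0)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place rolonies at the requested spacing")
        p = rng.uniform([margin, margin], [h - margin, w - margin])
        gy, gx = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for q in grid.get((gy + dy, gx + dx), ()):
                    if np.hypot(*(p - q)) < min_spacing:
                        ok = False
                        break
        if ok:
            pts.append(p)
            grid.setdefault((gy, gx), []).append(p)
    return np.array(pts)


def random_rolony_truth(n: int, shape: tuple[int, int], n_cycles: int,
                        lookup: pd.DataFrame, seed: int, min_spacing: float = 6.0,
                        snr: float = 8.0, psf_sigma: float = 1.5) -> RolonyTruth:
    """Place ``n`` rolonies carrying barcodes drawn from ``lookup``."""
    rng = np.random.default_rng(seed)
    pos = random_rolony_positions(n, shape, min_spacing, rng)
    codes = lookup_read_strings(lookup)
    if any(len(c) != n_cycles for c in codes):
        raise ValueError("lookup barcode length must equal n_cycles")
    barcodes = tuple(codes[i] for i in rng.integers(0, len(codes), size=n))
    return RolonyTruth(positions=pos, barcodes=barcodes, snr=snr, psf_sigma=psf_sigma)


def make_rolony_stack(truth: RolonyTruth, cycles: int, shape: tuple[int, int],
                      seed: int, noise_sd: float = 1.0,
                      cell_background: float = 0.0) -> np.ndarray:
    """Render a (cycle, channel, H, W) sequencing stack.

    Background is white Gaussian noise of SD ``noise_sd`` per channel; an
    optional low-frequency "cell body" background of amplitude
    ``cell_background`` is added to *all* channels of every cycle so the
    read-calling second-max suppression has something to suppress.
    """
    from scipy.ndimage import gaussian_filter

    if any(len(b) < cycles for b in truth.barcodes):
        raise ValueError("barcode shorter than the number of cycles")
    n_channels = len(set(truth.channel_map.values()))
    h, w = shape
    if len(truth.positions) and (
        truth.positions[:, 0].max() >= h or truth.positions[:, 1].max() >= w
        or truth.positions.min() < 0
    ):
        raise ValueError("rolony positions must lie inside shape")
    rng = np.random.default_rng(seed)
    stack = rng.normal(0.0, noise_sd, size=(cycles, n_channels, h, w))
    if cell_background > 0:
        bg = gaussian_filter(rng.standard_normal((h, w)), 12.0)
        sd = bg.std()
        if sd > 0:
            bg *= cell_background * noise_sd / sd
        bg = np.abs(bg)
        stack += bg[None, None]

    yy, xx = np.mgrid[0:h, 0:w]
    amp = truth.snr * noise_sd
    for p, code in zip(truth.positions, truth.barcodes):
        y0, x0 = p
        sl = (slice(max(0, int(y0) - 8), int(y0) + 9),
              slice(max(0, int(x0) - 8), int(x0) + 9))
        spot = amp * np.exp(-((yy[sl] - y0) ** 2 + (xx[sl] - x0) ** 2)
                            / (2 * truth.psf_sigma ** 2))
        for c in range(cycles):
            ch = truth.channel_map[code[c]]
            stack[c, ch][sl] += spot
    return stack


# ---------------------------------------------------------------------------
# segmentation masks
# ---------------------------------------------------------------------------

def make_cell_mask(shape: tuple[int, int], centers: np.ndarray, radius: float) -> np.ndarray:
    """Disk-shaped cells as a 16-bit label mask; overlaps go to the nearest center."""
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint16)
    if len(centers) == 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((yy[..., None] - centers[:, 0]) ** 2
          + (xx[..., None] - centers[:, 1]) ** 2)
    nearest = np.argmin(d2, axis=-1)
    within = np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0] <= radius ** 2
    mask[within] = (nearest[within] + 1).astype(np.uint16)
    return mask


# ---------------------------------------------------------------------------
# barcode lookup tables
# ---------------------------------------------------------------------------

def _levenshtein(a: str, b: str) -> int:
    import edlib
    return edlib.align(a, b, task="distance")["editDistance"]


def make_barcode_lookup(n_variants: int, length: int, min_distance: int,
                        n_barcodes_per_variant: int = 1, seed: int = 0,
                        dual: bool = False, n_synonymous: int = 0) -> pd.DataFrame:
    """Random barcode->variant table with pairwise edit distance >= ``min_distance``.

    Single-barcode dialect: columns ``barcode, variant``.  Dual dialect: each
    variant maps to an ordered pair of codes (columns ``barcode, barcode2,
    variant``); the distance guarantee holds within each column.  The first
    ``n_synonymous`` variants are named ``syn_*`` and the rest ``var_*``;
    variant index 0 is ``WT``.
    """
    n_codes = n_variants * n_barcodes_per_variant * (2 if dual else 1)
    if 4 ** length < n_codes:
        raise ValueError("alphabet capacity too small for the requested table")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    tries = 0
    while len(codes) < n_codes:
        tries += 1
        if tries > 500 * n_codes:
            raise ValueError("cannot satisfy min_distance at this capacity")
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if all(_levenshtein(cand, c) >= min_distance for c in codes):
            codes.append(cand)
    names = (["WT"]
             + [f"syn_{i}" for i in range(n_synonymous)]
             + [f"var_{i}" for i in range(n_variants - n_synonymous - 1)])
    rows = []
    it = iter(codes)
    for name in names:
        for _ in range(n_barcodes_per_variant):
            if dual:
                rows.append({"barcode": next(it), "barcode2": next(it), "variant": name})
            else:
                rows.append({"barcode": next(it), "variant": name})
    return pd.DataFrame(rows)


def lookup_read_strings(lookup: pd.DataFrame) -> list[str]:
    """The full read string each lookup row produces (pair concatenated if dual)."""
    if "barcode2" in lookup.columns:
        return (lookup["barcode"] + lookup["barcode2"]).tolist()
    return lookup["barcode"].tolist()


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTableTruth:
    """Planted per-variant effects over a WT/synonymous null baseline.

    ``effect_matrix[v, f]`` is the mean shift of variant v on feature f in
    baseline-SD units; ``dispersion_matrix[v, f]`` multiplies the baseline SD.
    The first ``n_synonymous`` variants are synonymous controls with zero
    effect and dispersion 1 (enforced at construction).
    """

    n_variants: int
    n_wt_cells: int = 2000
    cells_per_variant: int = 300
    n_features: int = 50
    n_synonymous: int = 5
    effect_matrix: np.ndarray | None = None
    dispersion_matrix: np.ndarray | None = None
    heavy_tailed: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_variants, self.n_wt_cells, self.cells_per_variant,
               self.n_features) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_synonymous <= self.n_variants:
            raise ValueError("n_synonymous must be <= n_variants")
        eff = self.effect_matrix
        if eff is None:
            eff = np.zeros((self.n_variants, self.n_features))
        eff = np.asarray(eff, dtype=float).copy()
        disp = self.dispersion_matrix
        if disp is None:
            disp = np.ones((self.n_variants, self.n_features))
        disp = np.asarray(disp, dtype=float).copy()
        if eff.shape != (self.n_variants, self.n_features):
            raise ValueError("effect_matrix has the wrong shape")
        eff[: self.n_synonymous] = 0.0
        disp[: self.n_synonymous] = 1.0
        object.__setattr__(self, "effect_matrix", eff)
        object.__setattr__(self, "dispersion_matrix", disp)

    @property
    def variant_names(self) -> list[str]:
        return ([f"syn_{i}" for i in range(self.n_synonymous)]
                + [f"var_{i}" for i in range(self.n_variants - self.n_synonymous)])


def make_feature_table(truth: FeatureTableTruth, n_replicates: int = 2) -> pd.DataFrame:
    """Single-cell feature table with planted mean shifts and dispersion changes.

    WT cells are drawn from per-feature baseline Gaussians (or t with 5 df
    when ``heavy_tailed``); variant cells from the baseline shifted by
    ``effect*SD`` and scaled by ``dispersion``.  Columns: ``cell_label``,
    ``variant``, ``replicate`` and ``f000..``.
    """
    rng = np.random.default_rng(truth.seed)
    F = truth.n_features
    mu = rng.normal(0.0, 2.0, size=F)
    sd = rng.uniform(0.5, 2.0, size=F)
    feat_names = [f"f{j:03d}" for j in range(F)]

    def draw(n):
        if truth.heavy_tailed:
            z = rng.standard_t(5, size=(n, F)) / np.sqrt(5 / 3)
        else:
            z = rng.standard_normal((n, F))
        return z

    blocks = []
    wt = mu + sd * draw(truth.n_wt_cells)
    blocks.append(("WT", wt))
    for v, name in enumerate(truth.variant_names):
        z = draw(truth.cells_per_variant) * truth.dispersion_matrix[v]
        x = mu + sd * (truth.effect_matrix[v] + z)
        blocks.append((name, x))

    frames = []
    label = 1
    for name, x in blocks:
        df = pd.DataFrame(x, columns=feat_names)
        df.insert(0, "variant", name)
        df.insert(0, "cell_label", np.arange(label, label + len(df)))
        label += len(df)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(2, "replicate", rng.integers(0, n_replicates, size=len(out)) + 1)
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature-value columns of a cell table."""
    meta = {"cell_label", "variant", "replicate", "well", "y", "x"}
    return [c for c in table.columns if c not in meta]
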