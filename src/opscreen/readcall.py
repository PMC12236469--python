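"""In situ sequencing read calling: filter chain, blob detection, base calls.

The signal of interest is a rolony: a bright, high-spatial-frequency dot
present in exactly one of the four base channels per cycle, hopping between
channels as the barcode is read out.  The filter chain is designed to keep
those and reject everything else — diffuse cell background (removed by
subtracting a wide Gaussian blur), channel brightness differences (per-channel
z-scoring), autofluorescent debris present in all channels (subtracting the
per-pixel second-largest channel), and pixel noise (a narrow smoothing blur).
A cross-cycle standard-deviation image then highlights pixels whose channel
identity changes between cycles, which is where Laplacian-of-Gaussian blob
detection finds the rolonies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, grey_dilation


@dataclass
class ReadCallConfig:
    sigma_bg: float = 4.0          # width of the background blur that is subtracted
    sigma_smooth: float = 1.0      # post-suppression smoothing blur
    log_sigma_min: float = 1.0     # LoG blob scale range (px)
    log_sigma_max: float = 3.0
    log_threshold: float = 0.8     # absolute LoG threshold, calibrated on synthetic stacks
    dilation_footprint: int = 2    # radius (px) of the max-sampling neighbourhood
    base_order: str = "GTAC"       # channel index -> base
    #: which stage of the filter chain intensities are sampled from:
    #: "znorm" = after background subtraction + z-scoring (default),
    #: "filtered" = after second-max suppression and smoothing
    extract_stage: str = "znorm"

    def __post_init__(self):
        if not 0 < self.sigma_smooth < self.sigma_bg:
            raise ValueError("need 0 < sigma_smooth < sigma_bg")
        if self.log_sigma_min > self.log_sigma_max:
            raise ValueError("log_sigma_min must be <= log_sigma_max")


@dataclass
class RolonyRead:
    position: tuple[float, float]
    bases: str
    per_cycle_intensities: np.ndarray  # (n_cycles, n_channels)
    quality: np.ndarray                # (n_cycles,) top1 - top2 margin


def filter_cycle_image(stack: np.ndarray, config: ReadCallConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the per-cycle filter chain to a (channel, H, W) stack.

    Steps, per channel: subtract a sigma_bg Gaussian blur; z-score normalize;
    then across channels subtract the per-pixel second-largest value from
    every channel; finally smooth with a sigma_smooth blur.

    Returns ``(filtered, znorm)`` where ``znorm`` is the intermediate stack
    after z-scoring but before second-max suppression (the stage base
    intensities are sampled from by default).
    """
    config = config or ReadCallConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (channel, H, W) with >= 2 channels")
    out = np.empty_like(stack)
    for c in range(stack.shape[0]):
        img = stack[c] - gaussian_filter(stack[c], config.sigma_bg)
        sd = img.std()
        if sd == 0:
            warnings.warn(f"zero-variance channel {c}; sd treated as 1")
            sd = 1.0
        out[c] = (img - img.mean()) / sd
    znorm = out.copy()
    second = np.partition(out, -2, axis=0)[-2]
    out = out - second[None]
    for c in range(out.shape[0]):
        out[c] = gaussian_filter(out[c], config.sigma_smooth)
    return out, znorm


def variability_image(filtered_stacks: np.ndarray) -> np.ndarray:
    """Per-pixel SD across cycles (population convention), summed over channels.

    ``filtered_stacks`` is (cycle, channel, H, W); at least two cycles are
    required for a standard deviation to exist.
    """
    filtered_stacks = np.asarray(filtered_stacks, dtype=float)
    if filtered_stacks.ndim != 4 or filtered_stacks.shape[0] < 2:
        raise ValueError("need a (cycle, channel, H, W) array with >= 2 cycles")
    return filtered_stacks.std(axis=0, ddof=0).sum(axis=0)


def detect_rolonies(score_image: np.ndarray, config: ReadCallConfig | None = None
                    ) -> np.ndarray:
    """LoG blob detection on the variability image; returns (n, 2) (y, x) positions."""
    from skimage.feature import blob_log

    config = config or ReadCallConfig()
    score_image = np.asarray(score_image, dtype=float)
    if not np.all(np.isfinite(score_image)):
        raise ValueError("score image must be finite")
    blobs = blob_log(score_image, min_sigma=config.log_sigma_min,
                     max_sigma=config.log_sigma_max, num_sigma=5,
                     threshold=config.log_threshold, overlap=0.5)
    return blobs[:, :2] if len(blobs) else np.empty((0, 2))


def extract_reads(positions: np.ndarray, stacks: np.ndarray,
                  config: ReadCallConfig | None = None,
                  filtered_stacks: np.ndarray | None = None) -> list[RolonyRead]:
    """Sample per-cycle channel intensities at each position and call bases.

    ``stacks`` is the (cycle, channel, H, W) array of the configured
    extraction stage.  Each channel image is grey-dilated with a square
    footprint of radius ``dilation_footprint`` so the maximum of each dot is
    sampled even if the detection is a pixel or two off; the base for a cycle
    is the channel of maximum intensity (exact ties break to the lowest
    channel index with quality 0) and the quality is the top-two margin.
    """
    config = config or ReadCallConfig()
    stacks = np.asarray(stacks, dtype=float)
    n_cycles, n_channels, h, w = stacks.shape
    size = 2 * config.dilation_footprint + 1
    dilated = grey_dilation(stacks, size=(1, 1, size, size))
    reads = []
    for pos in np.asarray(positions, dtype=float).reshape(-1, 2):
        yi = int(np.clip(round(pos[0]), 0, h - 1))
        xi = int(np.clip(round(pos[1]), 0, w - 1))
        inten = dilated[:, :, yi, xi]                       # (cycle, channel)
        calls = np.argmax(inten, axis=1)
        top2 = np.partition(inten, -2, axis=1)[:, -2:]
        qual = top2[:, 1] - top2[:, 0]
        bases = "".join(config.base_order[c] for c in calls)
        reads.append(RolonyRead(position=(float(pos[0]), float(pos[1])),
                                bases=bases, per_cycle_intensities=inten,
                                quality=qual))
    return reads


def call_stack(stacks: np.ndarray, config: ReadCallConfig | None = None
               ) -> tuple[np.ndarray, list[RolonyRead]]:
    """Full chain on a raw (cycle, channel, H, W) stack: filter, detect, extract."""
    config = config or ReadCallConfig()
    filtered = np.empty_like(np.asarray(stacks, dtype=float))
    znorm = np.empty_like(filtered)
    for c in range(stacks.shape[0]):
        filtered[c], znorm[c] = filter_cycle_image(stacks[c], config)
    score = variability_image(filtered)
    positions = detect_rolonies(score, config)
    stage = znorm if config.extract_stage == "znorm" else filtered
    reads = extract_reads(positions, stage, config)
    return positions, reads


# ---------------------------------------------------------------------------
# genotype assignment by edit distance
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _nearest(read: str, codes: list[str]) -> tuple[int, list[str]]:
    """Minimum edit distance and all codes achieving it."""
    best, hits = None, []
    for c in codes:
        d = levenshtein(read, c)
        if best is None or d < best:
            best, hits = d, [c]
        elif d == best:
            hits.append(c)
    return best, hits


def call_genotype(read_bases: str, lookup: pd.DataFrame,
                  max_edit: int | None = None) -> tuple[str | None, int]:
    """Assign a read to the nearest genotype by Levenshtein distance.

    No call (``None``) when two distinct genotypes are equally close.  Reads
    whose distance exceeds ``max_edit`` are still returned with their
    distance — population-level filtering happens downstream — but the
    variant is withheld.

    In the dual-barcode dialect (lookup has a ``barcode2`` column) the read
    string is split at the first barcode's length and each half is matched
    independently against its own column; the genotype is the variant of the
    ordered pair, and half-ties or pairs absent from the table are no-calls.
    """
    if len(lookup) == 0:
        raise ValueError("empty lookup")
    if "barcode2" in lookup.columns:
        len1 = len(lookup["barcode"].iloc[0])
        r1, r2 = read_bases[:len1], read_bases[len1:]
        d1, h1 = _nearest(r1, sorted(lookup["barcode"].unique()))
        d2, h2 = _nearest(r2, sorted(lookup["barcode2"].unique()))
        dist = d1 + d2
        if len(h1) > 1 or len(h2) > 1:
            return None, dist
        row = lookup[(lookup["barcode"] == h1[0]) & (lookup["barcode2"] == h2[0])]
        if len(row) == 0:
            return None, dist          # mismatched pair
        variants = set(row["variant"])
    else:
        codes = lookup["barcode"].tolist()
        dist, hits = _nearest(read_bases, codes)
        variants = set(lookup.loc[lookup["barcode"].isin(hits), "variant"])
    if len(variants) != 1:
        return None, dist
    if max_edit is not None and dist > max_edit:
        return None, dist
    return variants.pop(), dist


def reads_table(reads: list[RolonyRead], lookup: pd.DataFrame | None = None,
                max_edit: int | None = None) -> pd.DataFrame:
    """Tabulate reads (one row each) and optionally call genotypes."""
    rows = []
    for r in reads:
        row = {"y": r.position[0], "x": r.position[1], "bases": r.bases,
               "min_quality": float(r.quality.min()) if len(r.quality) else np.nan}
        if lookup is not None:
            variant, dist = call_genotype(r.bases, lookup, max_edit)
            row["called_variant"] = variant
            row["edit_distance"] = dist
        rows.append(row)
    cols = ["y", "x", "bases", "min_quality"]
    if lookup is not None:
        cols += ["called_variant", "edit_distance"]
    return pd.DataFrame(rows, columns=cols)
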