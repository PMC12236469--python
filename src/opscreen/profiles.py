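"""Variant-level morphological profiles from single-cell feature tables.

A variant's profile is the concatenation, over selected features, of (a) the
median of its cells' feature values and (b) the 1-D earth-mover (Wasserstein-1)
distance between its cells and the wild-type cells.  Features whose EMD is
not reproducible between random halves of the WT population are removed
first; the profile matrix is then pruned by blocklist, variance and
correlation, and z-scored against synonymous controls (or against all
variants), giving the vectors everything downstream — impact scores,
clustering, landmark analysis — operates on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance


@dataclass
class SelectionConfig:
    blocklist: tuple[str, ...] = ("Orientation", "Location", "Center", "_X$", "_Y$")
    variance_threshold: float = 1e-8
    correlation_threshold: float = 0.95
    emd_n_reps: int = 25
    emd_iqr_mult: float = 1.5


# ---------------------------------------------------------------------------
# image-level normalizations
# ---------------------------------------------------------------------------

def illumination_correct(fields: np.ndarray, clip: bool = False) -> np.ndarray:
    """Subtract the per-pixel 5th percentile across fields of view.

    ``fields`` is (n_fields, H, W), all imaged at the same position-in-well
    so they share the illumination profile; the pixelwise low percentile
    estimates that profile without assuming a parametric form.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 3:
        raise ValueError("fields must be (n_fields, H, W)")
    if fields.shape[0] < 2:
        warnings.warn("fewer than 2 fields; illumination correction is a no-op")
        return fields.copy()
    background = np.percentile(fields, 5, axis=0)
    out = fields - background[None]
    return np.clip(out, 0, None) if clip else out


def bleedthrough_correct(target: np.ndarray, source: np.ndarray,
                         coefficient: float) -> np.ndarray:
    """Remove spectral bleed-through: ``target - coefficient*source``, floored at 0."""
    if coefficient < 0:
        raise ValueError("bleed-through coefficient must be >= 0")
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.shape != source.shape:
        raise ValueError("images must share a shape")
    return np.clip(target - coefficient * source, 0, None)


def estimate_bleedthrough(target: np.ndarray, source: np.ndarray,
                          quantile: float = 0.99) -> float:
    """Robust (Theil-Sen) slope of target on source over source-dominated pixels.

    Helper for choosing the subtraction coefficient when no calibration
    acquisition is available; pixels above the ``quantile`` of the source
    image are assumed bleed-through dominated.
    """
    from scipy.stats import theilslopes

    s = np.asarray(source, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    sel = s >= np.quantile(s, quantile)
    slope, *_ = theilslopes(t[sel], s[sel])
    return float(max(slope, 0.0))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def emd_1d(sample_a, sample_b) -> float:
    """1-D Wasserstein-1 distance between two empirical distributions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(wasserstein_distance(a, b))


def aggregate_variants(cells: pd.DataFrame, features: list[str],
                       wt_label: str = "WT") -> pd.DataFrame:
    """Per-variant feature medians and EMDs from the WT cell population.

    Returns a DataFrame indexed by variant with columns ``median_<f>`` and
    ``emd_<f>`` plus ``n_cells``; variants with zero cells are absent.
    """
    wt = cells[cells["variant"] == wt_label]
    if len(wt) == 0:
        raise ValueError(f"no cells labelled {wt_label!r}")
    wt_vals = {f: wt[f].to_numpy() for f in features}
    rows = {}
    for variant, grp in cells.groupby("variant", sort=True):
        if len(grp) == 0:
            continue
        row = {}
        for f in features:
            v = grp[f].to_numpy()
            row[f"median_{f}"] = float(np.median(v))
            row[f"emd_{f}"] = emd_1d(v, wt_vals[f])
        row["n_cells"] = len(grp)
        rows[variant] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variant"
    return out


def mad(values: np.ndarray) -> float:
    """Median absolute deviation, unscaled (no consistency constant)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def emd_reproducibility_filter(wt_cells: pd.DataFrame, features: list[str],
                               config: SelectionConfig | None = None,
                               seed: int = 0) -> tuple[list[str], pd.Series]:
    """Remove features whose WT-vs-WT EMD is unstable.

    For each of ``emd_n_reps`` random half-splits of the WT cells, each
    feature scores EMD(half1, half2) / MAD(all WT values); scores are
    averaged over splits, and features whose average exceeds
    Q1 + ``emd_iqr_mult``·IQR of the per-feature averages are removed
    (features with zero MAD are removed outright).  Returns the kept feature
    names and the per-feature average scores.
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(seed)
    n = len(wt_cells)
    if n < 4:
        raise ValueError("need at least 4 WT cells to split")
    vals = {f: wt_cells[f].to_numpy(dtype=float) for f in features}
    mads = {f: mad(vals[f]) for f in features}
    degenerate = [f for f in features if mads[f] == 0]
    live = [f for f in features if mads[f] > 0]
    scores = np.zeros((config.emd_n_reps, len(live)))
    for r in range(config.emd_n_reps):
        perm = rng.permutation(n)
        h1, h2 = perm[: n // 2], perm[n // 2:]
        for j, f in enumerate(live):
            scores[r, j] = wasserstein_distance(vals[f][h1], vals[f][h2]) / mads[f]
    avg = pd.Series(scores.mean(axis=0), index=live)
    q1, q3 = np.percentile(avg, [25, 75])
    cut = q1 + config.emd_iqr_mult * (q3 - q1)
    kept = [f for f in live if avg[f] <= cut]
    if degenerate:
        warnings.warn(f"removed zero-MAD features: {degenerate}")
    return kept, avg


# ---------------------------------------------------------------------------
# selection and normalization of the profile matrix
# ---------------------------------------------------------------------------

def select_features(profiles: pd.DataFrame, config: SelectionConfig | None = None,
                    ) -> list[str]:
    """Blocklist, variance-threshold, and correlation-threshold selection.

    Operates on profile columns (across variants).  Correlation pruning is
    greedy in descending-variance order: a column is kept only if its |r|
    with every already-kept column stays at or below the threshold, so the
    higher-variance member of each correlated pair survives.
    """
    config = config or SelectionConfig()
    cols = [c for c in profiles.columns if c != "n_cells"]
    pattern = re.compile("|".join(config.blocklist)) if config.blocklist else None
    cols = [c for c in cols if pattern is None or not pattern.search(c)]
    var = profiles[cols].var(ddof=1)
    cols = [c for c in cols if var[c] > config.variance_threshold]
    if not cols:
        return []
    order = sorted(cols, key=lambda c: (-var[c], c))
    corr = profiles[order].corr().abs()
    kept: list[str] = []
    for c in order:
        if all(corr.loc[c, k] <= config.correlation_threshold for k in kept):
            kept.append(c)
    return [c for c in profiles.columns if c in set(kept)]  # original order


def normalize_profiles(profiles: pd.DataFrame, mode: str = "all",
                       synonymous_labels: list[str] | None = None) -> pd.DataFrame:
    """Z-score each profile column against a reference population of variants.

    ``mode="synonymous"`` uses the synonymous variants' mean and SD per
    column (requires >= 2 synonymous variants); ``mode="all"`` uses all
    variants.  Columns with zero reference SD are dropped with a warning.
    """
    cols = [c for c in profiles.columns if c != "n_cells"]
    if mode == "synonymous":
        if not synonymous_labels or len(set(synonymous_labels) & set(profiles.index)) < 2:
            raise ValueError("mode='synonymous' needs >= 2 synonymous variants")
        ref = profiles.loc[profiles.index.isin(synonymous_labels), cols]
    elif mode == "all":
        ref = profiles[cols]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mu = ref.mean()
    sd = ref.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-SD columns: {dead}")
    cols = [c for c in cols if c not in dead]
    out = (profiles[cols] - mu[cols]) / sd[cols]
    if "n_cells" in profiles.columns:
        out["n_cells"] = profiles["n_cells"]
    return out


def build_profiles(cells: pd.DataFrame, features: list[str], wt_label: str = "WT",
                   mode: str = "all", synonymous_labels: list[str] | None = None,
                   config: SelectionConfig | None = None, seed: int = 0,
                   ) -> tuple[pd.DataFrame, dict]:
    """Full profile pipeline: EMD filter, aggregate, select, normalize."""
    config = config or SelectionConfig()
    wt = cells[cells["variant"] == wt_label]
    kept_feats, emd_scores = emd_reproducibility_filter(wt, features, config, seed)
    raw = aggregate_variants(cells, kept_feats, wt_label)
    raw = raw.drop(index=wt_label, errors="ignore")
    selected = select_features(raw, config)
    norm = normalize_profiles(raw[selected + ["n_cells"]], mode, synonymous_labels)
    report = {
        "features_in": len(features),
        "features_after_emd_filter": len(kept_feats),
        "profile_columns_selected": len(selected),
        "n_variants": int(len(norm)),
    }
    return norm, report
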