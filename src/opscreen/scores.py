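"""Variant-level summary scores.

* morphological impact score: half of one minus the cosine similarity of a
  variant's profile to the median synonymous profile (0 = wild-type-like,
  1 = anti-correlated);
* Kolmogorov-Smirnov feature tests with Bonferroni correction and the
  derived "hit feature" sets;
* robust z-scores (median/MAD) and the two landmark perturbation-call modes
  (EMD z for heterogeneous phenotypes, median z for shift phenotypes);
* the mislocalization score: the standardized residual of a localization
  feature after regressing out protein abundance and activity;
* interface-position calling on inter-chain C-beta distance profiles of
  multimeric structures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# impact score
# ---------------------------------------------------------------------------

def impact_score(profile: np.ndarray, reference: np.ndarray) -> float:
    """Morphological impact: ``0.5 * (1 - cos(profile, reference))``.

    ``reference`` is normally the per-column median of the synonymous
    variants' profiles.  A zero-norm profile has no direction; it is flagged
    with NaN rather than silently scored.
    """
    p = np.asarray(profile, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError("profile and reference must have equal length")
    nr = np.linalg.norm(r)
    if nr == 0:
        raise ValueError("reference profile has zero norm")
    np_ = np.linalg.norm(p)
    if np_ == 0:
        return float("nan")
    return float(0.5 * (1.0 - p @ r / (np_ * nr)))


def impact_scores(profiles: pd.DataFrame, synonymous_labels: list[str]) -> pd.Series:
    """Impact score of every variant against the median synonymous profile."""
    cols = [c for c in profiles.columns if c != "n_cells"]
    syn = profiles.loc[profiles.index.isin(synonymous_labels), cols]
    if len(syn) == 0:
        raise ValueError("no synonymous variants found")
    ref = syn.median(axis=0).to_numpy()
    return pd.Series({v: impact_score(profiles.loc[v, cols].to_numpy(), ref)
                      for v in profiles.index}, name="impact_score")


# ---------------------------------------------------------------------------
# KS testing
# ---------------------------------------------------------------------------

def ks_statistic_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample KS D for each column of ``a`` (n, F) vs ``b`` (m, F).

    Vectorized sup|ECDF_a - ECDF_b| with tie handling: the ECDF difference is
    evaluated only after all observations tied at a value are consumed.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = a.shape[0], b.shape[0]
    data = np.concatenate([a, b], axis=0)
    is_b = np.concatenate([np.zeros(n), np.ones(m)])
    order = np.argsort(data, axis=0, kind="stable")
    v = np.take_along_axis(data, order, axis=0)
    indb = is_b[order]
    cum_b = np.cumsum(indb, axis=0)
    rows = np.arange(1, n + m + 1)[:, None]
    diff = np.abs((rows - cum_b) / n - cum_b / m)
    valid = np.ones_like(diff, dtype=bool)
    valid[:-1] = v[:-1] != v[1:]          # only group-final positions count
    diff = np.where(valid, diff, 0.0)
    return diff.max(axis=0)


def ks_p_asymptotic(d: np.ndarray, n: int, m: int) -> np.ndarray:
    """Two-sided asymptotic p-value matching scipy's large-sample formula."""
    en = float(n) * m / (n + m)
    return stats.kstwo.sf(np.asarray(d, dtype=float), int(np.round(en)))


def ks_feature_tests(variant_cells: pd.DataFrame, wt_cells: pd.DataFrame,
                     features: list[str], family_size: int | None = None,
                     method: str = "auto") -> pd.DataFrame:
    """Two-sided two-sample KS per feature, with Bonferroni correction.

    ``family_size`` is the total number of tests the Bonferroni factor spans
    (features x variants in a full run); it defaults to ``len(features)`` and
    is recorded in the output.  ``method="asymp"`` uses the vectorized batch
    statistic with the asymptotic p-value; ``"auto"``/``"exact"`` delegate to
    scipy per feature (exact small-sample p-values).
    """
    if len(variant_cells) == 0 or len(wt_cells) == 0:
        raise ValueError("both samples must be non-empty")
    family = family_size if family_size is not None else len(features)
    a = variant_cells[features].to_numpy(dtype=float)
    b = wt_cells[features].to_numpy(dtype=float)
    if method == "asymp":
        d = ks_statistic_batch(a, b)
        p = ks_p_asymptotic(d, a.shape[0], b.shape[0])
    else:
        d = np.empty(len(features))
        p = np.empty(len(features))
        for j in range(len(features)):
            res = stats.ks_2samp(a[:, j], b[:, j], method=method)
            d[j], p[j] = res.statistic, res.pvalue
    return pd.DataFrame({
        "feature": features, "D": d, "p_raw": p,
        "p_bonferroni": np.minimum(p * family, 1.0),
        "family_size": family,
    }).set_index("feature")


def hit_features(p_bonferroni: pd.DataFrame, alpha: float = 0.001,
                 min_variants: int = 25) -> list[str]:
    """Features significant (Bonferroni p < alpha) in at least ``min_variants`` variants.

    ``p_bonferroni`` is a variant x feature matrix of corrected p-values.
    """
    counts = (p_bonferroni < alpha).sum(axis=0)
    return [f for f in p_bonferroni.columns if counts[f] >= min_variants]


# ---------------------------------------------------------------------------
# robust z and landmark calls
# ---------------------------------------------------------------------------

def robust_z(values, reference) -> np.ndarray:
    """(x - median(ref)) / MAD(ref) with the MAD unscaled."""
    from .profiles import mad

    ref = np.asarray(reference, dtype=float)
    m = mad(ref)
    if m == 0:
        raise ValueError("MAD of reference is zero; robust z undefined")
    return (np.asarray(values, dtype=float) - np.median(ref)) / m


def landmark_perturbation_call(z: float, p_bonferroni: float, mode: str,
                               z_thresh: float = 2.5, p_thresh: float = 0.01) -> bool:
    """Perturbation call for one (variant, landmark feature).

    ``mode="lmna_emd"``: one-sided EMD z (EMD grows from zero under any
    perturbation, so only the upper tail is meaningful).  ``mode="pten_median"``:
    two-sided |median z|.  Both additionally require the Bonferroni-corrected
    KS p below ``p_thresh``; thresholds are strict inequalities.
    """
    if mode == "lmna_emd":
        z_ok = z > z_thresh
    elif mode == "pten_median":
        z_ok = abs(z) > z_thresh
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bool(z_ok and p_bonferroni < p_thresh)


def landmark_calls(z: pd.DataFrame, p_bonferroni: pd.DataFrame, mode: str,
                   z_thresh: float = 2.5, p_thresh: float = 0.01) -> pd.DataFrame:
    """Vectorized perturbation calls over a variant x feature z and p matrix."""
    if mode == "lmna_emd":
        z_ok = z > z_thresh
    elif mode == "pten_median":
        z_ok = z.abs() > z_thresh
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return z_ok & (p_bonferroni < p_thresh)


# ---------------------------------------------------------------------------
# mislocalization score
# ---------------------------------------------------------------------------

def mislocalization_score(feature_values, abundance_values, activity_values,
                          variants: list[str] | None = None,
                          max_condition: float = 1e8) -> pd.Series:
    """Standardized residual of localization after removing abundance and activity.

    Ordinary least squares of the localization feature on [1, abundance,
    activity] across variants; each variant's score is its residual divided
    by the residual SD.  Collinear regressors raise with the design-matrix
    condition number in the message.
    """
    y = np.asarray(feature_values, dtype=float)
    X = np.column_stack([np.ones_like(y),
                         np.asarray(abundance_values, dtype=float),
                         np.asarray(activity_values, dtype=float)])
    if len(y) < 10:
        raise ValueError("need at least 10 variants for a stable regression")
    cond = np.linalg.cond(X)
    if cond > max_condition:
        raise ValueError(f"collinear regressors (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=X.shape[1])
    # an (essentially) perfect fit has no residual scale; scores are zero
    tiny = 1e-10 * max(1.0, float(np.abs(y).mean()))
    z = resid / sd if sd > tiny else np.zeros_like(resid)
    index = variants if variants is not None else range(len(y))
    return pd.Series(z, index=index, name="mislocalization_z")


# ---------------------------------------------------------------------------
# structural interface calling
# ---------------------------------------------------------------------------

def _plateau_minima(d: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j] of local minima, treating equal-value plateaus as one.

    A plateau is a minimum when both flanking values (treated as +inf past
    the ends) are strictly larger; a constant profile is one degenerate
    minimum covering everything.
    """
    n = len(d)
    minima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        left = d[i - 1] if i > 0 else np.inf
        right = d[j + 1] if j + 1 < n else np.inf
        if d[i] < left and d[i] < right:
            minima.append((i, j))
        i = j + 1
    return minima


def call_interface_positions(coords: pd.DataFrame, tolerance: float = 1.5,
                             max_distance: float | None = None) -> pd.DataFrame:
    """Label residues interacting with an opposing chain.

    ``coords`` has columns ``chain, position, x, y, z`` — one C-beta per
    residue (glycines, which lack one, are simply absent).  For each chain
    the per-position minimum distance to any other chain's C-beta is
    profiled along the sequence; local minima of that profile, and every
    position whose distance is within ``tolerance`` of its nearest local
    minimum, are called interacting.  ``max_distance``, if given, vetoes
    calls whose distance exceeds it (the rule itself has no absolute cutoff).
    """
    chains = sorted(coords["chain"].unique())
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    out_rows = []
    xyz = {c: coords[coords["chain"] == c].sort_values("position") for c in chains}
    for c in chains:
        own = xyz[c]
        others = np.concatenate([xyz[o][["x", "y", "z"]].to_numpy() for o in chains if o != c])
        own_xyz = own[["x", "y", "z"]].to_numpy()
        dists = np.sqrt(((own_xyz[:, None, :] - others[None, :, :]) ** 2).sum(-1))
        d = dists.min(axis=1)
        minima = _plateau_minima(d)
        min_idx = np.array([k for (i, j) in minima for k in range(i, j + 1)])
        is_min = np.zeros(len(d), dtype=bool)
        if len(min_idx):
            is_min[min_idx] = True
        interacting = np.zeros(len(d), dtype=bool)
        for k in range(len(d)):
            if not len(min_idx):
                break
            nearest = min_idx[np.argmin(np.abs(min_idx - k))]
            if d[k] - d[nearest] <= tolerance:
                interacting[k] = True
        if max_distance is not None:
            interacting &= d <= max_distance
        for k, (_, row) in enumerate(own.iterrows()):
            out_rows.append({"chain": c, "position": row["position"],
                             "min_cb_distance": d[k], "is_local_min": bool(is_min[k]),
                             "interacting": bool(interacting[k])})
    return pd.DataFrame(out_rows)
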