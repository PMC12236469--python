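"""Global multi-cycle stitching via an offset graph and an L1 position solve.

Tiles from every imaging cycle become nodes of one graph.  Edges connect
stage-overlapping tile pairs within a cycle and the same tile across cycles;
each edge carries a translation offset estimated by phase cross-correlation
and scored by normalized cross-correlation (NCC) on the implied overlap.
Edges scoring below a null-derived NCC threshold are pruned and replaced by
offsets predicted from a linear model in stage-position deltas, and the
global tile positions are found by minimizing the summed absolute residual
of all edge equations with a linear program — an L1 objective, so a few bad
offsets cannot drag the whole layout the way least squares would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

NEG_INF = float("-inf")

Node = tuple[int, str]  # (cycle, tile_id)


@dataclass
class TileImage:
    """One tile at one cycle: a (C, H, W) channel stack plus its stage position."""

    pixels: np.ndarray
    tile_id: str
    cycle: int
    stage_position: tuple[float, float]

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ValueError("pixels must be (H, W) or (C, H, W)")
        if not np.all(np.isfinite(px)):
            raise ValueError("tile intensities must be finite")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def node(self) -> Node:
        return (self.cycle, self.tile_id)


def reference_channel(tiles: list[TileImage]) -> int:
    """Registration channel: the channel with the highest total variance."""
    var = np.zeros(tiles[0].pixels.shape[0])
    for t in tiles:
        var += t.pixels.var(axis=(1, 2))
    return int(np.argmax(var))


def _stage_overlap(a: TileImage, b: TileImage) -> tuple[float, float]:
    """Overlap extents (oy, ox) in px predicted by stage positions; <=0 if disjoint."""
    h, w = a.shape
    dy = b.stage_position[0] - a.stage_position[0]
    dx = b.stage_position[1] - a.stage_position[1]
    return h - abs(dy), w - abs(dx)


def _registrable(a: TileImage, b: TileImage, min_overlap_px: int) -> bool:
    """True when the stage-predicted overlap is worth an edge.

    The bar is an overlap area of at least a full-length band
    ``min_overlap_px`` wide — adjacent tiles with an 8+ px seam qualify,
    while the small corner square shared by diagonal neighbours does not.
    """
    h, w = a.shape
    oy, ox = _stage_overlap(a, b)
    return oy >= min_overlap_px and ox >= min_overlap_px \
        and oy * ox >= min_overlap_px * min(h, w)


def build_overlap_graph(tiles: list[TileImage], min_overlap_px: int = 8,
                        inter_cycle: str = "all-pairs") -> nx.Graph:
    """Graph of tiles with edges for every registrable pair (no offsets yet).

    Intra-cycle edges join tile pairs whose stage-predicted overlap is at
    least ``min_overlap_px`` in both axes; inter-cycle edges join the same
    tile_id across all cycle pairs (or consecutive cycles only when
    ``inter_cycle="consecutive"``).
    """
    if not tiles:
        raise ValueError("no tiles")
    g = nx.Graph(min_overlap_px=min_overlap_px)
    for t in tiles:
        g.add_node(t.node, tile=t)
    by_cycle: dict[int, list[TileImage]] = {}
    by_tile: dict[str, list[TileImage]] = {}
    for t in tiles:
        by_cycle.setdefault(t.cycle, []).append(t)
        by_tile.setdefault(t.tile_id, []).append(t)
    for group in by_cycle.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if _registrable(a, b, min_overlap_px):
                    g.add_edge(a.node, b.node, kind="intra-cycle")
    for group in by_tile.values():
        group = sorted(group, key=lambda t: t.cycle)
        for i, a in enumerate(group):
            partners = group[i + 1:] if inter_cycle == "all-pairs" else group[i + 1:i + 2]
            for b in partners:
                g.add_edge(a.node, b.node, kind="inter-cycle")
    for n in g.nodes:
        if g.degree(n) == 0:
            warnings.warn(f"tile {n} has no edges; will rely on infill")
    return g


def oriented_offset(d: dict, u, v) -> tuple[float, float]:
    """Edge offset in the direction u -> v.

    Offsets are directional (position_v - position_u) but networkx edges are
    not; the scoring step records the orientation in ``node_a``/``node_b``
    and this helper negates the stored offset when read the other way.
    """
    off = d["offset"]
    if d.get("node_a", u) == u:
        return off
    return (-off[0], -off[1])


def ncc_at_offset(a: np.ndarray, b: np.ndarray, offset: tuple[int, int],
                  min_overlap_px: int = 8) -> float:
    """NCC of the overlap implied by ``offset`` = position_b - position_a.

    Each overlap patch is mean-centered and normalized to a unit vector; the
    score is their dot product.  Returns ``-inf`` if the overlap is smaller
    than ``min_overlap_px`` in either axis, and 0 for a constant overlap.
    """
    h, w = a.shape
    dy, dx = int(round(offset[0])), int(round(offset[1]))
    ay0, ay1 = max(0, dy), min(h, h + dy)
    ax0, ax1 = max(0, dx), min(w, w + dx)
    if (ay1 - ay0) < min_overlap_px or (ax1 - ax0) < min_overlap_px:
        return NEG_INF
    pa = a[ay0:ay1, ax0:ax1]
    pb = b[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na == 0 or nb == 0:
        return 0.0
    return float((pa * pb).sum() / (na * nb))


def estimate_edge_offset(a: TileImage, b: TileImage, channel: int = 0,
                         min_overlap_px: int = 8, subpixel: bool = True,
                         upsample: int = 10) -> tuple[tuple[float, float], float]:
    """Offset (position_b - position_a) and NCC for one tile pair.

    Phase cross-correlation gives the shift up to a wrap-around ambiguity of
    one tile period per axis; the four candidate offsets are disambiguated by
    scoring each implied overlap with NCC and keeping the best.
    """
    from skimage.registration import phase_cross_correlation

    ia = a.pixels[channel].astype(float)
    ib = b.pixels[channel].astype(float)
    if ia.shape != ib.shape:
        raise ValueError("tiles must share a shape")
    h, w = ia.shape
    # phase normalization is sharp on feature-rich images but unstable on
    # smooth ones; plain correlation is the reverse — score both and let the
    # NCC of the implied overlap decide (which also resolves the FFT
    # wrap-around ambiguity of one tile period per axis)
    best, best_ncc, fallback = None, NEG_INF, None
    for norm in ("phase", None):
        shift, _, _ = phase_cross_correlation(
            ia, ib, upsample_factor=upsample if subpixel else 1,
            normalization=norm)
        fallback = fallback or (float(shift[0]), float(shift[1]))
        for dy in (shift[0], shift[0] - np.sign(shift[0]) * h if shift[0] != 0 else shift[0] + h):
            for dx in (shift[1], shift[1] - np.sign(shift[1]) * w if shift[1] != 0 else shift[1] + w):
                s = ncc_at_offset(ia, ib, (dy, dx), min_overlap_px)
                if s > best_ncc:
                    best, best_ncc = (float(dy), float(dx)), s
    if best is None:
        best = fallback
    return best, best_ncc


def score_graph_edges(graph: nx.Graph, channel: int | None = None,
                      subpixel: bool = True) -> nx.Graph:
    """Estimate offset and NCC for every edge in place; returns the graph."""
    tiles = [graph.nodes[n]["tile"] for n in graph.nodes]
    ch = reference_channel(tiles) if channel is None else channel
    mo = graph.graph.get("min_overlap_px", 8)
    for u, v, d in graph.edges(data=True):
        ta, tb = graph.nodes[u]["tile"], graph.nodes[v]["tile"]
        off, ncc = estimate_edge_offset(ta, tb, ch, mo, subpixel)
        d["offset"] = off
        d["node_a"], d["node_b"] = u, v
        d["ncc"] = ncc
    graph.graph["channel"] = ch
    return graph


def ncc_null_threshold(tiles: list[TileImage], n_random_pairs: int = 200,
                       seed: int = 0, min_overlap_px: int = 8,
                       channel: int | None = None, n_candidates: int = 8,
                       fallback: float = 0.3) -> float:
    """95th percentile of the null NCC between non-overlapping tiles.

    Pairs of tiles whose stage positions predict no overlap share no signal,
    so the alignment scores the estimator reports for them sample the null
    distribution a failed (signal-free) estimate is drawn from.  Each null
    sample therefore runs the *full offset estimator* on a non-overlapping
    pair — a failed phase correlation locks onto the best-correlating
    spurious offset, so its NCC is an extreme value of the pointwise null,
    and thresholding must be calibrated against that same maximization.
    If the grid is too small to supply non-overlapping pairs the configured
    ``fallback`` constant is returned (logged).
    """
    rng = np.random.default_rng(seed)
    ch = reference_channel(tiles) if channel is None else channel
    pairs = [(a, b) for i, a in enumerate(tiles) for b in tiles[i + 1:]
             if min(_stage_overlap(a, b)) <= 0]
    if not pairs:
        warnings.warn("no non-overlapping tile pairs; using fallback NCC threshold")
        return fallback
    scores: list[float] = []
    n_samples = max(50, n_random_pairs // 4)   # each sample runs two FFTs
    while len(scores) < n_samples:
        a, b = pairs[rng.integers(len(pairs))]
        _, s = estimate_edge_offset(a, b, ch, min_overlap_px, subpixel=False)
        if np.isfinite(s):
            scores.append(s)
    return float(np.percentile(scores, 95))


def _fit_offset_model(graph: nx.Graph):
    """Affine model offset ~ stage-position delta, fitted per axis by OLS."""
    rows, ys, xs = [], [], []
    for u, v, d in graph.edges(data=True):
        ta, tb = graph.nodes[u]["tile"], graph.nodes[v]["tile"]
        dsy = tb.stage_position[0] - ta.stage_position[0]
        dsx = tb.stage_position[1] - ta.stage_position[1]
        off = oriented_offset(d, u, v)
        rows.append([1.0, dsy, dsx])
        ys.append(off[0])
        xs.append(off[1])
    A = np.array(rows)
    coef_y, *_ = np.linalg.lstsq(A, np.array(ys), rcond=None)
    coef_x, *_ = np.linalg.lstsq(A, np.array(xs), rcond=None)

    def predict(ta: TileImage, tb: TileImage) -> tuple[float, float]:
        dsy = tb.stage_position[0] - ta.stage_position[0]
        dsx = tb.stage_position[1] - ta.stage_position[1]
        z = np.array([1.0, dsy, dsx])
        return float(z @ coef_y), float(z @ coef_x)

    return predict


def _stage_outliers(g: nx.Graph, k: float = 8.0, floor: float = 3.0) -> list:
    """Edges whose offset deviates implausibly from the stage prediction.

    The estimator maximizes NCC over candidate offsets, so a failed estimate
    reports the best of several null draws and can sneak past the null NCC
    threshold.  Offsets are therefore also checked against stage positions:
    per axis, residual = offset - stage delta; edges beyond ``k`` MADs
    (plus a ``floor`` px allowance for jitter) from the median are outliers.
    """
    res = {0: [], 1: []}
    edges = list(g.edges(data=True))
    for u, v, d in edges:
        ta, tb = g.nodes[u]["tile"], g.nodes[v]["tile"]
        off = oriented_offset(d, u, v)
        for ax in (0, 1):
            res[ax].append(off[ax]
                           - (tb.stage_position[ax] - ta.stage_position[ax]))
    bad = []
    for ax in (0, 1):
        r = np.array(res[ax])
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        cut = k * mad + floor
        for (u, v, _), ri in zip(edges, r):
            if abs(ri - med) > cut:
                bad.append((u, v))
    return bad


def prune_and_infill(graph: nx.Graph, threshold: float) -> nx.Graph:
    """Drop low-NCC and stage-implausible edges, then reconnect stragglers.

    A linear model of offset on stage-position deltas is fitted to the
    surviving edges; every node cut off from the main component gets
    ``kind="inferred"`` edges to its stage-predicted neighbours carrying the
    model's offsets.  If pruning removes everything, the layout degrades to
    the pure stage model (with a warning).
    """
    g = graph.copy()
    bad = [(u, v) for u, v, d in g.edges(data=True) if d["ncc"] < threshold]
    bad += [e for e in _stage_outliers(g) if e not in bad]
    removed = [(u, v, graph.edges[u, v]) for u, v in bad]
    g.remove_edges_from(bad)

    surviving = g.number_of_edges()
    if surviving == 0:
        warnings.warn("all edges pruned; falling back to stage-position layout")
        for u, v, d in removed:
            ta, tb = g.nodes[u]["tile"], g.nodes[v]["tile"]
            off = (tb.stage_position[0] - ta.stage_position[0],
                   tb.stage_position[1] - ta.stage_position[1])
            g.add_edge(u, v, offset=off, node_a=u, node_b=v,
                       ncc=float("nan"), kind="inferred")
        return g

    predict = _fit_offset_model(g)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    main = comps[0]
    # candidate edges: the pruned ones plus any original-graph adjacency
    candidates = {frozenset((u, v)) for u, v in graph.edges}
    for comp in comps[1:]:
        for n in comp:
            for pair in candidates:
                if n in pair:
                    other = next(m for m in pair if m != n)
                    if other in main and not g.has_edge(n, other):
                        ta, tb = g.nodes[n]["tile"], g.nodes[other]["tile"]
                        g.add_edge(n, other, offset=predict(ta, tb),
                                   node_a=n, node_b=other,
                                   ncc=float("nan"), kind="inferred")
        main = main | comp
    return g


def solve_global_positions(graph: nx.Graph, anchor: Node | None = None,
                           method: str = "l1") -> "GlobalLayout":
    """Global tile positions minimizing the summed edge residual.

    Each edge contributes the equation ``pos_b - pos_a = offset`` per axis.
    ``method="l1"`` minimizes the summed absolute residual with a linear
    program (slack variable per edge; HiGHS); ``method="l2"`` is the
    least-squares reference.  The y and x systems decouple and are solved
    independently.  The anchor node (lexicographically smallest by default)
    is fixed at (0, 0), removing the translation gauge freedom.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("graph is disconnected; run prune_and_infill first")
    nodes = sorted(graph.nodes)
    if anchor is None:
        anchor = nodes[0]
    idx = {n: i for i, n in enumerate(nodes)}
    free = [n for n in nodes if n != anchor]
    fidx = {n: i for i, n in enumerate(free)}
    edges = sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    m, n = len(edges), len(free)

    sol = {}
    oriented = [oriented_offset(d, u, v) for u, v, d in edges]
    for axis in (0, 1):
        b = np.array([off[axis] for off in oriented], dtype=float)
        rows, cols, vals = [], [], []
        for i, (u, v, _) in enumerate(edges):
            if u != anchor:
                rows.append(i); cols.append(fidx[u]); vals.append(-1.0)
            if v != anchor:
                rows.append(i); cols.append(fidx[v]); vals.append(1.0)
        A = coo_matrix((vals, (rows, cols)), shape=(m, n))
        if method == "l2":
            p, *_ = np.linalg.lstsq(A.toarray(), b, rcond=None)
        elif method == "l1":
            # minimize sum(t) s.t. -t <= A p - b <= t
            from scipy.sparse import eye, hstack, vstack
            I = eye(m, format="coo")
            A_ub = vstack([hstack([A, -I]), hstack([-A, -I])], format="csr")
            b_ub = np.concatenate([b, -b])
            c = np.concatenate([np.zeros(n), np.ones(m)])
            bounds = [(None, None)] * n + [(0, None)] * m
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
            if not res.success:
                raise RuntimeError(f"LP solve failed: {res.message}")
            p = res.x[:n]
        else:
            raise ValueError(f"unknown method {method!r}")
        sol[axis] = p

    positions: dict[Node, tuple[float, float]] = {}
    for nname in nodes:
        if nname == anchor:
            positions[nname] = (0.0, 0.0)
        else:
            positions[nname] = (float(sol[0][fidx[nname]]), float(sol[1][fidx[nname]]))
    residuals = {}
    for (u, v, d), off in zip(edges, oriented):
        ry = positions[v][0] - positions[u][0] - off[0]
        rx = positions[v][1] - positions[u][1] - off[1]
        residuals[(u, v)] = (abs(ry), abs(rx))
    return GlobalLayout(positions=positions, residuals=residuals, anchor=anchor)


@dataclass
class GlobalLayout:
    """Solved tile positions (anchor at origin) with per-edge absolute residuals."""

    positions: dict[Node, tuple[float, float]]
    residuals: dict[tuple[Node, Node], tuple[float, float]]
    anchor: Node


def refine_layout(graph: nx.Graph, layout: GlobalLayout,
                  inlier_threshold: float = 3.0, max_iter: int = 3) -> GlobalLayout:
    """Least-squares polish of an L1 layout over inlier edges only.

    The L1 solve is robust but statistically inefficient; once it has
    localized the outliers, re-solving by least squares restricted to edges
    with residual below ``inlier_threshold`` recovers the averaging
    efficiency of L2 without re-admitting the outliers.  Iterates the
    classify/solve cycle (at most ``max_iter`` times) until the inlier set
    stabilizes; falls back to the input layout if the inlier graph
    disconnects.
    """
    nodes = sorted(graph.nodes)
    anchor = layout.anchor
    free = [n for n in nodes if n != anchor]
    fidx = {n: i for i, n in enumerate(free)}
    pos = {n: list(p) for n, p in layout.positions.items()}
    prev_inliers = None
    for _ in range(max_iter):
        inliers = [(u, v, d) for u, v, d in sorted(graph.edges(data=True))
                   if max(abs(pos[v][a] - pos[u][a] - oriented_offset(d, u, v)[a])
                          for a in (0, 1)) <= inlier_threshold]
        keys = {(u, v) for u, v, _ in inliers}
        if keys == prev_inliers:
            break
        prev_inliers = keys
        sub = nx.Graph([(u, v) for u, v, _ in inliers])
        if (sub.number_of_nodes() != len(nodes)) or not nx.is_connected(sub):
            return layout
        for axis in (0, 1):
            rows, cols, vals, b = [], [], [], []
            for r, (u, v, d) in enumerate(inliers):
                if u != anchor:
                    rows.append(r); cols.append(fidx[u]); vals.append(-1.0)
                if v != anchor:
                    rows.append(r); cols.append(fidx[v]); vals.append(1.0)
                b.append(oriented_offset(d, u, v)[axis])
            A = coo_matrix((vals, (rows, cols)),
                           shape=(len(inliers), len(free))).toarray()
            p, *_ = np.linalg.lstsq(A, np.array(b), rcond=None)
            for n in free:
                pos[n][axis] = float(p[fidx[n]])
    positions = {n: (0.0, 0.0) if n == anchor else tuple(pos[n]) for n in nodes}
    residuals = {}
    for u, v, d in sorted(graph.edges(data=True)):
        off = oriented_offset(d, u, v)
        residuals[(u, v)] = (abs(positions[v][0] - positions[u][0] - off[0]),
                             abs(positions[v][1] - positions[u][1] - off[1]))
    return GlobalLayout(positions=positions, residuals=residuals, anchor=anchor)


def _feather_weights(shape: tuple[int, int]) -> np.ndarray:
    """Linear distance-to-nearest-tile-edge weights, floored at 1e-6."""
    h, w = shape
    y = np.minimum(np.arange(h), np.arange(h)[::-1]).astype(float)
    x = np.minimum(np.arange(w), np.arange(w)[::-1]).astype(float)
    return np.maximum(np.minimum(y[:, None], x[None, :]), 1e-6)


def composite_cycle(tiles: list[TileImage], layout: GlobalLayout,
                    channel: int = 0, origin: tuple[float, float] | None = None,
                    shape: tuple[int, int] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Feathered weighted-average mosaic of one cycle's tiles on one channel.

    Returns ``(composite, valid_mask)``; pixels covered by no tile are 0 and
    masked out.  Weights fall off linearly with distance to the tile edge so
    seams blend smoothly and the overlap midline averages both tiles equally.
    ``origin``/``shape`` pin the canvas so multiple cycles land on one frame.
    """
    pos = {t.node: layout.positions[t.node] for t in tiles}
    ys = [p[0] for p in pos.values()]
    xs = [p[1] for p in pos.values()]
    oy, ox = origin if origin is not None else (min(ys), min(xs))
    h, w = tiles[0].shape
    if shape is not None:
        H, W = shape
    else:
        H = int(np.ceil(max(ys) - oy)) + h
        W = int(np.ceil(max(xs) - ox)) + w
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    base_w = _feather_weights((h, w))
    for t in tiles:
        y0 = int(round(pos[t.node][0] - oy))
        x0 = int(round(pos[t.node][1] - ox))
        ty0, tx0 = max(0, -y0), max(0, -x0)
        ty1, tx1 = min(h, H - y0), min(w, W - x0)
        if ty1 <= ty0 or tx1 <= tx0:
            continue
        sl = (slice(y0 + ty0, y0 + ty1), slice(x0 + tx0, x0 + tx1))
        acc[sl] += base_w[ty0:ty1, tx0:tx1] * t.pixels[channel, ty0:ty1, tx0:tx1]
        wacc[sl] += base_w[ty0:ty1, tx0:tx1]
    valid = wacc > 0
    out = np.zeros_like(acc)
    out[valid] = acc[valid] / wacc[valid]
    return out, valid


def stitch(tiles: list[TileImage], min_overlap_px: int = 8, seed: int = 0,
           channel: int | None = None, inter_cycle: str = "all-pairs",
           subpixel: bool = True, threshold: float | None = None,
           refine: bool = True) -> tuple[GlobalLayout, nx.Graph]:
    """End-to-end stitch: graph build, offset estimation, prune/infill,
    L1 solve, and (by default) inlier least-squares refinement."""
    g = build_overlap_graph(tiles, min_overlap_px, inter_cycle)
    score_graph_edges(g, channel, subpixel)
    if threshold is None:
        threshold = ncc_null_threshold(tiles, seed=seed, channel=channel)
    g = prune_and_infill(g, threshold)
    layout = solve_global_positions(g)
    if refine:
        layout = refine_layout(g, layout)
    return layout, g


def layout_rms_error(layout: GlobalLayout,
                     truth: dict[str, tuple[float, float]]) -> float:
    """RMS position error vs truth after removing the best global translation."""
    err = []
    for (cycle, tile_id), p in layout.positions.items():
        t = truth[tile_id]
        err.append([p[0] - t[0], p[1] - t[1]])
    err = np.array(err)
    err -= err.mean(axis=0)
    return float(np.sqrt((err ** 2).sum(axis=1).mean()))
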