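"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without external downloads:

* gene trees with deep interspecific divergences (Yule process over
  species) and shallow intraspecific structure (Kingman coalescent within
  species), grafted so a separation factor guarantees an identifiable
  delimitation threshold;
* Jukes-Cantor (JC69) sequence evolution along any ultrametric tree;
* smooth latitudinal sea-surface-temperature fields with a seasonal
  amplitude growing away from the equator, written as matching
  min/mean/max layers with rectangular land masks;
* occurrence records confined to a species' thermal niche on such a
  raster.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .gmyc import Entity, ThresholdAssignment
from .seqdist import Alignment
from .thermal import GridSpec, OccurrenceRecord, SstRaster
from .treeio import UltrametricTree, parse_newick

__all__ = [
    "GmycSimConfig",
    "RasterSimConfig",
    "simulate_gmyc_tree",
    "simulate_yule_tree",
    "simulate_coalescent_tree",
    "simulate_sequences",
    "simulate_sst_raster",
    "simulate_occurrences",
    "graded_niche_world",
]


@dataclass
class GmycSimConfig:
    """Configuration of the species-tree / within-species simulator.

    ``k`` species arise from a Yule process with per-lineage rate
    ``lam_yule`` (depth units are substitutions/site); each species
    carries a Kingman coalescent genealogy of ``m`` tips with scale
    ``theta`` (waiting time with ``j`` lineages ~ Exp(j*(j-1)/(2*theta))).
    Within-species subtrees are rescaled so that
    (min species-divergence depth) / (max coalescent depth) = ``separation``;
    values well above 1 give cleanly delimitable species, values near 1
    give hard cases.
    """

    k: int = 10
    m: int = 5
    lam_yule: float = 1.0
    theta: float = 0.05
    separation: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValueError("k and m must be >= 1")
        if self.k * self.m < 2:
            raise ValueError("need at least 2 tips in total")
        if self.separation <= 0:
            raise ValueError("separation factor must be positive")
        if self.lam_yule <= 0 or self.theta <= 0:
            raise ValueError("rates must be positive")


class _N:
    """Build-time tree node: depth plus children or a tip label."""

    __slots__ = ("depth", "children", "label")

    def __init__(self, depth: float, children=None, label: str = ""):
        self.depth = depth
        self.children = children or []
        self.label = label


def _to_newick(node: _N, parent_depth: Optional[float] = None) -> str:
    if node.children:
        inner = ",".join(_to_newick(c, node.depth) for c in node.children)
        body = f"({inner})"
    else:
        body = node.label
    if parent_depth is None:
        return body + ";"
    return f"{body}:{parent_depth - node.depth:.12g}"


def _yule_nodes(k: int, lam: float, rng: np.random.Generator) -> Tuple[_N, List[_N]]:
    """Yule tree stopped at ``k`` tips; an extra Exp(k*lam) stem keeps the
    shallowest split strictly above the present.  Returns (root, tips)."""
    times = []
    t = 0.0
    for j in range(1, k):
        t += rng.exponential(1.0 / (lam * j))
        times.append(t)
    t_end = t + rng.exponential(1.0 / (lam * k))
    depths = [t_end - ti for ti in times]  # descending: first split deepest
    root = _N(depth=depths[0] if depths else 0.0)
    leaves = [root]
    for i, d in enumerate(depths):
        v = leaves.pop(int(rng.integers(0, len(leaves)))) if i else leaves.pop(0)
        v.depth = d
        a, b = _N(0.0), _N(0.0)
        v.children = [a, b]
        leaves.extend([a, b])
    return root, leaves


def _coalescent_nodes(
    labels: Sequence[str], theta: float, rng: np.random.Generator
) -> _N:
    """Kingman coalescent genealogy over ``labels``; root depth = height."""
    items = [_N(0.0, label=lab) for lab in labels]
    t = 0.0
    while len(items) > 1:
        j = len(items)
        t += rng.exponential(2.0 * theta / (j * (j - 1)))
        a = items.pop(int(rng.integers(0, len(items))))
        b = items.pop(int(rng.integers(0, len(items))))
        items.append(_N(t, children=[a, b]))
    return items[0]


def _scale_depths(node: _N, f: float) -> None:
    node.depth *= f
    for c in node.children:
        _scale_depths(c, f)


def simulate_yule_tree(n: int, lam: float = 1.0, seed: int = 0) -> UltrametricTree:
    """Pure-birth ultrametric tree with ``n`` tips (no species structure)."""
    rng = np.random.default_rng(seed)
    root, leaves = _yule_nodes(n, lam, rng)
    for i, leaf in enumerate(leaves):
        leaf.label = f"t{i + 1}"
    return parse_newick(_to_newick(root))


def simulate_coalescent_tree(
    m: int, theta: float = 0.05, seed: int = 0, prefix: str = "sp1"
) -> UltrametricTree:
    """Single-population Kingman coalescent genealogy of ``m`` tips."""
    rng = np.random.default_rng(seed)
    root = _coalescent_nodes([f"{prefix}_{i + 1}" for i in range(m)], theta, rng)
    return parse_newick(_to_newick(root))


def simulate_gmyc_tree(cfg: GmycSimConfig):
    """Simulate an ultrametric gene tree with known species structure.

    Returns ``(UltrametricTree, ThresholdAssignment)``; the assignment
    records the true clusters/singletons, with the true threshold at the
    geometric midpoint between the deepest within-species coalescence and
    the shallowest species divergence.  Identical seeds give identical
    trees.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if cfg.k == 1:
        labels = [f"sp1_{i + 1}" for i in range(cfg.m)]
        root = _coalescent_nodes(labels, cfg.theta, rng)
        tree = parse_newick(_to_newick(root))
        return tree, _truth_assignment(tree, [labels], tree.root_depth * 1.05)

    sp_root, sp_tips = _yule_nodes(cfg.k, cfg.lam_yule, rng)
    min_div = min(
        v.depth for v in _iter_nodes(sp_root) if v.children
    )
    subtrees, heights, groups = [], [], []
    for j, leaf in enumerate(sp_tips):
        labels = [f"sp{j + 1}_{i + 1}" for i in range(cfg.m)]
        sub = _coalescent_nodes(labels, cfg.theta, rng)
        subtrees.append(sub)
        heights.append(sub.depth)
        groups.append(labels)
    max_h = max(heights)
    if max_h > 0:
        f = min_div / (cfg.separation * max_h)
        for sub in subtrees:
            _scale_depths(sub, f)
        max_h *= f
    for leaf, sub in zip(sp_tips, subtrees):
        leaf.depth = sub.depth
        leaf.children = sub.children
        leaf.label = sub.label
    tree = parse_newick(_to_newick(sp_root))
    true_T = float(np.sqrt(max(max_h, min_div * 1e-9) * min_div))
    return tree, _truth_assignment(tree, groups, true_T)


def _iter_nodes(node: _N):
    stack = [node]
    while stack:
        v = stack.pop()
        yield v
        stack.extend(v.children)


def _truth_assignment(
    tree: UltrametricTree, tip_groups: Sequence[Sequence[str]], threshold: float
) -> ThresholdAssignment:
    label_to_idx = {tree.label[t]: t for t in tree.tips}
    entities = []
    for labels in tip_groups:
        idxs = tuple(label_to_idx[l] for l in labels)
        if len(idxs) == 1:
            entities.append(Entity(idxs[0], threshold, idxs, "singleton"))
        else:
            entities.append(
                Entity(_mrca(tree, idxs), threshold, idxs, "cluster")
            )
    return ThresholdAssignment(entities)


def _mrca(tree: UltrametricTree, nodes: Sequence[int]) -> int:
    ancestors = None
    for v in nodes:
        path = set()
        while True:
            path.add(v)
            if v == tree.root:
                break
            v = int(tree.parent[v])
        ancestors = path if ancestors is None else ancestors & path
    return min(ancestors, key=lambda v: tree.depth[v])


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    tree: UltrametricTree, length: int, rate: float = 1.0, seed: int = 0
) -> Alignment:
    """JC69 sequence simulation along the tree.

    Per site and branch, the substitution probability is
    ``3/4 * (1 - exp(-4*rate*len/3))``; a substituted site moves to one of
    the three other bases uniformly.  ``rate`` scales branch lengths, so
    with branch lengths already in substitutions/site use ``rate=1``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    states = np.empty((tree.n_nodes, length), dtype=np.int8)
    states[tree.root] = rng.integers(0, 4, size=length)
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent = states[tree.parent[v]]
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * rate * float(tree.length[v]) / 3.0))
        hit = rng.random(length) < p_sub
        child = parent.copy()
        if np.any(hit):
            child[hit] = (
                parent[hit] + 1 + rng.integers(0, 3, size=int(hit.sum()))
            ) % 4
        states[v] = child
    ids = [tree.label[t] or f"tip{t}" for t in tree.tips]
    seqs = ["".join("ACGT"[b] for b in states[t]) for t in tree.tips]
    return Alignment(ids=ids, seqs=seqs)


# ---------------------------------------------------------------------------
# rasters and occurrences


@dataclass
class RasterSimConfig:
    """Smooth latitudinal SST field with seasonal amplitude.

    mean(lat) = ``t_eq`` - ``delta_t`` * (|lat|/90)^2; the seasonal
    amplitude A(lat) = ``a0`` * |lat|/90 gives min = mean - A and
    max = mean + A.  Cell-wise Gaussian noise (sd ``sigma``) perturbs the
    mean surface before the layers are built, so min <= mean <= max holds
    by construction.  ``land`` lists (lat_min, lat_max, lon_min, lon_max)
    rectangles set to nodata.
    """

    nrows: int = 60
    ncols: int = 120
    cellsize: float = 3.0
    xllcorner: float = -180.0
    yllcorner: float = -90.0
    t_eq: float = 28.0
    delta_t: float = 30.0
    a0: float = 10.0
    sigma: float = 0.3
    nodata: float = -9999.0
    land: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.delta_t < 0 or self.a0 < 0 or self.sigma < 0:
            raise ValueError("delta_t, a0 and sigma must be non-negative")
        if self.nrows < 1 or self.ncols < 1 or self.cellsize <= 0:
            raise ValueError("invalid grid spec")


def simulate_sst_raster(cfg: RasterSimConfig) -> SstRaster:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spec = GridSpec(
        ncols=cfg.ncols,
        nrows=cfg.nrows,
        xllcorner=cfg.xllcorner,
        yllcorner=cfg.yllcorner,
        cellsize=cfg.cellsize,
        nodata=cfg.nodata,
    )
    lat = spec.cell_lats()[:, None] * np.ones((1, cfg.ncols))
    lon = np.ones((cfg.nrows, 1)) * spec.cell_lons()[None, :]
    frac = np.abs(lat) / 90.0
    mean = cfg.t_eq - cfg.delta_t * frac**2
    if cfg.sigma > 0:
        mean = mean + rng.normal(0.0, cfg.sigma, size=mean.shape)
    amp = cfg.a0 * frac
    tmin, tmax = mean - amp, mean + amp
    mask = np.zeros(mean.shape, dtype=bool)
    for (la0, la1, lo0, lo1) in cfg.land:
        mask |= (lat >= la0) & (lat <= la1) & (lon >= lo0) & (lon <= lo1)
    for layer in (tmin, mean, tmax):
        layer[mask] = cfg.nodata
    return SstRaster(spec=spec, tmin=tmin, tmean=mean, tmax=tmax)


def simulate_occurrences(
    raster: SstRaster,
    species: str,
    niche: Tuple[float, float],
    n: int,
    window: Optional[Tuple[float, float, float, float]] = None,
    seed: int = 0,
    replace: bool = True,
    provenance: str = "dna",
) -> List[OccurrenceRecord]:
    """Sample ``n`` occurrence records uniformly from raster cells whose
    minimum SST >= ``niche[0]`` and maximum SST <= ``niche[1]``.

    ``window`` optionally restricts sampling to (lat_min, lat_max,
    lon_min, lon_max).  Records sit at cell centers, so every returned
    record satisfies the suitability condition exactly.  Without
    replacement, requesting more records than suitable cells is an error.
    """
    lo, hi = niche
    rng = np.random.default_rng(seed)
    ok = raster.valid_mask() & (raster.tmin >= lo) & (raster.tmax <= hi)
    lat = raster.spec.cell_lats()[:, None] * np.ones((1, raster.spec.ncols))
    lon = np.ones((raster.spec.nrows, 1)) * raster.spec.cell_lons()[None, :]
    if window is not None:
        la0, la1, lo0, lo1 = window
        ok &= (lat >= la0) & (lat <= la1) & (lon >= lo0) & (lon <= lo1)
    rows, cols = np.nonzero(ok)
    if len(rows) == 0:
        raise ValueError("no suitable cell in window for the requested niche")
    if not replace and n > len(rows):
        raise ValueError(
            f"requested {n} distinct cells but only {len(rows)} are suitable"
        )
    pick = rng.choice(len(rows), size=n, replace=replace)
    return [
        OccurrenceRecord(
            species=species,
            lat=float(lat[rows[i], cols[i]]),
            lon=float(lon[rows[i], cols[i]]),
            provenance=provenance,
        )
        for i in pick
    ]


def graded_niche_world(
    seed: int,
    k: int = 8,
    n_records: int = 20,
    raster_cfg: Optional[RasterSimConfig] = None,
):
    """Raster plus occurrence records for ``k`` species with graded niche
    widths (narrow tropical specialists through broad eurythermal species).

    Species ``j`` tolerates SST in (28 - width_j, 30) deg C with width_j
    spread linearly from 4 to 30 deg C, so wider-niche species can occupy
    higher latitudes on the simulated gradient and should show both larger
    realized thermal ranges and larger latitudinal ranges.  Returns
    ``(SstRaster, list[OccurrenceRecord])``.
    """
    if raster_cfg is None:
        raster_cfg = RasterSimConfig(seed=(seed * 2 + 1) % 2**31)
    raster = simulate_sst_raster(raster_cfg)
    records: List[OccurrenceRecord] = []
    for j in range(k):
        width = 4.0 + 26.0 * j / max(k - 1, 1)
        niche = (28.0 - width, 30.0)
        records.extend(
            simulate_occurrences(
                raster,
                f"sp{j + 1}",
                niche,
                n=n_records,
                seed=(seed * 1009 + 13 * j + 5) % 2**31,
            )
        )
    return raster, records
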