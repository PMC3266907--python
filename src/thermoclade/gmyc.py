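"""Generalized mixed Yule-coalescent (GMYC) species delimitation.

The model locates the transition, on an ultrametric gene tree, between
interspecific branching (a generalized Yule process, rate ``lam1 * n**p1``
for ``n`` diversifying lineages) and intraspecific branching (a generalized
neutral coalescent, rate ``lam2 * (n*(n-1))**p2`` within each cluster of
``n`` lineages).  Tips coalescing below the threshold form clusters; tips
whose terminal branch crosses the threshold with no shallower node are
singletons.  Clusters plus singletons are the delimited entities.

Interval convention
-------------------
Time is swept from the root towards the tips and cut at every branching
event and at every threshold.  During a sub-interval the total branching
rate is ``b = lam1 * n_div**p1 + lam2 * sum_j (v_j*(v_j-1))**p2`` where
``n_div`` counts lineages still above their threshold and, for each cluster
``j`` that has entered its coalescent phase but not yet produced all of its
tips, ``v_j`` is the lineage count the cluster will hold after its next
event.  A sub-interval terminated by an event contributes ``log b - b*x``;
an event-free sub-interval contributes ``-b*x``; a cluster whose tips are
all present contributes nothing.  The root event opens the process and
carries no ``log`` term.  With the threshold at depth 0 (every tip a
singleton) the model reduces exactly to the single-process null model,
which guarantees a non-negative likelihood-ratio statistic.

The significance of the rate shift is assessed with a likelihood-ratio
test against the single-process null, referred to a chi-square distribution
with 3 degrees of freedom; the confidence set for the entity count collects
all scanned solutions within 2 log-likelihood units of the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .treeio import (
    BranchingSchedule,
    TreeError,
    UltrametricTree,
    branching_schedule,
)

__all__ = [
    "NullParams",
    "GmycParams",
    "Entity",
    "ThresholdAssignment",
    "GmycResult",
    "AssignmentError",
    "classify_nodes",
    "loglik_null",
    "fit_null",
    "loglik_gmyc",
    "fit_at_threshold",
    "fit_single_threshold",
    "fit_multiple_threshold",
    "lr_test",
    "entity_confidence",
    "delimitation_table",
]

LOG10_LAM_BOUNDS = (-8.0, 6.0)
P_BOUNDS = (-3.0, 5.0)
LR_DF = 3
CONF_DELTA = 2.0  # log-likelihood units defining the confidence set
_MERGE_TOL = 1e-10


class AssignmentError(ValueError):
    """Threshold assignment inconsistent with the tree."""


@dataclass
class NullParams:
    """Single-process branching model: rate ``lam * n**p``."""

    lam: float
    p: float
    loglik: float


@dataclass
class GmycParams:
    lam1: float  # diversification (Yule) rate scale
    p1: float
    lam2: float  # coalescent rate scale
    p2: float


@dataclass
class Entity:
    """One delimited entity: a cluster (>=2 tips) or a singleton tip.

    ``root`` is the tree node whose subtree holds the entity's tips and
    ``threshold`` the depth at which its stem switches to the coalescent
    process.
    """

    root: int
    threshold: float
    tips: tuple
    kind: str  # "cluster" | "singleton"

    @property
    def n_tips(self) -> int:
        return len(self.tips)


@dataclass
class ThresholdAssignment:
    entities: list

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def clusters(self) -> list:
        return [e for e in self.entities if e.kind == "cluster"]

    @property
    def singletons(self) -> list:
        return [e for e in self.entities if e.kind == "singleton"]

    @property
    def thresholds(self) -> list:
        return [e.threshold for e in self.entities]

    def node_classes(self, tree: UltrametricTree) -> np.ndarray:
        """Per-node class: coalescent inside an entity subtree, else
        diversification (a node is diversification iff deeper than its
        governing threshold)."""
        cls = np.array(["diversification"] * tree.n_nodes, dtype=object)
        for e in self.entities:
            stack = [e.root]
            while stack:
                v = stack.pop()
                cls[v] = "coalescent"
                stack.extend(tree.children[v])
        return cls

    def tip_entity(self, tree: UltrametricTree) -> dict:
        """Map tip label -> entity index (entities in stored order)."""
        out = {}
        for i, e in enumerate(self.entities):
            for t in e.tips:
                out[tree.label[t]] = i
        return out

    def _key(self):
        return tuple(sorted((e.root, round(e.threshold, 12)) for e in self.entities))


@dataclass
class GmycResult:
    model: str  # "single" | "multiple"
    assignment: ThresholdAssignment
    params: GmycParams
    loglik: float
    null: NullParams
    lr: float
    pvalue: float
    n_entities: int
    ci: tuple
    scan: pd.DataFrame  # columns: threshold, loglik, n_entities
    threshold: Optional[float] = None  # single-threshold depth
    boundary: bool = False
    converged: bool = True
    n_accepted_moves: int = 0
    max_iter_exhausted: bool = False

    @property
    def clusters(self) -> list:
        return self.assignment.clusters

    @property
    def singletons(self) -> list:
        return self.assignment.singletons

    def summary(self) -> dict:
        """JSON-able summary mirroring the standard delimitation report."""
        return {
            "model": self.model,
            "threshold": self.threshold,
            "n_entities": self.n_entities,
            "n_clusters": len(self.clusters),
            "n_singletons": len(self.singletons),
            "ci": list(self.ci),
            "loglik_null": self.null.loglik,
            "loglik_gmyc": self.loglik,
            "lr": self.lr,
            "pvalue": self.pvalue,
            "params": {
                "lam1": self.params.lam1,
                "p1": self.params.p1,
                "lam2": self.params.lam2,
                "p2": self.params.p2,
            },
            "boundary": self.boundary,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# classification


def classify_nodes(tree: UltrametricTree, T: float) -> ThresholdAssignment:
    """Partition tips into entities at a single threshold depth ``T``.

    Nodes deeper than ``T`` belong to the diversification process.  Each
    maximal node at depth <= ``T`` roots one entity: a cluster of its tips
    if internal, a singleton if it is a tip.  ``T`` at or beyond the root
    yields one all-tip entity; ``T = 0`` yields all singletons.
    """
    if T < 0:
        raise ValueError("threshold must be non-negative")
    entities = []
    if T >= tree.root_depth:
        tips = tuple(tree.subtree_tips(tree.root))
        kind = "cluster" if len(tips) >= 2 else "singleton"
        return ThresholdAssignment([Entity(tree.root, float(T), tips, kind)])
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if tree.depth[v] <= T:
            tips = tuple(tree.subtree_tips(v))
            kind = "cluster" if tree.children[v] else "singleton"
            entities.append(Entity(v, float(T), tips, kind))
        else:
            stack.extend(reversed(tree.children[v]))
    return ThresholdAssignment(entities)


# ---------------------------------------------------------------------------
# null (single-process) model


def loglik_null(schedule: BranchingSchedule, lam: float, p: float) -> float:
    """Log-likelihood of the single-process model ``b_i = lam * n_i**p``."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    b = lam * schedule.counts.astype(float) ** p
    return float(
        np.sum(np.log(b[schedule.ends_in_event]))
        - np.sum(b * schedule.durations)
    )


def fit_null(
    schedule: BranchingSchedule, fix_p: Optional[float] = None
) -> NullParams:
    """ML fit of the null model.

    For fixed ``p`` the rate scale has the closed form
    ``lam = E / sum(n_i**p * x_i)`` with ``E`` the number of
    event-terminated intervals; the free-``p`` fit profiles that closed
    form over a bounded ``p`` search.
    """
    ev = schedule.ends_in_event
    E = int(np.sum(ev))
    if E < 1:
        raise ValueError("degenerate schedule: no event-terminated interval")
    n = schedule.counts.astype(float)
    x = schedule.durations

    def lam_hat(p: float) -> float:
        denom = float(np.sum(n**p * x))
        return float(np.clip(E / denom, 10.0 ** LOG10_LAM_BOUNDS[0], 10.0 ** LOG10_LAM_BOUNDS[1]))

    def negll(p: float) -> float:
        return -loglik_null(schedule, lam_hat(p), p)

    if fix_p is not None:
        p = float(fix_p)
    else:
        res = optimize.minimize_scalar(
            negll, bounds=P_BOUNDS, method="bounded",
            options={"xatol": 1e-10},
        )
        p = float(res.x)
    lam = lam_hat(p)
    return NullParams(lam=lam, p=p, loglik=loglik_null(schedule, lam, p))


# ---------------------------------------------------------------------------
# interval structure for the mixed model


@dataclass
class _Structure:
    """Pre-digested sub-interval data for fast likelihood evaluation."""

    x: np.ndarray  # durations
    ev: np.ndarray  # bool: terminated by a branching event
    ndiv: np.ndarray  # diversifying lineages per sub-interval
    P: np.ndarray  # (K, n_v) counts of active clusters by pending size
    vv: np.ndarray  # v*(v-1) for each column of P
    logn: np.ndarray = None  # ln(ndiv) where ndiv > 0, else 0
    logvv: np.ndarray = None

    def __post_init__(self):
        self.logn = np.log(np.maximum(self.ndiv, 1.0))
        self.logvv = np.log(self.vv) if len(self.vv) else self.vv


def _build_structure(
    tree: UltrametricTree, assignment: ThresholdAssignment
) -> _Structure:
    root_depth = tree.root_depth
    ent_of = np.full(tree.n_nodes, -1, dtype=int)
    m_j = np.empty(len(assignment.entities), dtype=int)
    for j, e in enumerate(assignment.entities):
        m_j[j] = e.n_tips
        stack = [e.root]
        while stack:
            v = stack.pop()
            ent_of[v] = j
            stack.extend(tree.children[v])

    # pseudo-edges: (top, bottom, cid) with cid = -1 for diversification
    tops, bots, cids = [], [], []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        top = float(tree.depth[tree.parent[v]])
        bot = float(tree.depth[v])
        j = ent_of[v]
        if j < 0:
            tops.append(top), bots.append(bot), cids.append(-1)
        elif v == assignment.entities[j].root:
            t = min(assignment.entities[j].threshold, root_depth)
            if t >= top - _MERGE_TOL:
                raise AssignmentError(
                    "entity threshold at or above its stem's parent node"
                )
            tops.append(top), bots.append(float(t)), cids.append(-1)
            tops.append(float(t)), bots.append(bot), cids.append(j)
        else:
            tops.append(top), bots.append(bot), cids.append(j)
    tops = np.asarray(tops)
    bots = np.asarray(bots)
    cids = np.asarray(cids, dtype=int)

    cuts = np.concatenate(
        [
            tree.depth[tree.internal_nodes()],
            np.clip([e.threshold for e in assignment.entities], 0.0, root_depth),
            [0.0],
        ]
    )
    cuts = np.sort(cuts)[::-1]
    keep = np.concatenate([[True], np.diff(cuts) < -_MERGE_TOL])
    cuts = cuts[keep]
    hi, lo = cuts[:-1], cuts[1:]
    x = hi - lo
    mid = 0.5 * (hi + lo)

    internal_depths = np.sort(np.unique(tree.depth[tree.internal_nodes()]))
    pos = np.searchsorted(internal_depths, lo)
    near = np.zeros(len(lo), dtype=bool)
    for off in (0, 1):
        idx = np.clip(pos - 1 + off, 0, len(internal_depths) - 1)
        near |= np.abs(internal_depths[idx] - lo) < _MERGE_TOL
    ev = near & (lo > _MERGE_TOL)

    cover = (bots[:, None] <= mid[None, :] + _MERGE_TOL) & (
        tops[:, None] >= mid[None, :] - _MERGE_TOL
    )
    ndiv = cover[cids < 0].sum(axis=0)

    n_ent = len(assignment.entities)
    k = np.zeros((n_ent, len(mid)), dtype=int)
    for row, j in zip(cover, cids):
        if j >= 0:
            k[j] += row
    active = (k > 0) & (k < m_j[:, None])
    v = k + 1
    vmax = int(v[active].max()) if np.any(active) else 2
    P = np.zeros((len(mid), vmax + 1), dtype=float)
    jj, ii = np.nonzero(active)
    np.add.at(P, (ii, v[jj, ii]), 1.0)
    vcols = np.arange(vmax + 1, dtype=float)
    used = P.sum(axis=0) > 0
    used[:2] = False
    P = P[:, used]
    vv = (vcols * (vcols - 1))[used]

    # structural consistency: an event-terminated interval must have a
    # positive rate for some admissible parameters
    bad = ev & (ndiv == 0) & (P.sum(axis=1) == 0)
    if np.any(bad):
        raise AssignmentError(
            "zero branching rate on an event-terminated interval"
        )
    return _Structure(x=x, ev=ev, ndiv=ndiv.astype(float), P=P, vv=vv)


def _loglik_structure(
    S: _Structure, lam1: float, p1: float, lam2: float, p2: float
) -> float:
    A = (S.ndiv > 0) * np.exp(p1 * S.logn)
    C = S.P @ np.exp(p2 * S.logvv) if S.P.shape[1] else 0.0
    b = lam1 * A + lam2 * C
    bev = b[S.ev]
    if bev.min(initial=np.inf) <= 0:
        return -np.inf
    return float(np.log(bev).sum() - (b * S.x).sum())


def _loglik_grad_structure(vec: np.ndarray, S: _Structure, fix_p):
    """Negative log-likelihood and gradient in the optimization coordinates
    (log10 lam1[, p1], log10 lam2[, p2])."""
    if fix_p is None:
        u1, p1, u2, p2 = vec
    else:
        u1, u2 = vec
        p1, p2 = fix_p
    lam1, lam2 = 10.0**u1, 10.0**u2
    mask = S.ndiv > 0
    A = mask * np.exp(p1 * S.logn)
    if S.P.shape[1]:
        w = np.exp(p2 * S.logvv)
        C = S.P @ w
        dC = S.P @ (w * S.logvv)
    else:
        C = np.zeros_like(S.x)
        dC = C
    b = lam1 * A + lam2 * C
    bev = b[S.ev]
    if bev.min(initial=np.inf) <= 0:
        g = np.zeros_like(np.asarray(vec, dtype=float))
        return np.inf, g
    ll = np.log(bev).sum() - (b * S.x).sum()
    inv = np.zeros_like(b)
    inv[S.ev] = 1.0 / bev
    coef = inv - S.x  # d lnL / d b_i
    dA_dp1 = A * S.logn
    d_lam1 = float(coef @ A)
    d_p1 = float(coef @ dA_dp1) * lam1
    d_lam2 = float(coef @ C)
    d_p2 = float(coef @ dC) * lam2
    ln10 = np.log(10.0)
    if fix_p is None:
        grad = np.array(
            [d_lam1 * lam1 * ln10, d_p1, d_lam2 * lam2 * ln10, d_p2]
        )
    else:
        grad = np.array([d_lam1 * lam1 * ln10, d_lam2 * lam2 * ln10])
    return -float(ll), -grad


def loglik_gmyc(
    tree: UltrametricTree,
    assignment: ThresholdAssignment,
    params: GmycParams,
) -> float:
    """Mixed-model log-likelihood under the documented interval convention."""
    if params.lam1 < 0 or params.lam2 < 0:
        raise ValueError("rate scales must be non-negative")
    S = _build_structure(tree, assignment)
    return _loglik_structure(S, params.lam1, params.p1, params.lam2, params.p2)


# ---------------------------------------------------------------------------
# fitting


def _fit_structure(
    S: _Structure,
    fix_p: Optional[tuple] = None,
    extra_starts: Sequence[np.ndarray] = (),
    n_restarts: int = 5,
    tol: float = 1e-8,
):
    """Maximize the structure likelihood over (lam1, p1, lam2, p2).

    Bounded quasi-Newton (L-BFGS-B) search with analytic gradients over
    (log10 lam1, p1, log10 lam2, p2), from a deterministic ladder of start
    points (moment-matched rate scales at a few exponents, plus
    caller-provided warm starts).  Restarts stop early once they cease to
    improve the incumbent by more than ``tol`` log units.
    """
    E = max(int(np.sum(S.ev)), 1)
    expo = float(np.sum(S.ndiv * S.x) + np.sum((S.P @ S.vv) * S.x)) if S.P.shape[1] else float(np.sum(S.ndiv * S.x))
    lam0 = np.clip(E / max(expo, 1e-300), 1e-6, 1e6)
    l0 = float(np.log10(lam0))
    base = [
        (l0, 1.0, l0, 1.0),
        (l0 + 1.0, 1.0, l0 - 1.0, 1.0),
        (l0 - 1.0, 1.0, l0 + 1.0, 1.0),
        (l0, 0.2, l0, 0.2),
        (l0, 2.0, l0, 2.0),
    ]
    if fix_p is not None:
        pfix = (float(fix_p[0]), float(fix_p[1]))
        bounds = [LOG10_LAM_BOUNDS, LOG10_LAM_BOUNDS]
        take = lambda s: np.array([s[0], s[2]], dtype=float)
        make = lambda v: (10.0 ** v[0], pfix[0], 10.0 ** v[1], pfix[1])
        args = pfix
    else:
        pfix = None
        bounds = [LOG10_LAM_BOUNDS, P_BOUNDS, LOG10_LAM_BOUNDS, P_BOUNDS]
        take = lambda s: np.asarray(s, dtype=float)
        make = lambda v: (10.0 ** v[0], float(v[1]), 10.0 ** v[2], float(v[3]))
        args = None
    # extra_starts are already in optimization coordinates
    starts = [np.asarray(s, dtype=float) for s in extra_starts] + [
        take(np.asarray(s, dtype=float)) for s in base
    ]

    lob = np.array([b[0] for b in bounds])
    upb = np.array([b[1] for b in bounds])
    best = None
    stale = 0
    converged = False
    for i, x0 in enumerate(starts[: max(n_restarts, 1) + len(extra_starts)]):
        res = optimize.minimize(
            _loglik_grad_structure,
            np.clip(x0, lob, upb),
            args=(S, pfix),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - tol:
            best = res
            stale = 0
        else:
            stale += 1
        converged = converged or bool(res.success)
        if i >= 1 + len(extra_starts) and stale >= 2:
            break
    lam1, p1, lam2, p2 = make(best.x)
    ll = -float(best.fun)
    boundary = bool(
        np.any(np.abs(best.x - lob) < 1e-3) or np.any(np.abs(best.x - upb) < 1e-3)
    )
    params = GmycParams(lam1=lam1, p1=p1, lam2=lam2, p2=p2)
    return params, ll, boundary, converged, np.asarray(best.x, dtype=float)


def fit_at_threshold(
    tree: UltrametricTree,
    T: float,
    fix_p: Optional[tuple] = None,
    n_restarts: int = 5,
    seed: Optional[int] = None,
):
    """ML fit of the mixed model at a fixed threshold depth.

    Returns ``(GmycParams, loglik)``.  The optimizer start ladder is
    deterministic, so identical inputs give identical fits (``seed`` is
    accepted for interface symmetry and does not alter the result).
    """
    assignment = classify_nodes(tree, T)
    S = _build_structure(tree, assignment)
    params, ll, boundary, converged, _ = _fit_structure(
        S, fix_p=fix_p, n_restarts=n_restarts
    )
    if not converged:
        warnings.warn("optimizer did not report convergence; best point returned")
    return params, ll


def _candidate_cells(tree: UltrametricTree) -> list:
    """Candidate threshold cells, deepest first.

    Each cell is a depth interval (lo, hi) between consecutive distinct
    event depths inducing one tip partition; its canonical (reported)
    threshold is the midpoint.  The likelihood of the partition is profiled
    over the cell: it is linear in the threshold at fixed rates, so the
    within-cell profile maximum lies at a cell edge and evaluating both
    near-edge points is exact.  The list also holds the all-coalescent
    cell beyond the root (likelihood constant there) and the bottom cell
    whose deep edge is the all-singleton threshold 0, where the model
    reduces to the null.  Returns (midpoint, [eval points]) pairs.
    """
    d = np.sort(np.unique(tree.depth[tree.internal_nodes()]))[::-1]
    cells = [(float(d[0] * 1.05), [float(d[0] * 1.05)])]
    for lo, hi in zip(d[1:], d[:-1]):
        eps = 1e-3 * (hi - lo)
        if eps > 10 * _MERGE_TOL:
            points = [float(hi - eps), float(lo + eps)]
        else:  # cell too narrow to probe its edges distinctly
            points = [float(0.5 * (lo + hi))]
        cells.append((float(0.5 * (lo + hi)), points))
    dk = float(d[-1])
    eps = 1e-3 * dk
    points = [0.0] if eps <= 10 * _MERGE_TOL else [float(dk - eps), 0.0]
    cells.append((0.5 * dk, points))
    return cells


def fit_single_threshold(
    tree: UltrametricTree,
    fix_p: Optional[tuple] = None,
    n_restarts: int = 5,
) -> GmycResult:
    """Scan candidate thresholds, fit the mixed model at each, and report
    the maximum-likelihood delimitation with its LR test and confidence set.

    Candidates sit at midpoints between consecutive distinct event depths,
    plus an all-singleton candidate at depth 0 (which reduces the model to
    the null and so guarantees ``LR >= 0``) and an all-coalescent candidate
    beyond the root.  A threshold identifies a partition of the tips; the
    midpoint of the depth interval inducing that partition is its canonical
    reported value, and the likelihood of a delimitation is evaluated at
    that canonical depth.
    """
    if tree.n_tips < 3:
        raise TreeError("single-threshold fit requires at least 3 tips")
    sched = branching_schedule(tree)
    null = fit_null(sched, fix_p=None if fix_p is None else fix_p[0])

    rows = []
    best = None
    warm: list = []
    for T_mid, points in _candidate_cells(tree):
        cell_best = None
        for T in points:
            assignment = classify_nodes(tree, float(T))
            S = _build_structure(tree, assignment)
            params, ll, boundary, converged, xbest = _fit_structure(
                S, fix_p=fix_p, extra_starts=warm, n_restarts=n_restarts
            )
            warm = [xbest]
            if cell_best is None or ll > cell_best["loglik"]:
                cell_best = {
                    "T": float(T_mid),
                    "loglik": ll,
                    "assignment": assignment,
                    "params": params,
                    "boundary": boundary,
                    "converged": converged,
                    "x": xbest,
                }
        rows.append(
            (cell_best["T"], cell_best["loglik"], cell_best["assignment"].n_entities)
        )
        if (
            best is None
            or cell_best["loglik"] > best["loglik"] + 1e-12
            or (
                abs(cell_best["loglik"] - best["loglik"]) <= 1e-12
                and cell_best["T"] > best["T"]
            )
        ):
            best = cell_best

    scan = pd.DataFrame(rows, columns=["threshold", "loglik", "n_entities"])
    lr, pvalue = lr_test(null.loglik, best["loglik"])
    ci = entity_confidence(scan)
    return GmycResult(
        model="single",
        assignment=best["assignment"],
        params=best["params"],
        loglik=best["loglik"],
        null=null,
        lr=lr,
        pvalue=pvalue,
        n_entities=best["assignment"].n_entities,
        ci=ci,
        scan=scan,
        threshold=best["T"],
        boundary=best["boundary"],
        converged=best["converged"],
    )


# ---------------------------------------------------------------------------
# multiple-threshold model


def _recluster(tree: UltrametricTree, node: int, T: float) -> list:
    """Entities obtained by cutting the subtree of ``node`` at depth ``T``."""
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        if tree.depth[v] <= T:
            tips = tuple(tree.subtree_tips(v))
            kind = "cluster" if tree.children[v] else "singleton"
            out.append(Entity(v, float(T), tips, kind))
        else:
            stack.extend(reversed(tree.children[v]))
    return out


def _cell_edge_points(lo: float, hi: float) -> list:
    """Near-edge evaluation points of a threshold cell (profile maximum of
    the within-cell likelihood; see the single-threshold scan)."""
    eps = 1e-3 * (hi - lo)
    if eps > 10 * _MERGE_TOL:
        return [float(hi - eps), float(lo + eps)]
    return [float(0.5 * (lo + hi))]


def _moves(tree: UltrametricTree, assignment: ThresholdAssignment) -> list:
    """Candidate re-clusterings: per entity, shift its local threshold one
    event deeper (absorbing its parent's subtree) or one event shallower
    (splitting the cluster).  Each proposal is evaluated at both near-edge
    points of the new local threshold cell.  Deeper candidates first."""
    d_all = np.sort(np.unique(tree.depth[tree.internal_nodes()]))
    proposals = []
    for idx, e in enumerate(assignment.entities):
        # shallower: split a cluster within the cell below its root depth
        if e.kind == "cluster":
            sub_internal = [
                v for v in _subtree_nodes(tree, e.root) if tree.children[v]
            ]
            depths = np.sort(np.unique(tree.depth[sub_internal]))[::-1]
            d_next = float(depths[1]) if len(depths) > 1 else 0.0
            others = [x for i, x in enumerate(assignment.entities) if i != idx]
            for T_new in _cell_edge_points(d_next, float(tree.depth[e.root])):
                proposals.append(
                    (
                        T_new,
                        ThresholdAssignment(
                            others + _recluster(tree, e.root, T_new)
                        ),
                    )
                )
        # deeper: absorb the parent's subtree into one cluster
        if e.root != tree.root:
            p = int(tree.parent[e.root])
            dp = float(tree.depth[p])
            deeper = d_all[d_all > dp + _MERGE_TOL]
            top = float(deeper[0]) if len(deeper) else dp * 1.05
            absorbed = set(_subtree_nodes(tree, p))
            kept = [x for x in assignment.entities if x.root not in absorbed]
            tips = tuple(tree.subtree_tips(p))
            kind = "cluster" if len(tips) >= 2 else "singleton"
            for T_new in _cell_edge_points(dp, top):
                proposals.append(
                    (T_new, ThresholdAssignment(kept + [Entity(p, T_new, tips, kind)]))
                )
    proposals.sort(key=lambda t: -t[0])
    return [a for _, a in proposals]


def _subtree_nodes(tree: UltrametricTree, node: int) -> list:
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children[v])
    return out


def fit_multiple_threshold(
    tree: UltrametricTree,
    max_iter: int = 50,
    fix_p: Optional[tuple] = None,
    n_restarts: int = 5,
    single: Optional[GmycResult] = None,
) -> GmycResult:
    """Greedy stepwise multiple-threshold fit seeded at the single-threshold
    optimum.

    At each iteration every entity proposes shifting its local threshold one
    event deeper (absorbing its parent's subtree) or shallower (splitting),
    the model is refit for each proposal, and the best strictly improving
    move is accepted; the search stops at a fixed point or after
    ``max_iter`` iterations.  The seed state guarantees
    ``loglik >= single-threshold loglik``.
    """
    if single is None:
        single = fit_single_threshold(
            tree, fix_p=fix_p, n_restarts=n_restarts
        )
    current = single.assignment
    cur_ll = single.loglik
    cur_params = single.params
    cur_x = None
    visited = {current._key()}
    rows = [(np.nan, cur_ll, current.n_entities)]
    accepted = 0
    exhausted = False
    boundary = single.boundary
    for it in range(max_iter):
        best_cand = None
        for cand in _moves(tree, current):
            key = cand._key()
            if key in visited:
                continue
            visited.add(key)
            try:
                S = _build_structure(tree, cand)
            except AssignmentError:
                continue
            params, ll, bnd, conv, xb = _fit_structure(
                S,
                fix_p=fix_p,
                extra_starts=[cur_x] if cur_x is not None else [],
                n_restarts=n_restarts,
            )
            rows.append((np.nan, ll, cand.n_entities))
            if ll > cur_ll + 1e-9 and (
                best_cand is None or ll > best_cand[1]
            ):
                best_cand = (cand, ll, params, bnd, xb)
        if best_cand is None:
            break
        current, cur_ll, cur_params, bnd, cur_x = best_cand
        boundary = boundary or bnd
        accepted += 1
    else:
        exhausted = True
        warnings.warn("multiple-threshold search exhausted max_iter")

    scan = pd.DataFrame(rows, columns=["threshold", "loglik", "n_entities"])
    lr, pvalue = lr_test(single.null.loglik, cur_ll)
    ci = entity_confidence(scan[["loglik", "n_entities"]].assign(loglik=scan["loglik"]))
    return GmycResult(
        model="multiple",
        assignment=current,
        params=cur_params,
        loglik=cur_ll,
        null=single.null,
        lr=lr,
        pvalue=pvalue,
        n_entities=current.n_entities,
        ci=ci,
        scan=scan,
        threshold=None,
        boundary=boundary,
        converged=single.converged,
        n_accepted_moves=accepted,
        max_iter_exhausted=exhausted,
    )


# ---------------------------------------------------------------------------
# tests and summaries


def lr_test(L0: float, L1: float) -> tuple:
    """Likelihood-ratio statistic ``2*(L1 - L0)`` with a chi-square(3)
    p-value; a negative ratio is floored at zero with a warning."""
    lr = 2.0 * (L1 - L0)
    if lr < 0:
        warnings.warn("alternative log-likelihood below null; LR floored at 0")
        lr = 0.0
    return float(lr), float(stats.chi2.sf(lr, LR_DF))


def entity_confidence(scan: pd.DataFrame) -> tuple:
    """(N_min, N_max) over scanned solutions within 2 log-likelihood units
    of the maximum."""
    if len(scan) == 0:
        raise ValueError("empty scan table")
    ll = scan["loglik"].to_numpy(dtype=float)
    n = scan["n_entities"].to_numpy()
    keep = ll >= np.nanmax(ll) - CONF_DELTA
    return (int(np.min(n[keep])), int(np.max(n[keep])))


def delimitation_table(tree: UltrametricTree, result: GmycResult) -> pd.DataFrame:
    """Per-tip table: tip label, entity id (1-based), entity kind."""
    rows = []
    for i, e in enumerate(result.assignment.entities, start=1):
        for t in e.tips:
            rows.append((tree.label[t], i, e.kind))
    return pd.DataFrame(rows, columns=["tip", "entity", "kind"]).sort_values(
        "tip", kind="stable", ignore_index=True
    )
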