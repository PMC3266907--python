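"""Independent reference computations used by the test suite.

These deliberately avoid the package's optimizer and scan machinery: the
mixed-model reference maximizes the likelihood by brute-force grid search
over the threshold evaluation points and a dense two-stage rate grid, and
the simple-model references use closed forms.
"""

from __future__ import annotations

import numpy as np

from thermoclade.gmyc import _build_structure, classify_nodes
from thermoclade.treeio import UltrametricTree

LAM_LO, LAM_HI = 1e-8, 1e6


def _grid_loglik(S, lam1_grid: np.ndarray, lam2_grid: np.ndarray) -> np.ndarray:
    """lnL surface over a (lam1, lam2) grid with p1 = p2 = 1."""
    A = S.ndiv.astype(float)
    C = S.P @ S.vv if S.P.shape[1] else np.zeros_like(S.x)
    SA = float(np.sum(A * S.x))
    SC = float(np.sum(C * S.x))
    L1 = lam1_grid[:, None]
    L2 = lam2_grid[None, :]
    out = -(L1 * SA + L2 * SC) * np.ones((len(lam1_grid), len(lam2_grid)))
    for a, c in zip(A[S.ev], C[S.ev]):
        b = L1 * a + L2 * c
        with np.errstate(divide="ignore"):
            out = out + np.log(b)
    return out


def _threshold_points(tree: UltrametricTree) -> list:
    """The model's threshold evaluation points: both near-edge points of
    every inter-event cell, the all-singleton depth 0, and one beyond-root
    point (where the likelihood is constant in the threshold)."""
    d = np.sort(np.unique(tree.depth[tree.internal_nodes()]))[::-1]
    pts = [float(d[0] * 1.05)]
    for lo, hi in zip(d[1:], d[:-1]):
        eps = 1e-3 * (hi - lo)
        pts += [float(hi - eps), float(lo + eps)]
    pts += [float(d[-1]) * (1 - 1e-3), 0.0]
    return pts


def brute_force_gmyc_loglik(tree: UltrametricTree, n_grid: int = 200) -> float:
    """Best mixed-model lnL (p1 = p2 = 1) by exhaustive grid search.

    For every threshold evaluation point, a coarse ``n_grid`` x ``n_grid``
    log-spaced rate grid over [1e-8, 1e6] is scanned and then refined with
    a second ``n_grid`` x ``n_grid`` grid spanning one coarse step around
    the coarse argmax.
    """
    lo, hi = np.log10(LAM_LO), np.log10(LAM_HI)
    coarse = np.logspace(lo, hi, n_grid)
    step = np.log10(coarse[1]) - np.log10(coarse[0])

    def refine(center):
        c = np.log10(center)
        return np.logspace(max(c - step, lo), min(c + step, hi), n_grid)

    best = -np.inf
    for T in _threshold_points(tree):
        S = _build_structure(tree, classify_nodes(tree, T))
        surf = _grid_loglik(S, coarse, coarse)
        i, j = np.unravel_index(np.argmax(surf), surf.shape)
        best = max(
            best,
            float(np.max(_grid_loglik(S, refine(coarse[i]), refine(coarse[j])))),
        )
    return best


def yule_lambda_closed_form(schedule) -> float:
    """ML rate of the single-process model with p fixed at 1:
    (number of event-terminated intervals) / sum(n_i * x_i)."""
    E = int(np.sum(schedule.ends_in_event))
    return E / float(np.sum(schedule.counts * schedule.durations))


def jc_expected_p_distance(d: float) -> float:
    """Expected proportion of differing sites between two sequences at
    path distance ``d`` substitutions/site under JC69."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
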