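"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most naive correct procedure
available (enumeration, flood fill, direct formula) so the package's
implementations can be checked against a path they do not share.
"""

from collections import deque

import numpy as np
from scipy.optimize import minimize


def qp_dual_svm(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Solve the soft-margin SVM dual with a generic constrained QP solver.

    Returns the dual objective sum(a) - 1/2 a'Qa at the optimum.
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def neg_obj_grad(a):
        return Q @ a - np.ones(n)

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = minimize(
        neg_obj,
        np.full(n, min(C, 1.0) / 2),
        jac=neg_obj_grad,
        bounds=[(0.0, C)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return float(-res.fun)


def bh_stepup(p: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up rule, O(m log m)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D boolean lattice by BFS flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(comp)
    return comps


def pairwise_auc(y: np.ndarray, risk: np.ndarray, positive=-1) -> float:
    """AUC by exhaustive pair counting: concordant + half ties."""
    pos = risk[y == positive]
    neg = risk[y != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def manual_spearman(x, y):
    """Spearman rho via explicit mid-rank assignment and Pearson on ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
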