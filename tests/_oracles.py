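"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the LP optimum is
recomputed by brute-force vertex enumeration, GPR truth values by Python's
own boolean evaluator, and set statistics by naive enumeration.
"""

from __future__ import annotations

import itertools
import re

import numpy as np


def vertex_enumeration_max(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray,
                           tol: float = 1e-8) -> float:
    """Maximum of c·v over {v : S v = 0, lb <= v <= ub} by enumerating basic
    feasible points (every subset of variables held at a bound).

    Assumes finite bounds (bounded polytope), so the optimum is attained at
    a vertex.  Exponential in the number of reactions; fixtures keep n <= 8.
    """
    n = S.shape[1]
    best = -np.inf
    for assignment in itertools.product((0, 1, 2), repeat=n):
        fixed_idx = [j for j, a in enumerate(assignment) if a != 2]
        free_idx = [j for j, a in enumerate(assignment) if a == 2]
        v = np.zeros(n)
        for j in fixed_idx:
            v[j] = lb[j] if assignment[j] == 0 else ub[j]
        if free_idx:
            A = S[:, free_idx]
            if np.linalg.matrix_rank(A, tol=1e-10) < len(free_idx):
                continue  # not a unique basic point
            rhs = -S[:, fixed_idx] @ v[fixed_idx] if fixed_idx else np.zeros(S.shape[0])
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free_idx] = x
        if np.max(np.abs(S @ v)) > tol:
            continue
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            continue
        best = max(best, float(c @ v))
    return best


_WORD = re.compile(r"[^\s()]+")


def gpr_truth(expression: str, present: set[str]) -> bool:
    """Evaluate a GPR string with Python's own boolean machinery."""

    def sub(match: re.Match) -> str:
        word = match.group(0)
        if word.lower() in ("and", "or"):
            return word.lower()
        return str(word in present)

    return bool(eval(_WORD.sub(sub, expression)))  # noqa: S307 - test oracle


def classify_by_membership(group_sets: dict[str, set]) -> tuple[set, set, dict[str, set]]:
    """Naive common/dispensable/specific partition by counting memberships."""
    union = set().union(*group_sets.values())
    common, dispensable = set(), set()
    specific: dict[str, set] = {g: set() for g in group_sets}
    for element in union:
        hits = [g for g, s in group_sets.items() if element in s]
        if len(hits) == len(group_sets):
            common.add(element)
        elif len(hits) == 1:
            specific[hits[0]].add(element)
        else:
            dispensable.add(element)
    return common, dispensable, specific


def random_network(rng: np.random.Generator, n_rxns: int, n_mets: int):
    """A random bounded flux polytope: sparse integer S, finite bounds with
    0 always feasible.  Returns (S, lb, ub, objective index)."""
    while True:
        S = np.zeros((n_mets, n_rxns))
        for j in range(n_rxns):
            k = rng.integers(1, min(3, n_mets) + 1)
            rows = rng.choice(n_mets, size=k, replace=False)
            S[rows, j] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        if np.all(np.any(S != 0, axis=0)):
            break
    ub = rng.uniform(0.5, 10.0, size=n_rxns)
    lb = np.where(rng.random(n_rxns) < 0.5, 0.0, -rng.uniform(0.5, 10.0, size=n_rxns))
    obj = int(rng.integers(0, n_rxns))
    return S, lb, ub, obj
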