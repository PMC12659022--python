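"""Brute-force reference layer for small spin systems.

CSFs are expanded in the determinant (spin-string) basis of the ``M_S = S``
sector by sequential genealogical Clebsch-Gordan coupling.  For Heisenberg
systems this sector contains every total-spin block ``S' >= S`` exactly
once, so projecting the determinant Hamiltonian ``H = sum (-2 g_ij)
S_i.S_j`` onto the CSF expansion vectors isolates the spin-``S`` block
without any off-diagonal GUGA segment algebra.  The layer provides ground
states, L4 compactness norms, cumulative-partial-spin commutator reports
and exhaustive ordering scans for desk-scale systems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .csf import CSF, cumulative_profile, enumerate_vvs
from .hamiltonians import CouplingMatrix, apply_ordering, t_matrix

__all__ = [
    "csf_to_det",
    "csf_expansion_matrix",
    "pair_operators",
    "h_in_csf_basis",
    "ground_state",
    "l4_norm",
    "partial_spin_blocks",
    "exhaustive_scan",
    "symmetry_representatives",
    "ordering_symmetry_group",
    "ScanRecord",
    "scan_to_frame",
]

DENSE_EIG_CUTOFF = 2000
DEFAULT_SITE_CAP = 14


class SystemSizeError(ValueError):
    """Raised when a brute-force routine is asked for too large a system."""


def _det_basis(n: int, n_alpha: int) -> list[tuple[int, ...]]:
    """Spin strings (1 = alpha) with fixed alpha count, lexicographic."""
    basis = []
    for occ in itertools.combinations(range(n), n_alpha):
        s = [0] * n
        for k in occ:
            s[k] = 1
        basis.append(tuple(s))
    return basis


def _expand(csf_steps: str) -> dict[tuple[int, ...], float]:
    """Highest-M_S determinant expansion via sequential CG coupling."""
    n = len(csf_steps)
    two_j = [0]
    for c in csf_steps:
        two_j.append(two_j[-1] + (1 if c == "u" else -1))
    memo: dict[tuple[int, int], dict[tuple[int, ...], float]] = {}

    def state(k: int, two_m: int) -> dict[tuple[int, ...], float]:
        key = (k, two_m)
        if key in memo:
            return memo[key]
        if k == 0:
            memo[key] = {(): 1.0}
            return memo[key]
        res: dict[tuple[int, ...], float] = {}
        tjp, tj = two_j[k - 1], two_j[k]
        if abs(two_m) <= tj:
            if csf_steps[k - 1] == "u":
                ca = math.sqrt((tjp + two_m + 1) / (2 * (tjp + 1)))
                cb = math.sqrt((tjp - two_m + 1) / (2 * (tjp + 1)))
            else:
                ca = -math.sqrt((tjp - two_m + 1) / (2 * (tjp + 1)))
                cb = math.sqrt((tjp + two_m + 1) / (2 * (tjp + 1)))
            if ca and abs(two_m - 1) <= tjp:
                for s, c in state(k - 1, two_m - 1).items():
                    res[s + (1,)] = res.get(s + (1,), 0.0) + ca * c
            if cb and abs(two_m + 1) <= tjp:
                for s, c in state(k - 1, two_m + 1).items():
                    res[s + (0,)] = res.get(s + (0,), 0.0) + cb * c
        memo[key] = res
        return res

    return state(n, two_j[-1])


def csf_to_det(csf: CSF | str) -> dict[str, float]:
    """Determinant expansion of a CSF at ``M_S = S``.

    Returns a sparse map from spin strings (``a`` = alpha, ``b`` = beta)
    to coefficients; the vector has unit norm, distinct CSFs of one sector
    are orthogonal, and each vector is an S^2 eigenvector with eigenvalue
    S(S+1).  Closed-shell markers are not supported here: the oracle works
    on the open-shell skeleton.
    """
    steps = csf.steps if isinstance(csf, CSF) else csf
    cumulative_profile(steps)  # propagate invalid-CSF errors
    if set(steps) - set("ud"):
        raise ValueError("determinant oracle expects a pure u/d string")
    return {
        "".join("a" if x else "b" for x in s): c
        for s, c in _expand(steps).items()
        if abs(c) > 0.0
    }


@lru_cache(maxsize=32)
def _sector(n: int, two_s: int) -> tuple[tuple[str, ...], list[tuple[int, ...]], np.ndarray]:
    """CSF list, determinant basis and expansion matrix C (n_det x n_csf)."""
    csfs = tuple(c.steps for c in enumerate_vvs(n, two_s))
    n_alpha = (n + two_s) // 2
    basis = _det_basis(n, n_alpha)
    index = {s: r for r, s in enumerate(basis)}
    C = np.zeros((len(basis), len(csfs)))
    for col, steps in enumerate(csfs):
        for s, c in _expand(steps).items():
            C[index[s], col] = c
    return csfs, basis, C


def csf_expansion_matrix(n: int, two_s: int) -> tuple[list[CSF], np.ndarray]:
    """All sector CSFs and their expansion matrix over the M_S = S strings."""
    csfs, _, C = _sector(n, two_s)
    return [CSF(s) for s in csfs], C.copy()


def _sisj_det(basis: list[tuple[int, ...]], index: dict, i: int, j: int) -> sp.csr_matrix:
    """S_i.S_j in the fixed-M_S determinant basis (0-based i < j)."""
    dim = len(basis)
    rows, cols, vals = [], [], []
    for r, s in enumerate(basis):
        zi = 0.5 if s[i] else -0.5
        zj = 0.5 if s[j] else -0.5
        rows.append(r)
        cols.append(r)
        vals.append(zi * zj)
        if s[i] != s[j]:
            s2 = list(s)
            s2[i], s2[j] = s[j], s[i]
            rows.append(index[tuple(s2)])
            cols.append(r)
            vals.append(0.5)
    return sp.csr_matrix((vals, (rows, cols)), shape=(dim, dim))


@lru_cache(maxsize=16)
def pair_operators(n: int, two_s: int) -> tuple[tuple[str, ...], list[tuple[int, int]], np.ndarray]:
    """Projected pair operators ``O_ij = C^T (S_i.S_j) C`` in the CSF basis.

    Returns ``(csfs, pairs, O)`` with ``O`` of shape (n_pairs, D, D); any
    Hamiltonian or cumulative-partial-spin operator of the sector is a
    linear combination of these plus the identity.
    """
    csfs, basis, C = _sector(n, two_s)
    index = {s: r for r, s in enumerate(basis)}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    O = np.empty((len(pairs), C.shape[1], C.shape[1]))
    for p, (i, j) in enumerate(pairs):
        O[p] = C.T @ (_sisj_det(basis, index, i, j) @ C)
    return csfs, pairs, O


def h_in_csf_basis(cm: CouplingMatrix, two_s: int, site_cap: int = DEFAULT_SITE_CAP) -> np.ndarray:
    """Exact Hamiltonian ``sum (-2 g_ij) S_i.S_j`` over the sector CSFs.

    The matrix is symmetric; its diagonal coincides with the closed-form
    CSF energies of :func:`spinorder.hamiltonians.diagonal_element` and its
    spectrum is invariant under any site reordering of ``cm``.
    """
    n = cm.n_sites
    if n > site_cap:
        raise SystemSizeError(
            f"{n} sites exceeds the dense-work cap ({site_cap}); "
            "raise site_cap explicitly or use a sparse formulation"
        )
    _, pairs, O = pair_operators(n, two_s)
    coeff = np.array([-2.0 * cm.g[i, j] for i, j in pairs])
    return np.tensordot(coeff, O, axes=1)


def ground_state(h: np.ndarray) -> tuple[float, np.ndarray]:
    """Lowest eigenpair with a deterministic sign fix.

    Dense solver below ``DENSE_EIG_CUTOFF`` rows, Lanczos with a fixed
    all-ones start vector above.  The coefficient of largest magnitude is
    made positive (ties broken by lowest index); degenerate lowest pairs
    resolve to the solver's first root.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("expected a symmetric matrix")
    if h.shape[0] == 1:
        return float(h[0, 0]), np.ones(1)
    if h.shape[0] <= DENSE_EIG_CUTOFF:
        w, v = np.linalg.eigh(h)
        e, c = float(w[0]), v[:, 0]
    else:
        w, v = eigsh(sp.csr_matrix(h), k=1, which="SA", v0=np.ones(h.shape[0]))
        e, c = float(w[0]), v[:, 0]
    c = c / np.linalg.norm(c)
    if c[int(np.argmax(np.abs(c)))] < 0:
        c = -c
    return e, c


def l4_norm(coeffs: np.ndarray, root: bool = True) -> float:
    """Compactness ``(sum c^4)^(1/4)`` of a normalized coefficient vector.

    Equals 1 exactly when a single basis state carries all weight.  The
    alternative convention without the fourth root is exposed via
    ``root=False`` for sensitivity checks.
    """
    c = np.asarray(coeffs, dtype=float)
    if abs(np.sum(c * c) - 1.0) > 1e-8:
        raise ValueError("coefficient vector is not L2-normalized")
    q = float(np.sum(c**4))
    return q**0.25 if root else q


@dataclass
class PartialSpinReport:
    """Block structure of H with respect to one cumulative-spin cut."""

    cut: int
    frobenius_norm: float
    block_labels: tuple[int, ...]  # b_n value per CSF
    crossing_entries: int


def partial_spin_blocks(
    cm: CouplingMatrix,
    ordering: Sequence[int],
    cut: int,
    two_s: int,
    tol: float = 1e-10,
) -> PartialSpinReport:
    """Commutator of H with the squared cumulative partial spin over the
    first ``cut`` sites of the ordered system.

    A vanishing Frobenius norm is equivalent to H having no nonzero entry
    between CSFs of different cumulative spin ``b_cut`` -- the mechanism by
    which an ordering renders the Hamiltonian block-diagonal.
    """
    n = cm.n_sites
    if not (1 <= cut <= n):
        raise ValueError(f"cut must be in 1..{n}")
    cmp_ = apply_ordering(cm, ordering)
    csfs, pairs, O = pair_operators(n, two_s)
    h = h_in_csf_basis(cmp_, two_s)
    # (sum_{i<=cut} S_i)^2 = 0.75*cut*I + 2 * sum_{i<j<=cut} S_i.S_j
    q = 0.75 * cut * np.eye(h.shape[0])
    for p, (i, j) in enumerate(pairs):
        if j < cut:
            q += 2.0 * O[p]
    comm = h @ q - q @ h
    labels = tuple(cumulative_profile(s)[cut - 1] for s in csfs)
    lab = np.array(labels)
    crossing = int(np.sum((np.abs(h) > tol) & (lab[:, None] != lab[None, :])) // 2)
    return PartialSpinReport(cut, float(np.linalg.norm(comm)), labels, crossing)


@dataclass
class ScanRecord:
    """Per-ordering bundle produced by exhaustive scans."""

    ordering: tuple[int, ...]
    e_min: float
    e_max: float
    delta_e: float
    energy: float
    l4: float
    leading_csf: str
    leading_weight: float
    sms_score: float | None = None
    sms_valid: bool | None = None


def scan_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Flatten scan records to a DataFrame with a stable column schema."""
    return pd.DataFrame(
        {
            "ordering": [" ".join(map(str, r.ordering)) for r in records],
            "e_min": [r.e_min for r in records],
            "e_max": [r.e_max for r in records],
            "delta_e": [r.delta_e for r in records],
            "energy": [r.energy for r in records],
            "l4": [r.l4 for r in records],
            "leading_csf": [r.leading_csf for r in records],
            "leading_weight": [r.leading_weight for r in records],
            "sms_score": [r.sms_score for r in records],
            "sms_valid": [r.sms_valid for r in records],
        }
    )


def ordering_symmetry_group(cm: CouplingMatrix) -> list[tuple[tuple[int, ...], bool]]:
    """Transformations of an ordering that provably leave every scan
    quantity unchanged: relabelling the sites by an automorphism of the
    weighted coupling graph, and reversing the ordering sequence.

    Each element is ``(sigma, reversed)`` with ``sigma`` a 1-based site
    relabelling; the action is ``P -> sigma o P`` (optionally reading P
    backwards first).  Automorphisms are enumerated exactly, so keep this
    to desk-scale graphs.
    """
    import networkx as nx
    from networkx.algorithms import isomorphism as iso

    g = nx.Graph()
    g.add_nodes_from(range(cm.n_sites))
    ii, jj = np.nonzero(np.triu(cm.g, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(i, j, w=float(cm.g[i, j]))
    em = iso.numerical_edge_match("w", 0.0)
    gm = iso.GraphMatcher(g, g, edge_match=em)
    autos = []
    for mapping in gm.isomorphisms_iter():
        autos.append(tuple(mapping[k] + 1 for k in range(cm.n_sites)))
    return [(sig, rev) for sig in autos for rev in (False, True)]


def _canonical_ordering(
    p: tuple[int, ...], group: list[tuple[tuple[int, ...], bool]]
) -> tuple[tuple[int, ...], int]:
    """Lexicographic minimum over the orbit of ``p`` and the orbit size."""
    orbit = set()
    for sig, rev in group:
        q = p[::-1] if rev else p
        orbit.add(tuple(sig[s - 1] for s in q))
    return min(orbit), len(orbit)


def symmetry_representatives(cm: CouplingMatrix) -> tuple[list[tuple[int, ...]], list[int]]:
    """Orbit representatives of all orderings under the verified symmetry
    group, with their orbit sizes.

    Scan records are constant on each orbit, so a full-set statistic equals
    the representative statistic weighted by orbit size.  The action is not
    free in general (orderings mapped to themselves by a relabelling
    composed with reversal have smaller orbits), hence the multiplicities.
    """
    group = ordering_symmetry_group(cm)
    reps, mult = [], []
    for p in itertools.permutations(range(1, cm.n_sites + 1)):
        canon, size = _canonical_ordering(p, group)
        if canon == p:
            reps.append(p)
            mult.append(size)
    return reps, mult


def _scan_arrays(
    cm: CouplingMatrix,
    two_s: int,
    orderings: np.ndarray,
    l4_root: bool = True,
    chunk: int = 8192,
) -> dict[str, np.ndarray]:
    """Vectorized core of the exhaustive scan (orderings as (M, n) array)."""
    n = cm.n_sites
    csfs, pairs, O = pair_operators(n, two_s)
    T, _ = t_matrix([CSF(s) for s in csfs], n)
    ia = np.array([i for i, _ in pairs])
    ja = np.array([j for _, j in pairs])
    M = orderings.shape[0]
    out = {
        "e_min": np.empty(M),
        "e_max": np.empty(M),
        "energy": np.empty(M),
        "l4": np.empty(M),
        "leading": np.empty(M, dtype=int),
        "leading_weight": np.empty(M),
    }
    for lo in range(0, M, chunk):
        sl = slice(lo, min(lo + chunk, M))
        P = orderings[sl] - 1
        G = cm.g[P[:, ia], P[:, ja]]  # (m, n_pairs)
        E = G @ T.T  # collinear CSF diagonal energies per ordering
        out["e_min"][sl] = E.min(axis=1)
        out["e_max"][sl] = E.max(axis=1)
        H = np.einsum("mp,pij->mij", -2.0 * G, O)
        w, v = np.linalg.eigh(H)
        c = v[:, :, 0]
        out["energy"][sl] = w[:, 0]
        c2 = c * c
        out["l4"][sl] = np.sum(c2 * c2, axis=1) ** (0.25 if l4_root else 1.0)
        lead = np.argmax(c2, axis=1)
        out["leading"][sl] = lead
        out["leading_weight"][sl] = c2[np.arange(c2.shape[0]), lead]
    out["delta_e"] = out["e_max"] - out["e_min"]
    out["csfs"] = np.array(csfs)
    return out


def exhaustive_scan(
    cm: CouplingMatrix,
    two_s: int,
    orderings: Sequence[Sequence[int]] | None = None,
    symmetry_reduce: bool = False,
    l4_root: bool = True,
    sms_colors: np.ndarray | None = None,
    max_sites: int = 10,
) -> list[ScanRecord]:
    """One :class:`ScanRecord` per ordering (all ``n!`` by default).

    ``symmetry_reduce=True`` scans one representative per symmetry orbit
    (relabelling by coupling-graph automorphisms and sequence reversal).
    When ``sms_colors`` (a two-coloring of the coupling graph) is given,
    the Neel-consistent single-CSF fitness is attached to each record.
    """
    n = cm.n_sites
    if n > max_sites:
        raise SystemSizeError(f"{n} sites exceeds the factorial scan guard ({max_sites})")
    if orderings is None:
        if symmetry_reduce:
            orderings, _ = symmetry_representatives(cm)
        else:
            orderings = list(itertools.permutations(range(1, n + 1)))
    P = np.asarray(orderings, dtype=int)
    arr = _scan_arrays(cm, two_s, P, l4_root=l4_root)
    sms_scores: list[float | None] = [None] * P.shape[0]
    sms_valids: list[bool | None] = [None] * P.shape[0]
    if sms_colors is not None:
        from .fitness import sms_population_scores

        sc, va = sms_population_scores(P, cm, sms_colors)
        sms_scores = [float(s) if v else None for s, v in zip(sc, va)]
        sms_valids = [bool(v) for v in va]
    return [
        ScanRecord(
            ordering=tuple(int(x) for x in P[r]),
            e_min=float(arr["e_min"][r]),
            e_max=float(arr["e_max"][r]),
            delta_e=float(arr["delta_e"][r]),
            energy=float(arr["energy"][r]),
            l4=float(arr["l4"][r]),
            leading_csf=str(arr["csfs"][arr["leading"][r]]),
            leading_weight=float(arr["leading_weight"][r]),
            sms_score=sms_scores[r],
            sms_valid=sms_valids[r],
        )
        for r in range(P.shape[0])
    ]
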