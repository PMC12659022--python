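"""Cheap compactness proxies used as GA fitness functions.

Two variants are provided:

* ``delta_e_diag`` -- the spread (max - min) of the closed-form diagonal
  energies over the collinear CSF set of the reordered system.  Applicable
  to any Hamiltonian, frustrated or ab initio included; maximized.
* ``sms_fitness`` -- for unfrustrated bipartite NN antiferromagnets only:
  the Neel-consistent ("S-MS") CSF bound to an ordering by assigning ``u``
  to one sublattice and ``d`` to the other.  The fitness is minus its
  diagonal energy (so the GA still maximizes); orderings whose induced CSF
  violates the non-negative cumulative-spin rule are invalid and excluded
  from selection rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .csf import CSF, collinear_skeleton
from .hamiltonians import CouplingMatrix, apply_ordering, diagonal_element, t_matrix

__all__ = [
    "FitnessResult",
    "NonBipartiteError",
    "bipartition_colors",
    "delta_e_diag",
    "sms_csf",
    "sms_fitness",
    "sms_population_scores",
    "delta_population_scores",
    "selection_weights",
]


class NonBipartiteError(ValueError):
    """The coupling graph admits no two-coloring: S-MS mapping inapplicable."""


@dataclass
class FitnessResult:
    score: float
    valid: bool = True
    details: dict = field(default_factory=dict)


def bipartition_colors(cm: CouplingMatrix) -> np.ndarray:
    """Two-coloring of the coupling graph, 0/1 per site label.

    The class containing site 1 is colour 0 and is assigned ``u``.  Raises
    :class:`NonBipartiteError` when couplings frustrate the colouring
    (e.g. a J1-J2 chain).
    """
    g = nx.Graph()
    g.add_nodes_from(range(cm.n_sites))
    ii, jj = np.nonzero(np.triu(cm.g, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    if not nx.is_bipartite(g):
        raise NonBipartiteError(
            "coupling graph is not two-colorable; the S-MS mapping is inapplicable"
        )
    colors = np.zeros(cm.n_sites, dtype=int)
    for comp in nx.connected_components(g):
        side = nx.bipartite.sets(g.subgraph(comp).copy())[0]
        anchor = min(comp)
        flip = anchor not in side
        for node in comp:
            colors[node] = (node in side) == flip
    # make site 1's class colour 0 regardless of component iteration order
    if colors[0] == 1:
        colors = 1 - colors
    return colors


def sms_csf(ordering: Sequence[int], colors: np.ndarray) -> CSF | None:
    """The S-MS-consistent CSF of an ordering, or None when invalid.

    Site visited at position k contributes ``u`` if it belongs to the
    sublattice of site 1, else ``d``; the string must keep all cumulative
    spins non-negative to name a CSF.
    """
    steps = "".join("u" if colors[s - 1] == 0 else "d" for s in ordering)
    csf = CSF(steps)
    return csf if csf.is_valid else None


def sms_fitness(
    ordering: Sequence[int],
    cm: CouplingMatrix,
    colors: np.ndarray | None = None,
) -> FitnessResult:
    """Single-CSF fitness: minus the S-MS CSF diagonal energy (maximize).

    Invalid orderings return ``valid=False`` with score ``-inf`` and are
    given zero selection weight by the GA.
    """
    if colors is None:
        colors = bipartition_colors(cm)
    csf = sms_csf(ordering, colors)
    if csf is None:
        return FitnessResult(score=-np.inf, valid=False, details={"csf": None})
    energy = diagonal_element(csf, apply_ordering(cm, ordering))
    return FitnessResult(score=-energy, valid=True, details={"csf": str(csf), "energy": energy})


def delta_e_diag(
    ordering: Sequence[int],
    cm: CouplingMatrix,
    two_s_total: int = 0,
    two_s_loc: int = 1,
) -> FitnessResult:
    """Spread of the collinear CSF diagonal energies of the reordered system.

    For local spin 1/2 the collinear set is the full van Vleck--Sherman
    sector.  For larger local spins ``cm`` must be blocked site-wise (the
    energies are evaluated on the open-shell skeleton; closed-shell
    orbitals shift all diagonals equally and are ignored).  The score is
    invariant under adding a constant to every diagonal and scales linearly
    under uniform scaling of the couplings.
    """
    cmp_ = apply_ordering(cm, ordering)
    site_csfs, _ = collinear_skeleton(cm.n_sites, two_s_loc, two_s_total)
    if two_s_loc == 1:
        energies = [diagonal_element(c, cmp_) for c in site_csfs]
    else:
        energies = [_site_block_energy(c, cmp_, two_s_loc) for c in site_csfs]
    e_min, e_max = min(energies), max(energies)
    k_min, k_max = int(np.argmin(energies)), int(np.argmax(energies))
    return FitnessResult(
        score=e_max - e_min,
        valid=True,
        details={
            "e_min": e_min,
            "e_max": e_max,
            "csf_min": str(site_csfs[k_min]),
            "csf_max": str(site_csfs[k_max]),
        },
    )


def _site_block_energy(site_csf: CSF, cm_sites: CouplingMatrix, two_s_loc: int) -> float:
    """Diagonal energy of a collinear site-block CSF.

    Each magnetic site carries ``two_s_loc`` aligned unpaired spins; the
    inter-site exchange couples every orbital pair across two sites with
    the site-level ``g``.  Expanding the site string to the orbital level
    and summing T over cross-site orbital pairs gives the energy up to the
    (ordering-independent) intra-site constant, which is dropped.
    """
    from .csf import SiteBlockPattern

    pattern = SiteBlockPattern(two_s_loc)
    orb = pattern.expand(site_csf)
    n_sites = len(site_csf)
    w = two_s_loc
    from .hamiltonians import t_factor

    total = 0.0
    for a in range(n_sites):
        for b in range(a + 1, n_sites):
            g = cm_sites.g[a, b]
            if g == 0.0:
                continue
            for p in range(a * w, (a + 1) * w):
                for q in range(b * w, (b + 1) * w):
                    total += g * t_factor(orb, p + 1, q + 1)
    return total


def selection_weights(scores: np.ndarray, valid: np.ndarray, eps_frac: float = 1e-8) -> np.ndarray:
    """Roulette weights from raw scores (which may be negative).

    Scores are shifted so the worst valid chromosome gets a small positive
    weight ``eps = eps_frac * range`` (or 1 when all valid scores tie);
    invalid chromosomes get weight zero.  Raises when nothing is valid.
    """
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid chromosome in the population")
    s = np.asarray(scores, dtype=float)
    vs = s[valid]
    lo, hi = float(vs.min()), float(vs.max())
    eps = eps_frac * (hi - lo) if hi > lo else 1.0
    w = np.where(valid, s - lo + eps, 0.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# vectorized population evaluators (GA hot path)
# ---------------------------------------------------------------------------

def _t_pair_terms(b: np.ndarray, step_u: np.ndarray):
    """Prefix arrays for evaluating T_ij on many chromosomes at once.

    ``b``: (M, N) cumulative profiles; ``step_u``: (M, N) booleans.
    Returns (start, end, logprodable, zerocount) arrays such that for
    0-based positions i < j:

        T_ij = -2 * start[:, i] * (P[:, j-1]/P[:, i]) * end[:, j]

    with the product forced to zero when b vanishes anywhere in [i, j).
    """
    h = np.where(step_u, (b + 2) / (b + 1), b / np.maximum(b + 1, 1))
    zero = b == 0
    h_safe = np.where(zero, 1.0, h)
    P = np.cumprod(h_safe, axis=1)
    Z = np.cumsum(zero, axis=1)
    start = np.where(step_u, (b + 2) / 4.0, -b / 4.0)
    end = np.where(step_u, 1.0, -1.0) / (b + 1)
    return start, end, P, Z


def _t_values(start, end, P, Z, i, j):
    """T for per-row position pairs ``i < j`` (arrays of shape (M,))."""
    rows = np.arange(i.shape[0])
    inner = P[rows, j - 1] / P[rows, i]
    t = -2.0 * start[rows, i] * inner * end[rows, j]
    zeros_inside = Z[rows, j - 1] - np.where(i > 0, Z[rows, i - 1], 0)
    return np.where(zeros_inside > 0, 0.0, t)


def sms_population_scores(
    pop: np.ndarray, cm: CouplingMatrix, colors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """S-MS fitness scores for a whole population matrix (M, N) of 1-based
    orderings.  Returns ``(scores, valid)``; invalid rows carry ``-inf``.

    Agrees element-wise with :func:`sms_fitness`; the loop-free evaluation
    keeps desk-scale GA runs (hundreds of chromosomes, thousands of
    generations) in the seconds range.
    """
    pop = np.asarray(pop, dtype=int)
    M, N = pop.shape
    step_u = colors[pop - 1] == 0
    incr = np.where(step_u, 1, -1)
    b = np.cumsum(incr, axis=1)
    valid = (b >= 0).all(axis=1)
    bc = np.maximum(b, 0)  # clamp so prefix arrays stay finite on invalid rows
    start, end, P, Z = _t_pair_terms(bc, step_u)
    pos = np.argsort(pop, axis=1)  # pos[m, s-1] = 0-based position of site s
    energy = np.zeros(M)
    for s, t, g in cm.edges():
        pi, pj = pos[:, s - 1], pos[:, t - 1]
        i = np.minimum(pi, pj)
        j = np.maximum(pi, pj)
        energy += g * _t_values(start, end, P, Z, i, j)
    scores = np.where(valid, -energy, -np.inf)
    return scores, valid


def delta_population_scores(
    pop: np.ndarray, cm: CouplingMatrix, two_s: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-E-diag scores for a population matrix (local spin 1/2)."""
    pop = np.asarray(pop, dtype=int)
    n = cm.n_sites
    site_csfs, _ = collinear_skeleton(n, 1, two_s)
    T, pairs = t_matrix(site_csfs, n)
    ia = np.array([i for i, _ in pairs])
    ja = np.array([j for _, j in pairs])
    G = cm.g[pop[:, ia] - 1, pop[:, ja] - 1]
    E = G @ T.T
    scores = E.max(axis=1) - E.min(axis=1)
    return scores, np.ones(pop.shape[0], dtype=bool)
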