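"""Exchange-coupling matrices and closed-form CSF diagonal energies.

The exchange part of the Hamiltonian is realized as

    H_ex = sum_{i<j} (-2 g_ij) S_i . S_j

with ``g_ij`` the exchange parameter between sites/orbitals ``i`` and ``j``
(in Hartree).  Antiferromagnetic model systems carry ``g < 0``, so that
``-2g = 2|J|`` reproduces the standard ``J S_i.S_j`` Heisenberg form with
``J > 0``.  Ab initio exchange integrals ``g_ij,ji = (ij|ji)`` read from
FCIDUMP files are positive, which inverts the energetic ordering of the
CSFs relative to the model Hamiltonians.

Under this convention the diagonal element of a van Vleck--Sherman CSF is

    <m|H_ex|m> = sum_{i<j} g_ij T_ij(m)

exactly (no CSF-independent constant remains), where ``T_ij = -2 <m|S_i.S_j|m>``
has the closed product form implemented in :func:`t_factor`:

    T_ij = -2 s_i * prod_{i<k<j} h_k * s_j
    s_i  = (b_i + 2)/4  (u)   or  -b_i/4        (d)
    h_k  = (b_k + 2)/(b_k + 1)  (u)   or  b_k/(b_k + 1)   (d)
    s_j  = +1/(b_j + 1)  (u)   or  -1/(b_j + 1)  (d)

and ``T_ij = 0`` whenever the cumulative spin ``b_k`` vanishes anywhere in
``i <= k < j`` (the two orbitals then sit in decoupled singlet segments).
The sign is ``(-1)^(d_i + d_j + 1)``: positive exactly when the two step
values differ.  The product form follows from the Lande projection theorem
applied level by level to the genealogical coupling chain and is certified
against a determinant-expansion oracle in the test suite.  Closed-shell
orbitals interleaved between the open-shell ones leave ``b`` unchanged and
contribute a unit factor, so they only shift the CSF-independent constant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .csf import CSF, OPEN_STEPS, cumulative_profile

__all__ = [
    "CouplingMatrix",
    "chain",
    "ladder",
    "square",
    "j1j2_chain",
    "from_edges",
    "build_lattice",
    "apply_ordering",
    "read_fcidump",
    "t_factor",
    "diagonal_element",
    "t_matrix",
]


@dataclass
class CouplingMatrix:
    """Symmetric matrix of exchange parameters ``g_ij`` (Ha), zero diagonal."""

    g: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2 or self.g.shape[0] != self.g.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("coupling matrix entries must be finite")
        if not np.allclose(self.g, self.g.T):
            raise ValueError("coupling matrix must be symmetric")
        np.fill_diagonal(self.g, 0.0)

    @property
    def n_sites(self) -> int:
        return self.g.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        """Nonzero couplings as (i, j, g) with 1-based labels, i < j."""
        ii, jj = np.nonzero(np.triu(self.g, k=1))
        return [(int(i) + 1, int(j) + 1, float(self.g[i, j])) for i, j in zip(ii, jj)]

    def to_text(self) -> str:
        """Whitespace-delimited edge-list export."""
        lines = [f"# n_sites {self.n_sites}"]
        lines += [f"{i} {j} {g:.12g}" for i, j, g in self.edges()]
        return "\n".join(lines) + "\n"


def _edges_to_matrix(n: int, edges: Iterable[tuple[int, int, float]], meta: dict) -> CouplingMatrix:
    g = np.zeros((n, n))
    for i, j, v in edges:
        if not (1 <= i <= n and 1 <= j <= n) or i == j:
            raise ValueError(f"bad edge ({i}, {j}) for {n} sites")
        g[i - 1, j - 1] = v
        g[j - 1, i - 1] = v
    return CouplingMatrix(g, meta)


def chain(n: int, j: float = 0.5, periodic: bool = False) -> CouplingMatrix:
    """Open (default) or periodic NN chain; antiferromagnetic ``g = -j``."""
    if n < 2:
        raise ValueError("chain needs at least 2 sites")
    edges = [(i, i + 1, -j) for i in range(1, n)]
    if periodic:
        edges.append((1, n, -j))
    return _edges_to_matrix(n, edges, {"lattice": "chain", "n": n, "j": j, "periodic": periodic})


def ladder(n_legs: int, length: int, j: float = 0.5) -> CouplingMatrix:
    """N-leg ladder; site ``(leg, rung)`` is labelled ``(leg-1)*length + rung``.

    Leg bonds join consecutive rungs within a leg, rung bonds join adjacent
    legs at the same rung (the 2 x 11 ladder therefore has 2*10 + 11 = 31
    bonds).
    """
    if n_legs < 1 or length < 1:
        raise ValueError("ladder dimensions must be positive")
    lab = lambda leg, r: (leg - 1) * length + r
    edges = []
    for leg in range(1, n_legs + 1):
        for r in range(1, length):
            edges.append((lab(leg, r), lab(leg, r + 1), -j))
    for leg in range(1, n_legs):
        for r in range(1, length + 1):
            edges.append((lab(leg, r), lab(leg + 1, r), -j))
    return _edges_to_matrix(
        n_legs * length, edges, {"lattice": "ladder", "n_legs": n_legs, "length": length, "j": j}
    )


def square(l: int, j: float = 0.5) -> CouplingMatrix:
    """l x l square lattice with open boundaries, row-major labelling
    (an l x l square is an l-leg ladder of length l)."""
    if l < 1:
        raise ValueError("square lattice side must be positive")
    cm = ladder(l, l, j=j)
    cm.meta.update({"lattice": "square", "l": l})
    return cm


def j1j2_chain(n: int, j1: float = 0.5, j2: float = 0.25) -> CouplingMatrix:
    """Frustrated chain with NN coupling ``j1`` and next-NN coupling ``j2``."""
    if n < 3:
        raise ValueError("J1-J2 chain needs at least 3 sites")
    edges = [(i, i + 1, -j1) for i in range(1, n)]
    edges += [(i, i + 2, -j2) for i in range(1, n - 1)]
    return _edges_to_matrix(n, edges, {"lattice": "j1j2-chain", "n": n, "j1": j1, "j2": j2})


def from_edges(n: int, edges: Sequence[tuple[int, int, float]]) -> CouplingMatrix:
    """Arbitrary weighted edge list, 1-based labels, ``g`` given explicitly."""
    return _edges_to_matrix(n, edges, {"lattice": "edge-list", "n": n})


def build_lattice(spec: dict) -> CouplingMatrix:
    """Build a coupling matrix from a structured description (CLI/config).

    ``spec['type']`` selects among ``chain``, ``ladder``, ``square``,
    ``j1j2-chain`` and ``edge-list``; remaining keys are the builder
    arguments.
    """
    spec = dict(spec)
    kind = spec.pop("type", None)
    builders = {
        "chain": lambda: chain(int(spec["n"]), float(spec.get("j", 0.5)), bool(spec.get("periodic", False))),
        "ladder": lambda: ladder(int(spec["n_legs"]), int(spec["length"]), float(spec.get("j", 0.5))),
        "square": lambda: ladder(int(spec["l"]), int(spec["l"]), float(spec.get("j", 0.5))),
        "j1j2-chain": lambda: j1j2_chain(int(spec["n"]), float(spec.get("j1", 0.5)), float(spec.get("j2", 0.25))),
        "edge-list": lambda: from_edges(int(spec["n"]), [tuple(e[:2]) + (float(e[2]),) for e in spec["edges"]]),
    }
    if kind not in builders:
        raise ValueError(f"unknown lattice type {kind!r}; choose from {sorted(builders)}")
    return builders[kind]()


def _check_perm(p: Sequence[int], n: int) -> np.ndarray:
    p = np.asarray(p, dtype=int)
    if p.shape != (n,) or sorted(p.tolist()) != list(range(1, n + 1)):
        raise ValueError(f"ordering must be a permutation of 1..{n}, got {p.tolist()}")
    return p


def apply_ordering(cm: CouplingMatrix, ordering: Sequence[int]) -> CouplingMatrix:
    """Coupling matrix of the reordered system: ``J(P)_ab = g_{P(a),P(b)}``.

    A pure relabelling -- any Hamiltonian built from the result is a
    similarity transform of the original and has the identical spectrum.
    """
    p = _check_perm(ordering, cm.n_sites) - 1
    meta = dict(cm.meta)
    meta["ordering"] = tuple(int(x) + 1 for x in p)
    return CouplingMatrix(cm.g[np.ix_(p, p)], meta)


_NAMELIST_INT = re.compile(r"([A-Z0-9]+)\s*=\s*(-?\d+)")


def read_fcidump(path) -> CouplingMatrix:
    """Extract the exchange integrals ``g_ij,ji = (ij|ji)`` from an FCIDUMP.

    Real-valued chemist-notation integrals with 8-fold permutational
    symmetry are assumed; orbital indices are 1-based.  All non-exchange
    records (Coulomb, one-body, core energy) only enter the CSF-independent
    constant of the diagonal energies and are retained opaquely in
    ``meta['other_integrals']`` / ``meta['core_energy']``.
    """
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"&FCI(.*?)(?:/|&END)", text, flags=re.S | re.I)
    if m is None:
        raise ValueError(f"{path}: missing &FCI namelist header")
    header = m.group(1).upper()
    fields = dict(_NAMELIST_INT.findall(header))
    if "NORB" not in fields:
        raise ValueError(f"{path}: header does not declare NORB")
    norb = int(fields["NORB"])
    meta = {
        "source": str(path),
        "norb": norb,
        "nelec": int(fields.get("NELEC", 0)),
        "ms2": int(fields.get("MS2", 0)),
        "other_integrals": {},
        "core_energy": 0.0,
    }
    g = np.zeros((norb, norb))
    body = text[m.end():]
    for line in body.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed record {line!r}")
        v = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise ValueError(f"{path}: orbital index {idx} out of range 1..{norb}")
        if i == j == k == l == 0:
            meta["core_energy"] = v
        elif i != j and i and j and {k, l} == {i, j}:
            g[i - 1, j - 1] = v  # exchange-type (ij|ji) (= (ij|ij) by symmetry)
            g[j - 1, i - 1] = v
        else:
            meta["other_integrals"][(i, j, k, l)] = v  # Coulomb/one-body/rest
    return CouplingMatrix(g, meta)


def _t_prepare(csf: CSF | str, i: int, j: int) -> tuple[str, tuple[int, ...], int, int]:
    if isinstance(csf, str):
        csf = CSF(csf)
    n = len(csf)
    if not (1 <= i < j <= n):
        raise ValueError(f"need 1 <= i < j <= {n}, got ({i}, {j})")
    b = cumulative_profile(csf)
    if csf.steps[i - 1] not in OPEN_STEPS or csf.steps[j - 1] not in OPEN_STEPS:
        raise ValueError(
            f"positions ({i}, {j}) of {csf.steps!r} are not both open-shell"
        )
    return csf.steps, b, i - 1, j - 1


def t_factor(csf: CSF | str, i: int, j: int) -> float:
    """Exchange weight ``T_ij(m) = -2 <m|S_i.S_j|m>`` (1-based ``i < j``).

    Closed-shell markers strictly between ``i`` and ``j`` are transparent;
    the endpoints themselves must be open-shell.
    """
    steps, b, i0, j0 = _t_prepare(csf, i, j)
    if any(b[k] == 0 for k in range(i0, j0) if steps[k] in OPEN_STEPS) or (
        b[i0] == 0 and steps[i0] == "d"
    ):
        # b hits zero inside [i, j): the two spins sit in decoupled singlet
        # segments and their correlation vanishes.
        return 0.0
    s_i = (b[i0] + 2) / 4.0 if steps[i0] == "u" else -b[i0] / 4.0
    s_j = (1.0 if steps[j0] == "u" else -1.0) / (b[j0] + 1)
    prod = 1.0
    for k in range(i0 + 1, j0):
        c = steps[k]
        if c == "u":
            prod *= (b[k] + 2) / (b[k] + 1)
        elif c == "d":
            prod *= b[k] / (b[k] + 1)
        # markers: b unchanged, unit factor
    return -2.0 * s_i * prod * s_j


def diagonal_element(csf: CSF | str, cm: CouplingMatrix) -> float:
    """``<m|H_ex|m> = sum_{i<j} g_ij T_ij`` over the open-shell positions.

    ``cm`` is indexed at the orbital level and must match ``len(csf)``;
    pairs involving closed-shell markers are skipped (they contribute only
    to the CSF-independent constant).
    """
    if isinstance(csf, str):
        csf = CSF(csf)
    if len(csf) != cm.n_sites:
        raise ValueError(
            f"CSF length {len(csf)} does not match coupling dimension {cm.n_sites}"
        )
    total = 0.0
    pos = csf.open_positions
    for a in range(len(pos)):
        for bidx in range(a + 1, len(pos)):
            i, j = pos[a], pos[bidx]
            gij = cm.g[i, j]
            if gij != 0.0:
                total += gij * t_factor(csf, i + 1, j + 1)
    return total


def t_matrix(csfs: Sequence[CSF | str], n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack ``T_ij`` for many CSFs: returns ``(T, pairs)`` with ``T`` of
    shape ``(n_csf, n_pairs)`` over all 0-based orbital pairs ``i < j``.

    Used by the exhaustive scans and the Delta-E fitness, where the diagonal
    energies of a reordered system are ``T @ g_vec(P)``.
    """
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    T = np.empty((len(csfs), len(pairs)))
    for r, csf in enumerate(csfs):
        for c, (i, j) in enumerate(pairs):
            T[r, c] = t_factor(csf, i + 1, j + 1)
    return T, pairs
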