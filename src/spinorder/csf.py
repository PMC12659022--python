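"""Configuration state functions restricted to the van Vleck--Sherman subspace.

A CSF is written as a string of genealogical coupling steps, one per
orbital: ``u`` couples the next unpaired electron spin-up, ``d`` couples it
spin-down.  The cumulative profile ``b_k`` (twice the intermediate total
spin after coupling the first ``k`` orbitals) must remain non-negative at
every prefix; its final value equals ``2S``.  Closed-shell orbitals may be
interleaved using the marker ``2`` (doubly occupied) or ``0`` (empty); they
are transparent to the spin-coupling arithmetic.

Half-integer spins are represented as the integer ``2S`` throughout the
package so that spin sectors can be compared exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import Iterator, NamedTuple

OPEN_STEPS = frozenset("ud")
MARKER_STEPS = frozenset("02")
_ALLOWED = OPEN_STEPS | MARKER_STEPS


class InvalidCSFError(ValueError):
    """Raised when a coupling string drops below zero cumulative spin.

    ``position`` is the 1-based index of the first offending step.
    """

    def __init__(self, steps: str, position: int):
        self.steps = steps
        self.position = position
        super().__init__(
            f"invalid CSF {steps!r}: cumulative spin becomes negative at "
            f"position {position}"
        )


@dataclass(frozen=True)
class CSF:
    """A spin-coupling step string, not necessarily prefix-valid.

    Use :func:`cumulative_profile` (or :attr:`is_valid`) to check validity;
    enumeration routines only ever produce valid CSFs.
    """

    steps: str

    def __post_init__(self) -> None:
        bad = set(self.steps) - _ALLOWED
        if bad:
            raise ValueError(f"unknown step symbols {sorted(bad)!r} in {self.steps!r}")

    def __str__(self) -> str:
        return self.steps

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    @property
    def n_open(self) -> int:
        """Number of singly occupied (u/d) orbitals."""
        return sum(1 for c in self.steps if c in OPEN_STEPS)

    @property
    def open_positions(self) -> tuple[int, ...]:
        """0-based positions of the open-shell steps."""
        return tuple(k for k, c in enumerate(self.steps) if c in OPEN_STEPS)

    @property
    def open_string(self) -> str:
        """The u/d string with all closed-shell markers removed."""
        return "".join(c for c in self.steps if c in OPEN_STEPS)

    @property
    def two_s(self) -> int:
        """Twice the total spin, i.e. the final cumulative value."""
        return sum(+1 if c == "u" else -1 for c in self.steps if c in OPEN_STEPS)

    @property
    def is_valid(self) -> bool:
        try:
            cumulative_profile(self)
        except InvalidCSFError:
            return False
        return True


def _as_csf(csf: CSF | str) -> CSF:
    return csf if isinstance(csf, CSF) else CSF(csf)


def cumulative_profile(csf: CSF | str) -> tuple[int, ...]:
    """Return ``b_k`` for every position ``k`` (markers leave ``b`` unchanged).

    Raises :class:`InvalidCSFError` on the first negative prefix, which makes
    this function the canonical validity check.
    """
    csf = _as_csf(csf)
    profile = []
    b = 0
    for k, c in enumerate(csf.steps):
        if c == "u":
            b += 1
        elif c == "d":
            b -= 1
        if b < 0:
            raise InvalidCSFError(csf.steps, k + 1)
        profile.append(b)
    return tuple(profile)


def _check_sector(n_open: int, two_s: int) -> None:
    if n_open < 1:
        raise ValueError(f"need at least one open-shell orbital, got {n_open}")
    if two_s < 0 or two_s > n_open:
        raise ValueError(f"2S={two_s} outside [0, {n_open}]")
    if (n_open - two_s) % 2:
        raise ValueError(f"parity violation: N_o={n_open}, 2S={two_s}")


def count_vvs(n_open: int, two_s: int) -> int:
    """Number of van Vleck--Sherman CSFs with ``n_open`` unpaired electrons
    coupled to total spin ``S = two_s/2`` (a ballot-count difference of two
    binomials)."""
    _check_sector(n_open, two_s)
    n_d = (n_open - two_s) // 2
    return comb(n_open, n_d) - (comb(n_open, n_d - 1) if n_d >= 1 else 0)


def enumerate_vvs(n_open: int, two_s: int) -> list[CSF]:
    """All valid u/d strings of the sector in lexicographic order (u < d)."""
    _check_sector(n_open, two_s)
    return [CSF("".join(s)) for s in _iter_strings(n_open, two_s)]


def _iter_strings(n_open: int, two_s: int) -> Iterator[list[str]]:
    steps: list[str] = []

    def rec(b: int) -> Iterator[list[str]]:
        if len(steps) == n_open:
            if b == two_s:
                yield steps.copy()
            return
        rem = n_open - len(steps)
        # feasibility pruning: the remaining steps must bridge b -> two_s
        if abs(b - two_s) > rem:
            return
        steps.append("u")
        yield from rec(b + 1)
        steps.pop()
        if b >= 1:
            steps.append("d")
            yield from rec(b - 1)
            steps.pop()

    yield from rec(0)


@dataclass(frozen=True)
class SiteBlockPattern:
    """Collinear occupation template for magnetic sites with local spin > 1/2.

    A spin-up site (``U``) contributes ``n_paired`` doubly occupied orbitals
    followed by ``two_s_loc`` consecutive ``u`` couplings; a spin-down site
    (``D``) likewise with ``d``.  For the high-spin d6 site of an Fe(II)
    centre this is the ``2uuuu``/``2dddd`` template
    (``two_s_loc=4, n_paired=1``).
    """

    two_s_loc: int
    n_paired: int = 0

    def __post_init__(self) -> None:
        if self.two_s_loc < 1:
            raise ValueError("local spin must be at least 1/2")
        if self.n_paired < 0:
            raise ValueError("n_paired must be non-negative")

    @property
    def orbitals_per_site(self) -> int:
        return self.n_paired + self.two_s_loc

    def expand(self, site_csf: CSF | str) -> CSF:
        """Expand a site-level u/d string to the orbital-level CSF."""
        site_csf = _as_csf(site_csf)
        out = []
        for c in site_csf.steps:
            if c not in OPEN_STEPS:
                raise ValueError("site-level CSFs contain only u/d")
            out.append("2" * self.n_paired + c * self.two_s_loc)
        return CSF("".join(out))


class SkeletonResult(NamedTuple):
    site_csfs: list[CSF]
    orbital_csfs: list[CSF] | None


def collinear_skeleton(
    n_sites: int,
    two_s_loc: int,
    two_s_total: int,
    pattern: SiteBlockPattern | None = None,
) -> SkeletonResult:
    """Collinear CSF skeleton: one u/d symbol per magnetic site.

    Each site carries its full local moment up or down; the site-level
    string obeys the same prefix rule as an ordinary CSF (site-level
    validity is equivalent to orbital-level validity of the block
    expansion).  When ``pattern`` is given, the orbital-level expansions
    are returned as well.
    """
    if two_s_loc < 1:
        raise ValueError("local spin must be at least 1/2")
    if two_s_total % two_s_loc:
        raise ValueError(
            f"total 2S={two_s_total} not reachable with collinear sites of "
            f"local 2S={two_s_loc}"
        )
    two_s_site = two_s_total // two_s_loc
    site_csfs = enumerate_vvs(n_sites, two_s_site)
    orbital = None
    if pattern is not None:
        if pattern.two_s_loc != two_s_loc:
            raise ValueError("pattern local spin disagrees with two_s_loc")
        orbital = [pattern.expand(c) for c in site_csfs]
    return SkeletonResult(site_csfs, orbital)


class SearchSpaceReduction(NamedTuple):
    full: int
    restricted: int
    factor: int


def search_space_reduction(n_open: int, two_s: int) -> SearchSpaceReduction:
    """Size of the joint (ordering x CSF) search space before and after
    binding each ordering to its Neel-consistent CSF.

    ``full = N_VVS * N_o!`` orderings-times-CSFs, ``restricted =
    N_VVS * N_u! * N_d!`` and the reduction factor is the binomial
    ``C(N_o, N_d)``.
    """
    _check_sector(n_open, two_s)
    n_vvs = count_vvs(n_open, two_s)
    n_u = (n_open + two_s) // 2
    n_d = (n_open - two_s) // 2
    full = n_vvs * factorial(n_open)
    restricted = n_vvs * factorial(n_u) * factorial(n_d)
    return SearchSpaceReduction(full, restricted, comb(n_open, n_d))
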