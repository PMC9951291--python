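"""Linear coarse-graining maps and enumeration of candidate mapping spaces.

A linear CG mapping is an N x n row-stochastic matrix M with pairwise
disjoint row supports: ``X = M x`` reduces n fine-grained coordinates to
N CG bead coordinates.  Two styles are used throughout:

* slicing  -- each bead is a single selected atom (indicator rows);
* averaging -- each bead is the uniform average of a group of atoms.

Atom indices are 0-based.  Mappings are canonicalized so beads are ordered
by their smallest member atom, which makes enumeration deterministic and
argmax/argmin tie-breaking reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError

__all__ = [
    "LinearMapping",
    "slicing_map",
    "averaging_map",
    "identity_map",
    "block_map",
    "enumerate_two_bead_candidates",
    "enumerate_disjoint_pair_maps",
    "enumerate_contiguous_partitions",
    "contiguous_averaging_maps",
    "enumerate_slicings",
    "count_contiguous_partitions",
]


def _canonical_groups(groups):
    out = []
    for g in groups:
        g = tuple(sorted(int(a) for a in g))
        if not g:
            raise ParameterError("empty bead group")
        out.append(g)
    out.sort(key=lambda g: g[0])
    return tuple(out)


@dataclass(frozen=True)
class LinearMapping:
    """An N x n linear CG map with disjoint, normalized, non-negative rows.

    Do not instantiate directly; use :func:`slicing_map`,
    :func:`averaging_map` or the enumerators, which canonicalize the bead
    order (beads sorted by smallest member atom index).
    """

    n_atoms: int
    groups: tuple
    style: str  # "slicing" | "averaging"

    def __post_init__(self):
        groups = _canonical_groups(self.groups)
        object.__setattr__(self, "groups", groups)
        seen = set()
        for g in groups:
            for a in g:
                if a < 0 or a >= self.n_atoms:
                    raise ParameterError(
                        f"atom index {a} out of range for n={self.n_atoms}"
                    )
                if a in seen:
                    raise ParameterError(f"atom {a} assigned to multiple beads")
                seen.add(a)
        if self.style == "slicing" and any(len(g) != 1 for g in groups):
            raise ParameterError("slicing beads must be single atoms")
        if self.style not in ("slicing", "averaging"):
            raise ParameterError(f"unknown mapping style {self.style!r}")
        if len(groups) > self.n_atoms:
            raise ParameterError("more beads than atoms")

    @property
    def n_beads(self) -> int:
        return len(self.groups)

    @property
    def matrix(self) -> np.ndarray:
        """The N x n mapping matrix (uniform weights within each bead)."""
        m = np.zeros((self.n_beads, self.n_atoms))
        for i, g in enumerate(self.groups):
            m[i, list(g)] = 1.0 / len(g)
        return m

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates; the atom axis is ``-2`` for (..., n, d) arrays
        and ``-1`` for (..., n) arrays."""
        coords = np.asarray(coords)
        if coords.shape[-1] == self.n_atoms and coords.ndim >= 1 and (
            coords.ndim == 1 or coords.shape[-2] != self.n_atoms
        ):
            return coords @ self.matrix.T
        if coords.ndim >= 2 and coords.shape[-2] == self.n_atoms:
            return np.einsum("Na,...ad->...Nd", self.matrix, coords)
        raise ParameterError(
            f"coordinate shape {coords.shape} incompatible with n={self.n_atoms}"
        )

    @property
    def label(self) -> str:
        """Canonical text id, e.g. ``"0+1|2+3"``."""
        return "|".join("+".join(str(a) for a in g) for g in self.groups)

    def to_text(self) -> str:
        """One-line-per-bead serialization ``bead_index: atom indices``."""
        lines = [f"# n_atoms {self.n_atoms} style {self.style}"]
        for i, g in enumerate(self.groups):
            lines.append(f"{i}: " + " ".join(str(a) for a in g))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearMapping":
        n_atoms = style = None
        groups = []
        for ln, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                try:
                    n_atoms = int(tokens[tokens.index("n_atoms") + 1])
                    style = tokens[tokens.index("style") + 1]
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"bad mapping header (line {ln})") from exc
                continue
            try:
                _, atoms = line.split(":", 1)
                groups.append(tuple(int(a) for a in atoms.split()))
            except ValueError as exc:
                raise FormatError(f"bad mapping line {ln}: {raw!r}") from exc
        if n_atoms is None or style is None or not groups:
            raise FormatError("mapping text missing header or beads")
        return cls(n_atoms, tuple(groups), style)


def slicing_map(n: int, kept) -> LinearMapping:
    """Slicing map keeping the given distinct atom indices as beads."""
    kept = list(kept)
    if len(set(kept)) != len(kept):
        raise ParameterError(f"duplicate atom indices in {kept}")
    return LinearMapping(n, tuple((a,) for a in kept), "slicing")


def averaging_map(n: int, groups) -> LinearMapping:
    """Averaging map with uniform weights over each (disjoint) group."""
    return LinearMapping(n, tuple(tuple(g) for g in groups), "averaging")


def identity_map(n: int) -> LinearMapping:
    """The resolution-preserving map (every atom its own bead)."""
    return slicing_map(n, range(n))


def block_map(n: int, N: int) -> LinearMapping:
    """Contiguous averaging map with (near-)equal bead sizes.

    When ``N`` does not divide ``n`` the remainder atoms are attached to the
    last bead (documented convention).
    """
    if not 1 <= N <= n:
        raise ParameterError(f"need 1 <= N <= n, got N={N}, n={n}")
    size = n // N
    groups = [tuple(range(i * size, (i + 1) * size)) for i in range(N)]
    groups[-1] = tuple(range((N - 1) * size, n))
    return averaging_map(n, groups)


def enumerate_contiguous_partitions(n: int, N: int):
    """Yield every split of ``0..n-1`` into N contiguous non-empty blocks.

    Lexicographic in the cut positions; O(N) memory per item.
    """
    if not 1 <= N <= n:
        raise ParameterError(f"need 1 <= N <= n, got N={N}, n={n}")
    for cuts in itertools.combinations(range(1, n), N - 1):
        bounds = (0,) + cuts + (n,)
        yield tuple(tuple(range(bounds[i], bounds[i + 1])) for i in range(N))


def contiguous_averaging_maps(n: int, N: int):
    """Contiguous partitions wrapped as averaging :class:`LinearMapping`."""
    for groups in enumerate_contiguous_partitions(n, N):
        yield averaging_map(n, groups)


def count_contiguous_partitions(n: int, N: int) -> int:
    """Number of contiguous N-partitions of n ordered atoms (stars and bars)."""
    if not 1 <= N <= n:
        raise ParameterError(f"need 1 <= N <= n, got N={N}, n={n}")
    return math.comb(n - 1, N - 1)


def enumerate_slicings(n: int, N: int):
    """All slicing maps keeping N of n atoms, in lexicographic order."""
    if not 1 <= N <= n:
        raise ParameterError(f"need 1 <= N <= n, got N={N}, n={n}")
    for kept in itertools.combinations(range(n), N):
        yield slicing_map(n, kept)


def enumerate_two_bead_candidates(n: int = 4):
    """The canonical 2-bead candidate set for a chain of ``n`` atoms.

    All slicing maps keeping 2 atoms plus all contiguous averaging
    partitions into 2 beads, deduplicated and sorted by bead groups.  CG
    beads built from several atoms are groups of subsequent atoms, the same
    convention the network-model mapping space uses; slicing beads may drop
    atoms by construction.
    """
    seen = set()
    out = []
    for m in itertools.chain(
        enumerate_slicings(n, 2), contiguous_averaging_maps(n, 2)
    ):
        if m.groups in seen:
            continue
        seen.add(m.groups)
        out.append(m)
    out.sort(key=lambda m: m.groups)
    return out


def enumerate_disjoint_pair_maps(n: int = 4):
    """Exhaustive 2-bead space: all unordered pairs of disjoint non-empty
    atom subsets as uniform averaging maps (atoms may be left unassigned).

    This is the largest space representable by the mapping type at N=2; it
    contains non-contiguous beads and is provided for exploratory sweeps.
    """
    seen = set()
    out = []
    for assign in itertools.product((0, 1, 2), repeat=n):
        g1 = tuple(a for a in range(n) if assign[a] == 1)
        g2 = tuple(a for a in range(n) if assign[a] == 2)
        if not g1 or not g2:
            continue
        key = frozenset((g1, g2))
        if key in seen:
            continue
        seen.add(key)
        out.append(averaging_map(n, (g1, g2)))
    out.sort(key=lambda m: m.groups)
    return out
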