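"""Core data structures for multi-informant classroom social networks.

A classroom social network is stored as a square adjacency matrix over one
shared, ordered roster of children. Three informant kinds are supported:

* ``nomination`` — directed binary peer nominations (child report),
* ``rating``     — symmetric ordinal ratings on a 0-4 Likert scale
  (teacher report),
* ``count``      — symmetric nonnegative interaction counts accumulated
  over repeated observation cycles (researcher report).

All statistics run over the ``n*(n-1)`` *ordered* off-diagonal dyads; the
diagonal is formally undefined, stored as zero, and masked everywhere.
Symmetric networks are stored mirrored so the same dyad universe applies
to every informant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_KINDS = ("nomination", "rating", "count")
RATING_SCALE_MAX = 4


class NetworkFormatError(ValueError):
    """Malformed input: non-square matrix, unparsable cells."""


class NetworkDomainError(ValueError):
    """Values outside the domain a network kind allows."""


class RosterError(ValueError):
    """Node labels inconsistent between rows, columns, or networks."""


def ordered_dyads(n: int) -> int:
    """Number of ordered off-diagonal dyads among ``n`` children."""
    return n * (n - 1)


def offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def offdiag_values(matrix: np.ndarray) -> np.ndarray:
    """Off-diagonal cells in row-major order (length ``n*(n-1)``)."""
    matrix = np.asarray(matrix)
    return matrix[offdiag_mask(matrix.shape[0])]


def upper_pair_values(matrix: np.ndarray) -> np.ndarray:
    """Unordered-pair values of a symmetric matrix (each pair once)."""
    matrix = np.asarray(matrix)
    return matrix[np.triu_indices(matrix.shape[0], k=1)]


@dataclass(frozen=True)
class Roster:
    """The shared node set fixing matrix order for every network.

    Parameters
    ----------
    child_ids
        Ordered, unique child labels. This order is canonical for the
        rows and columns of every matrix built on the roster.
    consented
        Per-child consent flags. Nonconsented children must be excluded
        before matrix construction; the effective classroom size is the
        number of consented children.
    n_cycles
        Total observation cycles in the time-sampling protocol (optional).
    available_cycles
        Per-child count of cycles the child could be observed (optional).
    """

    child_ids: tuple[str, ...]
    consented: tuple[bool, ...] | None = None
    n_cycles: int | None = None
    available_cycles: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(c) for c in self.child_ids)
        object.__setattr__(self, "child_ids", ids)
        if len(set(ids)) != len(ids):
            raise RosterError("child_ids must be unique")
        if self.consented is not None:
            if len(self.consented) != len(ids):
                raise RosterError("consented length mismatch")
            object.__setattr__(self, "consented", tuple(bool(c) for c in self.consented))
        if self.available_cycles is not None:
            avail = tuple(int(a) for a in self.available_cycles)
            if len(avail) != len(ids):
                raise RosterError("available_cycles length mismatch")
            if self.n_cycles is not None and any(
                a < 0 or a > self.n_cycles for a in avail
            ):
                raise NetworkDomainError(
                    "available_cycles must lie in [0, n_cycles]"
                )
            object.__setattr__(self, "available_cycles", avail)
        if self.effective_size < 2:
            raise NetworkDomainError("effective classroom size must be >= 2")

    @property
    def n(self) -> int:
        return len(self.child_ids)

    @property
    def effective_size(self) -> int:
        """Number of consented children (all, if consent flags absent)."""
        if self.consented is None:
            return self.n
        return int(sum(self.consented))

    def index_of(self, child_id: str) -> int:
        return self.child_ids.index(child_id)


def _validate_matrix(roster: Roster, matrix: np.ndarray, label: str) -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise NetworkFormatError(f"{label}: matrix must be square, got {matrix.shape}")
    if matrix.shape[0] != roster.n:
        raise RosterError(
            f"{label}: matrix dimension {matrix.shape[0]} != roster size {roster.n}"
        )
    if np.any(np.diagonal(matrix) != 0):
        logger.warning("%s: nonzero diagonal entries zeroed (diagonal is undefined)", label)
        matrix = matrix.copy()
        np.fill_diagonal(matrix, 0)
    return matrix


@dataclass
class ValueNetwork:
    """Square matrix of dyadic values over a roster.

    ``kind`` fixes the value domain and directedness: nominations are
    directed 0/1, ratings are symmetric integers on 0-4, counts are
    symmetric nonnegative integers. The diagonal is undefined (stored 0).
    """

    roster: Roster
    values: np.ndarray
    kind: str
    directed: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise NetworkDomainError(f"unknown network kind {self.kind!r}")
        if self.directed is None:
            self.directed = self.kind == "nomination"
        self.values = _validate_matrix(self.roster, self.values, self.kind).astype(float)
        off = offdiag_values(self.values)
        if self.kind == "nomination":
            if not self.directed:
                raise NetworkDomainError("nomination networks are directed")
            if not np.isin(off, (0, 1)).all():
                raise NetworkDomainError("nomination values must be 0 or 1")
        elif self.kind == "rating":
            if self.directed:
                raise NetworkDomainError("rating networks are undirected")
            if np.any(off != np.round(off)) or off.min() < 0 or off.max() > RATING_SCALE_MAX:
                raise NetworkDomainError(
                    f"ratings must be integers on 0-{RATING_SCALE_MAX}"
                )
        else:  # count
            if self.directed:
                raise NetworkDomainError("count networks are undirected")
            if np.any(off != np.round(off)) or off.min() < 0:
                raise NetworkDomainError("counts must be nonnegative integers")
        if not self.directed and not np.array_equal(self.values, self.values.T):
            raise NetworkDomainError(f"{self.kind} matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.roster.n

    @property
    def matrix(self) -> np.ndarray:
        return self.values


@dataclass
class BinaryNetwork:
    """0/1 dyadic matrix; carries the binarization scheme that made it.

    ``scheme`` is ``"native"`` for networks that were measured binary
    (peer nominations) or a :class:`~classnet.binarize.BinarizationSpec`.
    """

    roster: Roster
    ties: np.ndarray
    scheme: Any = "native"
    directed: bool = True

    def __post_init__(self) -> None:
        ties = _validate_matrix(self.roster, self.ties, "binary network")
        off = offdiag_values(ties)
        if not np.isin(off, (0, 1)).all():
            raise NetworkDomainError("binary network cells must be 0 or 1")
        if not self.directed and not np.array_equal(ties, ties.T):
            raise NetworkDomainError("undirected binary network must be symmetric")
        self.ties = ties.astype(int)

    @property
    def n(self) -> int:
        return self.roster.n

    @property
    def matrix(self) -> np.ndarray:
        return self.ties


Network = ValueNetwork | BinaryNetwork


# ---------------------------------------------------------------------------
# Adjacency I/O — labeled CSV matrices (first row and first column = labels)
# ---------------------------------------------------------------------------

def read_adjacency(
    path: str | Path,
    kind: str,
    directed: bool | None = None,
    symmetrize: bool = False,
) -> ValueNetwork:
    """Read a labeled square adjacency CSV into a :class:`ValueNetwork`.

    The header row and the first column carry the child labels, which must
    match in content and order. Symmetric kinds (rating, count) are
    verified symmetric unless ``symmetrize=True``, which mirrors via the
    elementwise maximum (logged). Nonzero diagonals are zeroed with a
    warning.
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise NetworkFormatError(
            f"{path}: adjacency matrix must be square, got {frame.shape}"
        )
    rows = [str(r) for r in frame.index]
    cols = [str(c) for c in frame.columns]
    if rows != cols:
        raise RosterError(f"{path}: row labels do not match column labels")
    try:
        matrix = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: non-numeric cell ({exc})") from exc
    if symmetrize:
        logger.info("%s: symmetrizing via elementwise maximum", path)
        matrix = np.maximum(matrix, matrix.T)
    roster = Roster(child_ids=tuple(rows))
    return ValueNetwork(roster=roster, values=matrix, kind=kind, directed=directed)


def write_adjacency(net: Network, path: str | Path) -> None:
    """Write the labeled adjacency matrix as CSV (integer cells)."""
    matrix = net.matrix
    if np.allclose(matrix, np.round(matrix)):
        matrix = matrix.astype(int)
    frame = pd.DataFrame(matrix, index=net.roster.child_ids, columns=net.roster.child_ids)
    frame.to_csv(path)


def read_roster(path: str | Path, n_cycles: int | None = None) -> Roster:
    """Read a roster CSV with columns ``child_id, consented, available_cycles``."""
    frame = pd.read_csv(path, dtype={"child_id": str})
    if "child_id" not in frame.columns:
        raise NetworkFormatError(f"{path}: roster needs a child_id column")
    consented = (
        tuple(frame["consented"].astype(bool)) if "consented" in frame.columns else None
    )
    avail = (
        tuple(frame["available_cycles"].astype(int))
        if "available_cycles" in frame.columns
        else None
    )
    return Roster(
        child_ids=tuple(frame["child_id"]),
        consented=consented,
        n_cycles=n_cycles,
        available_cycles=avail,
    )


def write_roster(roster: Roster, path: str | Path) -> None:
    data: dict[str, Any] = {"child_id": roster.child_ids}
    if roster.consented is not None:
        data["consented"] = roster.consented
    if roster.available_cycles is not None:
        data["available_cycles"] = roster.available_cycles
    pd.DataFrame(data).to_csv(path, index=False)


def export_edge_list(net: Network, path: str | Path) -> None:
    """Write a ``source,target,weight`` edge list of present/nonzero dyads.

    Undirected networks emit each unordered pair once.
    """
    matrix = net.matrix
    ids = net.roster.child_ids
    rows, cols = np.nonzero(matrix)
    if not net.directed:
        keep = rows < cols
        rows, cols = rows[keep], cols[keep]
    frame = pd.DataFrame(
        {
            "source": [ids[i] for i in rows],
            "target": [ids[j] for j in cols],
            "weight": matrix[rows, cols],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def density(net: BinaryNetwork) -> float:
    """Proportion of present ties over the ordered off-diagonal dyads.

    For symmetric networks both mirrored cells count, which equals the
    unordered-pair density.
    """
    if net.n < 2:
        raise NetworkDomainError("density undefined for n < 2")
    off = offdiag_values(net.ties)
    return float(off.sum() / ordered_dyads(net.n))


def node_strength(net: Network, mode: str = "total") -> pd.Series:
    """Per-child strength: sum of dyadic values incident to each child.

    ``mode`` is one of ``in`` (column sums), ``out`` (row sums) or
    ``total`` (in + out for directed networks). For symmetric networks
    every mode coincides with the row sum, so a child's total strength is
    counted once per unordered pair.
    """
    if mode not in ("in", "out", "total"):
        raise NetworkDomainError(f"unknown strength mode {mode!r}")
    matrix = net.matrix
    out_strength = matrix.sum(axis=1)
    in_strength = matrix.sum(axis=0)
    if not net.directed:
        values = out_strength
    elif mode == "in":
        values = in_strength
    elif mode == "out":
        values = out_strength
    else:
        values = in_strength + out_strength
    return pd.Series(values, index=list(net.roster.child_ids), name=f"strength_{mode}")
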