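"""Pedigree handling and the inverse numerator relationship matrix.

A pedigree is a list of (individual, sire, dam) triples with 0 denoting an
unknown parent.  Internally individuals are renumbered 1..n in topological
order (parents before offspring), which is what every downstream recursion
(Henderson's A^-1 rules, the epigenetic T/T^-1 recursions, the simulator)
requires.  The original labels are preserved in a bidirectional mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "build_A_inverse",
    "build_A_tabular",
]

UNKNOWN = 0
# refuse dense tabular construction above this size unless overridden
DENSE_CAP = 2000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, undeclared
    parents, cycles)."""


@dataclass(frozen=True)
class Pedigree:
    """A validated, topologically ordered pedigree.

    Attributes
    ----------
    sire, dam : int arrays of length n
        Internal parent codes, 1-based; 0 means unknown.  Entry ``i``
        (0-based) describes internal individual ``i + 1``, and parents
        always have smaller internal codes than their offspring.
    labels : array of length n
        Original external ids; ``labels[i]`` is the external id of
        internal individual ``i + 1``.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {lab: i + 1 for i, lab in enumerate(self.labels)}
        )

    @property
    def n(self) -> int:
        return len(self.sire)

    def internal_id(self, label) -> int:
        """Map an external id to the internal 1..n code."""
        return self._index[label]

    @property
    def n_both_parents(self) -> int:
        return int(np.sum((self.sire != UNKNOWN) & (self.dam != UNKNOWN)))

    @property
    def n_single_parent(self) -> int:
        return int(np.sum((self.sire != UNKNOWN) ^ (self.dam != UNKNOWN)))

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Validate and topologically order raw (id, sire, dam) triples.

        Raises
        ------
        PedigreeError
            on duplicate ids, parents never declared as individuals, an
            individual listed as its own parent, or ancestry cycles.
        """
        records = list(records)
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise PedigreeError(f"duplicate individual id(s): {sorted(dups)}")
        id_set = set(ids)
        if UNKNOWN in id_set:
            raise PedigreeError("0 is reserved for unknown parents")
        parents = {}
        for ind, s, d in records:
            for p in (s, d):
                if p != UNKNOWN and p not in id_set:
                    raise PedigreeError(
                        f"parent {p!r} of individual {ind!r} never declared"
                    )
            if ind in (s, d):
                raise PedigreeError(f"individual {ind!r} is its own parent")
            parents[ind] = (s, d)

        # Kahn topological sort; stable w.r.t. input order.
        order: list = []
        n_children: dict = {i: 0 for i in ids}
        children: dict = {i: [] for i in ids}
        for ind, (s, d) in parents.items():
            for p in {s, d} - {UNKNOWN}:
                n_children[ind] += 0  # keep key
            deps = [p for p in (s, d) if p != UNKNOWN]
            n_children[ind] = len(set(deps))
            for p in set(deps):
                children[p].append(ind)
        ready = [i for i in ids if n_children[i] == 0]
        pos = 0
        while pos < len(ready):
            cur = ready[pos]
            pos += 1
            order.append(cur)
            for c in children[cur]:
                n_children[c] -= 1
                if n_children[c] == 0:
                    ready.append(c)
        if len(order) != len(ids):
            cyc = sorted(set(ids) - set(order), key=ids.index)
            raise PedigreeError(f"ancestry cycle involving id(s): {cyc}")

        internal = {lab: i + 1 for i, lab in enumerate(order)}
        sire = np.zeros(len(order), dtype=np.int64)
        dam = np.zeros(len(order), dtype=np.int64)
        for lab in order:
            s, d = parents[lab]
            i = internal[lab] - 1
            sire[i] = internal[s] if s != UNKNOWN else UNKNOWN
            dam[i] = internal[d] if d != UNKNOWN else UNKNOWN
        return cls(sire=sire, dam=dam, labels=np.asarray(order))


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file: columns id, sire, dam; 0 = unknown parent.

    Whitespace- or comma-delimited; lines starting with '#' are comments.
    Ids are parsed as integers when every token is integral, otherwise
    kept as strings.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    rows = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        toks = ln.replace(",", " ").split()
        if len(toks) < 3:
            raise PedigreeError(f"pedigree line has fewer than 3 columns: {ln!r}")
        rows.append(toks[:3])
    flat = [t for r in rows for t in r]
    if all(_is_int(t) for t in flat):
        records = [(int(a), int(b), int(c)) for a, b, c in rows]
    else:
        records = [
            (a, UNKNOWN if b == "0" else b, UNKNOWN if c == "0" else c)
            for a, b, c in rows
        ]
    return Pedigree.from_records(records)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree in the id/sire/dam text format (external labels)."""
    ext = {i + 1: lab for i, lab in enumerate(ped.labels)}
    ext[UNKNOWN] = 0
    buf = io.StringIO()
    buf.write("# id sire dam\n")
    for i in range(ped.n):
        buf.write(f"{ext[i + 1]} {ext[int(ped.sire[i])]} {ext[int(ped.dam[i])]}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse numerator relationship matrix by Henderson's rules.

    Inbreeding is not accounted for: each individual contributes the
    rank-one block (1/d) k k' with k = e_i - 1/2 e_sire - 1/2 e_dam and
    Mendelian-sampling scale d = 1/2 (both parents), 3/4 (one parent),
    1 (founder).  Exact whenever breeding individuals are non-inbred.
    """
    rows, cols, vals = _recursive_inverse_triplets(ped, 0.5)
    n = ped.n
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A


def _recursive_inverse_triplets(ped: Pedigree, coef: float, d_both=None,
                                d_one=None):
    """Shared engine for A^-1 (coef=1/2) and T^-1 (coef=lambda).

    Per individual i with parents p in P: add (1/d_i) at (i,i),
    (-coef/d_i) at (i,p), (coef^2/d_i) at every parent pair (p,q), where
    d_i = 1 - |P| coef^2 by default (Henderson: 1/2 and 3/4 at coef=1/2).
    Off-diagonals are emitted for both (i,j) and (j,i).
    """
    if d_both is None:
        d_both = 1.0 - 2.0 * coef * coef
    if d_one is None:
        d_one = 1.0 - coef * coef
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(v)

    for i in range(ped.n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        ps = [p - 1 for p in (s, d) if p != UNKNOWN]
        if len(ps) == 2:
            inv_d = 1.0 / d_both
        elif len(ps) == 1:
            inv_d = 1.0 / d_one
        else:
            inv_d = 1.0
        add(i, i, inv_d)
        for p in ps:
            add(i, p, -coef * inv_d)
        if len(ps) == 1:
            add(ps[0], ps[0], coef * coef * inv_d)
        elif len(ps) == 2:
            a, b = ps
            add(a, a, coef * coef * inv_d)
            add(b, b, coef * coef * inv_d)
            add(a, b, coef * coef * inv_d)
    return np.array(rows), np.array(cols), np.array(vals)


def build_A_tabular(ped: Pedigree, cap: int = DENSE_CAP) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    a_ii = 1 + 1/2 a_{sire,dam}; a_ij = 1/2 (a_{j,sire(i)} + a_{j,dam(i)}).
    Intended as a small-n oracle; refuses n above `cap`.
    """
    n = ped.n
    if n > cap:
        raise ValueError(f"dense A refused for n={n} > cap={cap}")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(ped.sire[i]) - 1, int(ped.dam[i]) - 1
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A
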