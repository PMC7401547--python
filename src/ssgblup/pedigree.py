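"""Pedigree (numerator) relationship machinery.

The additive relationship matrix A describes expected identity-by-descent
between animals given a pedigree.  This module builds A by the tabular
method, computes inbreeding coefficients by the Meuwissen–Luo algorithm,
assembles the sparse inverse A⁻¹ directly from Henderson's rules (with
inbreeding), and extracts the genotyped block A22 and its inverse.

Conventions: an unknown parent is the sentinel 0 (or NA in files); pedigrees
are topologically sorted internally so parents always precede offspring; no
genetic-group machinery is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

UNKNOWN = 0


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeTable:
    """Ordered pedigree records.

    ``ids`` holds original animal identifiers; ``sire`` / ``dam`` are
    0-based positional indices into ``ids`` or -1 when unknown, with
    parents always at smaller positions than their offspring.
    """

    ids: list
    sire: np.ndarray  # int, -1 = unknown
    dam: np.ndarray
    sex: np.ndarray | None = None  # 'M'/'F' per animal, optional
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise PedigreeError("duplicate animal ids in pedigree")
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par >= np.arange(len(self.ids))):
                raise PedigreeError(f"{name} index does not precede offspring; pedigree not sorted")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, ids) -> np.ndarray:
        try:
            return np.array([self._pos[a] for a in ids], dtype=np.int64)
        except KeyError:
            missing = [a for a in ids if a not in self._pos]
            raise PedigreeError(f"ids not in pedigree: {missing[:10]}")

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    @classmethod
    def from_records(cls, records: pd.DataFrame, sex=None) -> "PedigreeTable":
        """Build from a frame with columns animal, sire, dam (0/NA = unknown).

        Input may be in any order; a stable topological sort (original file
        order among ties) is applied.  Cycles raise ``PedigreeError``.
        """
        df = records.copy()
        df.columns = [c.lower() for c in df.columns[:3]] + list(df.columns[3:])
        animals = df.iloc[:, 0].tolist()
        if len(animals) != len(set(animals)):
            raise PedigreeError("duplicate animal ids in pedigree file")
        known = set(animals)

        def clean(v):
            if pd.isna(v) or v == UNKNOWN or v == str(UNKNOWN) or v == "NA":
                return None
            return v

        sire_of = {a: clean(s) for a, s in zip(animals, df.iloc[:, 1])}
        dam_of = {a: clean(d) for a, d in zip(animals, df.iloc[:, 2])}
        for a in animals:
            for p in (sire_of[a], dam_of[a]):
                if p is not None and p not in known:
                    # parent without its own record: treat as founder, prepend
                    known.add(p)
        extra = [p for a in animals for p in (sire_of[a], dam_of[a])
                 if p is not None and p not in sire_of]
        for p in dict.fromkeys(extra):
            sire_of[p] = None
            dam_of[p] = None
        all_animals = list(dict.fromkeys(extra)) + animals

        # stable topological sort: repeated in-order scans with immediate
        # placement, so an already-sorted file round-trips unchanged
        order: list = []
        placed: set = set()
        pending = list(all_animals)
        while pending:
            remaining = []
            progress = False
            for a in pending:
                if ((sire_of[a] is None or sire_of[a] in placed)
                        and (dam_of[a] is None or dam_of[a] in placed)):
                    order.append(a)
                    placed.add(a)
                    progress = True
                else:
                    remaining.append(a)
            if not progress:
                raise PedigreeError("pedigree contains a cycle (animal is its own ancestor)")
            pending = remaining
        pos = {a: i for i, a in enumerate(order)}
        sire = np.array([pos[sire_of[a]] if sire_of[a] is not None else -1 for a in order])
        dam = np.array([pos[dam_of[a]] if dam_of[a] is not None else -1 for a in order])
        sex_arr = None
        if sex is not None:
            sex_map = dict(zip(animals, sex))
            sex_arr = np.array([sex_map.get(a, "U") for a in order])
        return cls(ids=order, sire=sire, dam=dam, sex=sex_arr, _pos=pos)

    @classmethod
    def read_csv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path)
        return cls.from_records(df)

    def to_frame(self) -> pd.DataFrame:
        def lab(idx):
            return [self.ids[i] if i >= 0 else UNKNOWN for i in idx]

        return pd.DataFrame({"animal": self.ids, "sire": lab(self.sire), "dam": lab(self.dam)})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an explicit ordered id list."""

    values: np.ndarray
    ids: list
    kind: str  # A | A22 | G_raw | G_blended | Hinv_addend

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix/id shape mismatch")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-10:
            raise ValueError("matrix not symmetric within 1e-10")
        self.values = (v + v.T) / 2.0

    def write_coo_tsv(self, path) -> None:
        """Lower triangle in labelled coordinate format (diff-able)."""
        i, j = np.tril_indices(len(self.ids))
        pd.DataFrame({
            "id_i": [self.ids[a] for a in i],
            "id_j": [self.ids[b] for b in j],
            "value": self.values[i, j],
        }).to_csv(path, sep="\t", index=False)


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F by Meuwissen & Luo (1992).

    F(x) = 0.5·A(sire, dam); founders get F = 0.  Runs in O(n·d²) where d is
    the number of ancestors per animal, so it scales to very large pedigrees
    without forming A.
    """
    n = ped.n
    f = np.zeros(n)
    sire, dam = ped.sire, ped.dam

    def mend(j: int) -> float:
        # within-family variance coefficient d_j; the -1 stand-in for an
        # unknown parent's F folds all three parent-knowledge cases into one
        # expression: both known 0.5-0.25(Fs+Fd); one 0.75-0.25Fp; none 1.
        sj, dj = sire[j], dam[j]
        return 0.5 - 0.25 * ((f[sj] if sj >= 0 else -1.0) + (f[dj] if dj >= 0 else -1.0))

    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            f[i] = 0.0  # unknown parent assumed unrelated to the other
            continue
        # a_ii = sum_j T_ij^2 d_j over i and its ancestors, where T_ij is the
        # expected genetic contribution of j to i (T_ii = 1); F_i = a_ii - 1.
        AN: dict[int, float] = {}

        def add(anc: int, r: float):
            AN[anc] = AN.get(anc, 0.0) + r

        add(s, 0.5)
        add(d, 0.5)
        aii = mend(i)  # own-term contribution, T_ii = 1
        # pop youngest first so every path contribution to an ancestor has
        # been accumulated before its term is added
        while AN:
            j = max(AN)
            r = AN.pop(j)
            aii += r * r * mend(j)
            if sire[j] >= 0:
                add(sire[j], r * 0.5)
            if dam[j] >= 0:
                add(dam[j], r * 0.5)
        f[i] = aii - 1.0
    return f


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return RelationshipMatrix(values=A, ids=list(ped.ids), kind="A")


def build_Ainv(ped: PedigreeTable, f: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A⁻¹ assembled from Henderson's rules with inbreeding.

    The Mendelian sampling variance for animal i is
    d_i = 0.5 − 0.25·(F_s + F_d) with both parents known,
    d_i = 0.75 − 0.25·F_p with one parent known, and 1 for founders.
    """
    if f is None:
        f = compute_inbreeding(ped)
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def put(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * f[p]
        else:
            di = 1.0
        w = 1.0 / di
        put(i, i, w)
        for p in (s, d):
            if p >= 0:
                put(i, p, -0.5 * w)
                put(p, i, -0.5 * w)
                put(p, p, 0.25 * w)
        if s >= 0 and d >= 0:
            put(s, d, 0.25 * w)
            put(d, s, 0.25 * w)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def extract_A22(ped: PedigreeTable, genotyped_ids,
                dense_threshold: int = 10000) -> tuple[RelationshipMatrix, np.ndarray]:
    """Principal submatrix of A for the genotyped animals plus its inverse.

    For pedigrees small enough, slices the tabular A.  For larger pedigrees
    the full A is never materialised: with A⁻¹ partitioned by (ungenotyped,
    genotyped) blocks, A22⁻¹ = Ainv22 − Ainv21·Ainv11⁻¹·Ainv12 (Schur
    complement), which needs only a sparse factorisation of Ainv11.
    """
    idx = ped.positions(genotyped_ids)
    if ped.n <= dense_threshold:
        A = build_A(ped).values
        a22 = A[np.ix_(idx, idx)]
        a22_inv = np.linalg.inv(a22)
    else:
        ainv = build_Ainv(ped).tocsc()
        mask = np.zeros(ped.n, dtype=bool)
        mask[idx] = True
        rest = np.where(~mask)[0]
        A11 = ainv[np.ix_(rest, rest)]
        A12 = ainv[np.ix_(rest, idx)].toarray()
        A22b = ainv[np.ix_(idx, idx)].toarray()
        lu = splu(A11.tocsc())
        a22_inv = A22b - A12.T @ lu.solve(A12)
        a22_inv = (a22_inv + a22_inv.T) / 2
        a22 = np.linalg.inv(a22_inv)
    a22 = (a22 + a22.T) / 2
    return (RelationshipMatrix(values=a22, ids=list(genotyped_ids), kind="A22"),
            (a22_inv + a22_inv.T) / 2)


def summarize_inbreeding(ped: PedigreeTable, phenotyped_ids=None) -> dict:
    """Mean pedigree F over the full pedigree and, optionally, a subset."""
    f = compute_inbreeding(ped)
    out = {"mean_F_full": float(np.mean(f))}
    if phenotyped_ids is not None:
        out["mean_F_subset"] = float(np.mean(f[ped.positions(phenotyped_ids)]))
    return out
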