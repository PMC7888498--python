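"""Pedigree handling for the animal model.

Reads and validates pedigrees, renumbers animals so parents precede
offspring, computes inbreeding coefficients, and builds the numerator
relationship matrix A (dense tabular method, as an oracle for small
pedigrees) and its sparse inverse (Henderson's parent-offspring rules with
inbreeding-corrected Mendelian-sampling variances).  The sparse inverse is
what the Gibbs sampler consumes; the dense A exists only so the two
constructions can be checked against each other.

Unknown parents are treated as unrelated base-population draws (code 0);
there are no genetic groups.  Animals that appear only as a sire or dam are
auto-promoted to founders with a logged warning, since herd pedigrees
routinely list service sires without records of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .errors import FormatError, NumericalError, PedigreeCycleError, ValidationError
from ._kernels import meuwissen_luo_inbreeding

logger = logging.getLogger(__name__)

UNKNOWN = None

_DENSE_A_GUARD = 5000


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree line: an animal and its (possibly unknown) parents."""

    animal: str
    sire: str | None = None
    dam: str | None = None

    def __post_init__(self):
        if not self.animal:
            raise ValidationError("empty animal identifier")
        if self.sire is not None and self.sire == self.animal:
            raise ValidationError(f"animal {self.animal!r} is its own sire")
        if self.dam is not None and self.dam == self.animal:
            raise ValidationError(f"animal {self.animal!r} is its own dam")


@dataclass
class RenumberedPedigree:
    """Pedigree with integer codes 1..n, parents preceding offspring.

    ``sire`` and ``dam`` are int64 arrays of length n+1 whose index 0 is a
    dummy entry for the unknown parent (code 0).  ``ids[c-1]`` is the
    original identifier of code c.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    code_of: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def code(self, animal: str) -> int:
        try:
            return self.code_of[animal]
        except KeyError:
            raise ValidationError(f"animal {animal!r} not in pedigree") from None


@dataclass(frozen=True)
class PedigreeSummary:
    """Structural counts of a pedigree, in herd-book report style."""

    n_animals: int
    n_base_animals: int
    n_with_records: int
    n_unknown_sire: int
    n_unknown_dam: int
    n_both_unknown: int
    n_sires_with_progeny: int
    n_dams_with_progeny: int


def read_pedigree(path, unknown_tokens=("0", ""), sep=",") -> list[PedigreeRecord]:
    """Read a pedigree CSV with columns animal,sire,dam (header optional).

    Tokens in ``unknown_tokens`` (and empty cells) denote an unknown parent.
    Duplicate animal identifiers are rejected.
    """
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     keep_default_na=False)
    if df.shape[1] < 3:
        raise FormatError(
            f"pedigree file {path} needs 3 columns (animal,sire,dam), "
            f"found {df.shape[1]}"
        )
    first = [c.strip().lower() for c in df.iloc[0, :3]]
    if first == ["animal", "sire", "dam"]:
        df = df.iloc[1:]
    unknown = {t.lower() for t in unknown_tokens} | {""}

    def _parent(tok: str):
        tok = tok.strip()
        return None if tok.lower() in unknown else tok

    records = []
    seen = set()
    for _, row in df.iterrows():
        animal = row.iloc[0].strip()
        if animal in seen:
            raise ValidationError(f"duplicate animal id {animal!r} in pedigree")
        seen.add(animal)
        records.append(
            PedigreeRecord(animal, _parent(row.iloc[1]), _parent(row.iloc[2]))
        )
    return records


def renumber(records: list[PedigreeRecord]) -> RenumberedPedigree:
    """Topologically order animals so every parent precedes its offspring.

    Parents referenced but never listed as animals are inserted as founders
    (logged).  A pedigree cycle raises :class:`PedigreeCycleError` listing
    the cycle.
    """
    parents: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    for rec in records:
        parents[rec.animal] = (rec.sire, rec.dam)
        order_seen.append(rec.animal)
    promoted = []
    for rec in records:
        for p in (rec.sire, rec.dam):
            if p is not None and p not in parents:
                parents[p] = (None, None)
                order_seen.append(p)
                promoted.append(p)
    if promoted:
        logger.warning(
            "%d animals appeared only as parents; promoted to founders: %s",
            len(promoted), ", ".join(map(str, promoted[:10])),
        )

    # Kahn's algorithm, stable in first-appearance order.
    n_unresolved = {
        a: sum(p is not None for p in ps) for a, ps in parents.items()
    }
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, (s, d) in parents.items():
        for p in {s, d} - {None}:
            children[p].append(a)
    queue = [a for a in order_seen if n_unresolved[a] == 0]
    ordered: list[str] = []
    head = 0
    while head < len(queue):
        a = queue[head]
        head += 1
        ordered.append(a)
        for c in children[a]:
            s, d = parents[c]
            n_unresolved[c] -= (s == a) + (d == a)
            if n_unresolved[c] == 0:
                queue.append(c)
    if len(ordered) < len(parents):
        leftover = [a for a in order_seen if a not in set(ordered)]
        # walk parents among the leftovers to exhibit one cycle
        start = leftover[0]
        trail, cur = [], start
        while cur not in trail:
            trail.append(cur)
            s, d = parents[cur]
            cur = s if (s in leftover) else d
        cycle = trail[trail.index(cur):] + [cur]
        raise PedigreeCycleError(cycle)

    code_of = {a: i + 1 for i, a in enumerate(ordered)}
    n = len(ordered)
    sire = np.zeros(n + 1, dtype=np.int64)
    dam = np.zeros(n + 1, dtype=np.int64)
    for a, (s, d) in parents.items():
        c = code_of[a]
        sire[c] = code_of[s] if s is not None else 0
        dam[c] = code_of[d] if d is not None else 0
    return RenumberedPedigree(ids=ordered, sire=sire, dam=dam, code_of=code_of)


def compute_inbreeding(ped: RenumberedPedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen-Luo recursion)."""
    return meuwissen_luo_inbreeding(ped.sire, ped.dam)


def build_a_tabular(ped: RenumberedPedigree, max_n: int = _DENSE_A_GUARD) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a(i,i) = 1 + F_i and a(i,j) = (a(j, sire_i) + a(j, dam_i))/2 for j < i,
    with unknown parents contributing 0.  Guarded to small pedigrees: this
    is the oracle against which the sparse inverse is checked, not the
    production path.
    """
    n = ped.n
    if n > max_n:
        raise ValidationError(
            f"dense A refused for n={n} animals (guard is {max_n}); "
            "use build_a_inverse instead"
        )
    A = np.zeros((n + 1, n + 1))
    s, d = ped.sire, ped.dam
    for i in range(1, n + 1):
        if i > 1:
            row = 0.5 * (A[s[i], 1:i] + A[d[i], 1:i])
            A[i, 1:i] = row
            A[1:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[s[i], d[i]]
    return A[1:, 1:]


def mendelian_sampling_variances(
    ped: RenumberedPedigree, F: np.ndarray | None = None,
    use_inbreeding: bool = True,
) -> np.ndarray:
    """d_i, the within-family (Mendelian-sampling) variance fractions.

    d_i = 0.5 - 0.25 (F_s + F_d) with F of an unknown parent taken as -1,
    so founders get 1 and an animal with one unknown parent gets 0.75 when
    the known parent is non-inbred.
    """
    if F is None:
        F = compute_inbreeding(ped) if use_inbreeding else np.zeros(ped.n)
    Fpad = np.concatenate(([-1.0], F if use_inbreeding else np.zeros(ped.n)))
    d = 0.5 - 0.25 * (Fpad[ped.sire[1:]] + Fpad[ped.dam[1:]])
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        raise NumericalError(
            f"non-positive Mendelian sampling variance for animal "
            f"{ped.ids[bad]!r} (corrupt inbreeding input?)"
        )
    return d


def build_a_inverse(
    ped: RenumberedPedigree, F: np.ndarray | None = None,
    use_inbreeding: bool = True,
) -> sp.csr_matrix:
    """Sparse inverse of A via Henderson's rules.

    For each animal i with Mendelian variance d_i and alpha = 1/d_i, add
    alpha at (i,i), -alpha/2 at (i, parent), alpha/4 at (parent, parent')
    for every pair of known parents (including parent with itself).
    """
    n = ped.n
    d = mendelian_sampling_variances(ped, F, use_inbreeding)
    alpha = 1.0 / d
    rows, cols, vals = [], [], []
    s, dm = ped.sire, ped.dam
    for i in range(1, n + 1):
        a = alpha[i - 1]
        i0 = i - 1
        rows.append(i0); cols.append(i0); vals.append(a)
        for p in (s[i], dm[i]):
            if p > 0:
                p0 = p - 1
                rows += [i0, p0]
                cols += [p0, i0]
                vals += [-a / 2.0, -a / 2.0]
        for p in (s[i], dm[i]):
            if p > 0:
                for q in (s[i], dm[i]):
                    if q > 0:
                        rows.append(p - 1); cols.append(q - 1)
                        vals.append(a / 4.0)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv


def write_a_inverse(path, ainv: sp.spmatrix) -> None:
    """Export the sparse A inverse as MatrixMarket coordinate format."""
    mmwrite(str(path), sp.coo_matrix(ainv), symmetry="symmetric")


def summarize_pedigree(
    ped: RenumberedPedigree, record_ids,
) -> PedigreeSummary:
    """Structural counts: base animals, unknown-parent counts, parents with
    progeny that have records, etc.  ``record_ids`` is the set of animals
    that carry phenotype records; all must be in the pedigree."""
    record_ids = set(record_ids)
    missing = record_ids - set(ped.ids)
    if missing:
        raise ValidationError(
            f"record ids absent from pedigree: {sorted(missing)[:10]}"
        )
    s, d = ped.sire[1:], ped.dam[1:]
    both_unknown = (s == 0) & (d == 0)
    rec_codes = np.array([ped.code_of[a] for a in record_ids], dtype=np.int64)
    sires_of_recorded = {int(ped.sire[c]) for c in rec_codes} - {0}
    dams_of_recorded = {int(ped.dam[c]) for c in rec_codes} - {0}
    return PedigreeSummary(
        n_animals=ped.n,
        n_base_animals=int(both_unknown.sum()),
        n_with_records=len(record_ids),
        n_unknown_sire=int(((s == 0) & ~both_unknown).sum()),
        n_unknown_dam=int(((d == 0) & ~both_unknown).sum()),
        n_both_unknown=int(both_unknown.sum()),
        n_sires_with_progeny=len(sires_of_recorded),
        n_dams_with_progeny=len(dams_of_recorded),
    )
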