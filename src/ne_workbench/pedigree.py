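"""Pedigree ingestion, validation and genealogical algebra.

A pedigree is an acyclic parent-offspring table with sexes and birth
years.  It is the substrate for additive-relationship (kinship)
computations, pedigree-depth measures, classification of individuals
into discrete filial generations (F1 = founder x founder, F2 = F1 x F1,
...) and grouping into birth-year cohorts for downstream effective-size
estimation.

Founders (both parents unknown) are the base population: they are
assumed non-inbred and mutually unrelated, the standard tabular-method
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "KinshipResult",
    "SamplingScheme",
    "FOUNDER",
    "OVERLAPPED",
    "load_pedigree",
    "compute_kinship",
    "equivalent_generations",
    "classify_filial",
    "group_cohorts",
]

#: Filial-class label for founders (both parents unknown).
FOUNDER = "FOUNDER"
#: Filial-class label for anything that is not an exact F(k) x F(k) cross.
OVERLAPPED = "OVERLAPPED"


class PedigreeError(ValueError):
    """Structural, reference or parse error in a pedigree."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


_SEX_CODES = {
    "m": Sex.MALE, "male": Sex.MALE, "1": Sex.MALE,
    "f": Sex.FEMALE, "female": Sex.FEMALE, "2": Sex.FEMALE,
}

_UNKNOWN = {"", "0", "na", "nan", "none", "."}


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: Sex
    birth_year: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Validated, topologically ordered collection of individuals.

    Order guarantees every parent precedes its offspring, which lets the
    kinship and depth recursions run in a single forward pass.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        ids = [ind.id for ind in members]
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise PedigreeError(f"duplicated individual id(s): {dupes}")
        by_id = {ind.id: ind for ind in members}
        for ind in members:
            for role, pid in (("sire", ind.sire), ("dam", ind.dam)):
                if pid is None:
                    continue
                if pid == ind.id:
                    raise PedigreeError(
                        f"individual {ind.id!r} listed as its own {role}")
                if pid not in by_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} is not in the pedigree")
            sire = by_id.get(ind.sire) if ind.sire else None
            dam = by_id.get(ind.dam) if ind.dam else None
            if sire is not None and sire.sex is not Sex.MALE:
                raise PedigreeError(f"sire {sire.id!r} of {ind.id!r} is not male")
            if dam is not None and dam.sex is not Sex.FEMALE:
                raise PedigreeError(f"dam {dam.id!r} of {ind.id!r} is not female")
            for parent in (sire, dam):
                if (parent is not None and parent.birth_year is not None
                        and ind.birth_year is not None
                        and parent.birth_year >= ind.birth_year):
                    raise PedigreeError(
                        f"parent {parent.id!r} (born {parent.birth_year}) not "
                        f"older than offspring {ind.id!r} (born {ind.birth_year})")

        graph = nx.DiGraph()
        graph.add_nodes_from(by_id)
        for ind in members:
            for pid in (ind.sire, ind.dam):
                if pid is not None:
                    graph.add_edge(pid, ind.id)
        try:
            order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            raise PedigreeError(f"pedigree contains an ancestry cycle: {cycle}")
        # Stable: keep input order among nodes with no constraint between them.
        rank = {iid: k for k, iid in enumerate(ids)}
        order = list(nx.lexicographical_topological_sort(graph, key=lambda n: rank[n]))

        self._members: list[Individual] = [by_id[i] for i in order]
        self._by_id: dict[str, Individual] = by_id
        self._index: dict[str, int] = {i: k for k, i in enumerate(order)}

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self._members]

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self._members if ind.is_founder]

    def subset_ids(self, ids: Iterable[str]) -> list[str]:
        """Given ids, return them in pedigree (topological) order."""
        wanted = set(ids)
        return [i for i in self.ids if i in wanted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self._members],
                "sire": [m.sire or "0" for m in self._members],
                "dam": [m.dam or "0" for m in self._members],
                "sex": [m.sex.value for m in self._members],
                "birth_year": [m.birth_year for m in self._members],
            }
        )


def _parse_parent(raw) -> str | None:
    s = str(raw).strip()
    if s.lower() in _UNKNOWN:
        return None
    # pandas may read integer ids as floats when the column has blanks
    if s.endswith(".0"):
        s = s[:-2]
    return s


def load_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns ``id,sire,dam,sex,birth_year``.

    Unknown parents are coded ``0`` or empty.  Sex accepts
    ``m/f``, ``male/female`` or ``1/2``.  Birth year may be empty.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing column(s): {sorted(missing)}")
    individuals = []
    for row in df.itertuples(index=False):
        sex_raw = str(row.sex).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise PedigreeError(f"unknown sex code {row.sex!r} for id {row.id!r}")
        year_raw = str(getattr(row, "birth_year", "")).strip()
        year = int(float(year_raw)) if year_raw not in _UNKNOWN else None
        individuals.append(
            Individual(
                id=str(row.id).strip(),
                sire=_parse_parent(row.sire),
                dam=_parse_parent(row.dam),
                sex=_SEX_CODES[sex_raw],
                birth_year=year,
            )
        )
    return Pedigree(individuals)


def save_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


@dataclass
class KinshipResult:
    """Inbreeding vector F and coancestry matrix C for a pedigree.

    C[i, j] is the probability that a random allele from i and a random
    allele from j at a neutral locus are identical by descent relative
    to the founder base; C[i, i] = (1 + F_i) / 2.
    """

    ids: list[str]
    F: np.ndarray
    C: np.ndarray
    _pos: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._pos:
            self._pos = {i: k for k, i in enumerate(self.ids)}

    def inbreeding(self, iid: str) -> float:
        return float(self.F[self._pos[iid]])

    def coancestry(self, i: str, j: str) -> float:
        return float(self.C[self._pos[i], self._pos[j]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self._pos[i] for i in ids])
        return self.C[np.ix_(idx, idx)]


def compute_kinship(ped: Pedigree) -> KinshipResult:
    """Tabular (recursive) kinship over the whole pedigree.

    C(i, j) = [C(sire_i, j) + C(dam_i, j)] / 2 with unknown parents
    contributing 0, and C(i, i) = [1 + C(sire_i, dam_i)] / 2.  Runs in
    O(n^2) over the topological order.
    """
    n = len(ped)
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    C = np.zeros((n, n))
    for k, ind in enumerate(ped):
        s = pos[ind.sire] if ind.sire else -1
        d = pos[ind.dam] if ind.dam else -1
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * C[s]
        if d >= 0:
            row += 0.5 * C[d]
        C[k, :k] = row[:k]
        C[:k, k] = row[:k]
        f = C[s, d] if (s >= 0 and d >= 0) else 0.0
        C[k, k] = 0.5 * (1.0 + f)
    F = 2.0 * np.diag(C) - 1.0
    return KinshipResult(ids=ids, F=F, C=C)


def equivalent_generations(ped: Pedigree) -> dict[str, float]:
    """Equivalent complete generations t per individual.

    t_i is the sum over all known ancestors of (1/2)^n with n the number
    of generations separating them from i; computed recursively as the
    sum over known parents of (1 + t_parent)/2.  Founders have t = 0.
    A fully known k-generation pedigree gives t = k exactly.
    """
    t: dict[str, float] = {}
    for ind in ped:
        val = 0.0
        if ind.sire is not None:
            val += 0.5 * (1.0 + t[ind.sire])
        if ind.dam is not None:
            val += 0.5 * (1.0 + t[ind.dam])
        t[ind.id] = val
    return t


def classify_filial(ped: Pedigree) -> dict[str, str]:
    """Label each individual FOUNDER, F1, F2, ... or OVERLAPPED.

    F1 individuals are offspring of two founders; F(k) individuals are
    offspring of two F(k-1) individuals; every other parent combination
    (including one unknown parent) is OVERLAPPED.  The labels partition
    the pedigree.
    """
    labels: dict[str, str] = {}
    for ind in ped:
        if ind.is_founder:
            labels[ind.id] = FOUNDER
            continue
        if ind.sire is None or ind.dam is None:
            labels[ind.id] = OVERLAPPED
            continue
        ls, ld = labels[ind.sire], labels[ind.dam]
        if ls == ld == FOUNDER:
            labels[ind.id] = "F1"
        elif ls == ld and ls.startswith("F") and ls[1:].isdigit():
            labels[ind.id] = f"F{int(ls[1:]) + 1}"
        else:
            labels[ind.id] = OVERLAPPED
    return labels


@dataclass(frozen=True)
class SamplingScheme:
    """Cohort-forming rule.

    kind ``discrete_generation`` groups by filial class; ``yearly``
    groups by birth year; ``span`` uses sliding contiguous birth-year
    windows of ``span_years`` (1 = yearly, 2 = biannual, 3 = triennial),
    so consecutive windows overlap as in sequential biannual samplings.
    """

    kind: str = "yearly"
    span_years: int = 1
    filial_classes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in {"discrete_generation", "yearly", "span"}:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.span_years < 1:
            raise ValueError("span_years must be >= 1")


def group_cohorts(
    ped: Pedigree, scheme: SamplingScheme
) -> dict[str, list[str]]:
    """Group individuals into cohorts under a sampling scheme.

    Returns an ordered mapping label -> ids (pedigree order).  Empty
    cohorts are omitted.  For span schemes every individual belongs to
    each sliding window containing its birth year, so windows overlap.
    """
    if scheme.kind == "discrete_generation":
        labels = classify_filial(ped)
        wanted = scheme.filial_classes or tuple(
            sorted({v for v in labels.values() if v.startswith("F") and v[1:].isdigit()},
                   key=lambda s: int(s[1:]))
        )
        return {
            cls: [i for i in ped.ids if labels[i] == cls]
            for cls in wanted
            if any(labels[i] == cls for i in ped.ids)
        }

    years = sorted({ind.birth_year for ind in ped if ind.birth_year is not None})
    if not years:
        return {}
    span = 1 if scheme.kind == "yearly" else scheme.span_years
    cohorts: dict[str, list[str]] = {}
    for start in range(years[0], years[-1] - span + 2):
        window = range(start, start + span)
        label = str(start) if span == 1 else f"{start}-{start + span - 1}"
        members = [
            ind.id for ind in ped
            if ind.birth_year is not None and ind.birth_year in window
        ]
        if members:
            cohorts[label] = members
    return cohorts
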