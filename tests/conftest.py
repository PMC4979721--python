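"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ne_workbench.genepop import GenotypeMatrix
from ne_workbench.pedigree import Individual, Pedigree, Sex


def make_pedigree(rows) -> Pedigree:
    """Build a pedigree from (id, sire, dam, sex, birth_year) tuples;
    use None for unknown parents."""
    return Pedigree(
        Individual(id=i, sire=s, dam=d,
                   sex=Sex.MALE if x == "m" else Sex.FEMALE, birth_year=y)
        for i, s, d, x, y in rows
    )


@pytest.fixture
def three_generation_pedigree() -> Pedigree:
    """Six founders, two F1 full-sib pairs from distinct crosses, one F2."""
    return make_pedigree([
        ("A", None, None, "m", 2000),
        ("B", None, None, "f", 2000),
        ("C", None, None, "m", 2000),
        ("D", None, None, "f", 2000),
        ("E", None, None, "m", 2000),
        ("F", None, None, "f", 2000),
        ("G", "A", "B", "m", 2001),
        ("H", "C", "D", "f", 2001),
        ("I", "G", "H", "f", 2002),
    ])


def random_pedigree(rng: np.random.Generator, n: int, founders: int) -> Pedigree:
    """Random valid pedigree: first ``founders`` individuals parentless,
    later ones take random earlier parents of the right sex (possibly
    unknown)."""
    rows = []
    sexes = []
    for k in range(n):
        sex = "m" if rng.random() < 0.5 else "f"
        # guarantee both sexes among founders
        if k == 0:
            sex = "m"
        if k == 1:
            sex = "f"
        sexes.append(sex)
        sire = dam = None
        if k >= founders:
            males = [j for j in range(k) if sexes[j] == "m"]
            females = [j for j in range(k) if sexes[j] == "f"]
            if males and rng.random() < 0.9:
                sire = f"P{rng.choice(males)}"
            if females and rng.random() < 0.9:
                dam = f"P{rng.choice(females)}"
        rows.append((f"P{k}", sire, dam, sexes[k], 2000 + k))
    return make_pedigree(rows)


def kinship_by_path_counting(ped: Pedigree, i: str, j: str) -> float:
    """Wright's path-counting coancestry, independent of the tabular
    recursion: sum over common ancestors A and over pairs of descent
    paths meeting only at A of (1/2)^(n_i + n_j + 1) * (1 + F_A)."""
    parents = {
        ind.id: [p for p in (ind.sire, ind.dam) if p is not None] for ind in ped
    }

    def ancestor_paths(x: str):
        """All ascending paths from x to each ancestor (x included)."""
        out = [(x,)]
        for p in parents[x]:
            out.extend(path + (x,) for path in ancestor_paths(p))
        return out

    def inbreeding(x: str) -> float:
        ps = parents[x]
        if len(ps) < 2:
            return 0.0
        return coancestry(ps[0], ps[1])

    def coancestry(i: str, j: str) -> float:
        if i == j:
            return 0.5 * (1.0 + inbreeding(i))
        total = 0.0
        paths_i = ancestor_paths(i)
        paths_j = ancestor_paths(j)
        for pi in paths_i:
            for pj in paths_j:
                if pi[0] != pj[0]:
                    continue  # different top ancestor
                # paths must share only the common ancestor
                if set(pi[1:]) & set(pj[1:]):
                    continue
                a = pi[0]
                n_i, n_j = len(pi) - 1, len(pj) - 1
                total += 0.5 ** (n_i + n_j + 1) * (1.0 + inbreeding(a))
        return total

    return coancestry(i, j)


def genotypes_from_pairs(pairs, loci=None, ids=None, pops=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an (n, L, 2) nested list."""
    arr = np.asarray(pairs, dtype=int)
    n, L, _ = arr.shape
    return GenotypeMatrix(
        ids=ids or [f"ind{k}" for k in range(n)],
        loci=loci or [f"L{l}" for l in range(L)],
        alleles=arr,
        pops=pops or ["pop1"] * n,
    )


def random_genotypes(
    rng: np.random.Generator, n: int, loci: int, alleles: int,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    arr = rng.integers(1, alleles + 1, size=(n, loci, 2))
    if missing_rate > 0:
        mask = rng.random((n, loci)) < missing_rate
        arr[mask] = 0
    return genotypes_from_pairs(arr)


def explicit_loop_r2(g, filt):
    """Independent oracle: per locus pair and allele pair, the squared
    Pearson correlation of allele dosages over pairwise-complete
    individuals, written with plain Python loops."""
    rows = {}
    for la, lb in itertools.combinations(range(g.n_loci), 2):
        na, nb = g.loci[la], g.loci[lb]
        if na not in filt.retained or nb not in filt.retained:
            continue
        complete = [
            k for k in range(g.n)
            if 0 not in g.alleles[k, la] and 0 not in g.alleles[k, lb]
        ]
        n = len(complete)
        if n < 2:
            continue
        r2s = []
        for a in sorted(filt.retained[na]):
            for b in sorted(filt.retained[nb]):
                x = [list(g.alleles[k, la]).count(a) for k in complete]
                y = [list(g.alleles[k, lb]).count(b) for k in complete]
                mx, my = sum(x) / n, sum(y) / n
                sxx = sum((v - mx) ** 2 for v in x)
                syy = sum((v - my) ** 2 for v in y)
                sxy = sum((u - mx) * (v - my) for u, v in zip(x, y))
                if sxx == 0 or syy == 0:
                    continue
                r2s.append(sxy**2 / (sxx * syy))
        if r2s:
            rows[(na, nb)] = (sum(r2s) / len(r2s), len(r2s), n)
    return rows
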