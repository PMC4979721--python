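"""Gene-dropping simulator of managed overlapping-generation populations.

The generator emulates the data structure of a small conserved
livestock herd rebuilt from a handful of founders: few founders (three
boars and three sows by default), litter-based reproduction over a
year-stepped life table with overlapping generations, a mating policy
that rejects pairs above a coancestry threshold, and multi-allelic
unlinked marker genotypes dropped down the pedigree by Mendelian
sampling.  Three modes are exposed:

* :func:`simulate_population` — overlapping generations driven by a
  two-sex life table; the demographic process matches the deterministic
  model of :mod:`ne_workbench.demography` when litters have size 1
  (each recruit draws parents independently, giving within-age Poisson
  offspring variance).
* :func:`simulate_discrete_ladder` — synchronized filial generations
  F1, F2, ... (every cohort is an exact F(k) x F(k) cross), the
  discrete-generation benchmark.
* :func:`simulate_wright_fisher` — the ideal population: constant N,
  discrete generations, random union of gametes (Ne = N), used as the
  parameter-recovery oracle for the molecular estimators.

All randomness flows from one seed; identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demography import LifeTable, SexSchedule
from .genepop import GenotypeMatrix, write_genepop
from .pedigree import (
    Individual,
    Pedigree,
    SamplingScheme,
    Sex,
    compute_kinship,
    group_cohorts,
)

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "default_life_table",
    "simulate_population",
    "simulate_discrete_ladder",
    "simulate_wright_fisher",
    "WrightFisherResult",
    "realized_ne",
    "realized_nb",
    "RealizedNe",
    "sample_and_export",
]


def default_life_table(n1: float = 1000.0) -> LifeTable:
    """Pig-like five-age-class schedule, identical for both sexes.

    Survival (0.8, 0.7, 0.6, 0.5, 0) caps parental age at 5 years;
    with birth rates (1.5, 1.2, 0.8, 0.5, 0.3) the generation interval
    is about 1.8 years, the value typical of managed pig herds.
    """
    sched = lambda: SexSchedule(  # noqa: E731
        s=np.array([0.8, 0.7, 0.6, 0.5, 0.0]),
        b=np.array([1.5, 1.2, 0.8, 0.5, 0.3]),
    )
    return LifeTable(male=sched(), female=sched(), n1=n1)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mimic the managed-herd scenario:
    six founders, 17 microsatellite-like loci with eight founder alleles
    each, yearly breeding with parents' age capped at five."""

    founders_per_sex: int = 3
    n_loci: int = 17
    alleles_per_locus: int = 8
    dirichlet_alpha: float = 1.0
    years: int = 9
    start_year: int = 2002
    cohort_size: int = 60
    litter_mean: float = 6.0
    max_coancestry: float = 1.0  # 1 = random mating, no restriction
    typing_fraction: float = 1.0
    life_table: LifeTable | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.founders_per_sex < 1:
            raise ValueError("need at least one founder per sex")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need >= 1 locus with >= 2 alleles")
        if not 0.0 < self.typing_fraction <= 1.0:
            raise ValueError("typing fraction must be in (0, 1]")
        if self.life_table is None:
            self.life_table = default_life_table(float(self.cohort_size))


@dataclass
class SimulatedPopulation:
    """Pedigree + genotypes + truth bundle from one simulation run."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    config: SimulationConfig
    cohorts: dict[int, list[str]]  # birth year -> ids
    eligible_breeders: dict[int, list[tuple[str, str]]]  # year -> (id, sex)
    census: dict[int, int]
    generation_length: float
    skipped_years: list[int] = field(default_factory=list)

    def cohort_matrix(self, year: int) -> GenotypeMatrix:
        return self.genotypes.subset(ids=self.cohorts[year])


class _Pop:
    """Mutable individual store shared by the simulator modes."""

    def __init__(self, n_loci: int):
        self.ids: list[str] = []
        self.sex: list[str] = []
        self.sire: list[str | None] = []
        self.dam: list[str | None] = []
        self.birth_year: list[int] = []
        self.age: list[int] = []
        self.alive: list[bool] = []
        self.geno: list[np.ndarray] = []
        self.n_loci = n_loci

    def add(self, sex, birth_year, age, geno, sire=None, dam=None) -> int:
        k = len(self.ids)
        self.ids.append(f"I{k + 1:05d}")
        self.sex.append(sex)
        self.sire.append(sire)
        self.dam.append(dam)
        self.birth_year.append(birth_year)
        self.age.append(age)
        self.alive.append(True)
        self.geno.append(geno)
        return k

    def living(self, sex: str | None = None) -> list[int]:
        return [
            k
            for k in range(len(self.ids))
            if self.alive[k]
            and self.age[k] >= 1
            and (sex is None or self.sex[k] == sex)
        ]

    def to_pedigree(self) -> Pedigree:
        return Pedigree(
            Individual(
                id=self.ids[k],
                sire=self.sire[k],
                dam=self.dam[k],
                sex=Sex.MALE if self.sex[k] == "m" else Sex.FEMALE,
                birth_year=self.birth_year[k],
            )
            for k in range(len(self.ids))
        )

    def to_genotypes(self, pop_labels: list[str]) -> GenotypeMatrix:
        return GenotypeMatrix(
            ids=list(self.ids),
            loci=[f"L{l + 1:03d}" for l in range(self.n_loci)],
            alleles=np.stack(self.geno),
            pops=pop_labels,
        )


def _founder_genotypes(rng, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Draw founder allele pairs from per-locus Dirichlet frequencies."""
    freqs = rng.dirichlet(
        np.full(cfg.alleles_per_locus, cfg.dirichlet_alpha), size=cfg.n_loci
    )
    out = np.zeros((n, cfg.n_loci, 2), dtype=int)
    for l in range(cfg.n_loci):
        out[:, l, :] = (
            rng.choice(cfg.alleles_per_locus, size=(n, 2), p=freqs[l]) + 1
        )
    return out


def _mendel(rng, geno_sire: np.ndarray, geno_dam: np.ndarray) -> np.ndarray:
    L = geno_sire.shape[0]
    pick_s = rng.integers(2, size=L)
    pick_d = rng.integers(2, size=L)
    child = np.empty((L, 2), dtype=int)
    child[:, 0] = geno_sire[np.arange(L), pick_s]
    child[:, 1] = geno_dam[np.arange(L), pick_d]
    return child


class SimulationError(RuntimeError):
    pass


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    """Year-stepped overlapping-generation simulation.

    Each year: eligible breeders are living adults whose age class has
    a positive birth rate; litters (Poisson-sized around
    ``litter_mean``, or single recruits when ``litter_mean <= 1``) are
    assigned a dam and a sire drawn with probability proportional to
    their age-class birth rates, rejecting sires whose pedigree
    coancestry with the dam exceeds ``max_coancestry``; exactly
    ``cohort_size`` recruits enter age 1 the next year (fecundity
    scaling of the stationary model); adults then survive their age-
    class rate and age one year.  Offspring genotypes are dropped
    Mendelianly from the recorded parents.
    """
    rng = np.random.default_rng(cfg.seed)
    lt = cfg.life_table
    pop = _Pop(cfg.n_loci)
    founders = 2 * cfg.founders_per_sex
    geno = _founder_genotypes(rng, cfg, founders)
    for k in range(founders):
        pop.add(
            sex="m" if k < cfg.founders_per_sex else "f",
            birth_year=cfg.start_year - 1,
            age=1,
            geno=geno[k],
        )

    cohorts: dict[int, list[str]] = {}
    eligible: dict[int, list[tuple[str, str]]] = {}
    census: dict[int, int] = {}
    skipped: list[int] = []

    for year in range(cfg.start_year, cfg.start_year + cfg.years):
        males = pop.living("m")
        females = pop.living("f")

        def _weights(idx, sched: SexSchedule):
            w = np.array(
                [
                    sched.b[pop.age[k] - 1] if pop.age[k] <= sched.max_age else 0.0
                    for k in idx
                ]
            )
            return w

        wm = _weights(males, lt.male)
        wf = _weights(females, lt.female)
        fert_m = [k for k, w in zip(males, wm) if w > 0]
        fert_f = [k for k, w in zip(females, wf) if w > 0]
        eligible[year] = [(pop.ids[k], pop.sex[k]) for k in fert_m + fert_f]
        if not fert_m or not fert_f:
            if not any(pop.alive):
                raise SimulationError(f"population extinct in {year}")
            skipped.append(year)
            census[year] = sum(pop.alive)
            _survive_and_age(rng, pop, lt)
            continue
        pm = wm[wm > 0] / wm[wm > 0].sum()
        pf = wf[wf > 0] / wf[wf > 0].sum()

        kin = None
        if cfg.max_coancestry < 1.0:
            kinres = compute_kinship(pop.to_pedigree())
            kin = kinres

        if cfg.litter_mean <= 1.0:
            litter_sizes = [1] * cfg.cohort_size
        else:
            n_litters = max(1, round(cfg.cohort_size / cfg.litter_mean))
            litter_sizes = []
            remaining = cfg.cohort_size
            for _ in range(n_litters - 1):
                size = min(int(rng.poisson(cfg.litter_mean)), remaining)
                litter_sizes.append(size)
                remaining -= size
            litter_sizes.append(remaining)
            litter_sizes = [s for s in litter_sizes if s > 0]

        born: list[int] = []
        for size in litter_sizes:
            pair = None
            for _ in range(50):
                dam = int(rng.choice(fert_f, p=pf))
                sire = int(rng.choice(fert_m, p=pm))
                if kin is None or kin.coancestry(
                    pop.ids[sire], pop.ids[dam]
                ) <= cfg.max_coancestry:
                    pair = (sire, dam)
                    break
            if pair is None:
                continue  # policy too strict for this draw; litter dropped
            sire, dam = pair
            for _ in range(size):
                child = _mendel(rng, pop.geno[sire], pop.geno[dam])
                born.append(
                    pop.add(
                        sex="m" if rng.random() < 0.5 else "f",
                        birth_year=year,
                        age=0,
                        geno=child,
                        sire=pop.ids[sire],
                        dam=pop.ids[dam],
                    )
                )
        if not born:
            skipped.append(year)
        cohorts[year] = [pop.ids[k] for k in born]
        census[year] = sum(pop.alive)
        _survive_and_age(rng, pop, lt)

    _, _, T = _generation_length(lt)
    labels = [
        "founder" if pop.birth_year[k] < cfg.start_year else str(pop.birth_year[k])
        for k in range(len(pop.ids))
    ]
    return SimulatedPopulation(
        pedigree=pop.to_pedigree(),
        genotypes=pop.to_genotypes(labels),
        config=cfg,
        cohorts=cohorts,
        eligible_breeders=eligible,
        census=census,
        generation_length=T,
        skipped_years=skipped,
    )


def _generation_length(lt: LifeTable) -> tuple[float, float, float]:
    def one(s: SexSchedule) -> float:
        l = s.survivorship
        rep = l * s.b
        ages = np.arange(1, s.max_age + 1)
        return float(np.sum(ages * rep) / rep.sum())

    tm, tf = one(lt.male), one(lt.female)
    return tm, tf, (tm + tf) / 2.0


def _survive_and_age(rng, pop: _Pop, lt: LifeTable) -> None:
    for k in range(len(pop.ids)):
        if not pop.alive[k]:
            continue
        age = pop.age[k]
        if age == 0:
            pop.age[k] = 1  # recruits always reach their first birthday
            continue
        sched = lt.male if pop.sex[k] == "m" else lt.female
        s = sched.s[age - 1] if age <= sched.max_age else 0.0
        if rng.random() < s:
            pop.age[k] = age + 1
        else:
            pop.alive[k] = False


def simulate_discrete_ladder(
    cfg: SimulationConfig, n_generations: int = 4
) -> SimulatedPopulation:
    """Synchronized filial generations: F(k) is produced only from
    F(k-1) x F(k-1) crosses, one generation per year.  The resulting
    pedigree classifies exactly into F1..F(n_generations)."""
    rng = np.random.default_rng(cfg.seed)
    pop = _Pop(cfg.n_loci)
    founders = 2 * cfg.founders_per_sex
    geno = _founder_genotypes(rng, cfg, founders)
    current: list[int] = []
    for k in range(founders):
        current.append(
            pop.add(
                sex="m" if k < cfg.founders_per_sex else "f",
                birth_year=cfg.start_year - 1,
                age=1,
                geno=geno[k],
            )
        )
    cohorts: dict[int, list[str]] = {}
    for g in range(1, n_generations + 1):
        year = cfg.start_year + g - 1
        males = [k for k in current if pop.sex[k] == "m"]
        females = [k for k in current if pop.sex[k] == "f"]
        if not males or not females:
            raise SimulationError(f"generation {g} lacks one sex")
        kin = compute_kinship(pop.to_pedigree()) if cfg.max_coancestry < 1 else None
        nxt: list[int] = []
        for _ in range(cfg.cohort_size):
            pair = None
            for _ in range(50):
                dam = int(rng.choice(females))
                sire = int(rng.choice(males))
                if kin is None or kin.coancestry(
                    pop.ids[sire], pop.ids[dam]
                ) <= cfg.max_coancestry:
                    pair = (sire, dam)
                    break
            if pair is None:
                continue
            sire, dam = pair
            child = _mendel(rng, pop.geno[sire], pop.geno[dam])
            nxt.append(
                pop.add(
                    sex="m" if rng.random() < 0.5 else "f",
                    birth_year=year,
                    age=1,
                    geno=child,
                    sire=pop.ids[sire],
                    dam=pop.ids[dam],
                )
            )
        if not nxt:
            raise SimulationError(f"generation {g} produced no offspring")
        cohorts[year] = [pop.ids[k] for k in nxt]
        current = nxt
    labels = [
        "founder" if pop.birth_year[k] < cfg.start_year else str(pop.birth_year[k])
        for k in range(len(pop.ids))
    ]
    return SimulatedPopulation(
        pedigree=pop.to_pedigree(),
        genotypes=pop.to_genotypes(labels),
        config=cfg,
        cohorts=cohorts,
        eligible_breeders={},
        census={y: len(c) for y, c in cohorts.items()},
        generation_length=1.0,
    )


@dataclass
class WrightFisherResult:
    """Ideal-population trajectory: per-generation genotypes and truth."""

    generations: list[np.ndarray]  # each (N, L, 2) allele codes
    loci: list[str]
    n: int

    def matrix(self, generation: int, label: str | None = None) -> GenotypeMatrix:
        g = self.generations[generation]
        return GenotypeMatrix(
            ids=[f"G{generation}_{k + 1:04d}" for k in range(self.n)],
            loci=list(self.loci),
            alleles=g,
            pops=[label or f"gen{generation}"] * self.n,
        )

    def drift_ne(self, start: int = 0, end: int | None = None) -> float:
        """Realized variance Ne from standardized per-generation
        allele-frequency change, pooled over loci and alleles."""
        end = len(self.generations) - 1 if end is None else end
        if end <= start:
            raise ValueError("need at least two generations")
        num = den = 0.0
        for t in range(start, end):
            x = _freq_array(self.generations[t])
            y = _freq_array(self.generations[t + 1])
            z = (x + y) / 2.0
            num += float(np.sum((x - y) ** 2))
            den += float(np.sum(z * (1.0 - z)))
        if num == 0.0:
            return math.inf
        return den / (2.0 * num) * 1.0  # F per gen = num/den; Ne = 1/(2F)


def _freq_array(geno: np.ndarray) -> np.ndarray:
    """(L, A) frequency table from an (N, L, 2) allele-code array."""
    n, L, _ = geno.shape
    amax = int(geno.max())
    out = np.zeros((L, amax))
    for l in range(L):
        codes, counts = np.unique(geno[:, l, :], return_counts=True)
        keep = codes > 0
        tot = counts[keep].sum()
        for c, k in zip(codes[keep], counts[keep]):
            out[l, c - 1] = k / tot
    return out


def simulate_wright_fisher(
    n: int,
    n_loci: int = 17,
    alleles_per_locus: int = 8,
    generations: int = 10,
    dirichlet_alpha: float = 1.0,
    seed: int | None = None,
) -> WrightFisherResult:
    """Constant-size ideal population: discrete generations, random
    union of gametes (selfing allowed), unlinked loci; Ne = N."""
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(alleles_per_locus, dirichlet_alpha), size=n_loci)
    geno = np.zeros((n, n_loci, 2), dtype=int)
    for l in range(n_loci):
        geno[:, l, :] = rng.choice(alleles_per_locus, size=(n, 2), p=freqs[l]) + 1
    out = [geno]
    for _ in range(generations):
        prev = out[-1]
        child = np.empty_like(prev)
        for parent_slot in range(2):
            parents = rng.integers(n, size=n)
            picks = rng.integers(2, size=(n, n_loci))
            child[:, :, parent_slot] = prev[
                parents[:, None], np.arange(n_loci)[None, :], picks
            ]
        out.append(child)
    return WrightFisherResult(
        generations=out,
        loci=[f"L{l + 1:03d}" for l in range(n_loci)],
        n=n,
    )


@dataclass
class RealizedNe:
    drift_ne: float | None
    inbreeding_ne: float | None
    per_year_rate: float | None
    generation_length: float
    flagged: bool = False
    reason: str = ""


def realized_ne(
    sim: SimulatedPopulation, window: tuple[int, int] | None = None
) -> RealizedNe:
    """Realized per-generation Ne truth from a simulation.

    Drift route: standardized squared change of newborn-cohort allele
    frequencies, regressed on the year span (the regression slope
    removes the cohort-level offset that mortality and parental overlap
    add to one-year comparisons), giving a per-year rate lambda;
    Ne = 1/(2 lambda T).  Inbreeding route: the rise of mean pedigree
    inbreeding between the first and last cohort converted to a
    per-generation rate.
    """
    years = sorted(y for y, c in sim.cohorts.items() if c)
    if window is not None:
        years = [y for y in years if window[0] <= y <= window[1]]
    if len(years) < 2:
        return RealizedNe(None, None, None, sim.generation_length, True,
                          "window shorter than 2 cohort years")
    freqs = {
        y: _freq_array_padded(sim, y)
        for y in years
    }
    spans: list[int] = []
    fvals: list[float] = []
    for i, y0 in enumerate(years):
        for y1 in years[i + 1:]:
            x, y = freqs[y0], freqs[y1]
            amax = max(x.shape[1], y.shape[1])
            x = np.pad(x, ((0, 0), (0, amax - x.shape[1])))
            y = np.pad(y, ((0, 0), (0, amax - y.shape[1])))
            z = (x + y) / 2.0
            den = float(np.sum(z * (1 - z)))
            if den == 0:
                continue
            spans.append(y1 - y0)
            fvals.append(float(np.sum((x - y) ** 2)) / den)
    if len(set(spans)) < 2:
        return RealizedNe(None, None, None, sim.generation_length, True,
                          "not enough distinct spans for the drift slope")
    slope = float(np.polyfit(spans, fvals, 1)[0])
    T = sim.generation_length
    drift = 1.0 / (2.0 * slope * T) if slope > 0 else math.inf

    kin = compute_kinship(sim.pedigree)
    f0 = float(np.mean([kin.inbreeding(i) for i in sim.cohorts[years[0]]]))
    f1 = float(np.mean([kin.inbreeding(i) for i in sim.cohorts[years[-1]]]))
    elapsed = years[-1] - years[0]
    if f1 > f0:
        rate_year = 1.0 - ((1.0 - f1) / (1.0 - f0)) ** (1.0 / elapsed)
        rate_gen = 1.0 - (1.0 - rate_year) ** T
        inb = 1.0 / (2.0 * rate_gen)
    else:
        inb = math.inf
    return RealizedNe(
        drift_ne=drift,
        inbreeding_ne=inb,
        per_year_rate=slope,
        generation_length=T,
    )


def _freq_array_padded(sim: SimulatedPopulation, year: int) -> np.ndarray:
    sub = sim.genotypes.subset(ids=sim.cohorts[year])
    return _freq_array(sub.alleles)


def realized_nb(
    sim: SimulatedPopulation, window: tuple[int, int] | None = None
) -> float:
    """Realized effective number of breeders per cohort.

    For each simulated year, the realized offspring-number mean and
    variance among that year's eligible breeders (zero counts included)
    enter the variance formula Nb = N k / (k - 1 + Vk / k) per sex,
    sexes combined as 4 Nbm Nbf / (Nbm + Nbf); the harmonic mean over
    years is returned (drift contributions add reciprocally).
    """
    years = [
        y for y, e in sim.eligible_breeders.items()
        if e and sim.cohorts.get(y)
        and (window is None or window[0] <= y <= window[1])
    ]
    if not years:
        raise ValueError("no breeding years in window")
    counts: dict[tuple[str, int], int] = {}
    for y in years:
        for iid in sim.cohorts[y]:
            ind = sim.pedigree[iid]
            counts[(ind.sire, y)] = counts.get((ind.sire, y), 0) + 1
            counts[(ind.dam, y)] = counts.get((ind.dam, y), 0) + 1
    inv = []
    for y in years:
        nb_sex = []
        for sex in ("m", "f"):
            k = np.array(
                [counts.get((iid, y), 0)
                 for iid, s in sim.eligible_breeders[y] if s == sex],
                dtype=float,
            )
            if k.size == 0 or k.mean() == 0:
                nb_sex = []
                break
            kbar = k.mean()
            vk = k.var()
            nb_sex.append(k.size * kbar / (kbar - 1.0 + vk / kbar))
        if len(nb_sex) == 2 and min(nb_sex) > 0:
            inv.append(1.0 / (4 * nb_sex[0] * nb_sex[1] / (nb_sex[0] + nb_sex[1])))
    if not inv:
        raise ValueError("no usable breeding years")
    return float(len(inv) / np.sum(inv))


def sample_and_export(
    sim: SimulatedPopulation,
    scheme: SamplingScheme,
    typing_fraction: float | None = None,
    seed: int | None = None,
    outdir=None,
) -> tuple[GenotypeMatrix, dict]:
    """Random within-cohort subsample (floor of fraction * cohort size,
    without replacement), exported as one GenePop Pop block per cohort
    with a companion pedigree CSV and a count manifest."""
    frac = sim.config.typing_fraction if typing_fraction is None else typing_fraction
    if not 0.0 < frac <= 1.0:
        raise ValueError("typing fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    cohorts = group_cohorts(sim.pedigree, scheme)
    ids: list[str] = []
    pops: list[str] = []
    manifest: dict[str, dict] = {}
    for label, members in cohorts.items():
        k = max(1, int(math.floor(frac * len(members)))) if members else 0
        if k == 0:
            continue
        chosen = sorted(
            rng.choice(len(members), size=k, replace=False).tolist()
        )
        picked = [members[i] for i in chosen]
        ids.extend(picked)
        pops.extend([str(label)] * k)
        manifest[str(label)] = {"registered": len(members), "typed": k}
    sub = sim.genotypes.subset(ids=ids)
    order = {iid: k for k, iid in enumerate(ids)}
    perm = sorted(range(len(sub.ids)), key=lambda k: order[sub.ids[k]])
    sub = GenotypeMatrix(
        ids=[sub.ids[k] for k in perm],
        loci=sub.loci,
        alleles=sub.alleles[perm],
        pops=[pops[order[sub.ids[k]]] for k in perm],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(sub, outdir / "genotypes.gen")
        sim.pedigree.to_frame().to_csv(outdir / "pedigree.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return sub, manifest
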