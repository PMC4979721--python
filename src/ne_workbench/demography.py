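"""Life-table models for demographic bias correction of Ne estimates.

Overlapping generations bias molecular Ne estimators in two distinct
ways, each with its own life-table correction:

* Single-cohort LD estimates measure the effective number of breeders
  Nb that produced the cohort rather than the per-generation Ne.  A
  discrete-time, age-structured, deterministic model turns age-specific
  survival rates s_x and birth rates b_x (per sex) into the ratio
  Nb/Ne; cohort LD estimates are rescaled by that ratio.

* Temporal (two-sample) estimates from cohorts a few years apart see
  extra variance from cohort mortality and from the genetic covariance
  among cohorts that share parents.  The Jorde-Ryman factor C converts
  the per-year drift estimate to a per-generation one via the ratio
  C/G, with G the generation interval.

The model assumes yearly reproduction, survival and fecundity
independent of past events, no upper bound on offspring per breeding
cycle (within-age Poisson variance), and that every cohort member
survives to its first birthday, with fecundities rescaled to a
stationary population producing N1 age-1 recruits per cohort.

Per-generation effective size follows Hill's result for age-structured
populations, Ne = 4 N1 T / (Vk + 2), where T is the generation length
and Vk the variance of lifetime offspring number among the N1 cohort
members; the seasonal Nb applies the analogous variance formula to the
parents of a single cohort, sexes combined as 4 Nbm Nbf/(Nbm + Nbf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "DemographicSummary",
    "load_life_table",
    "agene_nb_ne",
    "factor_c",
    "adjust_ld",
    "adjust_temporal",
    "expected_r2",
]


@dataclass
class SexSchedule:
    """One sex's vital rates over age classes 1..max_age.

    ``s[x-1]`` is the probability of surviving from age x to x+1;
    ``b[x-1]`` the mean number of offspring produced at age x.
    """

    s: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.s.shape != self.b.shape:
            raise ValueError("survival and birth-rate vectors differ in length")
        if np.any((self.s < 0) | (self.s > 1)):
            raise ValueError("survival rates must lie in [0, 1]")
        if np.any(self.b < 0):
            raise ValueError("birth rates must be non-negative")

    @property
    def max_age(self) -> int:
        return len(self.s)

    @property
    def survivorship(self) -> np.ndarray:
        """Cumulative survivorship l_x to each age class (l_1 = 1)."""
        return np.concatenate([[1.0], np.cumprod(self.s[:-1])])

    def scaled(self, lifetime_total: float = 2.0) -> "SexSchedule":
        """Rescale fecundities so sum l_x b_x = ``lifetime_total``.

        2.0 is the stationary two-sex value: each sex parents every
        member of the next cohort once.
        """
        l = self.survivorship
        total = float(np.sum(l * self.b))
        if total <= 0:
            raise ValueError("no reproduction: sum l_x b_x = 0")
        return SexSchedule(s=self.s.copy(), b=self.b * (lifetime_total / total))


@dataclass
class LifeTable:
    """Age x sex vital rates plus the recruit cohort size N1."""

    male: SexSchedule
    female: SexSchedule
    n1: float = 1000.0

    def __post_init__(self):
        if self.male.max_age != self.female.max_age:
            raise ValueError("sexes must share the same age classes")
        if self.n1 <= 0:
            raise ValueError("N1 must be positive")

    @property
    def max_age(self) -> int:
        return self.male.max_age

    def sex_averaged(self) -> SexSchedule:
        """Mean schedule across sexes (used by the factor-C model,
        which takes a single combined life table)."""
        return SexSchedule(
            s=(self.male.s + self.female.s) / 2.0,
            b=(self.male.b + self.female.b) / 2.0,
        )


def load_life_table(path, n1: float = 1000.0) -> LifeTable:
    """Read a life-table TSV with columns ``sex, age, s_x, b_x``."""
    df = pd.read_csv(path, sep="\t")
    required = {"sex", "age", "s_x", "b_x"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"life table missing column(s): {sorted(missing)}")
    schedules = {}
    for sex, grp in df.groupby(df["sex"].str.lower().str[0]):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if not np.array_equal(ages, np.arange(1, len(ages) + 1)):
            raise ValueError(f"age classes for sex {sex!r} must be 1..max_age")
        schedules[sex] = SexSchedule(
            s=grp["s_x"].to_numpy(float), b=grp["b_x"].to_numpy(float)
        )
    if set(schedules) != {"m", "f"}:
        raise ValueError("life table must contain both sexes (m/f)")
    return LifeTable(male=schedules["m"], female=schedules["f"], n1=n1)


@dataclass
class DemographicSummary:
    ne_dem: float
    nb_dem: float
    generation_length: float
    factor_c_value: float | None = None
    model_g: float | None = None
    rescaled: bool = False
    per_sex: dict = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        """Nb/Ne; < 1 when cohorts are produced by fewer effective
        parents than a full generation."""
        return self.nb_dem / self.ne_dem


def _lifetime_moments(sched: SexSchedule) -> tuple[float, float, float]:
    """(mean, variance, generation length) of lifetime offspring number
    for one newborn, under within-age Poisson variance and
    independence of survival and fecundity across ages."""
    l = sched.survivorship
    b = sched.b
    mean = float(np.sum(l * b))
    ages = np.arange(1, sched.max_age + 1)
    T = float(np.sum(ages * l * b) / mean)
    # Var = sum_x [l_x b_x + l_x b_x^2 - (l_x b_x)^2]
    #     + 2 sum_{x<y} b_x b_y l_y (1 - l_x)
    var = float(np.sum(l * b + l * b**2 - (l * b) ** 2))
    for x in range(sched.max_age):
        for y in range(x + 1, sched.max_age):
            var += 2.0 * b[x] * b[y] * l[y] * (1.0 - l[x])
    return mean, var, T


def _seasonal_nb(sched: SexSchedule, n1_sex: float) -> float:
    """Effective number of breeders of one sex for a single cohort.

    Breeders are the individuals in age classes with b_x > 0; their
    offspring-number mean and variance (within-age Poisson + between-
    age heterogeneity) feed the variance formula
    Nb = N k / (k - 1 + Vk / k).
    """
    l = sched.survivorship
    active = sched.b > 0
    N_x = n1_sex * l[active]
    b_x = sched.b[active]
    N_total = float(np.sum(N_x))
    kbar = float(np.sum(N_x * b_x) / N_total)
    second = float(np.sum(N_x * (b_x + b_x**2)) / N_total)
    vk = second - kbar**2
    return N_total * kbar / (kbar - 1.0 + vk / kbar)


def agene_nb_ne(lt: LifeTable, rescale: bool = True) -> DemographicSummary:
    """Per-generation Ne, single-cohort Nb and their ratio from a
    two-sex life table.

    Fecundities are rescaled to stationarity (sum l_x b_x = 2 per sex)
    unless already stationary; ``rescaled`` records whether this
    happened.  The ratio Nb/Ne is invariant to the recruit cohort size
    N1.  A semelparous table collapses to the discrete-generation limit
    Nb = Ne = N1, ratio 1.
    """
    summaries = {}
    rescaled = False
    n1_sex = lt.n1 / 2.0
    vks, Ts, nbs = [], [], []
    for name, sched in (("male", lt.male), ("female", lt.female)):
        scaled = sched.scaled(2.0)
        if not np.allclose(scaled.b, sched.b, rtol=1e-9, atol=1e-12):
            rescaled = True
        mean, var, T = _lifetime_moments(scaled)
        nb = _seasonal_nb(scaled, n1_sex)
        summaries[name] = {"mean_k": mean, "var_k": var, "T": T, "nb": nb}
        vks.append(var)
        Ts.append(T)
        nbs.append(nb)
    vk_combined = float(np.mean(vks))  # equal sex ratio, equal means
    T = float(np.mean(Ts))
    ne = 4.0 * lt.n1 * T / (vk_combined + 2.0)
    nb = 4.0 * nbs[0] * nbs[1] / (nbs[0] + nbs[1])
    return DemographicSummary(
        ne_dem=ne,
        nb_dem=nb,
        generation_length=T,
        rescaled=rescaled,
        per_sex=summaries,
    )


def factor_c(
    lt: LifeTable | SexSchedule, years: int = 400
) -> tuple[float, float]:
    """Jorde-Ryman correction factor C and model generation interval G.

    C is the ratio between the standardized allele-frequency variance
    observed between two *consecutive* cohorts and the long-term
    per-year drift accumulation; multiplying a raw per-year temporal
    estimate by C/G converts it to a per-generation Ne.

    Computed by propagating the standardized variance/covariance matrix
    of age-class cohort allele frequencies to its stationary increments:
    reproduction draws 2 N1 gene copies binomially from parental age
    classes weighted by l_i b_i, survival thins each cohort
    hypergeometrically from N1 l_i to N1 l_{i+1} individuals.  Both
    noise sources scale as 1/N1, so C is size-free.  A semelparous
    schedule gives C = G = 1 exactly.
    """
    sched = lt.sex_averaged() if isinstance(lt, LifeTable) else lt
    n1 = lt.n1 if isinstance(lt, LifeTable) else 1000.0
    l = sched.survivorship
    b = sched.b
    alive = l > 0  # trim age classes nobody reaches
    if not alive.all():
        last = int(np.max(np.nonzero(alive)[0])) + 1
        l, b = l[:last], b[:last]
        sched = SexSchedule(s=sched.s[:last], b=b)
    rep = l * b
    total = rep.sum()
    if total <= 0:
        raise ValueError("no reproduction: sum l_i b_i = 0")
    w = rep / total
    ages = np.arange(1, sched.max_age + 1)
    G = float(np.sum(ages * rep) / total)

    A = sched.max_age
    genes = 2.0 * n1 * l  # gene copies per age class
    V = np.zeros((A, A))  # standardized covariances, index = age-1
    prev_vnn = None
    f_year = math.nan
    lam = math.nan
    for step in range(years):
        c_new = V @ w  # cov(newborn, cohort currently aged i+1)
        v_nn = 1.0 / (2.0 * n1) + float(w @ V @ w)
        if prev_vnn is not None:
            # the age-1 cohort at this step is last year's newborns
            f_year = v_nn + prev_vnn - 2.0 * c_new[0]
            lam = v_nn - prev_vnn
        # survival thinning while aging i -> i+1 (oldest class dies)
        shifted = np.zeros_like(V)
        shifted[1:, 1:] = V[:-1, :-1]
        for i in range(A - 1):
            shifted[i + 1, i + 1] += 1.0 / genes[i + 1] - 1.0 / genes[i]
        shifted[0, 0] = v_nn
        shifted[0, 1:] = c_new[:-1]
        shifted[1:, 0] = c_new[:-1]
        V = shifted
        prev_vnn = v_nn
    if not math.isfinite(f_year) or lam <= 0:
        raise ValueError("factor-C recursion did not stabilize")
    return f_year / lam, G


def _apply(value: float, factor: float) -> float:
    if math.isinf(value):
        return math.inf
    return value * factor


def adjust_ld(ne_ld: float, ratio: float, divide: bool = False) -> float:
    """Rescale a cohort LD estimate by the demographic ratio Nb/Ne.

    The default multiplies (an LD estimate from a single cohort tracks
    Nb, which is ratio * Ne, so the per-generation scale is recovered
    by multiplying the overestimated cohort value by the ratio);
    ``divide=True`` applies the reciprocal instead.  Infinite estimates
    propagate unchanged.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return _apply(ne_ld, (1.0 / ratio) if divide else ratio)


def adjust_temporal(ne_jr: float, c: float, g: float) -> float:
    """Rescale a per-year temporal estimate to per-generation Ne by C/G."""
    if c <= 0 or g <= 0:
        raise ValueError("C and G must be positive")
    return _apply(ne_jr, c / g)


def expected_r2(ne: float, nb: float) -> float:
    """Expected squared allele correlation under neutrality and constant
    size: r^2 = 1/(3H) with H the harmonic mean of Ne and Nb."""
    if ne <= 0 or nb <= 0:
        raise ValueError("Ne and Nb must be positive")
    h = 2.0 / (1.0 / ne + 1.0 / nb)
    return 1.0 / (3.0 * h)
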