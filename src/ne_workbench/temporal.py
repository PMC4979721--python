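"""Two-sample (temporal) effective size via the Jorde-Ryman Fs.

Allele-frequency change between two samples of the same population
taken some years apart reflects drift plus sampling noise.  Per locus,
with x_i and y_i the frequencies of allele i in the first and second
sample and z_i = (x_i + y_i)/2,

    Fs = [sum_i (x_i - y_i)^2] / [sum_i z_i (1 - z_i)]

pooled over loci as the ratio of summed numerators to summed
denominators (not the mean of per-locus ratios).  Under sampling plan
I — individuals sampled non-destructively and returned, census N at
first sampling — the bias-corrected statistic is

    Fs' = [Fs (1 - 1/(4 nt)) - 1/nt + 1/N] / [(1 + Fs/4)(1 - 1/(2 ny))]

with nt the harmonic mean of the two sample sizes and ny the second
sample's size, and the raw effective size accumulates one unit of
drift per elapsed year:

    Ne_raw = elapsed_years / (2 Fs')

Under overlapping generations Ne_raw is a per-year quantity and must be
rescaled by the life-table factor C/G (see
:mod:`ne_workbench.demography`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genepop import AlleleFrequencies, GenotypeMatrix, allele_frequencies

__all__ = ["TemporalNeEstimate", "fs_statistic", "ne_jr", "temporal_ne"]


@dataclass
class FsResult:
    fs: float
    numerators: dict[str, float]
    denominators: dict[str, float]
    degenerate: bool = False

    def pooled(self, exclude_locus: str | None = None) -> float:
        num = sum(v for k, v in self.numerators.items() if k != exclude_locus)
        den = sum(v for k, v in self.denominators.items() if k != exclude_locus)
        if den == 0:
            return math.nan
        return num / den


@dataclass
class TemporalNeEstimate:
    fs: float
    fs_prime: float
    n_x: float
    n_y: float
    harmonic_n: float
    census: float
    elapsed_years: float
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    adjusted: float | None = None
    infinite: bool = False
    cohorts: tuple[str, str] | None = None


def fs_statistic(
    freqs_x: AlleleFrequencies,
    freqs_y: AlleleFrequencies,
    halved_denominator: bool = False,
) -> FsResult:
    """Pooled Fs over the loci shared by two frequency tables.

    Allele sets are unioned per locus (an allele absent from one sample
    has frequency 0 there).  Loci fixed for the same allele in both
    samples contribute 0/0 and are skipped.  ``halved_denominator``
    switches to the sum of z_i(1-z_i)/2 variant.
    """
    shared = [l for l in freqs_x.loci if l in freqs_y.loci]
    if not shared:
        raise ValueError("no shared loci between the two samples")
    nums: dict[str, float] = {}
    dens: dict[str, float] = {}
    for name in shared:
        fx, fy = freqs_x[name].freqs, freqs_y[name].freqs
        alleles = sorted(set(fx) | set(fy))
        x = np.array([fx.get(a, 0.0) for a in alleles])
        y = np.array([fy.get(a, 0.0) for a in alleles])
        z = (x + y) / 2.0
        num = float(np.sum((x - y) ** 2))
        den = float(np.sum(z * (1.0 - z)))
        if halved_denominator:
            den /= 2.0
        if den == 0.0:
            continue  # fixed identically in both samples
        nums[name] = num
        dens[name] = den
    if not dens:
        return FsResult(fs=0.0, numerators={}, denominators={}, degenerate=True)
    total_den = sum(dens.values())
    return FsResult(
        fs=sum(nums.values()) / total_den, numerators=nums, denominators=dens
    )


def _fs_prime(fs: float, n_harm: float, n_y: float, census: float) -> float:
    num = fs * (1.0 - 1.0 / (4.0 * n_harm)) - 1.0 / n_harm + 1.0 / census
    den = (1.0 + fs / 4.0) * (1.0 - 1.0 / (2.0 * n_y))
    return num / den


def ne_jr(
    fs_result: FsResult,
    n_x: float,
    n_y: float,
    census: float,
    elapsed_years: float,
) -> TemporalNeEstimate:
    """Plan-I Jorde-Ryman effective size from a pooled Fs.

    ``census`` is the population size at the time of first sampling
    (plan I returns sampled individuals, so the sample is part of it).
    Fs' at or below zero means the observed change is within pure
    sampling expectation: the estimate is flagged infinite.  The 95% CI
    is a delete-one-locus jackknife formed on the Fs scale and mapped
    through the inversion.
    """
    if census < max(n_x, n_y):
        raise ValueError("census must be at least the larger sample size")
    if elapsed_years < 1:
        raise ValueError("elapsed_years must be >= 1")
    n_harm = 2.0 / (1.0 / n_x + 1.0 / n_y)
    fsp = _fs_prime(fs_result.fs, n_harm, n_y, census)

    def invert(fp: float) -> float:
        if fp <= 0:
            return math.inf
        return elapsed_years / (2.0 * fp)

    point = invert(fsp)

    bounds = None
    loci = list(fs_result.denominators)
    if len(loci) >= 3:
        theta = np.array([fs_result.pooled(exclude_locus=l) for l in loci])
        L = theta.size
        var = (L - 1) / L * np.sum((theta - theta.mean()) ** 2)
        half = 1.96 * math.sqrt(var)
        lo_fs, hi_fs = fs_result.fs - half, fs_result.fs + half
        ne_hi = invert(_fs_prime(lo_fs, n_harm, n_y, census))
        ne_lo = invert(_fs_prime(hi_fs, n_harm, n_y, census))
        bounds = (min(ne_lo, ne_hi), max(ne_lo, ne_hi))

    return TemporalNeEstimate(
        fs=fs_result.fs,
        fs_prime=fsp,
        n_x=n_x,
        n_y=n_y,
        harmonic_n=n_harm,
        census=census,
        elapsed_years=elapsed_years,
        point=point,
        ci_low=bounds[0] if bounds else None,
        ci_high=bounds[1] if bounds else None,
        infinite=math.isinf(point),
    )


def temporal_ne(
    g_x: GenotypeMatrix,
    g_y: GenotypeMatrix,
    census: float,
    elapsed_years: float,
    halved_denominator: bool = False,
) -> TemporalNeEstimate:
    """Convenience wrapper: frequencies, Fs and plan-I Ne from two
    genotype samples of the same loci."""
    fs = fs_statistic(
        allele_frequencies(g_x),
        allele_frequencies(g_y),
        halved_denominator=halved_denominator,
    )
    return ne_jr(fs, n_x=g_x.n, n_y=g_y.n, census=census,
                 elapsed_years=elapsed_years)
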