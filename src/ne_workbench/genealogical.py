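"""Pedigree-based effective size from individual increases in
inbreeding and pairwise increases in coancestry.

The individual increase in inbreeding standardizes an individual's
inbreeding coefficient F by its pedigree depth t (equivalent complete
generations):

    dF_i = 1 - (1 - F_i)^(1/(t_i - 1))

The t - 1 exponent accounts for the absence of self-fertilization: in a
dioecious population inbreeding can first appear two generations after
the base.  The analogous pairwise quantity uses the coancestry C_ij of
a pair and the mean of their depths:

    dC_ij = 1 - (1 - C_ij)^(2/(t_i + t_j))

Effective sizes follow as Ne_Fi = 1/(2*mean(dF)) and
Ne_Cij = 1/(2*mean(dC)); their ratio is a diagnostic for hidden
population structure (ratio > 1 suggests subdivision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, compute_kinship, equivalent_generations

__all__ = [
    "GenealogicalNeEstimate",
    "delta_F_individual",
    "delta_C_pairwise",
    "ne_from_mean_delta",
    "genealogical_ne",
]


def delta_F_individual(F: float, t: float) -> float:
    """Depth-standardized per-generation inbreeding rate of one individual.

    Undefined for t <= 1 (raises ValueError); callers exclude such
    individuals (founders, F1) from averaging.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"inbreeding coefficient out of range: {F}")
    if t <= 1.0:
        raise ValueError(f"equivalent generations t={t} <= 1: dF undefined")
    return 1.0 - (1.0 - F) ** (1.0 / (t - 1.0))


def delta_C_pairwise(C: float, t_i: float, t_j: float) -> float:
    """Per-generation increase in coancestry for one unordered pair."""
    if not 0.0 <= C < 1.0:
        raise ValueError(f"coancestry out of range: {C}")
    if t_i + t_j <= 0.0:
        raise ValueError("t_i + t_j must be positive")
    return 1.0 - (1.0 - C) ** (2.0 / (t_i + t_j))


def ne_from_mean_delta(mean_delta: float) -> float:
    """Ne = 1/(2 * mean increase); infinite when the mean is zero."""
    if mean_delta < 0:
        raise ValueError("mean increase must be non-negative")
    if mean_delta == 0:
        return math.inf
    return 1.0 / (2.0 * mean_delta)


@dataclass
class GenealogicalNeEstimate:
    """Genealogical effective sizes for one reference subpopulation.

    SEs of the Ne values propagate the dispersion of the individual
    (or pairwise) increases through Ne = 1/(2*mean) by the first-order
    delta method: SE(Ne) = SD(delta) / (2 * mean^2 * sqrt(n)).
    """

    cohort: str
    n_individuals: int
    mean_F: float
    mean_t: float
    mean_delta_F: float
    sd_delta_F: float
    ne_fi: float
    se_ne_fi: float
    mean_delta_C: float
    sd_delta_C: float
    ne_cij: float
    se_ne_cij: float
    n_excluded: int = 0

    @property
    def ratio(self) -> float:
        """Structure diagnostic Ne_Cij / Ne_Fi (1 = no hidden structure)."""
        if math.isinf(self.ne_fi):
            return math.nan
        return self.ne_cij / self.ne_fi


def _delta_se(deltas: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas, ddof=1)) if deltas.size > 1 else 0.0
    ne = ne_from_mean_delta(mean)
    se = (
        sd / (2.0 * mean**2 * math.sqrt(deltas.size))
        if mean > 0 and deltas.size > 0
        else 0.0
    )
    return mean, sd, ne, se


def genealogical_ne(
    ped: Pedigree,
    ids: list[str] | None = None,
    cohort: str = "all",
    kinship=None,
    equiv_gen: dict[str, float] | None = None,
) -> GenealogicalNeEstimate:
    """Genealogical Ne for a reference subset of a pedigree.

    Kinship and depth are computed on the *whole* pedigree (ancestry
    outside the subset counts); averaging is over the subset.
    Individuals with t <= 1 are excluded from the dF average (the rate
    is undefined at that depth) and counted in ``n_excluded``; pairs
    are all unordered pairs within the subset, self-pairs excluded.
    """
    if ids is None:
        ids = ped.ids
    ids = ped.subset_ids(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    kin = kinship if kinship is not None else compute_kinship(ped)
    t = equiv_gen if equiv_gen is not None else equivalent_generations(ped)

    F = np.array([kin.inbreeding(i) for i in ids])
    tv = np.array([t[i] for i in ids])

    usable = tv > 1.0
    deltas_F = np.array(
        [delta_F_individual(f, ti) for f, ti in zip(F[usable], tv[usable])]
    )
    if deltas_F.size == 0:
        raise ValueError("no individual has t > 1: dF undefined for all")
    mF, sdF, neF, seF = _delta_se(deltas_F)

    Csub = kin.submatrix(ids)
    iu = np.triu_indices(len(ids), k=1)
    pair_C = Csub[iu]
    pair_t = (tv[iu[0]] + tv[iu[1]]) / 2.0
    ok = pair_t > 0
    deltas_C = 1.0 - (1.0 - pair_C[ok]) ** (1.0 / pair_t[ok])
    mC, sdC, neC, seC = _delta_se(deltas_C)

    return GenealogicalNeEstimate(
        cohort=cohort,
        n_individuals=len(ids),
        mean_F=float(np.mean(F)),
        mean_t=float(np.mean(tv)),
        mean_delta_F=mF,
        sd_delta_F=sdF,
        ne_fi=neF,
        se_ne_fi=seF,
        mean_delta_C=mC,
        sd_delta_C=sdC,
        ne_cij=neC,
        se_ne_cij=seC,
        n_excluded=int(np.sum(~usable)),
    )
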