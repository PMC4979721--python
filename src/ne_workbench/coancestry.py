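"""Single-sample effective size from molecular coancestry (Nomura).

The molecular coancestry of individuals i and j at locus l is the
probability that two alleles drawn one from each are identical in
state: with genotypes (a, b) and (c, d),

    f_ij,l = (I_ac + I_ad + I_bc + I_bd) / 4.

Identity in state overstates identity by descent, so each pair-locus
term is corrected by the locus's expected homozygosity s_l = sum p_i^2
(the chance of alike-by-state identity in the base):

    f'_ij,l = (f_ij,l - s_l) / (1 - s_l)

and loci are weighted by w_l = (1 - s_l)^2 / [s_l (1 - s_l)], which
up-weights polymorphic loci with balanced frequencies.  The estimator
averages the weighted corrected coancestry over the n(n-1)/2 pairs
(self-coancestries excluded) and inverts it:

    Ne(M) = 1 / (2 * fhat)

Unlike the LD method, this uses alleles at any frequency (no Pcrit).
Excluding self-coancestries is what separates Ne(M) from the founder
genome equivalents Ng = 1/(2f) of the full coancestry mean; fhat < f,
hence Ne(M) > Ng on the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genepop import AlleleFrequencies, GenotypeMatrix, allele_frequencies

__all__ = [
    "MolecularCoancestryEstimate",
    "pair_locus_coancestry",
    "locus_weights",
    "ne_m_from_fhat",
    "ne_m_estimate",
    "founder_genome_equivalents",
]


def pair_locus_coancestry(genotype_i, genotype_j) -> float:
    """Identity-in-state coancestry of two genotypes at one locus."""
    a, b = genotype_i
    c, d = genotype_j
    if 0 in (a, b, c, d):
        raise ValueError("missing genotype: pair-locus term undefined")
    return (int(a == c) + int(a == d) + int(b == c) + int(b == d)) / 4.0


def locus_weights(s: np.ndarray) -> np.ndarray:
    """Nomura locus weights w_l = (1 - s_l)^2 / [s_l (1 - s_l)].

    Monomorphic loci (s_l = 1) get weight 0 and drop out.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("expected homozygosity must lie in (0, 1]")
    w = np.zeros_like(s)
    poly = s < 1.0
    w[poly] = (1.0 - s[poly]) ** 2 / (s[poly] * (1.0 - s[poly]))
    return w


def ne_m_from_fhat(fhat: float) -> float:
    """Ne(M) = 1/(2 fhat); infinite when fhat <= 0 (the alike-by-state
    correction can push the mean negative in samples of unrelated
    individuals)."""
    if fhat <= 0:
        return math.inf
    return 1.0 / (2.0 * fhat)


@dataclass
class MolecularCoancestryEstimate:
    fhat: float
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_pairs: int = 0
    n_loci: int = 0
    weights: dict[str, float] = field(default_factory=dict)
    infinite: bool = False

    @property
    def W(self) -> float:
        return float(sum(self.weights.values()))


def _locus_f_matrices(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus pairwise identity matrices.

    Returns (f, typed): f is (L, n, n) molecular coancestry per locus,
    typed is (L, n) presence mask; entries of f where either member is
    untyped are 0 and must be masked by the caller.
    """
    n, L = g.n, g.n_loci
    f = np.zeros((L, n, n))
    typed = ~g.missing_mask().T  # (L, n)
    for l in range(L):
        al = g.alleles[:, l, :]  # (n, 2)
        acc = np.zeros((n, n))
        for u in range(2):
            for v in range(2):
                acc += al[:, u][:, None] == al[:, v][None, :]
        f[l] = acc / 4.0
    return f, typed


def ne_m_estimate(
    g: GenotypeMatrix,
    ci: bool = True,
    base_frequencies: AlleleFrequencies | None = None,
) -> MolecularCoancestryEstimate:
    """Nomura molecular-coancestry Ne for one sample.

    Pairs are all n(n-1)/2 unordered pairs; each pair averages its
    corrected terms over the loci at which both members are typed,
    weighted by w_l.  Pairs sharing no typed locus are dropped.  The
    95% CI comes from a delete-one-locus jackknife on the fhat scale.

    ``base_frequencies`` supplies the reference allele frequencies that
    define the alike-by-state expectation s_l.  By default the sample's
    own frequencies are used; note that this centres the corrected
    coancestry close to zero by construction (the ordered-pair mean of
    raw coancestry equals the sample's expected homozygosity exactly),
    so absolute effective-size readings are only meaningful against an
    external base such as a founder sample.
    """
    if g.n < 2:
        raise ValueError("need at least 2 individuals")
    freqs = base_frequencies if base_frequencies is not None else allele_frequencies(g)
    names = [l for l in g.loci if l in freqs.loci]
    s = np.array([freqs[l].expected_homozygosity for l in names])
    w = locus_weights(s)
    poly = w > 0
    if not poly.any():
        raise ValueError("no polymorphic locus")

    keep_idx = [g.loci.index(l) for l, p in zip(names, poly) if p]
    names = [l for l, p in zip(names, poly) if p]
    s = s[poly]
    w = w[poly]

    f_all, typed_all = _locus_f_matrices(g)
    f = f_all[keep_idx]
    typed = typed_all[keep_idx]

    corrected = (f - s[:, None, None]) / (1.0 - s)[:, None, None]
    pair_typed = typed[:, :, None] & typed[:, None, :]  # (L, n, n)

    iu = np.triu_indices(g.n, k=1)

    def fhat_over_pairs(mask: np.ndarray) -> float:
        wl = w[mask][:, None]
        num = np.sum(wl * (corrected[mask][:, iu[0], iu[1]]
                           * pair_typed[mask][:, iu[0], iu[1]]), axis=0)
        den = np.sum(wl * pair_typed[mask][:, iu[0], iu[1]], axis=0)
        ok = den > 0
        if not ok.any():
            return math.nan
        return float(np.mean(num[ok] / den[ok]))

    full_mask = np.ones(len(names), dtype=bool)
    fhat = fhat_over_pairs(full_mask)
    point = ne_m_from_fhat(fhat)

    bounds = None
    if ci and len(names) >= 3:
        theta = []
        for k in range(len(names)):
            m = full_mask.copy()
            m[k] = False
            theta.append(fhat_over_pairs(m))
        theta = np.array(theta)
        L = theta.size
        var = (L - 1) / L * np.sum((theta - theta.mean()) ** 2)
        half = 1.96 * math.sqrt(var)
        ne_hi = ne_m_from_fhat(fhat - half)
        ne_lo = ne_m_from_fhat(fhat + half)
        bounds = (min(ne_lo, ne_hi), max(ne_lo, ne_hi))

    return MolecularCoancestryEstimate(
        fhat=fhat,
        point=point,
        ci_low=bounds[0] if bounds else None,
        ci_high=bounds[1] if bounds else None,
        n_pairs=g.n * (g.n - 1) // 2,
        n_loci=len(names),
        weights={l: float(x) for l, x in zip(names, w)},
        infinite=math.isinf(point),
    )


def pairwise_molecular_coancestry(
    g: GenotypeMatrix,
    base_frequencies: AlleleFrequencies | None = None,
) -> np.ndarray:
    """(n, n) matrix of weighted, alike-by-state-corrected molecular
    coancestries (the per-pair terms averaged by :func:`ne_m_estimate`);
    diagonal holds self-coancestries on the same corrected scale."""
    freqs = base_frequencies if base_frequencies is not None else allele_frequencies(g)
    names = [l for l in g.loci if l in freqs.loci]
    s = np.array([freqs[l].expected_homozygosity for l in names])
    w = locus_weights(s)
    poly = w > 0
    keep_idx = [g.loci.index(l) for l, p in zip(names, poly) if p]
    s, w = s[poly], w[poly]
    f_all, typed_all = _locus_f_matrices(g)
    f = f_all[keep_idx]
    typed = typed_all[keep_idx]
    corrected = (f - s[:, None, None]) / (1.0 - s)[:, None, None]
    pair_typed = (typed[:, :, None] & typed[:, None, :]).astype(float)
    wl = w[:, None, None]
    num = np.sum(wl * corrected * pair_typed, axis=0)
    den = np.sum(wl * pair_typed, axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def founder_genome_equivalents(g: GenotypeMatrix) -> float:
    """Diagnostic Ng = 1/(2f) with f the plain (uncorrected, unweighted)
    molecular coancestry averaged over all n^2 ordered pairs including
    self-coancestries."""
    f_all, typed_all = _locus_f_matrices(g)
    pair_typed = typed_all[:, :, None] & typed_all[:, None, :]
    num = np.sum(f_all * pair_typed, axis=0)
    den = np.sum(pair_typed, axis=0)
    ok = den > 0
    fbar = float(np.mean(num[ok] / den[ok]))
    if fbar <= 0:
        return math.inf
    return 1.0 / (2.0 * fbar)
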