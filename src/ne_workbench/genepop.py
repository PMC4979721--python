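"""GenePop-format genotype I/O and allele-frequency utilities.

Genotypes are unordered allele pairs at codominant loci (microsatellite
style).  Internally a :class:`GenotypeMatrix` stores an
``(n_individuals, n_loci, 2)`` integer array; allele code 0 means
missing.  The GenePop dialect supported is the common 2- or 3-digit
one: a title line, one locus name per line (or comma-separated),
``Pop`` separators, and per-individual lines ``name ,  0101 0102 ...``
with ``0000``/``000000`` for missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GenePopError",
    "LocusFrequencies",
    "AlleleFrequencies",
    "PcritFilter",
    "read_genepop",
    "write_genepop",
    "allele_frequencies",
    "apply_pcrit",
]


class GenePopError(ValueError):
    """Parse or consistency error in genotype data."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci unordered allele pairs with explicit missing.

    ``alleles[i, l]`` is the pair of integer allele codes for individual
    i at locus l; 0 encodes a missing allele.  ``pops`` assigns each
    individual to a sample (GenePop ``Pop`` block label).
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, L, 2) int
    pops: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.shape != (len(self.ids), len(self.loci), 2):
            raise GenePopError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci")
        if np.any(self.alleles < 0):
            raise GenePopError("allele codes must be non-negative integers")
        if not self.pops:
            self.pops = ["pop1"] * len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the genotype is missing."""
        return np.any(self.alleles == 0, axis=2)

    def subset(self, ids: Sequence[str] | None = None,
               pop: str | None = None) -> "GenotypeMatrix":
        if pop is not None:
            keep = [k for k, p in enumerate(self.pops) if p == pop]
        else:
            wanted = set(ids)
            keep = [k for k, i in enumerate(self.ids) if i in wanted]
        return GenotypeMatrix(
            ids=[self.ids[k] for k in keep],
            loci=list(self.loci),
            alleles=self.alleles[keep].copy(),
            pops=[self.pops[k] for k in keep],
        )

    def dosage(self, locus: int, allele: int) -> np.ndarray:
        """Per-individual copy number of ``allele`` at ``locus`` (0/1/2)."""
        return np.sum(self.alleles[:, locus, :] == allele, axis=1)


@dataclass
class LocusFrequencies:
    """Gene-count allele frequencies at one locus."""

    locus: str
    freqs: dict[int, float]
    n_genes: int

    @property
    def expected_homozygosity(self) -> float:
        """s = sum p_i^2; 1 iff the locus is monomorphic."""
        return float(sum(p * p for p in self.freqs.values()))

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)


@dataclass
class AlleleFrequencies:
    """Per-locus frequency tables for one genotype matrix."""

    loci: dict[str, LocusFrequencies]
    dropped: list[str] = field(default_factory=list)

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def __iter__(self):
        return iter(self.loci.values())


def allele_frequencies(
    g: GenotypeMatrix,
    retained: Mapping[str, set[int]] | None = None,
) -> AlleleFrequencies:
    """Gene-count frequencies per locus, ignoring missing genotypes.

    If ``retained`` (locus -> allele set) is given, only those alleles
    are counted and frequencies are renormalized over them.  Loci with
    no observed genotype are dropped with a record in ``dropped``.
    """
    out: dict[str, LocusFrequencies] = {}
    dropped: list[str] = []
    for l, name in enumerate(g.loci):
        genes = g.alleles[:, l, :].ravel()
        genes = genes[genes > 0]
        if retained is not None and name in retained:
            genes = genes[np.isin(genes, sorted(retained[name]))]
        if genes.size == 0:
            dropped.append(name)
            continue
        codes, counts = np.unique(genes, return_counts=True)
        total = counts.sum()
        out[name] = LocusFrequencies(
            locus=name,
            freqs={int(c): float(k) / total for c, k in zip(codes, counts)},
            n_genes=int(total),
        )
    return AlleleFrequencies(loci=out, dropped=dropped)


@dataclass
class PcritFilter:
    """Result of rare-allele screening at one threshold.

    ``retained`` maps each usable locus to its retained allele set;
    loci reduced below two retained alleles are in ``excluded_loci``.
    Masking never removes individuals, only alleles from the LD
    comparisons.
    """

    pcrit: float
    retained: dict[str, set[int]]
    excluded_loci: list[str]
    masked_alleles: dict[str, set[int]]

    @property
    def loci(self) -> list[str]:
        return list(self.retained)


def apply_pcrit(g: GenotypeMatrix, pcrit: float) -> PcritFilter:
    """Screen alleles with sample frequency < pcrit before LD estimation.

    pcrit must lie in [0, 0.5).  With pcrit = 0 the filter is the
    identity.  Loci left with fewer than two retained alleles carry no
    association information and are excluded.
    """
    if not 0.0 <= pcrit < 0.5:
        raise ValueError(f"pcrit must be in [0, 0.5), got {pcrit}")
    freqs = allele_frequencies(g)
    retained: dict[str, set[int]] = {}
    masked: dict[str, set[int]] = {}
    excluded: list[str] = []
    for lf in freqs:
        keep = {a for a, p in lf.freqs.items() if p >= pcrit}
        drop = set(lf.freqs) - keep
        if len(keep) < 2:
            excluded.append(lf.locus)
            continue
        retained[lf.locus] = keep
        if drop:
            masked[lf.locus] = drop
    excluded.extend(freqs.dropped)
    return PcritFilter(
        pcrit=pcrit, retained=retained, excluded_loci=excluded, masked_alleles=masked
    )


def _format_genotype(pair: np.ndarray, width: int) -> str:
    return f"{pair[0]:0{width}d}{pair[1]:0{width}d}"


def write_genepop(
    g: GenotypeMatrix, path, title: str = "ne-workbench export", digits: int = 3
) -> None:
    """Write a GenotypeMatrix in GenePop format, one Pop block per sample."""
    if digits not in (2, 3):
        raise ValueError("GenePop allele codes are 2 or 3 digits")
    if np.any(g.alleles >= 10**digits):
        raise GenePopError(f"allele code too large for {digits}-digit format")
    lines = [title]
    lines.extend(g.loci)
    last_pop = None
    for k, iid in enumerate(g.ids):
        if g.pops[k] != last_pop:
            lines.append("Pop")
            last_pop = g.pops[k]
        geno = " ".join(
            _format_genotype(np.sort(g.alleles[k, l]), digits)
            for l in range(g.n_loci)
        )
        lines.append(f"{iid} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_genepop(path) -> GenotypeMatrix:
    """Read a GenePop file (2- or 3-digit dialect) into a GenotypeMatrix.

    Pop blocks are preserved as sample labels ``pop1``, ``pop2``, ...
    (GenePop files carry no explicit block names).
    """
    text = Path(path).read_text(encoding="utf-8")
    raw_lines = text.splitlines()
    if len(raw_lines) < 3:
        raise GenePopError("file too short for GenePop format")
    # Header: title, then locus names until the first Pop line.
    loci: list[str] = []
    i = 1
    while i < len(raw_lines) and raw_lines[i].strip().lower() != "pop":
        chunk = raw_lines[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(raw_lines):
        raise GenePopError("no 'Pop' line found")
    if not loci:
        raise GenePopError("no locus names in header")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    pop_idx = 0
    for lineno in range(i, len(raw_lines)):
        line = raw_lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenePopError(f"line {lineno + 1}: expected 'name , genotypes'")
        name, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenePopError(
                f"line {lineno + 1}: {len(fields)} genotype fields for "
                f"{len(loci)} loci")
        pair_row = np.zeros((len(loci), 2), dtype=int)
        for l, tok in enumerate(fields):
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise GenePopError(
                    f"line {lineno + 1}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenePopError(
                    f"line {lineno + 1}: inconsistent allele code width "
                    f"({w} vs {width} digits)")
            pair_row[l] = (int(tok[:w]), int(tok[w:]))
            # half-missing genotypes are treated as fully missing
            if pair_row[l, 0] == 0 or pair_row[l, 1] == 0:
                pair_row[l] = (0, 0)
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(pair_row)
    if not ids:
        raise GenePopError("no individuals found")
    return GenotypeMatrix(
        ids=ids, loci=loci, alleles=np.stack(rows), pops=pops
    )
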