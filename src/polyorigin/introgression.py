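"""Patterson's D (ABBA-BABA) from population allele frequencies.

For a species trio (P1, P2, P3) with outgroup O and per-locus alternative
allele frequencies p1, p2, p3, p4:

    ABBA_l = (1 - p1) p2 p3 (1 - p4)
    BABA_l = p1 (1 - p2) p3 (1 - p4)
    D = sum(ABBA - BABA) / sum(ABBA + BABA)

Under incomplete lineage sorting alone D is centered at zero; gene flow
between P3 and one of P1/P2 drives |D| away from zero. Significance comes
from a weighted delete-one block jackknife over SNP blocks (weights
proportional to the block denominators), giving Z = D / SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variants_io import GenotypeMatrix


@dataclass
class DStatResult:
    trio: tuple  # (P1, P2, P3)
    outgroup: str
    d: float
    z: float
    se: float
    n_blocks: int
    block_size_snps: int
    block_numerators: np.ndarray
    block_denominators: np.ndarray


def population_frequencies(g: GenotypeMatrix, group: str) -> np.ndarray:
    """Per-site alternative allele frequency of one species/population group.

    Matches samples by species label first, then by population label.
    """
    idx = g.samples_of(species=group)
    if len(idx) == 0:
        idx = g.samples_of(population=group)
    if len(idx) == 0:
        raise KeyError(f"no samples with species or population label {group!r}")
    dosage = g.dosage[idx]
    ploidy = g.ploidy[idx].astype(float)
    called = ~np.isnan(dosage)
    num = np.where(called, dosage, 0.0).sum(axis=0)
    den = (called * ploidy[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def abba_baba(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ABBA and BABA terms; loci with any missing frequency drop out."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    if not (p1.shape == p2.shape == p3.shape == p4.shape):
        raise ValueError("frequency arrays must have equal length")
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(p4)
    abba = np.where(ok, (1 - p1) * p2 * p3 * (1 - p4), 0.0)
    baba = np.where(ok, p1 * (1 - p2) * p3 * (1 - p4), 0.0)
    return abba, baba


def patterson_d(p1, p2, p3, p4) -> float:
    """Genome-wide D; raises when every locus has zero ABBA+BABA."""
    abba, baba = abba_baba(p1, p2, p3, p4)
    denom = float((abba + baba).sum())
    if denom == 0:
        raise ValueError("D undefined: all loci have zero ABBA+BABA")
    return float((abba - baba).sum() / denom)


def block_jackknife_z(
    abba: np.ndarray, baba: np.ndarray, block_size_snps: int = 100
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Weighted delete-one-block jackknife Z and SE for D.

    Blocks are consecutive runs of ``block_size_snps`` loci in input (genome)
    order; block weights are the block ABBA+BABA sums. Identical blocks give
    SE = 0, reported as Z = +/-inf.
    """
    abba = np.asarray(abba, dtype=float)
    baba = np.asarray(baba, dtype=float)
    n_loci = abba.size
    starts = np.arange(0, n_loci, block_size_snps)
    if len(starts) < 3:
        raise ValueError(f"need >= 3 jackknife blocks, got {len(starts)}")
    num_b = np.array([(abba - baba)[s : s + block_size_snps].sum() for s in starts])
    den_b = np.array([(abba + baba)[s : s + block_size_snps].sum() for s in starts])
    nonzero = den_b > 0
    num_b, den_b = num_b[nonzero], den_b[nonzero]
    nb = len(num_b)
    if nb < 3:
        raise ValueError(f"need >= 3 non-degenerate blocks, got {nb}")

    num_tot, den_tot = num_b.sum(), den_b.sum()
    theta = num_tot / den_tot
    loo = (num_tot - num_b) / (den_tot - den_b)
    # Busing-style weighted jackknife with weights m_j = block denominators
    h = den_tot / den_b
    theta_jack = nb * theta - ((1 - den_b / den_tot) * loo).sum()
    pseudo = h * theta - (h - 1) * loo
    var = float((((pseudo - theta_jack) ** 2) / (h - 1)).sum() / nb)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(np.sign(theta) * np.inf) if se == 0 else float(theta / se)
    return z, se, num_b, den_b


def dstat(
    g: GenotypeMatrix, p1: str, p2: str, p3: str, outgroup: str, block_size_snps: int = 100
) -> DStatResult:
    """D and jackknife Z for one trio from a mixed-ploidy genotype matrix."""
    f1, f2, f3, f4 = (population_frequencies(g, s) for s in (p1, p2, p3, outgroup))
    abba, baba = abba_baba(f1, f2, f3, f4)
    denom = float((abba + baba).sum())
    if denom == 0:
        raise ValueError("D undefined: all loci have zero ABBA+BABA")
    d = float((abba - baba).sum() / denom)
    z, se, num_b, den_b = block_jackknife_z(abba, baba, block_size_snps)
    return DStatResult((p1, p2, p3), outgroup, d, z, se, len(num_b), block_size_snps, num_b, den_b)
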