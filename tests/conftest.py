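"""Shared fixtures and independent reference implementations used as oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyorigin.variants_io import SITE_COLUMNS, GenotypeMatrix, SampleRecord
from polyorigin.simdata import SpeciesFrequencyTable


def make_sites(n, chrom="chr1", spacing=200, ref="A", alt="G", start=100):
    pos = start + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "locus": [f"{chrom}:{p}" for p in pos],
        }
    )[SITE_COLUMNS]


def make_genotypes(dosage, ploidy=2, species=None, population=None, sites=None):
    """GenotypeMatrix from a raw dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if np.isscalar(ploidy) or isinstance(ploidy, int):
        ploidy = [int(ploidy)] * n
    species = species or [f"sp{i}" for i in range(n)]
    population = population or species
    samples = [
        SampleRecord(f"s{i}", population[i], species[i], ploidy[i]) for i in range(n)
    ]
    return GenotypeMatrix(samples, sites if sites is not None else make_sites(m), dosage)


def make_freq_table(freqs_by_species, sites=None):
    species = list(freqs_by_species)
    freq = np.vstack([np.asarray(freqs_by_species[s], dtype=float) for s in species])
    return SpeciesFrequencyTable(species, freq, sites if sites is not None else make_sites(freq.shape[1]))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, per-element implementations)
# ---------------------------------------------------------------------------

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, "-": set(),
}
_SET_TO_CODE = {frozenset(v): k for k, v in _IUPAC_SETS.items()}


def brute_force_polarize(poly: str, ref: str) -> str:
    """Per-column restatement of the polarization rule over the 16-symbol alphabet."""
    out = []
    for p, r in zip(poly, ref):
        ps, rs = _IUPAC_SETS[p.upper()], _IUPAC_SETS[r.upper()]
        if len(ps) == 2 and len(rs) == 1 and rs < ps:
            out.append(_SET_TO_CODE[frozenset(ps - rs)])
        else:
            out.append(p.upper())
    return "".join(out)


def loop_relatedness(dosage, ploidy):
    """Per-pair, per-locus loop implementation of the moment estimator."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ploidy = np.asarray(ploidy, dtype=float)
    p = np.full(m, np.nan)
    for l in range(m):
        num = den = 0.0
        for i in range(n):
            if not np.isnan(dosage[i, l]):
                num += dosage[i, l]
                den += ploidy[i]
        if den > 0:
            p[l] = num / den
    r = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for l in range(m):
                if np.isnan(p[l]) or p[l] <= 0 or p[l] >= 1:
                    continue
                if np.isnan(dosage[i, l]) or np.isnan(dosage[j, l]):
                    continue
                xi = dosage[i, l] / ploidy[i]
                xj = dosage[j, l] / ploidy[j]
                num += (xi - p[l]) * (xj - p[l])
                den += p[l] * (1 - p[l])
            if den > 0:
                r[i, j] = num / den
    return r


def loop_patterson_d(p1, p2, p3, p4):
    num = den = 0.0
    for a, b, c, d in zip(p1, p2, p3, p4):
        abba = (1 - a) * b * c * (1 - d)
        baba = a * (1 - b) * c * (1 - d)
        num += abba - baba
        den += abba + baba
    return num / den


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
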