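"""Mixed-ploidy relatedness ranking of candidate progenitors.

Pairwise relatedness between samples x and y is a dosage-based moment
estimator on allele-frequency-centered dosage fractions:

    r_xy = sum_l (x_l - p_l)(y_l - p_l) / sum_l p_l (1 - p_l)

with x_l = dosage/ploidy, p_l the ploidy-weighted global alternative-allele
frequency, and sums over loci non-missing in both samples with 0 < p_l < 1.
This is a Ritland/Loiselle-style correlation estimator that works across
ploidy levels; only the *relative ranking* of candidate species matters for
progenitor inference, and group differences are assessed with Wilcoxon
rank-sum tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants_io import GenotypeMatrix

logger = logging.getLogger("polyorigin")


@dataclass
class RelatednessResult:
    samples: list  # SampleRecord
    matrix: np.ndarray  # symmetric, NaN where no shared informative loci
    n_informative_loci: int

    def pairs_between(self, species_a: str, species_b: str) -> np.ndarray:
        """All r_xy with x in species_a, y in species_b (within-group pairs once)."""
        ia = [i for i, s in enumerate(self.samples) if s.species == species_a]
        ib = [i for i, s in enumerate(self.samples) if s.species == species_b]
        if species_a == species_b:
            vals = [self.matrix[i, j] for i, j in itertools.combinations(ia, 2)]
        else:
            vals = [self.matrix[i, j] for i in ia for j in ib]
        return np.array([v for v in vals if np.isfinite(v)])


def pairwise_relatedness(g: GenotypeMatrix, exclude_species_from_freqs: Sequence[str] = ()) -> RelatednessResult:
    """Moment-estimator relatedness matrix over all sample pairs.

    Frequencies are computed over all samples jointly (dosage sum / ploidy
    sum at each locus over non-missing genotypes); species listed in
    ``exclude_species_from_freqs`` are left out of the frequency estimate
    (but not the matrix) to reduce circularity for a focal polyploid.
    Loci monomorphic overall are excluded entirely.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    dosage = g.dosage
    ploidy = g.ploidy.astype(float)
    in_freq = ~np.isin(np.array([s.species for s in g.samples]), list(exclude_species_from_freqs))
    called = ~np.isnan(dosage)
    dz = np.where(called, dosage, 0.0)
    kz = np.where(called, ploidy[:, None], 0.0)
    num_p = dz[in_freq].sum(axis=0)
    den_p = kz[in_freq].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(den_p > 0, num_p / np.maximum(den_p, 1), np.nan)
    informative = np.isfinite(p) & (p > 0) & (p < 1)

    pi = p[informative]
    x = dosage[:, informative] / ploidy[:, None]
    ok = ~np.isnan(x)
    xc = np.where(ok, x - pi[None, :], 0.0)
    w = pi * (1 - pi)
    num = xc @ xc.T
    den = (ok * w[None, :]) @ ok.T  # sum of p(1-p) over loci called in both
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    n_missing_pairs = int(np.isnan(r).sum() - np.isnan(np.diag(r)).sum())
    if n_missing_pairs:
        logger.warning("pairwise_relatedness: %d pairs share no informative loci", n_missing_pairs // 2)
    return RelatednessResult(list(g.samples), r, int(informative.sum()))


def group_relatedness(
    result: RelatednessResult, focal_species: str, candidate_species: Sequence[str]
) -> pd.DataFrame:
    """Mean +/- SD relatedness of the focal species to each candidate group."""
    rows = []
    for cand in candidate_species:
        vals = result.pairs_between(focal_species, cand)
        if vals.size == 0:
            logger.warning("group_relatedness: no pairs between %s and %s", focal_species, cand)
            rows.append((cand, np.nan, np.nan, 0))
            continue
        rows.append((cand, float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else np.nan, vals.size))
    return pd.DataFrame(rows, columns=["candidate", "mean", "sd", "n_pairs"]).sort_values(
        "mean", ascending=False, ignore_index=True
    )


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of the first sample with a two-sided p-value.

    Exact p by enumeration of label assignments (midranks, so ties are
    handled) when n_a + n_b <= 12; otherwise the normal approximation with
    tie and continuity corrections. Fully tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return na * nb / 2.0, 1.0
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    if na + nb <= 12:
        mu = na * nb / 2.0
        dev = abs(u_obs - mu)
        n_total = na + nb
        count = 0
        for idx in itertools.combinations(range(n_total), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / comb(n_total, na)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def rank_candidates(
    result: RelatednessResult,
    focal_species: str,
    candidate_species: Sequence[str],
    true_parents: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group summary plus Wilcoxon tests between consecutive-ranked candidates."""
    table = group_relatedness(result, focal_species, candidate_species)
    pvals = [np.nan]
    for i in range(1, len(table)):
        x = result.pairs_between(focal_species, table.loc[i - 1, "candidate"])
        y = result.pairs_between(focal_species, table.loc[i, "candidate"])
        if x.size and y.size:
            pvals.append(wilcoxon_rank_sum(x, y)[1])
        else:
            pvals.append(np.nan)
    table["p_vs_next_rank"] = pvals
    if true_parents is not None:
        table["is_true_parent"] = table["candidate"].isin(list(true_parents))
    return table
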