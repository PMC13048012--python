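"""Disomic vs tetrasomic inheritance from genotype frequencies and allele depths.

Two complementary signals distinguish allopolyploids (disomic inheritance:
chromosomes pair within parental subgenomes, producing fixed heterozygosity)
from autopolyploids (tetrasomic inheritance: dosages follow Binomial(k, q)
under Hardy-Weinberg equilibrium):

* population level — the distribution of genotype (dosage-class) frequencies
  against the alternative allele frequency q. Under tetrasomy the balanced
  class G_{k/2} follows the binomial expectation; under disomy loci with
  subgenome-fixed differences pile up extra balanced heterozygotes at
  intermediate q. The excess statistic Delta quantifies this.
* individual level — the distribution of per-site alternative-read ratios at
  heterozygous sites. Tetrasomic tetraploids show modes near 0.25/0.5/0.75
  with Hardy-Weinberg-ish weights; fixed heterozygosity concentrates mass at
  0.5. A fixed-mean Gaussian mixture (plus a capped uniform background as
  denoising) is fitted by EM and the weight on the 0.5 component is the
  classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .variants_io import AlleleDepthMatrix, GenotypeMatrix

logger = logging.getLogger("polyorigin")


@dataclass
class GenotypeFrequencyCurve:
    """Observed dosage-class frequencies binned by alternative allele frequency."""

    population: str
    ploidy: int
    bin_centers: np.ndarray  # (n_bins,)
    n_sites: np.ndarray  # (n_bins,) sites per bin
    class_freq: np.ndarray  # (ploidy+1, n_bins), NaN where n_sites == 0
    smoothed: np.ndarray  # moving average over bins, same shape


@dataclass
class InheritanceCall:
    population: str
    mode: str  # "disomic" | "tetrasomic" | "ambiguous"
    delta: float  # observed balanced-class excess over the tetrasomic expectation
    n_sites: int
    thresholds: tuple = (0.15, 0.05)


@dataclass
class RatioProfile:
    """Alt-read ratios of one sample at depth-filtered heterozygous-ish sites."""

    sample: str
    ratios: np.ndarray
    reliable: bool = True
    weights: np.ndarray | None = None  # (w_0.25, w_0.5, w_0.75)
    background_weight: float | None = None
    sigma: float | None = None
    loglik: float | None = None
    loglik_single: float | None = None
    loglik_path: np.ndarray | None = None
    converged: bool = True
    call: str | None = None  # "allo-like" | "auto-like" | "ambiguous"


# ---------------------------------------------------------------------------
# Genotype-frequency curves
# ---------------------------------------------------------------------------

def observed_genotype_curve(
    g: GenotypeMatrix,
    population: str,
    bin_width: float = 0.05,
    min_sites_per_bin: int = 10,
    min_samples: int = 6,
) -> GenotypeFrequencyCurve:
    """Bin sites by allele frequency and tabulate dosage-class frequencies.

    All samples of the population must share one ploidy. Sites with fewer
    than ``min_samples`` non-missing genotypes are excluded; q is the mean
    dosage / ploidy over non-missing samples. The smoothed curve is a
    site-count-weighted moving average over a 3-bin window.
    """
    idx = g.samples_of(population=population)
    if len(idx) == 0:
        raise ValueError(f"no samples in population {population!r}")
    ploidies = {g.samples[i].ploidy for i in idx}
    if len(ploidies) > 1:
        raise ValueError(f"population {population!r} mixes ploidies {sorted(ploidies)}")
    k = ploidies.pop()
    dos = g.dosage[idx]

    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    use = n_called >= min_samples
    with np.errstate(invalid="ignore"):
        q = np.nansum(dos, axis=0) / (k * np.maximum(n_called, 1))
    poly = use & (q > 0) & (q < 1)
    if not poly.any():
        logger.warning("population %s: all usable sites monomorphic", population)

    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)

    n_sites = np.zeros(n_bins, dtype=int)
    counts = np.zeros((k + 1, n_bins))
    for b in range(n_bins):
        sel = use & (which == b)
        n_sites[b] = int(sel.sum())
        if n_sites[b] == 0:
            continue
        sub = dos[:, sel]
        ok = ~np.isnan(sub)
        for j in range(k + 1):
            counts[j, b] = ((sub == j) & ok).sum()
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)

    smoothed = np.full_like(freq, np.nan)
    for b in range(n_bins):
        lo, hi = max(0, b - 1), min(n_bins, b + 2)
        w = n_sites[lo:hi].astype(float)
        if w.sum() == 0:
            continue
        block = freq[:, lo:hi]
        ok = ~np.isnan(block)
        ww = np.where(ok, w[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed[:, b] = np.where(
                ww.sum(axis=1) > 0,
                np.nansum(block * ww, axis=1) / np.maximum(ww.sum(axis=1), 1e-300),
                np.nan,
            )
    return GenotypeFrequencyCurve(population, k, centers, n_sites, freq, smoothed)


def expected_tetrasomic(q: float, ploidy: int = 4) -> np.ndarray:
    """Hardy-Weinberg dosage-class probabilities under polysomic inheritance."""
    return stats.binom.pmf(np.arange(ploidy + 1), ploidy, q)


def expected_disomic(q1: float, q2: float) -> np.ndarray:
    """Dosage distribution of two independent HWE subgenomes: Bin(2,q1) * Bin(2,q2)."""
    return np.convolve(stats.binom.pmf(np.arange(3), 2, q1), stats.binom.pmf(np.arange(3), 2, q2))


def classify_population_inheritance(
    curve: GenotypeFrequencyCurve,
    central_band: tuple = (0.35, 0.65),
    thresholds: tuple = (0.15, 0.05),
    min_sites_per_bin: int = 10,
) -> InheritanceCall:
    """Call disomic/tetrasomic from the balanced-class excess Delta.

    Delta is the site-count-weighted mean, over bins with centers in the
    central band, of observed G_{k/2} minus the tetrasomic (binomial)
    expectation at the bin center. Delta >= thresholds[0] -> disomic;
    Delta <= thresholds[1] -> tetrasomic; otherwise ambiguous. The default
    thresholds (0.15 / 0.05) come from simulation calibration and are
    reported with every call. For hexaploids the same statistic on G_3 is
    computed but should be treated as experimental.
    """
    k = curve.ploidy
    mid = k // 2
    lo, hi = central_band
    sel = (
        (curve.bin_centers >= lo)
        & (curve.bin_centers <= hi)
        & (curve.n_sites >= min_sites_per_bin)
        & ~np.isnan(curve.class_freq[mid])
    )
    if not sel.any():
        logger.warning("population %s: no informative central bins; call ambiguous", curve.population)
        return InheritanceCall(curve.population, "ambiguous", float("nan"), 0, thresholds)
    w = curve.n_sites[sel].astype(float)
    exp_mid = np.array([expected_tetrasomic(c, k)[mid] for c in curve.bin_centers[sel]])
    delta = float(np.average(curve.class_freq[mid, sel] - exp_mid, weights=w))
    if delta >= thresholds[0]:
        mode = "disomic"
    elif delta <= thresholds[1]:
        mode = "tetrasomic"
    else:
        mode = "ambiguous"
    return InheritanceCall(curve.population, mode, delta, int(w.sum()), thresholds)


# ---------------------------------------------------------------------------
# Allelic-depth-ratio mixtures
# ---------------------------------------------------------------------------

def het_ratio_profile(
    d: AlleleDepthMatrix,
    sample_index_or_id,
    g: GenotypeMatrix | None = None,
    min_total: int = 30,
    max_total: int = 200,
    min_minor: int = 3,
) -> RatioProfile:
    """Alt/(ref+alt) ratios at sites passing depth and minor-read filters.

    Retains sites with min_total <= depth <= max_total (the genotype depth
    regime for tetraploids, capped at the paralog-exclusion maximum) and
    min(ref, alt) >= min_minor, which selects heterozygous-ish sites without
    using genotype calls. Profiles with < 50 sites are flagged unreliable.
    """
    if isinstance(sample_index_or_id, str):
        if g is None:
            raise ValueError("sample given by id requires the genotype matrix")
        i = g.sample_index(sample_index_or_id)
        name = sample_index_or_id
    else:
        i = int(sample_index_or_id)
        name = g.samples[i].id if g is not None else str(i)
    ref, alt = d.ref_depth[i], d.alt_depth[i]
    total = ref + alt
    keep = (total >= min_total) & (total <= max_total) & (np.minimum(ref, alt) >= min_minor)
    ratios = alt[keep] / total[keep]
    reliable = keep.sum() >= 50
    if not reliable:
        logger.warning("sample %s: only %d sites in ratio profile; flagged unreliable", name, int(keep.sum()))
    return RatioProfile(sample=name, ratios=ratios, reliable=reliable)


_MEANS = np.array([0.25, 0.5, 0.75])
_BG_CAP = 0.2


def fit_ratio_mixture(
    profile: RatioProfile,
    max_iter: int = 500,
    tol: float = 1e-8,
    allo_threshold: float = 0.6,
    auto_threshold: float = 0.45,
) -> RatioProfile:
    """EM fit of the fixed-mean three-component mixture with uniform background.

    Component means are fixed at 0.25/0.5/0.75 with a shared free variance
    and free weights; a uniform background on (0,1), weight capped at 0.2,
    absorbs noise. A one-component model at 0.5 is fitted for comparison.
    The individual call is allo-like when w(0.5) >= 0.6, auto-like when
    w(0.5) <= 0.45, else ambiguous. The log-likelihood is non-decreasing
    across EM iterations (the capped M-step is the constrained maximizer).
    """
    x = np.asarray(profile.ratios, dtype=float)
    if x.size == 0:
        raise ValueError(f"sample {profile.sample}: empty ratio profile")

    weights = np.full(3, (1.0 - 0.1) / 3)
    w_bg = 0.1
    sigma = 0.1
    path = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        comp = weights[None, :] * stats.norm.pdf(x[:, None], _MEANS[None, :], sigma)
        bg = np.full_like(x, w_bg)  # uniform density 1 on (0,1)
        total = comp.sum(axis=1) + bg
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        path.append(ll)
        resp = comp / total[:, None]
        resp_bg = bg / total
        n_c = resp.sum(axis=0)
        n_bg = float(resp_bg.sum())
        w_bg_new = n_bg / x.size
        if w_bg_new > _BG_CAP:
            w_bg_new = _BG_CAP
            weights_new = n_c / n_c.sum() * (1.0 - _BG_CAP)
        else:
            weights_new = n_c / x.size
        var = float((resp * (x[:, None] - _MEANS[None, :]) ** 2).sum() / max(n_c.sum(), 1e-12))
        sigma_new = max(np.sqrt(var), 1e-4)
        weights, w_bg, sigma = weights_new, w_bg_new, sigma_new
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    if not converged:
        logger.warning("sample %s: EM did not converge in %d iterations", profile.sample, max_iter)

    ll_single = _single_component_loglik(x)

    w_mid = float(weights[1])
    if w_mid >= allo_threshold:
        call = "allo-like"
    elif w_mid <= auto_threshold:
        call = "auto-like"
    else:
        call = "ambiguous"
    profile.weights = weights
    profile.background_weight = w_bg
    profile.sigma = sigma
    profile.loglik = path[-1]
    profile.loglik_single = ll_single
    profile.loglik_path = np.array(path)
    profile.converged = converged
    profile.call = call
    return profile


def _single_component_loglik(x: np.ndarray, max_iter: int = 200) -> float:
    """One Gaussian fixed at 0.5 (free sigma) plus the capped uniform background."""
    w_bg, sigma = 0.1, 0.1
    prev = -np.inf
    for _ in range(max_iter):
        comp = (1 - w_bg) * stats.norm.pdf(x, 0.5, sigma)
        total = np.maximum(comp + w_bg, 1e-300)
        ll = float(np.log(total).sum())
        resp = comp / total
        n_c = float(resp.sum())
        w_bg = min(1.0 - n_c / x.size, _BG_CAP)
        var = float((resp * (x - 0.5) ** 2).sum() / max(n_c, 1e-12))
        sigma = max(np.sqrt(var), 1e-4)
        if ll - prev < 1e-8 and np.isfinite(prev):
            break
        prev = ll
    return ll


def classify_individuals(
    d: AlleleDepthMatrix, g: GenotypeMatrix, samples: Sequence[str] | None = None, **kwargs
) -> list:
    """Ratio-mixture calls for a set of samples (default: all polyploids)."""
    if samples is None:
        samples = [s.id for s in g.samples if s.ploidy > 2]
    out = []
    for s in samples:
        prof = het_ratio_profile(d, s, g=g)
        if prof.ratios.size >= 50:
            prof = fit_ratio_mixture(prof, **kwargs)
        out.append(prof)
    return out
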