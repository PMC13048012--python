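"""Mixed-ploidy variant containers, VCF/popmap I/O, SNP filtering and RGS ploidy calls.

The central in-memory currency is :class:`GenotypeMatrix`: a samples x sites
matrix of alternative-allele dosages (0..ploidy, NaN = missing) together with
per-sample records (population, species, ploidy, relative genome size) and
per-site metadata (chromosome, 1-based position, ref/alt alleles, RAD locus id).
:class:`AlleleDepthMatrix` carries the matched ref/alt read counts.

Filtering implements the RADseq quality rules used throughout the analysis:
ploidy-specific genotype depth masking, site missingness, minor allele count,
maximum observed heterozygosity, one-SNP-per-locus thinning and LD pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("polyorigin")

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "locus"]


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual.

    ``rgs`` is the flow-cytometric relative genome size (sample/standard
    fluorescence ratio), unitless; ``None`` when not measured.
    """

    id: str
    population: str
    species: str
    ploidy: int
    rgs: float | None = None


@dataclass
class GenotypeMatrix:
    """Samples x sites allele-dosage matrix.

    ``dosage`` is float so missing genotypes can be NaN; defined entries are
    integers in ``{0..ploidy}``. ``sites`` is a DataFrame with columns
    ``chrom, pos, ref, alt, locus`` (pos 1-based, biallelic sites only,
    positions strictly increasing within a chromosome).
    """

    samples: list[SampleRecord]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        k = self.ploidy[:, None]
        with np.errstate(invalid="ignore"):
            if np.any(self.dosage > k) or np.any(self.dosage < 0):
                raise ValueError("dosage outside 0..ploidy for some sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ploidy(self) -> np.ndarray:
        return np.array([s.ploidy for s in self.samples])

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples,
            self.sites.iloc[idx].reset_index(drop=True),
            self.dosage[:, idx],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.sites.copy(), self.dosage[idx]
        )

    def samples_of(self, *, population: str | None = None, species: str | None = None) -> np.ndarray:
        """Indices of samples matching a population and/or species label."""
        keep = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            keep &= np.array([s.population == population for s in self.samples])
        if species is not None:
            keep &= np.array([s.species == species for s in self.samples])
        return np.flatnonzero(keep)


@dataclass
class AlleleDepthMatrix:
    """Per-sample, per-site reference/alternative read counts (>= 0)."""

    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=int)
        self.alt_depth = np.asarray(self.alt_depth, dtype=int)
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref/alt depth shapes differ")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("negative read depths")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "AlleleDepthMatrix":
        idx = np.asarray(idx)
        return AlleleDepthMatrix(self.ref_depth[:, idx], self.alt_depth[:, idx])


@dataclass(frozen=True)
class FilterConfig:
    """Site/genotype quality thresholds.

    Defaults follow the RADseq filtering regime of the analysis: genotype
    depth 8/30/40 by ploidy (max 200), site missingness <= 0.5, minor allele
    count >= 3, observed heterozygosity <= 0.65. ``het_ploidies`` restricts
    which ploidies enter the heterozygosity fraction (the maxHo rule is a
    diploid-dataset rule; extending it to polyploids is optional).
    """

    max_missing_fraction: float = 0.5
    mac_min: int = 3
    max_obs_het: float = 0.65
    min_dp_by_ploidy: dict = field(default_factory=lambda: {2: 8, 4: 30, 6: 40})
    max_dp: int = 200
    ld_r2: float = 0.2
    ld_window_bp: int = 1000
    one_snp_per_locus: bool = False
    het_ploidies: tuple = (2,)

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_fraction <= 1 and 0 <= self.max_obs_het <= 1):
            raise ValueError("fractions must lie in [0,1]")
        if self.max_dp <= 0 or any(v <= 0 for v in self.min_dp_by_ploidy.values()):
            raise ValueError("depth thresholds must be positive")


class FilterResult(NamedTuple):
    genotypes: GenotypeMatrix
    depths: AlleleDepthMatrix | None
    report: pd.DataFrame


# ---------------------------------------------------------------------------
# popmap / RGS tables
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> pd.DataFrame:
    """Read a 4-column popmap TSV: sample, population, species, ploidy."""
    pm = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "population", "species", "ploidy"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"popmap missing columns: {sorted(missing)}")
    return pm


def write_popmap(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [s.id for s in samples],
            "population": [s.population for s in samples],
            "species": [s.species for s in samples],
            "ploidy": [s.ploidy for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, popmap: pd.DataFrame | str | Path) -> tuple[GenotypeMatrix, AlleleDepthMatrix | None]:
    """Parse a mixed-ploidy VCF into dosage + allele-depth matrices.

    GT is converted to the count of alternative alleles; any missing allele
    makes the genotype missing. Multiallelic records are skipped (counted in
    the log). Every VCF sample must appear in the popmap, and the GT ploidy
    of each called genotype must equal the popmap ploidy.
    """
    if not isinstance(popmap, pd.DataFrame):
        popmap = read_popmap(popmap)
    pmi = popmap.set_index("sample")

    vcf = pysam.VariantFile(str(path))
    vcf_samples = list(vcf.header.samples)
    absent = [s for s in vcf_samples if s not in pmi.index]
    if absent:
        raise ValueError(f"samples in VCF absent from popmap: {absent}")
    records = [
        SampleRecord(
            id=s,
            population=str(pmi.loc[s, "population"]),
            species=str(pmi.loc[s, "species"]),
            ploidy=int(pmi.loc[s, "ploidy"]),
            rgs=float(pmi.loc[s, "rgs"]) if "rgs" in pmi.columns and pd.notna(pmi.loc[s, "rgs"]) else None,
        )
        for s in vcf_samples
    ]
    ploidies = np.array([r.ploidy for r in records])

    rows_d, rows_rd, rows_ad, meta = [], [], [], []
    n_multi = 0
    has_ad = "AD" in vcf.header.formats
    has_locus = "LOCUS" in vcf.header.info
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        dos = np.full(len(vcf_samples), np.nan)
        rd = np.zeros(len(vcf_samples), dtype=int)
        ad = np.zeros(len(vcf_samples), dtype=int)
        for i, s in enumerate(vcf_samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                pass
            else:
                if len(gt) != ploidies[i]:
                    raise ValueError(
                        f"sample {s!r}: GT ploidy {len(gt)} at {rec.chrom}:{rec.pos} "
                        f"inconsistent with popmap ploidy {ploidies[i]}"
                    )
                dos[i] = sum(1 for a in gt if a == 1)
            if has_ad:
                adv = call.get("AD")
                if adv is not None and len(adv) >= 2 and adv[0] is not None:
                    rd[i], ad[i] = int(adv[0]), int(adv[1])
        rows_d.append(dos)
        rows_rd.append(rd)
        rows_ad.append(ad)
        locus = rec.info.get("LOCUS") if has_locus else None
        locus = locus if locus is not None else f"{rec.chrom}:{rec.pos}"
        meta.append((rec.chrom, rec.pos, rec.ref, rec.alts[0], locus))
    vcf.close()
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)

    sites = pd.DataFrame(meta, columns=SITE_COLUMNS)
    g = GenotypeMatrix(records, sites, np.array(rows_d).T if rows_d else np.empty((len(records), 0)))
    d = None
    if has_ad and rows_rd:
        d = AlleleDepthMatrix(np.array(rows_rd).T, np.array(rows_ad).T)
    return g, d


def write_vcf(g: GenotypeMatrix, d: AlleleDepthMatrix | None, path: str | Path) -> None:
    """Write a VCF v4.2 with mixed-ploidy GT (and AD when depths are given).

    A genotype with dosage ``x`` and ploidy ``k`` is written as ``k - x``
    reference alleles followed by ``x`` alternative alleles (unphased).
    """
    chrom_last: dict[str, int] = {}
    contigs: list[str] = []
    for chrom, pos in zip(g.sites["chrom"], g.sites["pos"]):
        if chrom not in chrom_last:
            contigs.append(chrom)
        chrom_last[chrom] = max(int(pos), chrom_last.get(chrom, 0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyorigin\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={chrom_last[c] + 1000}>\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if d is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids) + "\n")
        fmt = "GT:AD" if d is not None else "GT"
        ploidy = g.ploidy
        for j in range(g.n_sites):
            row = g.sites.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]), str(row["alt"]),
                ".", "PASS", f"LOCUS={row['locus']}", fmt,
            ]
            for i in range(g.n_samples):
                x = g.dosage[i, j]
                if np.isnan(x):
                    gt = "/".join(["."] * ploidy[i])
                else:
                    x = int(x)
                    gt = "/".join(["0"] * (ploidy[i] - x) + ["1"] * x)
                if d is not None:
                    gt += f":{d.ref_depth[i, j]},{d.alt_depth[i, j]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_variants(g: GenotypeMatrix, d: AlleleDepthMatrix | None, cfg: FilterConfig | None = None) -> FilterResult:
    """Apply the quality filters in a fixed order and return surviving sites.

    Order: (1) genotype-level depth mask, (2) site missingness, (3) minor
    allele count, (4) observed heterozygosity. Depth masking comes first
    because masked genotypes change the site-level statistics the later
    rules are computed from. An empty result is legal (warning only).
    """
    cfg = cfg or FilterConfig()
    dosage = g.dosage.copy()
    ploidy = g.ploidy
    report_rows = []

    if d is not None:
        total = d.total_depth
        min_dp = np.array([
            cfg.min_dp_by_ploidy.get(k, max(cfg.min_dp_by_ploidy.values())) for k in ploidy
        ])[:, None]
        bad = (total < min_dp) | (total > cfg.max_dp)
        n_masked = int((bad & ~np.isnan(dosage)).sum())
        dosage[bad] = np.nan
        report_rows.append(("genotype_depth_mask", n_masked))

    n0 = dosage.shape[1]
    missing_frac = np.isnan(dosage).mean(axis=0)
    keep = missing_frac <= cfg.max_missing_fraction
    report_rows.append(("site_missingness", int(n0 - keep.sum())))

    with np.errstate(invalid="ignore"):
        alt_copies = np.nansum(dosage, axis=0)
        tot_copies = np.nansum(np.where(np.isnan(dosage), np.nan, ploidy[:, None] + 0.0 * dosage), axis=0)
    mac = np.minimum(alt_copies, tot_copies - alt_copies)
    drop_mac = keep & (mac < cfg.mac_min)
    report_rows.append(("minor_allele_count", int(drop_mac.sum())))
    keep &= ~drop_mac

    het_samples = np.isin(ploidy, list(cfg.het_ploidies))
    if het_samples.any():
        sub = dosage[het_samples]
        k_sub = ploidy[het_samples][:, None]
        is_het = (sub > 0) & (sub < k_sub)
        n_called = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n_called > 0, is_het.sum(axis=0) / np.maximum(n_called, 1), 0.0)
        drop_het = keep & (ho > cfg.max_obs_het)
        report_rows.append(("max_observed_het", int(drop_het.sum())))
        keep &= ~drop_het
    else:
        report_rows.append(("max_observed_het", 0))

    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        logger.warning("filter_variants: no sites survived filtering")
    out_g = GenotypeMatrix(g.samples, g.sites.iloc[idx].reset_index(drop=True), dosage[:, idx])
    out_d = d.take_sites(idx) if d is not None else None
    report = pd.DataFrame(report_rows, columns=["rule", "sites_removed"])
    # depth mask row counts masked genotypes, not sites; keep both units in the log
    for rule, n in report_rows:
        logger.info("filter_variants: %s removed %d", rule, n)
    return FilterResult(out_g, out_d, report)


def thin_one_snp_per_locus(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Retain exactly one uniformly chosen SNP per RAD locus."""
    rng = np.random.default_rng(seed)
    chosen = []
    for _, idx in g.sites.groupby("locus", sort=False).indices.items():
        chosen.append(idx[rng.integers(len(idx))])
    chosen = np.sort(np.asarray(chosen))
    return g.take_sites(chosen)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over samples non-missing at both sites."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 1000) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning per chromosome.

    A site is dropped if its r^2 with any previously retained site within
    ``window_bp`` exceeds ``r2_max``; correlation with a monomorphic retained
    site is defined as 0.
    """
    keep_idx: list[int] = []
    pos = g.sites["pos"].to_numpy()
    for _, idx in g.sites.groupby("chrom", sort=False).indices.items():
        retained: list[int] = []
        for j in idx:
            ok = True
            for r in reversed(retained):
                if pos[j] - pos[r] > window_bp:
                    break
                if _pairwise_r2(g.dosage[:, j], g.dosage[:, r]) > r2_max:
                    ok = False
                    break
            if ok:
                retained.append(j)
        keep_idx.extend(retained)
    return g.take_sites(np.sort(np.asarray(keep_idx)))


# ---------------------------------------------------------------------------
# RGS -> ploidy
# ---------------------------------------------------------------------------

#: (low, high, call) bands for the flow-cytometric relative-genome-size ratio.
#: Even-ploidy bands are checked first so the shared endpoints resolve to the
#: observed ploidy rather than the gap flag.
RGS_BANDS = [
    (0.15, 0.29, 2),
    (0.47, 0.60, 4),
    (0.77, 0.95, 6),
    (0.29, 0.47, "putative-3"),
    (0.60, 0.77, "putative-5"),
]


def assign_ploidy_from_rgs(rgs: float) -> int | str:
    """Call ploidy from relative genome size.

    Observed bands: 0.21-0.29 diploid, 0.47-0.60 tetraploid, 0.77-0.84
    hexaploid. Values falling between bands are flagged putative triploids /
    pentaploids; values outside [0.15, 0.95] are 'unknown'. The narrow
    unobserved margins just outside the diploid and hexaploid bands are
    assigned to the adjacent even ploidy.
    """
    if not np.isfinite(rgs) or rgs <= 0:
        raise ValueError(f"RGS must be a positive number, got {rgs!r}")
    if rgs < 0.15 or rgs > 0.95:
        return "unknown"
    for lo, hi, call in RGS_BANDS:
        if lo <= rgs <= hi:
            return call
    return "unknown"  # pragma: no cover
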