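"""Synthetic mixed-ploidy RADseq-like datasets with known polyploid origins.

The generator emulates the statistical structure the downstream analyses
assume: six diploid species drifting from shared ancestral allele frequencies
under a two-level Balding-Nichols hierarchy (clade draw, then terminal draw)
matching the topology (CAM,((PAL,SUD),(TAU,(DIF,EXS)))), with the
(TAU,DIF,EXS) clade weakly differentiated; allotetraploids formed as the sum
of two independent disomic (HWE) subgenomes; an autotetraploid control with
tetrasomic Binomial(4, p) dosages; an allohexaploid with three subgenomes;
optional admixture edges between species frequencies; Poisson (optionally
negative-binomial) read depths with symmetric base error.

Ground truth (parent species, inheritance mode, per-sample subgenome dosage
decomposition) is carried in :class:`SimTruth` so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variants_io import (
    SITE_COLUMNS,
    AlleleDepthMatrix,
    GenotypeMatrix,
    SampleRecord,
    write_popmap,
    write_vcf,
)

DEFAULT_SPECIES = ("CAM", "PAL", "SUD", "TAU", "DIF", "EXS")
#: clade grouping implied by the default topology (CAM,((PAL,SUD),(TAU,(DIF,EXS))))
DEFAULT_CLADES = {
    "CAM": ("CAM",),
    "PALSUD": ("PAL", "SUD"),
    "DET": ("TAU", "DIF", "EXS"),
}
#: terminal drift: weak within the DET clade, stronger elsewhere
DEFAULT_DIVERGENCE = {"CAM": 0.15, "PAL": 0.15, "SUD": 0.15, "TAU": 0.05, "DIF": 0.05, "EXS": 0.05}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``divergence`` maps each species to its Balding-Nichols drift parameter
    F in (0,1); ``clade_f`` is the shared clade-level drift. ``gene_flow_edges``
    are (donor, recipient, m) admixture proportions applied to species
    frequencies. ``mean_depth`` is the Poisson mean reads/site; ``error_rate``
    the symmetric per-read base error; ``missing_rate`` the post-hoc
    per-genotype missingness. The same seed yields byte-identical outputs.
    """

    species_labels: tuple = DEFAULT_SPECIES
    clades: dict = field(default_factory=lambda: dict(DEFAULT_CLADES))
    clade_f: float = 0.02
    divergence: dict = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    gene_flow_edges: tuple = ()
    n_loci: int = 5000
    n_chromosomes: int = 6
    samples_per_population: int = 20
    mean_depth: float = 60.0
    error_rate: float = 0.01
    missing_rate: float = 0.1
    depth_dispersion: float | None = None
    min_spacing_bp: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.species_labels:
            f = self.divergence.get(s)
            if f is None or not (0 < f < 1):
                raise ValueError(f"divergence F for {s!r} must lie strictly in (0,1)")
        if not (0 < self.clade_f < 1):
            raise ValueError("clade_f must lie strictly in (0,1)")
        for donor, recipient, m in self.gene_flow_edges:
            if not (0 <= m <= 1):
                raise ValueError(f"gene-flow proportion m={m} outside [0,1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        in_clades = [s for members in self.clades.values() for s in members]
        if sorted(in_clades) != sorted(self.species_labels):
            raise ValueError("clades must partition species_labels")


@dataclass
class SpeciesFrequencyTable:
    """Per-species, per-locus alternative-allele frequencies plus site metadata."""

    species: list[str]
    freq: np.ndarray  # (n_species, n_loci) in [0,1]
    sites: pd.DataFrame  # columns chrom, pos, ref, alt, locus
    p0: np.ndarray | None = None  # ancestral frequencies, for diagnostics

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.species), len(self.sites)):
            raise ValueError("freq shape does not match species x sites")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("frequencies outside [0,1]")

    @property
    def n_loci(self) -> int:
        return len(self.sites)

    def index_of(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def freq_of(self, species: str) -> np.ndarray:
        return self.freq[self.index_of(species)]


@dataclass
class SimTruth:
    """Ground truth for one simulated polyploid population.

    ``subgenome_dosage`` maps a subgenome key (parent species label, suffixed
    when a parent contributes twice) to its (n_samples, n_loci) dosage array;
    the per-subgenome dosages sum to the total dosage at every site.
    """

    population: str
    parents: tuple
    inheritance_mode: str  # "disomic" | "tetrasomic"
    subgenome_dosage: dict

    def total_dosage(self) -> np.ndarray:
        return sum(self.subgenome_dosage.values())


# ---------------------------------------------------------------------------
# Species frequencies
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw drifted frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); degenerate p kept fixed."""
    c = (1.0 - f) / f
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]
    pi = p[interior]
    out[interior] = rng.beta(pi * c, (1.0 - pi) * c)
    return out


def _site_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    rows = []
    for c, n in enumerate(per_chrom, start=1):
        gaps = config.min_spacing_bp + rng.integers(0, 851, size=n)
        pos = np.cumsum(gaps)
        chrom = f"chr{c}"
        for p in pos:
            rows.append((chrom, int(p), f"{chrom}_{int(p) // 500}"))
    alleles = np.array([rng.choice(4, size=2, replace=False) for _ in range(config.n_loci)])
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "locus"])
    sites["ref"] = _BASES[alleles[:, 0]]
    sites["alt"] = _BASES[alleles[:, 1]]
    return sites[SITE_COLUMNS]


def draw_species_frequencies(config: SimConfig) -> SpeciesFrequencyTable:
    """Hierarchical Balding-Nichols frequency draw.

    Per locus an ancestral frequency p0 ~ U(0.05, 0.95) is drawn; each clade
    draws an intermediate frequency with drift ``clade_f`` from p0, and each
    species drifts from its clade's intermediate with its terminal F.
    """
    rng = np.random.default_rng(config.seed)
    p0 = rng.uniform(0.05, 0.95, size=config.n_loci)
    sites = _site_table(config, rng)
    freq = np.empty((len(config.species_labels), config.n_loci))
    order = {s: i for i, s in enumerate(config.species_labels)}
    for clade in sorted(config.clades):
        members = config.clades[clade]
        p_clade = _balding_nichols(rng, p0, config.clade_f)
        for s in sorted(members):
            freq[order[s]] = _balding_nichols(rng, p_clade, config.divergence[s])
    table = SpeciesFrequencyTable(list(config.species_labels), freq, sites, p0=p0)
    for donor, recipient, m in config.gene_flow_edges:
        table = apply_gene_flow(table, donor, recipient, m)
    return table


def apply_gene_flow(table: SpeciesFrequencyTable, donor: str, recipient: str, m: float) -> SpeciesFrequencyTable:
    """Admix the recipient's frequencies toward the donor's: (1-m) p_r + m p_d."""
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    if not (0 <= m <= 1):
        raise ValueError(f"m={m} outside [0,1]")
    i_d, i_r = table.index_of(donor), table.index_of(recipient)
    freq = table.freq.copy()
    freq[i_r] = (1.0 - m) * freq[i_r] + m * freq[i_d]
    return SpeciesFrequencyTable(list(table.species), freq, table.sites, p0=table.p0)


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def _records(label: str, species: str, ploidy: int, n: int) -> list[SampleRecord]:
    return [SampleRecord(f"{label}_{i:03d}", label, species, ploidy) for i in range(n)]


def sample_diploid_genotypes(table: SpeciesFrequencyTable, species: str, n: int, seed: int) -> GenotypeMatrix:
    """n diploid samples with dosage ~ Binomial(2, p_species) per locus."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = table.freq_of(species)
    dosage = rng.binomial(2, p, size=(n, table.n_loci))
    return GenotypeMatrix(_records(species, species, 2, n), table.sites.copy(), dosage)


def sample_allotetraploid(
    table: SpeciesFrequencyTable, parent_a: str, parent_b: str, n: int, seed: int, name: str | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Allotetraploid: two independent HWE subgenomes, no homoeologous exchange."""
    if parent_a == parent_b:
        raise ValueError("allotetraploid parents must differ")
    rng = np.random.default_rng(seed)
    name = name or f"{parent_a}x{parent_b}"
    xa = rng.binomial(2, table.freq_of(parent_a), size=(n, table.n_loci))
    xb = rng.binomial(2, table.freq_of(parent_b), size=(n, table.n_loci))
    g = GenotypeMatrix(_records(name, name, 4, n), table.sites.copy(), xa + xb)
    truth = SimTruth(name, (parent_a, parent_b), "disomic", {parent_a: xa, parent_b: xb})
    return g, truth


def sample_autotetraploid(
    table: SpeciesFrequencyTable, parent: str, n: int, seed: int, name: str | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Autotetraploid: tetrasomic inheritance, dosage ~ Binomial(4, p_parent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    name = name or f"{parent}auto"
    dosage = rng.binomial(4, table.freq_of(parent), size=(n, table.n_loci))
    g = GenotypeMatrix(_records(name, name, 4, n), table.sites.copy(), dosage)
    truth = SimTruth(name, (parent,), "tetrasomic", {parent: dosage.copy()})
    return g, truth


def sample_allohexaploid(
    table: SpeciesFrequencyTable, parent_a: str, parent_b: str, parent_c: str, n: int, seed: int,
    name: str | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Allohexaploid: three independent disomic subgenomes."""
    parents = (parent_a, parent_b, parent_c)
    if len(set(parents)) != 3:
        raise ValueError("allohexaploid parents must be three distinct species")
    rng = np.random.default_rng(seed)
    name = name or "x".join(parents)
    sub = {p: rng.binomial(2, table.freq_of(p), size=(n, table.n_loci)) for p in parents}
    g = GenotypeMatrix(_records(name, name, 6, n), table.sites.copy(), sum(sub.values()))
    return g, SimTruth(name, parents, "disomic", sub)


def stack_samples(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate sample sets sharing one site table."""
    first = matrices[0]
    for m in matrices[1:]:
        if not first.sites[["chrom", "pos"]].equals(m.sites[["chrom", "pos"]]):
            raise ValueError("site tables differ between matrices")
    samples = [s for m in matrices for s in m.samples]
    return GenotypeMatrix(samples, first.sites.copy(), np.vstack([m.dosage for m in matrices]))


# ---------------------------------------------------------------------------
# Read depths and missingness
# ---------------------------------------------------------------------------

def simulate_read_depths(
    g: GenotypeMatrix, mean_depth: float, error_rate: float, seed: int,
    dispersion: float | None = None,
) -> AlleleDepthMatrix:
    """RADseq-like allele depths.

    Total depth t ~ Poisson(mean_depth) (negative binomial with the given
    dispersion r when requested, mean preserved); alternative reads
    ~ Binomial(t, pi) with pi = (d/k)(1-e) + (1-d/k)e for dosage d, ploidy k
    and base error e. Missing genotypes get zero depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    shape = g.dosage.shape
    if dispersion is None:
        total = rng.poisson(mean_depth, size=shape)
    else:
        total = rng.negative_binomial(dispersion, dispersion / (dispersion + mean_depth), size=shape)
    frac = np.where(np.isnan(g.dosage), 0.0, g.dosage) / g.ploidy[:, None]
    pi = frac * (1 - error_rate) + (1 - frac) * error_rate
    total = np.where(np.isnan(g.dosage), 0, total)
    alt = rng.binomial(total, pi)
    return AlleleDepthMatrix(total - alt, alt)


def inject_missing(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype missing independently with the given probability."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    dosage = g.dosage.copy()
    dosage[rng.random(dosage.shape) < rate] = np.nan
    return GenotypeMatrix(g.samples, g.sites.copy(), dosage)


# ---------------------------------------------------------------------------
# IUPAC alignments
# ---------------------------------------------------------------------------

def genotypes_to_alignments(
    g: GenotypeMatrix, regions_per_chromosome: int = 20, background_length: int = 60, seed: int = 0
):
    """Per-region multi-sample IUPAC alignments from called dosages.

    Heterozygous genotypes (0 < dosage < ploidy) become the two-allele
    ambiguity code, homozygous ones the plain base, missing ones 'N'.
    ``background_length`` monomorphic bases shared by every sample are mixed
    into each region so the alignments resemble RAD loci rather than bare
    SNP strings.
    """
    from .polarize import IUPACAlignment, iupac_code, split_regions

    rng = np.random.default_rng(seed)
    positions = {c: sub["pos"].to_numpy() for c, sub in g.sites.groupby("chrom", sort=False)}
    regions = split_regions(positions, regions_per_chromosome)
    site_lookup = {(r["chrom"], r["pos"]): j for j, r in g.sites.iterrows()}
    ploidy = g.ploidy

    out = []
    for region in regions.regions:
        snp_idx = [site_lookup[(region.chrom, p)] for p in region.snp_positions]
        n_cols = len(snp_idx) + background_length
        cols = np.empty((g.n_samples, n_cols), dtype="<U1")
        bg = rng.choice(_BASES, size=background_length)
        # deterministic interleave: background split evenly between SNP columns
        per_gap = np.full(len(snp_idx) + 1, background_length // (len(snp_idx) + 1))
        per_gap[: background_length % (len(snp_idx) + 1)] += 1
        col = 0
        bpos = 0
        for s_i, j in enumerate([None] + snp_idx):
            if s_i > 0:
                site = g.sites.iloc[j]
                ref, alt = site["ref"], site["alt"]
                het_code = iupac_code(ref, alt)
                d = g.dosage[:, j]
                chars = np.where(
                    np.isnan(d), "N",
                    np.where(d == 0, ref, np.where(d == ploidy, alt, het_code)),
                )
                cols[:, col] = chars
                col += 1
            gap = per_gap[s_i]
            cols[:, col : col + gap] = bg[bpos : bpos + gap]
            col += gap
            bpos += gap
        seqs = {name: "".join(cols[i]) for i, name in enumerate(g.sample_ids)}
        out.append(IUPACAlignment(region=region, sequences=seqs))
    return out


# ---------------------------------------------------------------------------
# Study-level orchestration
# ---------------------------------------------------------------------------

def parent_inference_config(**overrides) -> SimConfig:
    """Default configuration for parent-recovery studies.

    Extends the six-species default with a NIV-analog outgroup (its own
    clade, strong drift F = 0.30) so polarization locus trees can be rooted.
    """
    clades = dict(DEFAULT_CLADES)
    clades["NIV"] = ("NIV",)
    divergence = dict(DEFAULT_DIVERGENCE)
    divergence["NIV"] = 0.30
    base = dict(
        species_labels=DEFAULT_SPECIES + ("NIV",),
        clades=clades,
        divergence=divergence,
        n_loci=6000,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimBundle:
    """One fully simulated study: genotypes, depths, truths and frequencies."""

    config: SimConfig
    table: SpeciesFrequencyTable
    genotypes: GenotypeMatrix
    depths: AlleleDepthMatrix
    truths: list


def simulate_study(
    config: SimConfig,
    polyploids: Sequence[dict] = (
        {"kind": "allotetraploid", "parents": ("TAU", "PAL")},
        {"kind": "autotetraploid", "parents": ("PAL",)},
        {"kind": "allohexaploid", "parents": ("TAU", "PAL", "CAM")},
    ),
) -> SimBundle:
    """Simulate diploid species plus the requested polyploid populations.

    Each polyploid spec is a dict with ``kind`` in {allotetraploid,
    autotetraploid, allohexaploid}, ``parents`` and optional ``name``/``n``.
    """
    table = draw_species_frequencies(config)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(2 * (len(config.species_labels) + len(polyploids)) + 4) % (2**31)]
    it = iter(seeds)

    mats = [
        sample_diploid_genotypes(table, s, config.samples_per_population, next(it))
        for s in config.species_labels
    ]
    truths = []
    samplers = {
        "allotetraploid": sample_allotetraploid,
        "autotetraploid": sample_autotetraploid,
        "allohexaploid": sample_allohexaploid,
    }
    for spec_ in polyploids:
        fn = samplers[spec_["kind"]]
        kwargs = {"name": spec_.get("name")} if spec_.get("name") else {}
        n = spec_.get("n", config.samples_per_population)
        g, truth = fn(table, *spec_["parents"], n, next(it), **kwargs)
        mats.append(g)
        truths.append(truth)

    g_all = stack_samples(mats)
    depths = simulate_read_depths(
        g_all, config.mean_depth, config.error_rate, next(it), dispersion=config.depth_dispersion
    )
    if config.missing_rate > 0:
        g_all = inject_missing(g_all, config.missing_rate, next(it))
    return SimBundle(config, table, g_all, depths, truths)


def write_study(bundle: SimBundle, outdir: str | Path) -> None:
    """Write VCF, per-sample FASTA consensus, popmap TSV and truth JSON."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(bundle.genotypes, bundle.depths, outdir / "simulated.vcf")
    write_popmap(bundle.genotypes.samples, outdir / "popmap.tsv")

    alignments = genotypes_to_alignments(bundle.genotypes, seed=bundle.config.seed)
    per_sample: dict[str, list[str]] = {s: [] for s in bundle.genotypes.sample_ids}
    for aln in alignments:
        for name, seq in aln.sequences.items():
            per_sample[name].append(seq)
    records = [
        SeqRecord(Seq("".join(chunks)), id=name, description="synthetic IUPAC consensus")
        for name, chunks in per_sample.items()
    ]
    SeqIO.write(records, str(outdir / "consensus.fasta"), "fasta")

    truth = {
        t.population: {
            "parents": list(t.parents),
            "inheritance_mode": t.inheritance_mode,
        }
        for t in bundle.truths
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
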