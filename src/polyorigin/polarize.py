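"""Genomic polarization and iterative inference of allopolyploid parents.

A polyploid's IUPAC consensus sequence is *polarized* against a reference
species: every heterozygous position where the reference carries one of the
two alleles is replaced by the other allele, masking the variation shared
with the reference and retaining the haplotype fraction that deviates from
it. If the reference is one parent of an allotetraploid, the polarized
sequence resembles the second parent. Locus trees built from polarized
per-region alignments then place the polyploid sister to that second parent,
and iterating the choice of reference (next reference = current sister)
converges on the parental pair.

Locus trees are neighbor-joining trees on an ambiguity-aware p-distance
(match score between two IUPAC symbols = |allele-set intersection| /
|allele-set union|); the species-tree summary is a greedy majority-rule
consensus with clade frequencies as support. Both engines are pluggable:
externally computed newick trees may be fed to the pairing/iteration layer.
"""

from __future__ import annotations

import io
import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .variants_io import AlleleDepthMatrix, GenotypeMatrix

logger = logging.getLogger("polyorigin")

# ---------------------------------------------------------------------------
# IUPAC machinery
# ---------------------------------------------------------------------------

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
#: IUPAC symbol -> allele bitmask; gap/missing ('-', '?') -> 0, 'N' -> all four
IUPAC_TO_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14,
    "N": 15, "-": 0, "?": 0,
}
BITS_TO_IUPAC = {v: k for k, v in IUPAC_TO_BITS.items() if k not in "?"}

_CHAR_CODE = np.zeros(256, dtype=np.uint8)
for ch, b in IUPAC_TO_BITS.items():
    _CHAR_CODE[ord(ch)] = b
    _CHAR_CODE[ord(ch.lower())] = b
_CODE_CHAR = np.array([BITS_TO_IUPAC[i] for i in range(16)])

_POPCOUNT = np.array([bin(i).count("1") for i in range(16)])

#: polarization map: out = POLARIZE_TABLE[poly_code, ref_code]
POLARIZE_TABLE = np.empty((16, 16), dtype=np.uint8)
for pc in range(16):
    for rc in range(16):
        if _POPCOUNT[pc] == 2 and _POPCOUNT[rc] == 1 and (pc & rc):
            POLARIZE_TABLE[pc, rc] = pc & ~rc
        else:
            POLARIZE_TABLE[pc, rc] = pc

#: ambiguity-aware match score |intersection| / |union|; NaN where either
#: symbol is missing (gap or N), so those columns can be excluded
MATCH_SCORE = np.full((16, 16), np.nan)
for a in range(1, 15):
    for b in range(1, 15):
        MATCH_SCORE[a, b] = _POPCOUNT[a & b] / _POPCOUNT[a | b]


def iupac_code(base_a: str, base_b: str) -> str:
    """Two-allele ambiguity code (e.g. A,G -> R); identical bases return themselves."""
    return BITS_TO_IUPAC[_BIT[base_a.upper()] | _BIT[base_b.upper()]]


def encode(seq: str) -> np.ndarray:
    """IUPAC string -> uint8 allele-bitmask array."""
    return _CHAR_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_CHAR[codes])


# ---------------------------------------------------------------------------
# Regions and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A contiguous chromosome slice (1-based closed) holding a block of SNPs."""

    chrom: str
    start: int
    end: int
    snp_positions: tuple

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class RegionSet:
    regions: list

    def __len__(self) -> int:
        return len(self.regions)

    def by_chrom(self) -> dict:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


@dataclass
class IUPACAlignment:
    """Equal-length per-sample sequences over the IUPAC alphabet for one region."""

    region: Region
    sequences: dict  # sample id -> str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in region {self.region.id}")


def split_regions(positions_by_chrom: Mapping[str, Sequence[int]], regions_per_chromosome: int = 20) -> RegionSet:
    """Partition each chromosome into regions with equal numbers of SNPs.

    Block sizes are floor or ceil of n/k with the larger blocks first; region
    boundaries fall midway between adjacent SNPs of neighboring blocks, so
    regions are disjoint and jointly cover every SNP.
    """
    regions = []
    for chrom in positions_by_chrom:
        pos = np.asarray(positions_by_chrom[chrom], dtype=int)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"SNP positions on {chrom} must be strictly increasing")
        n, k = len(pos), regions_per_chromosome
        if n < k:
            raise ValueError(f"chromosome {chrom}: {n} SNPs < {k} regions")
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for b in range(k):
            block = pos[bounds[b] : bounds[b + 1]]
            start = 1 if b == 0 else (pos[bounds[b] - 1] + block[0]) // 2 + 1
            end = int(block[-1]) if b == k - 1 else (block[-1] + pos[bounds[b + 1]]) // 2
            regions.append(Region(chrom, int(start), int(end), tuple(int(p) for p in block)))
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# Consensus and polarization
# ---------------------------------------------------------------------------

def consensus_from_depths(d: AlleleDepthMatrix, g: GenotypeMatrix, sample: str, min_dp: int = 5) -> np.ndarray:
    """Per-site IUPAC consensus call for one sample.

    Sites with total depth below ``min_dp`` (default 5) or a missing genotype
    are 'N'; heterozygous dosages get the two-allele ambiguity code.
    """
    i = g.sample_index(sample)
    k = g.samples[i].ploidy
    dos = g.dosage[i]
    total = d.total_depth[i]
    ref = g.sites["ref"].to_numpy()
    alt = g.sites["alt"].to_numpy()
    het = np.array([iupac_code(r, a) for r, a in zip(ref, alt)])
    call = np.where(dos == 0, ref, np.where(dos == k, alt, het))
    call = np.where(np.isnan(dos) | (total < min_dp), "N", call)
    return call


def polarize_sequence(polyploid_seq: str, reference_seq: str) -> str:
    """Polarize a polyploid IUPAC sequence against an unambiguous reference.

    Per column: a two-allele ambiguity code whose set contains the (single,
    unambiguous) reference base becomes the *other* allele; every other
    combination — homozygous polyploid base, reference not among the two
    alleles, reference N/gap/ambiguous, polyploid N/gap — is left unchanged.
    """
    if len(polyploid_seq) != len(reference_seq):
        raise ValueError(
            f"sequence lengths differ: {len(polyploid_seq)} vs {len(reference_seq)}"
        )
    return decode(POLARIZE_TABLE[encode(polyploid_seq), encode(reference_seq)])


# ---------------------------------------------------------------------------
# Distances and locus trees
# ---------------------------------------------------------------------------

def _pairwise_distance(a: np.ndarray, b: np.ndarray, ambiguity: str = "jaccard") -> float:
    """1 - mean ambiguity-aware match over comparable columns (N/gap excluded)."""
    scores = MATCH_SCORE[a, b]
    if ambiguity == "missing":
        bad = (_POPCOUNT[a] > 1) | (_POPCOUNT[b] > 1)
        scores = np.where(bad, np.nan, scores)
    ok = ~np.isnan(scores)
    if not ok.any():
        return 0.0
    return float(1.0 - scores[ok].mean())


def distance_matrix(sequences: Mapping[str, str], ambiguity: str = "jaccard") -> tuple[list, np.ndarray]:
    names = list(sequences)
    codes = [encode(sequences[n]) for n in names]
    m = len(names)
    dm = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        dm[i, j] = dm[j, i] = _pairwise_distance(codes[i], codes[j], ambiguity)
    return names, dm


def _nj_tree(names: list, dm: np.ndarray, outgroup: str) -> dendropy.Tree:
    if len(names) < 4:
        raise ValueError(f"need >= 4 sequences for a locus tree, got {len(names)}")
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among sequences")
    if np.allclose(dm, 0):
        warnings.warn("all sequences identical: star tree with zero branch lengths")
    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i, n in enumerate(names):
        buf.write(n + "," + ",".join(f"{dm[i, j]:.10f}" for j in range(len(names))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, is_first_row_column_names=True, is_first_column_row_names=True
    )
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    og = next(l for l in tree.leaf_node_iter() if l.taxon.label == outgroup)
    tree.reroot_at_edge(og.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def locus_tree(alignment: IUPACAlignment, outgroup: str, ambiguity: str = "jaccard") -> dendropy.Tree:
    """Neighbor-joining tree for one region, rooted on the outgroup.

    Distance between two sequences is one minus the mean per-column match
    score |set intersection| / |set union|; columns with N or a gap in either
    sequence are excluded. Negative NJ branch lengths are clamped to zero.
    """
    names, dm = distance_matrix(alignment.sequences, ambiguity)
    return _nj_tree(names, dm, outgroup)


# ---------------------------------------------------------------------------
# Sisters, pairing frequencies and the consensus summary tree
# ---------------------------------------------------------------------------

def _leaf_labels(node) -> list:
    return [l.taxon.label for l in node.leaf_iter()]


def sister_of(
    tree: dendropy.Tree,
    focal: str,
    clades: Mapping[str, Sequence[str]] | None = None,
    species_of: Mapping[str, str] | None = None,
) -> str:
    """Label of the focal tip's sibling subtree.

    The sibling's taxa are mapped to species via ``species_of`` (identity by
    default); a single species maps to itself, otherwise the smallest named
    clade covering the set is reported, else ``"unresolved"``.
    """
    leaf = next((l for l in tree.leaf_node_iter() if l.taxon.label == focal), None)
    if leaf is None:
        raise ValueError(f"focal taxon {focal!r} absent from tree")
    parent = leaf.parent_node
    if parent is None:
        raise ValueError(f"focal taxon {focal!r} is the root")
    sibs = [c for c in parent.child_nodes() if c is not leaf]
    taxa = [t for c in sibs for t in _leaf_labels(c)]
    species = {(species_of or {}).get(t, t) for t in taxa}
    if len(species) == 1:
        return species.pop()
    if clades:
        covering = [(len(members), name) for name, members in clades.items() if species <= set(members)]
        if covering:
            return min(covering)[1]
    return "unresolved"


def pairing_frequencies(
    trees: Sequence[dendropy.Tree],
    focal: str,
    clades: Mapping[str, Sequence[str]] | None = None,
    species_of: Mapping[str, str] | None = None,
) -> dict:
    """Tally of the focal taxon's sister label across locus trees."""
    if not trees:
        raise ValueError("no trees given")
    counts: dict[str, int] = {}
    for t in trees:
        lab = sister_of(t, focal, clades=clades, species_of=species_of)
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def summary_tree(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Greedy majority-rule consensus of rooted trees on one leaf set.

    Clades are added in order of decreasing frequency (ties broken by clade
    size then labels) when compatible with those already accepted; node
    supports are the clade frequencies.
    """
    if not trees:
        raise ValueError("no trees given")
    leafsets = [frozenset(_leaf_labels(t.seed_node)) for t in trees]
    full = leafsets[0]
    if any(ls != full for ls in leafsets):
        raise ValueError("trees have differing leaf sets")
    n = len(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for node in t.preorder_node_iter():
            labs = frozenset(_leaf_labels(node))
            if 1 < len(labs) < len(full):
                counts[labs] = counts.get(labs, 0) + 1
    accepted: list[tuple[frozenset, float]] = []
    for clade, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))):
        if all(c.isdisjoint(clade) or c <= clade or clade <= c for c, _ in accepted):
            accepted.append((clade, cnt / n))
    support = {c: s for c, s in accepted}

    def build(members: frozenset, sup: float | None) -> str:
        children = []
        inner = sorted((c for c in support if c < members), key=len, reverse=True)
        used: set = set()
        for c in inner:
            if not (c & used):
                children.append(build(c, support[c]))
                used |= c
        for leaf in sorted(members - used):
            children.append(leaf)
        lab = "" if sup is None else f"{sup:.4f}"
        return "(" + ",".join(children) + ")" + lab

    newick = build(full, None) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Iterative parent inference
# ---------------------------------------------------------------------------

@dataclass
class PolarizationIteration:
    """Audit record of one round of the reference-iteration loop."""

    index: int
    reference: str
    pairing_counts: dict
    sister: str
    next_reference: str
    converged: bool
    summary_newick: str = ""


def _call_rate(seq: str) -> float:
    codes = encode(seq)
    return float(np.mean((codes != 0) & (codes != 15)))


def choose_representatives(
    alignments: Sequence[IUPACAlignment], species_of: Mapping[str, str]
) -> dict:
    """One representative sample per species: highest overall call rate."""
    rates: dict[str, float] = {}
    lengths: dict[str, int] = {}
    for aln in alignments:
        for name, seq in aln.sequences.items():
            codes = encode(seq)
            rates[name] = rates.get(name, 0.0) + int(((codes != 0) & (codes != 15)).sum())
            lengths[name] = lengths.get(name, 0) + len(seq)
    best: dict[str, tuple[float, str]] = {}
    for name in sorted(rates):
        sp = species_of.get(name, name)
        rate = rates[name] / lengths[name]
        if sp not in best or rate > best[sp][0]:
            best[sp] = (rate, name)
    return {sp: name for sp, (_, name) in best.items()}


def iterate_parents(
    alignments: Sequence[IUPACAlignment],
    focal: str,
    candidates: Sequence[str],
    start_reference: str,
    outgroup: str,
    clades: Mapping[str, Sequence[str]] | None = None,
    species_of: Mapping[str, str] | None = None,
    ploidy_of: Mapping[str, int] | None = None,
    max_iter: int = 6,
    ambiguity: str = "jaccard",
) -> tuple[list, tuple | None]:
    """Iterative genomic polarization until the parental pair stabilizes.

    Each round polarizes the focal polyploid against the current reference
    species in every region, infers NJ locus trees, summarizes them with the
    greedy consensus, and takes the focal's sister in the summary tree as the
    next reference (when the sister is a named clade, the within-clade
    species with the most locus-tree pairings is used). The loop converges
    when the unordered pair {reference, sister} repeats between consecutive
    rounds; that pair is reported as the parents. Hexaploids are rejected:
    the two-allele polarization rule assumes exactly two subgenomes.
    """
    species_of = dict(species_of or {})
    if start_reference not in candidates:
        raise ValueError(f"start_reference {start_reference!r} not among candidates")
    if ploidy_of is not None:
        k = ploidy_of.get(focal)
        if k is not None and k != 4:
            raise ValueError(f"focal {focal!r} has ploidy {k}; polarization applies to tetraploids only")

    reps = choose_representatives(alignments, species_of)
    needed = list(candidates) + [outgroup]
    missing = [sp for sp in needed if sp not in reps]
    if missing:
        raise ValueError(f"no representative sample for species: {missing}")
    focal_species = species_of.get(focal, focal)

    # encode once: focal + one representative per needed species, per region
    region_codes = []
    for aln in alignments:
        entry = {"focal": encode(aln.sequences[focal])}
        for sp in needed:
            entry[sp] = encode(aln.sequences[reps[sp]])
        region_codes.append(entry)

    tip_names = [focal_species] + [sp for sp in needed]
    iterations: list[PolarizationIteration] = []
    parents: tuple | None = None
    reference = start_reference
    prev_pair: frozenset | None = None

    for t in range(1, max_iter + 1):
        trees = []
        for entry in region_codes:
            pol = POLARIZE_TABLE[entry["focal"], entry[reference]]
            codes = [pol] + [entry[sp] for sp in needed]
            m = len(codes)
            dm = np.zeros((m, m))
            for i, j in itertools.combinations(range(m), 2):
                dm[i, j] = dm[j, i] = _pairwise_distance(codes[i], codes[j], ambiguity)
            trees.append(_nj_tree(tip_names, dm, outgroup))
        counts = pairing_frequencies(trees, focal_species, clades=clades)
        stree = summary_tree(trees)
        sister = sister_of(stree, focal_species, clades=clades)
        next_ref = _resolve_reference(sister, counts, candidates, clades)
        pair = frozenset({reference, next_ref})
        converged = prev_pair is not None and pair == prev_pair
        iterations.append(
            PolarizationIteration(
                index=t,
                reference=reference,
                pairing_counts=counts,
                sister=sister,
                next_reference=next_ref,
                converged=converged,
                summary_newick=stree.as_string(schema="newick").strip(),
            )
        )
        if converged:
            parents = tuple(sorted(pair))
            break
        prev_pair = pair
        reference = next_ref

    if parents is None:
        refs = [it.reference for it in iterations]
        logger.warning(
            "iterate_parents: no convergence within %d iterations; reference cycle %s",
            max_iter, " -> ".join(refs + [iterations[-1].next_reference]),
        )
    return iterations, parents


def _resolve_reference(sister: str, counts: Mapping[str, int], candidates: Sequence[str], clades) -> str:
    """Map a summary-tree sister label to the next reference species."""
    cand = set(candidates)
    if sister in cand:
        return sister
    members = (clades or {}).get(sister, [])
    pool = [sp for sp in members if sp in cand] or sorted(cand)
    # highest species-level pairing count wins; ties break alphabetically
    top = max(counts.get(sp, 0) for sp in pool)
    tied = sorted(sp for sp in pool if counts.get(sp, 0) == top)
    return tied[0]
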