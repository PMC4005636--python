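"""Self-contained synthetic reference sets and mock metagenomes.

Reference genomes are simulated in protein space on a planted four-level
hierarchy (phylum / genus / species / genome).  Each gene family evolves a
root sequence down the hierarchy by exact-count random substitution; the
per-level substitution rates are solved backwards from target pairwise
identities drawn inside configurable per-rank AAI bands, using the
independence approximation identity(a, b) ~ prod(1 - rate) along both paths
from their common ancestor.  A controllable fraction of genes is re-rooted
onto a foreign species ancestor to plant HGT (gene-tree discordance).

Mock metagenomes are nucleotide fragments cut from reverse-translated
genomes with per-base substitution error; gene calls are emitted as GFF3 and
hits as an outfmt-6 TSV whose identities derive from the true sequences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifier import GeneFeature, HitRecord, QueryContig
from .clustering import Gene, PairMatch
from .taxa import Lineage

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical codon per amino acid for reverse translation (standard code).
CODON_FOR_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
def _standard_code() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


#: Full standard genetic code, so substitution errors can be synonymous.
AA_FOR_CODON = _standard_code()
BASES = "ACGT"

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "species": (96.0, 99.0),
    "genus": (65.0, 80.0),
    "phylum": (48.0, 58.0),
    "none": (30.0, 42.0),
}

#: Position of each conservation class within a band (fraction of span).
CLASS_POSITION = {"slow": 0.95, "medium": 0.5, "fast": 0.15}

#: Residue-length range per conservation class.  Conserved (slow) families
#: are long, ribosomal-protein-like genes; this also keeps their
#: cross-phylum identities tight enough that every genome pair retains at
#: least one above-threshold RBM edge.
CLASS_LENGTH_RANGES = {"slow": (250, 400), "medium": (100, 160), "fast": (80, 140)}


class InfeasibleSpecError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonomySpec:
    n_phyla: int = 3
    genera_per_phylum: int = 3
    species_per_genus: int = 3
    genomes_per_species: int = 2
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        lows = [self.bands[k][0] for k in ("none", "phylum", "genus", "species")]
        highs = [self.bands[k][1] for k in ("none", "phylum", "genus", "species")]
        if not all(l < h for l, h in zip(lows, highs)):
            raise InfeasibleSpecError("each band needs low < high")
        if not all(highs[i] < lows[i + 1] for i in range(3)):
            raise InfeasibleSpecError("bands must be ordered none < phylum < genus < species")

    @property
    def n_genomes(self) -> int:
        return (
            self.n_phyla
            * self.genera_per_phylum
            * self.species_per_genus
            * self.genomes_per_species
        )


@dataclass(frozen=True)
class GeneFamilySpec:
    n_families: int = 24
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"slow": 0.25, "medium": 0.5, "fast": 0.25}
    )
    hgt_rate: float = 0.0
    class_length_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(CLASS_LENGTH_RANGES)
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.hgt_rate < 1.0):
            raise InfeasibleSpecError("hgt_rate must lie in [0, 1)")


@dataclass(frozen=True)
class FragmentSpec:
    lengths: tuple[int, ...] = (500, 800, 1000, 1500, 2000)
    error_rate: float = 0.01
    n_fragments: int = 200
    min_gene_overlap_aa: int = 40

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise InfeasibleSpecError("fragment lengths must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise InfeasibleSpecError("error_rate must lie in [0, 0.1]")


@dataclass
class ReferenceSet:
    genes: dict[str, Gene]
    genomes: dict[str, list[str]]  # genome id -> gene accessions
    taxonomy: dict[str, Lineage]
    families: dict[str, list[str]]  # family id -> gene accessions (true clusters)
    gene_family: dict[str, str]
    family_class: dict[str, str]
    hgt_events: list[tuple[str, str, str]]  # (family, genome, donor species path)
    nt_genomes: dict[str, str]
    gene_coords: dict[str, list[tuple[str, int, int]]]  # (accession, start, end) 1-based
    family_length: dict[str, int]

    def gene_to_genome(self) -> dict[str, str]:
        return {acc: g.genome_id for acc, g in self.genes.items()}

    def subset(self, genome_ids: Iterable[str]) -> "ReferenceSet":
        """Restrict the reference to the given genomes (leave-out experiments)."""
        keep = set(genome_ids)
        genes = {a: g for a, g in self.genes.items() if g.genome_id in keep}
        return ReferenceSet(
            genes=genes,
            genomes={g: accs for g, accs in self.genomes.items() if g in keep},
            taxonomy={g: l for g, l in self.taxonomy.items() if g in keep},
            families={
                f: [a for a in accs if a in genes] for f, accs in self.families.items()
            },
            gene_family={a: f for a, f in self.gene_family.items() if a in genes},
            family_class=dict(self.family_class),
            hgt_events=[e for e in self.hgt_events if e[1] in keep],
            nt_genomes={g: s for g, s in self.nt_genomes.items() if g in keep},
            gene_coords={g: c for g, c in self.gene_coords.items() if g in keep},
            family_length=dict(self.family_length),
        )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``.

    Substituted residues always change (a random different amino acid), so a
    branch of rate r retains an expected fraction (1 - r) of positions.
    """
    out = seq.copy()
    if rate <= 0.0:
        return out
    n_sites = rng.binomial(seq.size, min(rate, 1.0))
    if n_sites == 0:
        return out
    pos = rng.choice(seq.size, size=n_sites, replace=False)
    for p in pos:
        choices = [a for a in range(20) if a != out[p]]
        out[p] = choices[rng.integers(0, 19)]
    return out


def _band_target(band: tuple[float, float], cls: str, rng: np.random.Generator) -> float:
    lo, hi = band
    pos = CLASS_POSITION[cls]
    jitter = rng.uniform(-0.03, 0.03)
    return lo + (hi - lo) * float(np.clip(pos + jitter, 0.02, 0.98))


def _level_rates(targets: dict[str, float]) -> dict[str, float]:
    """Per-level substitution rates from target identities (fractions).

    identity(same species)   = (1 - r_genome)^2
    identity(same genus)     = (1 - r_species)^2 * identity(same species)
    identity(same phylum)    = (1 - r_genus)^2   * identity(same genus)
    identity(cross phyla)    = (1 - r_phylum)^2  * identity(same phylum)
    """
    i_sp, i_ge, i_ph, i_no = (
        targets["species"], targets["genus"], targets["phylum"], targets["none"]
    )
    if not (i_no < i_ph < i_ge < i_sp <= 1.0):
        raise InfeasibleSpecError("band targets must be strictly ordered")
    return {
        "genome": 1.0 - math.sqrt(i_sp),
        "species": 1.0 - math.sqrt(i_ge / i_sp),
        "genus": 1.0 - math.sqrt(i_ph / i_ge),
        "phylum": 1.0 - math.sqrt(i_no / i_ph),
    }


def simulate_reference_set(
    tax: TaxonomySpec = TaxonomySpec(),
    fam: GeneFamilySpec = GeneFamilySpec(),
    seed: int = 0,
) -> ReferenceSet:
    """Generate reference genomes with planted taxonomy, AAI structure and HGT."""
    rng = np.random.default_rng(seed)
    # Deterministically proportional class assignment: the conserved (slow)
    # families anchor cross-phylum RBM edges, so their count must not vary
    # with the draw.
    classes = sorted(fam.class_fractions)
    fractions = np.array([fam.class_fractions[c] for c in classes], dtype=float)
    fractions /= fractions.sum()
    counts = np.floor(fractions * fam.n_families).astype(int)
    order = np.argsort(-(fractions * fam.n_families - counts))
    for i in range(fam.n_families - counts.sum()):
        counts[order[i % len(classes)]] += 1
    class_sequence = [c for c, n in zip(classes, counts) for _ in range(n)]
    rng.shuffle(class_sequence)

    # genome labels and lineages
    genome_lineage: dict[str, Lineage] = {}
    species_members: dict[tuple[int, int, int], list[str]] = {}
    for p in range(tax.n_phyla):
        for g in range(tax.genera_per_phylum):
            for s in range(tax.species_per_genus):
                for n in range(tax.genomes_per_species):
                    gid = f"g_p{p}g{g}s{s}n{n}"
                    genome_lineage[gid] = Lineage(
                        phylum=f"Phylum{p}",
                        genus=f"Genus{p}.{g}",
                        species=f"Species{p}.{g}.{s}",
                    )
                    species_members.setdefault((p, g, s), []).append(gid)
    species_keys = sorted(species_members)

    genes: dict[str, Gene] = {}
    genomes: dict[str, list[str]] = {gid: [] for gid in genome_lineage}
    families: dict[str, list[str]] = {}
    gene_family: dict[str, str] = {}
    family_class: dict[str, str] = {}
    family_length: dict[str, int] = {}
    hgt_events: list[tuple[str, str, str]] = []

    for f in range(fam.n_families):
        fid = f"fam{f:03d}"
        cls = class_sequence[f]
        family_class[fid] = cls
        lo, hi = fam.class_length_ranges[cls]
        L = int(rng.integers(lo, hi + 1))
        family_length[fid] = L
        targets = {
            band: _band_target(tax.bands[band], cls, rng) / 100.0
            for band in ("species", "genus", "phylum", "none")
        }
        rates = _level_rates(targets)

        root = rng.integers(0, 20, size=L)
        phylum_anc = {p: _mutate(root, rates["phylum"], rng) for p in range(tax.n_phyla)}
        genus_anc = {
            (p, g): _mutate(phylum_anc[p], rates["genus"], rng)
            for p in range(tax.n_phyla)
            for g in range(tax.genera_per_phylum)
        }
        species_anc = {
            (p, g, s): _mutate(genus_anc[(p, g)], rates["species"], rng)
            for (p, g, s) in species_keys
        }

        # Per-species divergence multipliers: real species differ widely in
        # intra-species diversity, and the D-weight KDEs need that spread.
        species_factor = {
            key: float(rng.uniform(0.5, 1.8)) for key in species_keys
        }

        members: list[str] = []
        for (p, g, s) in species_keys:
            for gid in species_members[(p, g, s)]:
                source = species_anc[(p, g, s)]
                if fam.hgt_rate > 0 and rng.random() < fam.hgt_rate:
                    donors = [key for key in species_keys if key != (p, g, s)]
                    donor = donors[int(rng.integers(0, len(donors)))]
                    source = species_anc[donor]
                    hgt_events.append((fid, gid, f"Species{donor[0]}.{donor[1]}.{donor[2]}"))
                seq_arr = _mutate(
                    source, rates["genome"] * species_factor[(p, g, s)], rng
                )
                seq = "".join(AMINO_ACIDS[a] for a in seq_arr)
                acc = f"{gid}|{fid}"
                genes[acc] = Gene(accession=acc, genome_id=gid, sequence=seq)
                genomes[gid].append(acc)
                members.append(acc)
                gene_family[acc] = fid
        families[fid] = members

    nt_genomes: dict[str, str] = {}
    gene_coords: dict[str, list[tuple[str, int, int]]] = {}
    for gid, accs in genomes.items():
        parts: list[str] = []
        coords: list[tuple[str, int, int]] = []
        pos = 0
        for acc in accs:
            spacer = "".join(BASES[b] for b in rng.integers(0, 4, size=30))
            parts.append(spacer)
            pos += 30
            nt = "".join(CODON_FOR_AA[aa] for aa in genes[acc].sequence)
            coords.append((acc, pos + 1, pos + len(nt)))
            parts.append(nt)
            pos += len(nt)
        nt_genomes[gid] = "".join(parts)
        gene_coords[gid] = coords

    return ReferenceSet(
        genes=genes,
        genomes=genomes,
        taxonomy=genome_lineage,
        families=families,
        gene_family=gene_family,
        family_class=family_class,
        hgt_events=hgt_events,
        nt_genomes=nt_genomes,
        gene_coords=gene_coords,
        family_length=family_length,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent position-wise identity of two equal-length protein sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length (no-indel model)")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    return float((a == b).mean() * 100.0)


def reference_match_table(ref: ReferenceSet, seed: int | None = None) -> list[PairMatch]:
    """All-vs-all within-family match rows over the reference genes.

    Identity is the exact position-wise identity; coverage is 1 (equal-length
    model); the bit-score is the stated monotone function of identity and
    length.  Cross-family comparisons (random-level identity) are omitted.
    """
    out: list[PairMatch] = []
    for fid in sorted(ref.families):
        members = sorted(ref.families[fid])
        for a, b in itertools.combinations(members, 2):
            ident = pairwise_identity(ref.genes[a].sequence, ref.genes[b].sequence)
            L = len(ref.genes[a].sequence)
            bitscore = round(2.0 * L * ident / 100.0, 1)
            evalue = 10.0 ** (-min(180.0, bitscore / 5.0))
            out.append(PairMatch(a, b, round(ident, 2), 1.0, evalue, bitscore))
    return out


@dataclass
class FragmentGene:
    """A gene call on a simulated fragment, with its true protein window."""

    gene_id: str
    fragment_id: str
    family_id: str
    source_accession: str
    aa_start: int  # 0-based window into the family alignment
    aa_end: int  # exclusive
    protein: str  # translated from the (error-bearing) fragment sequence


@dataclass
class Metagenome:
    contigs: list[QueryContig]
    sequences: dict[str, str]  # fragment id -> nucleotide sequence (with errors)
    truth: dict[str, str]  # fragment id -> source genome id
    fragment_genes: list[FragmentGene]
    source_windows: dict[str, tuple[str, int, int]]  # fragment -> (genome, start0, end0)


_STOP = "*"


def _translate(nt: str) -> str:
    aas = []
    for i in range(0, len(nt) - 2, 3):
        aas.append(AA_FOR_CODON.get(nt[i : i + 3], _STOP))
    return "".join(aas)


def simulate_metagenome(
    ref: ReferenceSet,
    frag: FragmentSpec = FragmentSpec(),
    seed: int = 0,
    genome_ids: Sequence[str] | None = None,
) -> Metagenome:
    """Cut error-bearing fragments from the nucleotide genomes.

    Fragments are sampled uniformly (genome, then position); per-base
    substitution errors are applied at ``frag.error_rate``; genes overlapping
    a fragment by at least ``min_gene_overlap_aa`` codons are emitted with
    coordinates clipped to the fragment (1-based inclusive, GFF3 style).
    """
    rng = np.random.default_rng(seed)
    pool = sorted(genome_ids) if genome_ids is not None else sorted(ref.nt_genomes)
    contigs: list[QueryContig] = []
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    fragment_genes: list[FragmentGene] = []
    source_windows: dict[str, tuple[str, int, int]] = {}

    for i in range(frag.n_fragments):
        gid = pool[int(rng.integers(0, len(pool)))]
        genome_nt = ref.nt_genomes[gid]
        length = int(frag.lengths[int(rng.integers(0, len(frag.lengths)))])
        if length > len(genome_nt):
            raise InfeasibleSpecError(
                f"fragment length {length} exceeds genome {gid} length {len(genome_nt)}"
            )
        start = int(rng.integers(0, len(genome_nt) - length + 1))
        window = np.frombuffer(genome_nt[start : start + length].encode(), dtype=np.uint8).copy()
        if frag.error_rate > 0:
            err = rng.random(length) < frag.error_rate
            for p in np.flatnonzero(err):
                current = chr(window[p])
                alternatives = [b for b in BASES if b != current]
                window[p] = ord(alternatives[int(rng.integers(0, 3))])
        frag_seq = window.tobytes().decode()
        frag_id = f"frag{i:05d}"
        sequences[frag_id] = frag_seq
        truth[frag_id] = gid
        source_windows[frag_id] = (gid, start, start + length)

        contig = QueryContig(contig_id=frag_id)
        fs, fe = start + 1, start + length  # 1-based inclusive fragment bounds
        for acc, gs, ge in ref.gene_coords[gid]:
            lo, hi = max(gs, fs), min(ge, fe)
            if hi < lo:
                continue
            aa_lo = math.ceil((lo - gs) / 3)
            aa_hi = (hi - gs + 1) // 3
            if aa_hi - aa_lo < frag.min_gene_overlap_aa:
                continue
            gene_start_on_frag = (gs + 3 * aa_lo) - fs + 1
            gene_end_on_frag = gene_start_on_frag + 3 * (aa_hi - aa_lo) - 1
            gene_id = f"{frag_id}_{len(contig.genes) + 1}"
            contig.genes.append(
                GeneFeature(gene_id, gene_start_on_frag, gene_end_on_frag, "+")
            )
            nt_slice = frag_seq[gene_start_on_frag - 1 : gene_end_on_frag]
            fragment_genes.append(
                FragmentGene(
                    gene_id=gene_id,
                    fragment_id=frag_id,
                    family_id=ref.gene_family[acc],
                    source_accession=acc,
                    aa_start=aa_lo,
                    aa_end=aa_hi,
                    protein=_translate(nt_slice),
                )
            )
        contigs.append(contig)
    return Metagenome(contigs, sequences, truth, fragment_genes, source_windows)


def simulate_hits(
    fragment_genes: Sequence[FragmentGene],
    ref: ReferenceSet,
    noise_sd: float = 0.5,
    seed: int = 0,
    min_identity: float = 25.0,
    exclude_genomes: Iterable[str] = (),
) -> list[HitRecord]:
    """Outfmt-6-style hits of fragment genes against the reference genes.

    pident = true window identity + Gaussian noise (clamped to [0, 100]);
    the bit-score is a fixed monotone function of identity x aligned length,
    so ranking by bit-score follows identity.  Stands in for the external
    similarity search.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    excluded = set(exclude_genomes)
    hits: list[HitRecord] = []
    for fg in fragment_genes:
        query = np.frombuffer(fg.protein.encode(), dtype=np.uint8)
        for acc in sorted(ref.families.get(fg.family_id, ())):
            gene = ref.genes[acc]
            if gene.genome_id in excluded:
                continue
            window = gene.sequence[fg.aa_start : fg.aa_end]
            subject = np.frombuffer(window.encode(), dtype=np.uint8)
            n = min(query.size, subject.size)
            if n == 0:
                continue
            ident = float((query[:n] == subject[:n]).mean() * 100.0)
            if ident < min_identity:
                continue
            pident = float(np.clip(ident + rng.normal(0.0, noise_sd) if noise_sd else ident, 0.0, 100.0))
            bitscore = round(2.0 * n * pident / 100.0, 1)
            evalue = 10.0 ** (-min(180.0, bitscore / 5.0))
            hits.append(
                HitRecord(
                    query_gene_id=fg.gene_id,
                    subject_accession=acc,
                    identity=round(pident, 2),
                    aln_length=n,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Presets

def preset(name: str) -> tuple[TaxonomySpec, GeneFamilySpec, FragmentSpec]:
    if name == "small":
        return (
            TaxonomySpec(
                n_phyla=3, genera_per_phylum=3, species_per_genus=3,
                genomes_per_species=2,
            ),
            GeneFamilySpec(n_families=24, hgt_rate=0.02),
            FragmentSpec(n_fragments=1000),
        )
    if name == "medium":
        return (
            TaxonomySpec(
                n_phyla=4, genera_per_phylum=4, species_per_genus=3,
                genomes_per_species=3,
            ),
            GeneFamilySpec(n_families=40, hgt_rate=0.05),
            FragmentSpec(n_fragments=2000),
        )
    raise ValueError(f"unknown preset: {name!r}")
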