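"""Readers and writers for the external formats.

All tabular files are UTF-8, tab-separated, unquoted.  The weight DB is a
plain-text directory (clusters TSV, weights TSV, KDE point sets as JSON)
with a manifest carrying build parameters and per-file SHA-256 checksums so
truncated copies are rejected at load time.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classifier import ClassificationResult, GeneFeature, HitRecord, QueryContig
from .clustering import Gene, PairMatch
from .taxa import RANKS, Lineage
from .weights import DCurve, RankWeights

logger = logging.getLogger(__name__)

WEIGHT_DB_FORMAT_VERSION = 1

HITS_COLUMNS_12 = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore"
).split()


class FormatError(ValueError):
    """A structurally invalid input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession (first header token) -> sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate accession {rec.id}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Gene accession -> genome id from a two-column TSV (header optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0] in ("accession", "gene_id", "gene"):
                continue
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = parts[1]
    return out


def write_gene_map(gene_to_genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tgenome_id\n")
        for acc, genome in gene_to_genome.items():
            fh.write(f"{acc}\t{genome}\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[QueryContig]:
    """Parse gene/CDS features into contigs; 1-based inclusive coordinates.

    Features of type gene/CDS/mRNA sharing an ID are deduplicated.  A record
    with end < start raises a record-level error naming the line.
    """
    contigs: dict[str, QueryContig] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "CDS", "mRNA"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            gene_id = None
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    if k.strip() in ("ID", "Parent") and gene_id is None:
                        gene_id = v.strip()
                    if k.strip() == "ID":
                        gene_id = v.strip()
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: feature without ID attribute")
            if seqid not in contigs:
                contigs[seqid] = QueryContig(contig_id=seqid)
            if (seqid, gene_id) in seen:
                continue
            seen.add((seqid, gene_id))
            contigs[seqid].genes.append(GeneFeature(gene_id, start, end, strand))
    return list(contigs.values())


def write_gff3(contigs: Sequence[QueryContig], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            for g in contig.genes:
                fh.write(
                    f"{contig.contig_id}\tmytaxa\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Hits (BLAST outfmt 6, optional 13th coverage column)

@dataclass
class HitTable:
    records: list[HitRecord] = field(default_factory=list)
    n_skipped: int = 0


def read_hits(path: str | Path) -> HitTable:
    """Parse an outfmt-6-style TSV; rows with unparsable numerics are skipped
    and counted, never fatal."""
    table = HitTable()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                table.n_skipped += 1
                continue
            try:
                table.records.append(
                    HitRecord(
                        query_gene_id=cols[0],
                        subject_accession=cols[1],
                        identity=float(cols[2]),
                        aln_length=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError:
                table.n_skipped += 1
    return table


def read_matches(path: str | Path, gene_lengths: Mapping[str, int] | None = None) -> list[PairMatch]:
    """Read an all-vs-all search TSV into PairMatch rows.

    Coverage comes from an optional 13th column; otherwise it is computed as
    aligned length / min(query length, subject length) when gene lengths are
    known, else assumed 1.0.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                continue
            qid, sid = cols[0], cols[1]
            ident = float(cols[2])
            aln = int(cols[3])
            evalue = float(cols[10])
            bitscore = float(cols[11])
            if len(cols) >= 13:
                coverage = float(cols[12])
            elif gene_lengths and qid in gene_lengths and sid in gene_lengths:
                shorter = min(gene_lengths[qid], gene_lengths[sid])
                coverage = min(aln / shorter, 1.0) if shorter else 0.0
            else:
                coverage = 1.0
            out.append(PairMatch(qid, sid, ident, coverage, evalue, bitscore))
    return out


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene_id}\t{h.subject_accession}\t{h.identity:.2f}\t"
                f"{h.aln_length}\t0\t0\t1\t{h.aln_length}\t1\t{h.aln_length}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy

_TAX_CORE = ("genome_id", "phylum", "genus", "species")
_TAX_OPTIONAL = ("class", "order", "family")


def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Genome -> lineage from a flat TSV.

    Requires genome_id/phylum/genus/species columns; class/order/family are
    carried as intermediate ranks.  Empty cells mean unranked; duplicate
    genome ids are an error.
    """
    out: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty taxonomy file")
        missing = [c for c in _TAX_CORE if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing taxonomy columns {missing}")
        for row in reader:
            gid = row["genome_id"]
            if gid in out:
                raise FormatError(f"{path}: duplicate genome_id {gid}")
            intermediate = tuple(
                (c, row.get(c, "") or "") for c in _TAX_OPTIONAL if c in reader.fieldnames
            )
            out[gid] = Lineage(
                phylum=row.get("phylum", "") or "",
                genus=row.get("genus", "") or "",
                species=row.get("species", "") or "",
                intermediate=intermediate,
            )
    return out


def write_taxonomy(taxonomy: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tphylum\tgenus\tspecies\n")
        for gid, lin in taxonomy.items():
            fh.write(f"{gid}\t{lin.phylum}\t{lin.genus}\t{lin.species}\n")


# ---------------------------------------------------------------------------
# Results + Krona

RESULT_COLUMNS = (
    "contig_id phylum phylum_score genus genus_score species species_score "
    "lowest_rank novelty_call best_match_aai n_genes n_hits_used"
).split()


def write_results(results: Sequence[ClassificationResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = [r.contig_id]
            for rank in RANKS:
                row.append(r.accepted.get(rank, ""))
                score = r.scores.get(rank)
                row.append(f"{score:.4f}" if score is not None else "")
            row.append(r.lowest_resolved_rank or "")
            row.append(r.novelty_call or "")
            row.append(f"{r.best_match_aai:.2f}" if r.best_match_aai is not None else "")
            row.append(str(r.n_genes))
            row.append(str(r.n_hits_used))
            fh.write("\t".join(row) + "\n")


def write_krona_xml(results: Sequence[ClassificationResult], path: str | Path) -> None:
    """Krona-compatible nested node/count XML over accepted lineages.

    Leaf counts sum to the number of classified contigs; unclassified contigs
    are aggregated under an "Unclassified" node.
    """
    counts: dict[tuple[str, ...], int] = {}
    for r in results:
        lineage = tuple(r.accepted[rank] for rank in RANKS if rank in r.accepted)
        if not lineage:
            lineage = ("Unclassified",)
        counts[lineage] = counts.get(lineage, 0) + 1

    root = ET.Element("krona")
    attrs = ET.SubElement(root, "attributes", magnitude="magnitude")
    attr = ET.SubElement(attrs, "attribute", display="Count")
    attr.text = "magnitude"
    datasets = ET.SubElement(root, "datasets")
    ET.SubElement(datasets, "dataset").text = "mytaxa"

    def node(parent: ET.Element, name: str, magnitude: int) -> ET.Element:
        el = ET.SubElement(parent, "node", name=name)
        mag = ET.SubElement(el, "magnitude")
        ET.SubElement(mag, "val").text = str(magnitude)
        return el

    total = sum(counts.values())
    root_node = node(root, "Root", total)
    tree: dict[tuple[str, ...], ET.Element] = {(): root_node}
    for lineage in sorted(counts):
        for depth in range(1, len(lineage) + 1):
            prefix = lineage[:depth]
            if prefix not in tree:
                magnitude = sum(
                    c for lin, c in counts.items() if lin[:depth] == prefix
                )
                tree[prefix] = node(tree[prefix[:-1]], prefix[-1], magnitude)
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Weight DB directory

_CLUSTERS_FILE = "clusters.tsv"
_WEIGHTS_FILE = "weights.tsv"
_KDE_FILE = "kde.json"
_MANIFEST_FILE = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class WeightDB:
    """In-memory weight database with a plain-text on-disk layout.

    Lookup surface used by the classifier:
      * ``lookup(accession) -> (cluster_id, genome_id) | None``
      * ``rank_weights(cluster_id, rank) -> RankWeights | None``
    """

    def __init__(
        self,
        gene_to_cluster: Mapping[str, str],
        gene_to_genome: Mapping[str, str],
        weights: Mapping[tuple[str, str], RankWeights],
        params: Mapping | None = None,
    ):
        self.gene_to_cluster = dict(gene_to_cluster)
        self.gene_to_genome = dict(gene_to_genome)
        self.weights = dict(weights)
        self.params = dict(params or {})

    def lookup(self, accession: str) -> tuple[str, str] | None:
        cluster = self.gene_to_cluster.get(accession)
        if cluster is None:
            return None
        return cluster, self.gene_to_genome[accession]

    def rank_weights(self, cluster_id: str, rank: str) -> RankWeights | None:
        return self.weights.get((cluster_id, rank))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / _CLUSTERS_FILE, "w", encoding="utf-8") as fh:
            fh.write("cluster_id\taccession\tgenome_id\n")
            for acc in sorted(self.gene_to_cluster):
                fh.write(
                    f"{self.gene_to_cluster[acc]}\t{acc}\t{self.gene_to_genome[acc]}\n"
                )
        with open(directory / _WEIGHTS_FILE, "w", encoding="utf-8") as fh:
            fh.write(
                "cluster_id\trank\tm_value\tm_se\tm_method\tn_intra\tn_inter\t"
                "n_triplets\td_mode\n"
            )
            for (cid, rank), rw in sorted(self.weights.items()):
                mode = rw.d_curve.mode if rw.d_curve is not None else ""
                fh.write(
                    f"{cid}\t{rank}\t{rw.m_value:.10g}\t{rw.m_se:.6g}\t"
                    f"{rw.m_method}\t{rw.n_intra}\t{rw.n_inter}\t{rw.n_triplets}\t"
                    f"{mode}\n"
                )
        kde = {}
        for (cid, rank), rw in self.weights.items():
            if rw.d_curve is None:
                continue
            kde.setdefault(cid, {})[rank] = {
                "intra": list(rw.d_curve.intra),
                "inter": list(rw.d_curve.inter),
                "h_intra": rw.d_curve.h_intra,
                "h_inter": rw.d_curve.h_inter,
                "mode": rw.d_curve.mode,
            }
        with open(directory / _KDE_FILE, "w", encoding="utf-8") as fh:
            json.dump(kde, fh, sort_keys=True)
        manifest = {
            "format_version": WEIGHT_DB_FORMAT_VERSION,
            "params": self.params,
            "n_genes": len(self.gene_to_cluster),
            "n_clusters": len({c for c in self.gene_to_cluster.values()}),
            "sha256": {},
        }
        for name in (_CLUSTERS_FILE, _WEIGHTS_FILE, _KDE_FILE):
            manifest["sha256"][name] = _sha256(directory / name)
        with open(directory / _MANIFEST_FILE, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: str | Path) -> "WeightDB":
        directory = Path(directory)
        manifest_path = directory / _MANIFEST_FILE
        if not manifest_path.exists():
            raise FormatError(
                f"{directory}: not a weight DB (missing {_MANIFEST_FILE})"
            )
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
        version = manifest.get("format_version")
        if version != WEIGHT_DB_FORMAT_VERSION:
            warnings.warn(
                f"weight DB format version {version} != supported "
                f"{WEIGHT_DB_FORMAT_VERSION}; attempting to load anyway",
                stacklevel=2,
            )
        for name, digest in manifest.get("sha256", {}).items():
            actual = _sha256(directory / name)
            if actual != digest:
                raise FormatError(
                    f"{directory / name}: checksum mismatch (truncated or modified file)"
                )

        gene_to_cluster: dict[str, str] = {}
        gene_to_genome: dict[str, str] = {}
        with open(directory / _CLUSTERS_FILE, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                cid, acc, genome = line.rstrip("\n").split("\t")
                gene_to_cluster[acc] = cid
                gene_to_genome[acc] = genome

        with open(directory / _KDE_FILE, encoding="utf-8") as fh:
            kde = json.load(fh)

        weights: dict[tuple[str, str], RankWeights] = {}
        with open(directory / _WEIGHTS_FILE, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                cid, rank, m_value, m_se, m_method, n_intra, n_inter, n_trip, mode = (
                    line.rstrip("\n").split("\t")
                )
                curve = None
                entry = kde.get(cid, {}).get(rank)
                if entry is not None:
                    curve = DCurve(
                        intra=tuple(entry["intra"]),
                        inter=tuple(entry["inter"]),
                        h_intra=entry["h_intra"],
                        h_inter=entry["h_inter"],
                        mode=entry["mode"],
                    )
                weights[(cid, rank)] = RankWeights(
                    cluster_id=cid,
                    rank=rank,
                    d_curve=curve,
                    m_value=float(m_value),
                    m_se=float(m_se),
                    m_method=m_method,
                    n_intra=int(n_intra),
                    n_inter=int(n_inter),
                    n_triplets=int(n_trip),
                )
        return cls(gene_to_cluster, gene_to_genome, weights, manifest.get("params"))


# ---------------------------------------------------------------------------
# AAI long format

def write_aai_long(aai, path: str | Path) -> None:
    import numpy as np

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_a\tgenome_b\taai\tn_rbm\n")
        ids = aai.genome_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                v = aai.values[i, j]
                if np.isnan(v):
                    continue
                fh.write(f"{ids[i]}\t{ids[j]}\t{v:.4f}\t{int(aai.n_shared[i, j])}\n")
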