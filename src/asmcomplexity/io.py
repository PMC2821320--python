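"""Readers and writers for the standard formats around the analysis.

FASTA goes through Biopython; .ptt is the GenBank protein-table dialect
(tab-separated, location column "start..end", 1-based inclusive); GFA 1.0
serializes the multigraph with multiplicities in an RC integer tag and
conversion labels in an LB string tag.  All coordinate conversion to the
internal 0-based half-open convention happens here and nowhere else.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome, GeneAnnotation, DNA_ALPHABET
from .graph import KmerGraph
from .contigs import Contig, N50Report
from .simplify import ReductionStats
from .genes import GeneReconReport

__all__ = [
    "read_fasta", "write_fasta", "read_ptt", "write_ptt", "read_gff3",
    "write_graph_gfa", "read_graph_gfa", "write_contigs_fasta",
    "write_reduction_stats_tsv", "write_n50_tsv", "write_gene_report_tsv",
    "write_manifest_json",
]


class FastaParseError(ValueError):
    pass


def read_fasta(path, topology: str, plasmid_filter: bool = False,
               alphabet: str | None = DNA_ALPHABET) -> list[Genome]:
    """Read genomes from FASTA with an explicit topology.

    Records whose header contains the word "plasmid" (case-insensitive) are
    dropped when `plasmid_filter` is on; sequences are uppercased; symbols
    outside the alphabet raise unless ``alphabet=None``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(f"{path}:{lineno}: expected FASTA header line")
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = f"{rec.id} {rec.description}".lower()
        if plasmid_filter and "plasmid" in header:
            continue
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        genomes.append(Genome(rec.id, seq, topology, alphabet=alphabet))
    return genomes


def write_fasta(genomes: list[Genome], path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_ptt(path) -> list[GeneAnnotation]:
    """Read a GenBank .ptt protein table.

    Header lines are skipped; each data row starts with a "start..end"
    location column, followed by strand, length, PID, gene, synonym, code,
    COG and product columns.
    """
    annots = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue  # title line (may itself contain "1..N")
            loc = fields[0].strip()
            if loc.lower().startswith("location"):
                continue  # column-header line
            if not re.fullmatch(r"\d+\.\.\d+", loc):
                raise ValueError(f"{path}: row {rowno}: unparsable location {loc!r}")
            a, _, b = loc.partition("..")
            start, end = int(a), int(b)
            strand = fields[1].strip() if len(fields) > 1 else "+"
            product = fields[8].strip() if len(fields) > 8 else ""
            synonym = fields[5].strip() if len(fields) > 5 else ""
            pid = fields[3].strip() if len(fields) > 3 else ""
            gene_id = synonym or pid or f"row{rowno}"
            annots.append(GeneAnnotation(gene_id, start, end, strand, product))
    if not annots:
        raise ValueError(f"{path}: no gene rows found (missing location column?)")
    return annots


def write_ptt(annotations: list[GeneAnnotation], path, title: str = "synthetic") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(annotations)} proteins\n")
        fh.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
        for a in annotations:
            fh.write(f"{a.start}..{a.end}\t{a.strand}\t-\t-\t-\t{a.gene_id}\t-\t-\t{a.product}\n")


def read_gff3(path) -> list[GeneAnnotation]:
    """Minimal GFF3 reader: one annotation per CDS (or gene) feature."""
    annots = []
    with open(path) as fh:
        for rowno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: row {rowno}: not a 9-column GFF3 line")
            ftype = fields[2]
            if ftype not in ("CDS", "gene"):
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            gid = attrs.get("locus_tag") or attrs.get("ID") or f"row{rowno}"
            annots.append(GeneAnnotation(gid, int(fields[3]), int(fields[4]),
                                         fields[6], attrs.get("product", "")))
    return annots


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_graph_gfa(graph: KmerGraph, path) -> None:
    """GFA 1.0: segments = node sequences, links = edge groups with the
    multiplicity in an RC:i tag and any conversion label in an LB:Z tag."""
    with open(path, "w") as fh:
        gl = graph.genome_length if graph.genome_length is not None else -1
        fh.write(f"H\tVN:Z:1.0\tKL:i:{graph.k}\tTP:Z:{graph.topology}\tGL:i:{gl}\n")
        for u in sorted(graph.nodes):
            fh.write(f"S\t{u}\t{graph.seq(u)}\n")
        for u, v, label, mult in graph.edge_groups():
            tags = f"RC:i:{mult}"
            if label is not None:
                tags += f"\tLB:Z:{label}"
            fh.write(f"L\t{u}\t+\t{v}\t+\t{graph.k - 2}M\t{tags}\n")


def read_graph_gfa(path) -> KmerGraph:
    k = topology = None
    glen = None
    segments: list[tuple[int, str]] = []
    links: list[tuple[int, int, str | None, int]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "H":
                for tag in fields[1:]:
                    name, typ, val = tag.split(":", 2)
                    if name == "KL":
                        k = int(val)
                    elif name == "TP":
                        topology = val
                    elif name == "GL":
                        glen = None if val == "-1" else int(val)
            elif fields[0] == "S":
                segments.append((int(fields[1]), fields[2]))
            elif fields[0] == "L":
                mult, label = 1, None
                for tag in fields[6:]:
                    name, typ, val = tag.split(":", 2)
                    if name == "RC":
                        mult = int(val)
                    elif name == "LB":
                        label = val
                links.append((int(fields[1]), int(fields[3]), label, mult))
    if k is None or topology is None:
        raise ValueError(f"{path}: missing KL/TP header tags; not written by this package?")
    g = KmerGraph(k, topology, genome_length=glen)
    for nid, seq in segments:
        g.new_node(seq, nid)
    for u, v, label, mult in links:
        g.add_edge(u, v, mult, label)
    g.terminals = g.balance()
    return g


# ---------------------------------------------------------------------------
# Tabular / FASTA outputs
# ---------------------------------------------------------------------------

def write_contigs_fasta(contigs: list[Contig], path) -> None:
    records = [SeqRecord(Seq(c.sequence or ""), id=c.name,
                         description=f"length={c.length}") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def write_reduction_stats_tsv(stats: ReductionStats, path, genome_id: str = "-",
                              k: int | None = None) -> None:
    rows = [{"genome": genome_id, "k": k, "stage": stage, "edges": edges,
             "percent_reduction": round(pct, 4)}
            for stage, edges, pct in stats.rows()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_n50_tsv(report: N50Report, path, genome_id: str = "-",
                  k: int | None = None) -> None:
    pd.DataFrame([{
        "genome": genome_id, "k": k, "contig_count": report.contig_count,
        "n50": report.n50, "relative_n50": round(report.relative_n50, 4),
        "genome_length": report.genome_length,
    }]).to_csv(path, sep="\t", index=False)


def write_gene_report_tsv(report: GeneReconReport, annotations, per_gene_path,
                          summary_path, genome_id: str = "-", k: int | None = None) -> None:
    ann = {a.gene_id: a for a in annotations}
    rows = []
    for gid, rec in report.per_gene.items():
        a = ann.get(gid)
        rows.append({
            "gene_id": gid,
            "start": a.start if a else "-", "end": a.end if a else "-",
            "strand": a.strand if a else "-",
            "reconstructible": rec["reconstructible"], "reason": rec["reason"],
        })
    pd.DataFrame(rows).to_csv(per_gene_path, sep="\t", index=False)
    summary = {"genome": genome_id, "k": k, "n_genes": report.n_genes,
               "n_reconstructible": report.n_reconstructible,
               "fraction_reconstructible":
                   None if report.fraction_reconstructible is None
                   else round(report.fraction_reconstructible, 4)}
    summary.update({f"kw_{kw.replace(' ', '_')}": n
                    for kw, n in report.keyword_tallies.items()})
    pd.DataFrame([summary]).to_csv(summary_path, sep="\t", index=False)


def write_manifest_json(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
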