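"""On-disk formats: FASTA, GFF3, metadata TSV and the ground-truth ledger.

A dataset directory layout:

    genomes/<genome_id>.fasta       one chromosome record per genome
    genomes/<genome_id>.gff3        CDS and prophage features
    metadata.tsv                    genome_id, taxonomy ranks, habitat
    ledger.jsonl                    optional ground-truth transfer events

GFF3 uses the standard 1-based inclusive coordinates; the in-memory model is
0-based half-open. CDS attributes carry ID, product, functional_category and,
for prophage genes, gene_class (bacterial|viral). Prophage regions are
``prophage`` features whose child CDS are matched by coordinate containment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import Dataset, Gene, Genome, GroundTruthLedger, LedgerEvent, Prophage

_GFF_COLS = 9


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(records.items())]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def _attr_str(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k] = v
    return out


def write_gff3(path: str | Path, genome: Genome) -> None:
    """CDS rows for every gene plus a ``prophage`` row per prophage region,
    all in 1-based inclusive coordinates, sorted by start position."""
    lines = ["##gff-version 3",
             f"##sequence-region {genome.genome_id} 1 {len(genome.seq)}"]
    rows = []
    for pro in genome.prophages:
        rows.append((pro.start, 0, "\t".join([
            genome.genome_id, "phagelgt", "prophage",
            str(pro.start + 1), str(pro.end), ".", "+", ".",
            _attr_str({"ID": pro.prophage_id}),
        ])))
    for gene in genome.genes.values():
        attrs = {"ID": gene.gene_id, "product": gene.product,
                 "functional_category": gene.functional_category}
        if gene.in_prophage:
            attrs["gene_class"] = gene.gene_class
        rows.append((gene.start, 1, "\t".join([
            genome.genome_id, "phagelgt", "CDS",
            str(gene.start + 1), str(gene.end), ".", gene.strand, "0",
            _attr_str(attrs),
        ])))
    lines += [r for _, _, r in sorted(rows, key=lambda t: (t[0], t[1], t[2]))]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, genome_id: str, seq: str) -> tuple[dict[str, Gene], list[Prophage]]:
    """Parse CDS and prophage features back into the in-memory model.

    Gene nucleotide and protein sequences are re-extracted from ``seq``;
    prophage membership is assigned by coordinate containment.
    """
    genes: dict[str, Gene] = {}
    prophages: list[Prophage] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != _GFF_COLS:
            raise ValueError(f"malformed GFF3 row in {path}: {line!r}")
        _, _, ftype, start1, end1, _, strand, _, attr_text = cols
        attrs = _parse_attrs(attr_text)
        start, end = int(start1) - 1, int(end1)
        if ftype == "prophage":
            prophages.append(Prophage(attrs["ID"], genome_id, start, end))
        elif ftype == "CDS":
            nt = seq[start:end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            protein = str(Seq(nt).translate()).rstrip("*")
            genes[attrs["ID"]] = Gene(
                gene_id=attrs["ID"], genome_id=genome_id, start=start, end=end,
                nt=nt, protein=protein, strand=strand,
                product=attrs.get("product", "hypothetical protein"),
                functional_category=attrs.get("functional_category"),
                gene_class=attrs.get("gene_class"),
            )
    for pro in prophages:
        pro.gene_ids = sorted(
            gid for gid, g in genes.items()
            if g.start >= pro.start and g.end <= pro.end
        )
        for gid in pro.gene_ids:
            genes[gid].in_prophage = True
    return genes, prophages


# --------------------------------------------------------------------------
# Metadata and ledger
# --------------------------------------------------------------------------

def write_metadata(path: str | Path, genomes: dict[str, Genome]) -> None:
    header = ["genome_id", *Genome.RANKS, "habitat"]
    lines = ["\t".join(header)]
    for gid in sorted(genomes):
        g = genomes[gid]
        lines.append("\t".join(
            [gid, *(g.taxonomy.get(r, "") for r in Genome.RANKS), g.habitat or ""]
        ))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> dict[str, dict]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = {}
    for line in lines[1:]:
        if not line:
            continue
        row = dict(zip(header, line.split("\t")))
        gid = row.pop("genome_id")
        habitat = row.pop("habitat", "") or None
        out[gid] = {"taxonomy": {k: v for k, v in row.items() if v},
                    "habitat": habitat}
    return out


def write_ledger(path: str | Path, ledger: GroundTruthLedger) -> None:
    with open(path, "w") as fh:
        for ev in sorted(ledger.events, key=lambda e: e.gene_id):
            fh.write(json.dumps({
                "gene_id": ev.gene_id, "donor": ev.donor, "recipient": ev.recipient,
                "phage": ev.phage, "family": ev.family,
                "n_substitutions_planted": ev.n_substitutions_planted,
                "is_autolog": ev.is_autolog,
            }, sort_keys=True) + "\n")


def read_ledger(path: str | Path) -> GroundTruthLedger:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        d = json.loads(line)
        events.append(LedgerEvent(**d))
    return GroundTruthLedger(events=events)


# --------------------------------------------------------------------------
# Dataset round-trip
# --------------------------------------------------------------------------

def save_dataset(dataset: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for gid in sorted(dataset.genomes):
        genome = dataset.genomes[gid]
        write_fasta(gdir / f"{gid}.fasta", {gid: genome.seq})
        write_gff3(gdir / f"{gid}.gff3", genome)
    write_metadata(outdir / "metadata.tsv", dataset.genomes)
    if dataset.ledger is not None:
        write_ledger(outdir / "ledger.jsonl", dataset.ledger)


def load_dataset(indir: str | Path) -> Dataset:
    indir = Path(indir)
    meta = read_metadata(indir / "metadata.tsv")
    genomes: dict[str, Genome] = {}
    for fasta in sorted((indir / "genomes").glob("*.fasta")):
        gid = fasta.stem
        seq = read_fasta(fasta)[gid]
        genes, prophages = read_gff3(indir / "genomes" / f"{gid}.gff3", gid, seq)
        info = meta.get(gid, {"taxonomy": {}, "habitat": None})
        genomes[gid] = Genome(genome_id=gid, seq=seq, genes=genes,
                              prophages=prophages,
                              taxonomy=info["taxonomy"], habitat=info["habitat"])
    ledger = None
    if (indir / "ledger.jsonl").exists():
        ledger = read_ledger(indir / "ledger.jsonl")
    return Dataset(genomes=genomes, ledger=ledger)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, msg: str) -> None:
        self.findings.append(msg)


def validate_inputs(dataset: Dataset) -> ValidationReport:
    """Itemized consistency checks: CDS bounds and frame, start/stop codons,
    prophage interval sanity, and gene_class labels on prophage genes."""
    report = ValidationReport()
    for gid in sorted(dataset.genomes):
        genome = dataset.genomes[gid]
        L = len(genome.seq)
        for gene_id in sorted(genome.genes):
            g = genome.genes[gene_id]
            if not (0 <= g.start < g.end <= L):
                report.add(f"{gid}/{gene_id}: CDS outside chromosome bounds")
                continue
            if (g.end - g.start) % 3 != 0:
                report.add(f"{gid}/{gene_id}: CDS length not a multiple of 3")
                continue
            nt = g.nt.upper()
            if len(nt) != g.end - g.start:
                report.add(f"{gid}/{gene_id}: stored sequence length mismatch")
            if not nt.startswith("ATG"):
                report.add(f"{gid}/{gene_id}: missing ATG start codon")
            prot = str(Seq(nt).translate())
            if not prot.endswith("*"):
                report.add(f"{gid}/{gene_id}: missing terminal stop codon")
            if "*" in prot[:-1]:
                report.add(f"{gid}/{gene_id}: internal stop codon")
            if g.in_prophage and g.gene_class not in ("bacterial", "viral"):
                report.add(f"{gid}/{gene_id}: prophage gene missing gene_class")
        for pro in genome.prophages:
            if not (0 <= pro.start < pro.end <= L):
                report.add(f"{gid}/{pro.prophage_id}: prophage outside bounds")
            for gene_id in pro.gene_ids:
                if gene_id not in genome.genes:
                    report.add(f"{gid}/{pro.prophage_id}: unknown gene {gene_id}")
    if dataset.ledger is not None:
        all_genes = dataset.all_genes()
        for ev in dataset.ledger.events:
            if ev.gene_id not in all_genes:
                report.add(f"ledger: unknown gene {ev.gene_id}")
            for genome_id in (ev.donor, ev.recipient):
                if genome_id not in dataset.genomes:
                    report.add(f"ledger/{ev.gene_id}: unknown genome {genome_id}")
    return report
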