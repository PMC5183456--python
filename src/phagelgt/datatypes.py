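"""In-memory data model shared by the simulator, I/O layer and pipeline stages.

Coordinates are 0-based half-open internally; the GFF3 layer converts to the
1-based inclusive convention on the way out and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import seqsim


@dataclass
class Gene:
    gene_id: str
    genome_id: str
    start: int
    end: int
    nt: str
    protein: str
    strand: str = "+"
    product: str = "hypothetical protein"
    functional_category: str | None = None
    in_prophage: bool = False
    gene_class: str | None = None  # 'bacterial' | 'viral' for prophage genes


@dataclass
class Prophage:
    prophage_id: str
    genome_id: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)

    def bacterial_gene_ids(self, genome: "Genome") -> list[str]:
        return [g for g in self.gene_ids if genome.genes[g].gene_class == "bacterial"]


@dataclass
class Genome:
    genome_id: str
    seq: str
    genes: dict[str, Gene] = field(default_factory=dict)
    prophages: list[Prophage] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)
    habitat: str | None = None

    RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species", "strain")

    def cds_intervals(self) -> list[tuple[int, int]]:
        return [(g.start, g.end) for g in self.genes.values()]

    @cached_property
    def gc(self) -> float:
        return seqsim.gc_percent(self.seq)

    @cached_property
    def usage_profile(self) -> np.ndarray:
        """Relative codon-usage vector over all chromosomal (non-prophage) CDS."""
        seqs = [g.nt for g in self.genes.values() if not g.in_prophage]
        if not seqs:  # genome annotated with prophage genes only
            seqs = [g.nt for g in self.genes.values()]
        return seqsim.codon_usage_profile(seqs)

    @cached_property
    def kmer_codes(self) -> np.ndarray:
        return seqsim.kmer_set(self.seq)

    @cached_property
    def cds_kmer_codes(self) -> np.ndarray:
        return seqsim.cds_kmer_set(self.seq, self.cds_intervals())

    def host_segments(self) -> list[tuple[int, int]]:
        """Chromosome intervals outside prophage regions (0-based half-open)."""
        pos, segs = 0, []
        for pp in sorted(self.prophages, key=lambda p: p.start):
            if pp.start > pos:
                segs.append((pos, pp.start))
            pos = max(pos, pp.end)
        if pos < len(self.seq):
            segs.append((pos, len(self.seq)))
        return segs

    @cached_property
    def host_kmer_codes(self) -> np.ndarray:
        """Canonical k-mers of the prophage-masked chromosome. Prophages are
        mobile cargo, so genome-genome similarity built on these sets reflects
        the host backbone rather than shared or transferred phage material."""
        parts = [
            seqsim.kmer_set(self.seq[s:e])
            for s, e in self.host_segments() if e - s >= 20
        ]
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(parts))

    @cached_property
    def host_cds_kmer_codes(self) -> np.ndarray:
        """CDS-restricted canonical k-mers over the prophage-masked chromosome
        (chromosomal CDS only)."""
        parts = []
        for s, e in self.host_segments():
            if e - s < 20:
                continue
            ivals = [
                (max(g.start, s) - s, min(g.end, e) - s)
                for g in self.genes.values()
                if not g.in_prophage and g.end > s and g.start < e
            ]
            if ivals:
                parts.append(seqsim.cds_kmer_set(self.seq[s:e], sorted(ivals)))
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(parts))


@dataclass(frozen=True)
class LedgerEvent:
    gene_id: str
    donor: str
    recipient: str
    phage: str  # prophage id carrying the transferred copy
    family: str
    n_substitutions_planted: int
    is_autolog: bool


@dataclass
class GroundTruthLedger:
    events: list[LedgerEvent] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for ev in self.events:
            if ev.gene_id in seen:
                raise ValueError(f"duplicate gene id in ledger: {ev.gene_id}")
            seen.add(ev.gene_id)
            if ev.is_autolog != (ev.donor == ev.recipient):
                raise ValueError(f"autolog flag inconsistent for {ev.gene_id}")

    def by_gene(self) -> dict[str, LedgerEvent]:
        return {ev.gene_id: ev for ev in self.events}

    @property
    def n_autologs(self) -> int:
        return sum(ev.is_autolog for ev in self.events)


@dataclass
class TransductionEvent:
    """An inferred (or planted) transfer: gene into a recipient via a phage."""

    gene_id: str
    phage_entity: str
    recipient: str
    donor: str | None = None
    is_autolog: bool = False

    def __post_init__(self):
        self.is_autolog = self.donor is not None and self.donor == self.recipient


@dataclass
class Dataset:
    genomes: dict[str, Genome]
    ledger: GroundTruthLedger | None = None

    def all_prophages(self) -> list[Prophage]:
        return [p for g in self.genomes.values() for p in g.prophages]

    def all_genes(self) -> dict[str, Gene]:
        out: dict[str, Gene] = {}
        for g in self.genomes.values():
            out.update(g.genes)
        return out

    def prophage_bacterial_genes(self) -> list[Gene]:
        out = []
        for g in self.genomes.values():
            for p in g.prophages:
                for gid in p.gene_ids:
                    gene = g.genes[gid]
                    if gene.gene_class == "bacterial":
                        out.append(gene)
        return out

    def prophage_of_gene(self) -> dict[str, str]:
        mapping = {}
        for g in self.genomes.values():
            for p in g.prophages:
                for gid in p.gene_ids:
                    mapping[gid] = p.prophage_id
        return mapping
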