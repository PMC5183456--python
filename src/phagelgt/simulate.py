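"""Synthetic genomes, prophages and planted transduction events.

The generator emulates the statistical structure the transduction-network
inference assumes:

* a clonal frame: genomes evolve along a random Yule species tree by point
  substitution only (no indels), so homologous CDS remain positionally aligned
  and planted donors are unambiguous;
* lineage-specific GC drift, which induces both GC and codon-usage
  heterogeneity among genomes;
* prophages drawn from a small pool of unrelated ancestral phage types, so
  prophages of the same type cluster as orthologous prophages and viral genes
  never collide with the bacterial gene pool;
* planted transduction events: a copy of a donor CDS is inserted into a
  prophage of the recipient, optionally mutated with a controlled
  non-synonymous/synonymous substitution ratio (``omega_true``); autologs
  (donor == recipient) are planted at a configurable fraction;
* habitat labels (11 classes by default) assigned along the tree with a
  mixing rate, so habitat correlates with phylogeny unless mixing is 1;
* a complete ground-truth ledger for recovery tests.

Recipient choice follows a similarity kernel: the probability of placing an
event between donor d and recipient r is proportional to
``exp(-similarity_kernel_strength * patristic_distance(d, r))``, a monotone
increasing function of donor–recipient sequence similarity. Strength 0 gives
uniform placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import Dataset, Gene, Genome, GroundTruthLedger, LedgerEvent, Prophage
from .genetic_code import (
    BASES,
    CODONS,
    MUT_CLASS,
    STOP_CODONS,
    encode_nt,
    decode_nt,
    translate_codons,
)

DEFAULT_HABITATS = (
    "human_associated",
    "host",
    "soil_sediment",
    "plant",
    "marine",
    "freshwater",
    "thermal_spring",
    "hypersaline",
    "food",
    "wastewater",
    "air",
)

FUNCTIONAL_CATEGORIES = ("metabolism", "information", "cellular_processes")


@dataclass
class SimConfig:
    n_genomes: int = 50
    species_tree_depth: float = 0.3      # expected substitutions/site, root to tip
    n_cds_per_genome: int = 250
    n_events: int = 200
    autolog_fraction: float = 0.09
    similarity_kernel_strength: float = 10.0
    habitat_classes: tuple[str, ...] = DEFAULT_HABITATS
    gc_range: tuple[float, float] = (35.0, 65.0)
    omega_true: float = 0.12
    seed: int = 0
    # generator shape knobs
    cds_length_codons: int = 300
    n_subs_per_event: float = 0.0        # Poisson mean of post-transfer substitutions
    n_phage_types: int = 5
    phage_genes_per_prophage: int = 8
    habitat_mixing: float = 0.15
    allow_family_reuse: bool = False
    intergenic_length: int = 30
    min_branch_length: float = 0.02      # floor on pendant branches (distinct strains)
    gc_drift_sigma: float = 20.0         # GC drift scale, % per sqrt(subs/site)
    functional_categories: tuple[str, ...] = FUNCTIONAL_CATEGORIES
    functional_weights: tuple[float, ...] = (0.42, 0.35, 0.23)

    def __post_init__(self):
        if not (0.0 <= self.autolog_fraction <= 1.0):
            raise ValueError("autolog_fraction must be in [0, 1]")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not self.habitat_classes:
            raise ValueError("habitat_classes must be non-empty")
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.cds_length_codons < 10:
            raise ValueError("cds_length_codons too small")
        if not (0.0 <= self.gc_range[0] <= self.gc_range[1] <= 100.0):
            raise ValueError("invalid gc_range")


# --------------------------------------------------------------------------
# Species tree
# --------------------------------------------------------------------------

@dataclass
class _Node:
    children: list["_Node"] = field(default_factory=list)
    height: float = 0.0       # distance above the leaves (ultrametric)
    leaf: int | None = None   # leaf index

    def leaves(self) -> list[int]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _random_tree(n: int, depth: float, rng: np.random.Generator) -> _Node:
    """Random coalescent-topology ultrametric tree scaled to the given depth."""
    nodes = [_Node(leaf=i) for i in range(n)]
    height = 0.0
    k = n
    while k > 1:
        height += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = _Node(children=[nodes[i], nodes[j]], height=height)
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)] + [parent]
        k -= 1
    root = nodes[0]
    scale = depth / root.height
    _scale_heights(root, scale)
    return root


def _scale_heights(node: _Node, scale: float) -> None:
    node.height *= scale
    for c in node.children:
        _scale_heights(c, scale)


def patristic_distances(root: _Node, n: int) -> np.ndarray:
    """All-pairs leaf path lengths on the ultrametric tree: 2 * MRCA height."""
    dist = np.zeros((n, n))

    def visit(node: _Node):
        if node.leaf is not None:
            return
        for c in node.children:
            visit(c)
        for a_i, a in enumerate(node.children):
            for b in node.children[a_i + 1:]:
                for la in a.leaves():
                    for lb in b.leaves():
                        dist[la, lb] = dist[lb, la] = 2.0 * node.height
    visit(root)
    return dist


def _taxonomy_from_tree(root: _Node, n: int, depth: float) -> list[dict[str, str]]:
    """Assign taxonomy ranks by cutting the ultrametric tree at fixed heights."""
    cuts = {
        "phylum": 0.85, "class": 0.70, "order": 0.50,
        "family": 0.30, "genus": 0.15, "species": 0.05,
    }
    tax: list[dict[str, str]] = [{"domain": "Bacteria"} for _ in range(n)]
    for rank, frac in cuts.items():
        h = frac * depth
        groups: list[list[int]] = []

        def collect(node: _Node):
            # a group = a maximal clade whose top is below the cut height
            if node.height <= h or node.leaf is not None:
                groups.append(node.leaves())
                return
            for c in node.children:
                collect(c)
        collect(root)
        for gi, leaves in enumerate(sorted(groups, key=min)):
            label = f"{rank[0]}{gi:03d}"
            for leaf in leaves:
                tax[leaf][rank] = label
    for i in range(n):
        tax[i]["strain"] = f"G{i:03d}"
    return tax


def _assign_habitats(
    root: _Node, n: int, classes: tuple[str, ...], mixing: float, rng: np.random.Generator
) -> list[str]:
    habitats = [""] * n

    def visit(node: _Node, habitat: str):
        if node.leaf is not None:
            habitats[node.leaf] = habitat
            return
        for c in node.children:
            child_hab = habitat
            if rng.random() < mixing:
                child_hab = classes[rng.integers(len(classes))]
            visit(c, child_hab)

    visit(root, classes[rng.integers(len(classes))])
    return habitats


# --------------------------------------------------------------------------
# Sequence machinery
# --------------------------------------------------------------------------

def _random_cds(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + random non-stop sense codons + TAA, biased toward target GC%."""
    p = np.array([(100 - gc) / 2, gc / 2, gc / 2, (100 - gc) / 2]) / 100.0
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(BASES[i] for i in rng.choice(4, size=3, p=p))
        if codon not in STOP_CODONS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(100 - gc) / 2, gc / 2, gc / 2, (100 - gc) / 2]) / 100.0
    return decode_nt(rng.choice(4, size=length, p=p).astype(np.uint8))


def _evolve_seq(
    enc: np.ndarray,
    n_subs: int,
    gc: float,
    cds_bounds: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply ~n_subs random point substitutions with GC-biased target bases.

    Substitutions that would create an internal stop codon or destroy a start
    or stop codon of an annotated CDS are reverted (a few percent of draws), so
    the realized count is marginally below ``n_subs``.
    """
    if n_subs <= 0:
        return enc.copy()
    out = enc.copy()
    L = out.size
    pos = rng.integers(0, L, size=n_subs)
    cur = out[pos]
    # sample replacement bases != current, biased toward the lineage GC target
    base_p = np.array([(100 - gc) / 2, gc / 2, gc / 2, (100 - gc) / 2]) / 100.0
    new = np.empty(n_subs, dtype=np.uint8)
    for b in range(4):
        mask = cur == b
        if not np.any(mask):
            continue
        alts = np.array([x for x in range(4) if x != b], dtype=np.uint8)
        w = base_p[alts]
        w = w / w.sum()
        new[mask] = rng.choice(alts, size=int(mask.sum()), p=w)
    out[pos] = new

    # repair CDS violations codon-wise
    for s, e in cds_bounds:
        region = out[s:e]
        codons = region.reshape(-1, 3)
        idx = codons[:, 0].astype(np.int64) * 16 + codons[:, 1] * 4 + codons[:, 2]
        bad = np.zeros(idx.size, dtype=bool)
        stop_idx = np.array([CODONS.index(c) for c in STOP_CODONS])
        bad[:-1] |= np.isin(idx[:-1], stop_idx)       # internal stop created
        bad[-1] |= ~np.isin(idx[-1], stop_idx)        # terminal stop destroyed
        orig = enc[s:e].reshape(-1, 3)
        oidx = orig[:, 0].astype(np.int64) * 16 + orig[:, 1] * 4 + orig[:, 2]
        bad[0] |= idx[0] != oidx[0]                   # start codon fixed
        if np.any(bad):
            codons[bad] = orig[bad]
            out[s:e] = codons.reshape(-1)
    return out


def mutate_transferred_gene(
    gene: str,
    n_subs: int,
    omega_true: float,
    seed: int | np.random.Generator,
) -> str:
    """Apply exactly ``n_subs`` point substitutions to a codon sequence with the
    non-synonymous:synonymous rate ratio governed by ``omega_true``.

    At each step every possible single-nucleotide change in the internal codons
    is enumerated and classified; synonymous candidates carry weight 1 and
    non-synonymous candidates weight ``omega_true`` (each divided by the number
    of valid changes at the position, so per-site rates match Nei–Gojobori
    opportunity counting). Changes creating stop codons are never drawn, and
    each nucleotide position is substituted at most once. The first (start) and
    last (stop) codons are left untouched.
    """
    if len(gene) % 3:
        raise ValueError("gene length not divisible by 3")
    if omega_true < 0:
        raise ValueError("omega_true must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    enc = encode_nt(gene)
    n_codons = len(gene) // 3
    if n_codons < 3 and n_subs > 0:
        raise ValueError("gene too short to mutate (needs internal codons)")
    internal = np.arange(1, n_codons - 1)
    for ci in internal:
        codon = gene[3 * ci: 3 * ci + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {ci}")
    max_positions = internal.size * 3
    if n_subs > max_positions:
        raise ValueError(
            f"cannot place {n_subs} substitutions in {max_positions} mutable positions"
        )
    if n_subs == 0:
        return gene

    used = np.zeros(enc.size, dtype=bool)
    out = enc.copy()
    for _ in range(n_subs):
        codon_idx = (
            out[3 * internal].astype(np.int64) * 16
            + out[3 * internal + 1] * 4
            + out[3 * internal + 2]
        )
        cls = MUT_CLASS[codon_idx]                      # (n_int, 3, 4)
        weights = np.where(cls == 0, 1.0, np.where(cls == 1, omega_true, 0.0))
        valid = (cls <= 1).sum(axis=2, keepdims=True).astype(float)
        valid[valid == 0] = 1.0
        weights = weights / valid
        flat_pos = (3 * internal[:, None] + np.arange(3)[None, :]).reshape(-1)
        weights = weights.reshape(internal.size * 3, 4)
        weights[used[flat_pos]] = 0.0
        total = weights.sum()
        if total <= 0:
            raise ValueError("no admissible substitution left (omega_true too small?)")
        flat = weights.reshape(-1)
        choice = rng.choice(flat.size, p=flat / total)
        pi, base = divmod(choice, 4)
        pos = flat_pos[pi]
        out[pos] = base
        used[pos] = True
    return decode_nt(out)


# --------------------------------------------------------------------------
# Dataset assembly
# --------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[Dataset, GroundTruthLedger]:
    """Generate genomes, prophages and planted transduction events.

    Returns the dataset (the prophage set hangs off each genome) and the
    ground-truth ledger. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    gc_mid = 0.5 * (config.gc_range[0] + config.gc_range[1])

    root = _random_tree(n, config.species_tree_depth, rng)
    dist = patristic_distances(root, n)
    taxonomy = _taxonomy_from_tree(root, n, config.species_tree_depth)
    habitats = _assign_habitats(root, n, config.habitat_classes, config.habitat_mixing, rng)

    # root genome
    fam_cats = list(
        rng.choice(
            len(config.functional_categories),
            size=config.n_cds_per_genome,
            p=np.asarray(config.functional_weights) / sum(config.functional_weights),
        )
    )
    cds_len = config.cds_length_codons * 3
    parts: list[str] = []
    cds_bounds: list[tuple[int, int]] = []
    cursor = 0
    for _f in range(config.n_cds_per_genome):
        spacer = _random_dna(config.intergenic_length, gc_mid, rng)
        parts.append(spacer)
        cursor += len(spacer)
        cds = _random_cds(config.cds_length_codons, gc_mid, rng)
        parts.append(cds)
        cds_bounds.append((cursor, cursor + cds_len))
        cursor += cds_len
    root_seq = encode_nt("".join(parts))

    # evolve along the tree
    leaf_seqs: dict[int, np.ndarray] = {}
    leaf_gc: dict[int, float] = {}

    def evolve(node: _Node, seq: np.ndarray, gc: float, parent_height: float):
        bl = parent_height - node.height
        if node.leaf is not None:
            bl = max(bl, config.min_branch_length)
        if bl > 0:
            gc = float(np.clip(
                gc + rng.normal(0.0, config.gc_drift_sigma * math.sqrt(bl)),
                config.gc_range[0], config.gc_range[1],
            ))
            n_subs = int(rng.poisson(bl * seq.size))
            seq = _evolve_seq(seq, n_subs, gc, cds_bounds, rng)
        if node.leaf is not None:
            leaf_seqs[node.leaf] = seq
            leaf_gc[node.leaf] = gc
            return
        for c in node.children:
            evolve(c, seq, gc, node.height)

    evolve(root, root_seq, gc_mid, root.height)

    # ancestral phage pool (unrelated sequence space, own GC)
    phage_gc = 45.0
    phage_gene_len = 200  # codons
    ancestral_phages = [
        [_random_cds(phage_gene_len, phage_gc, rng) for _ in range(config.phage_genes_per_prophage)]
        for _ in range(config.n_phage_types)
    ]

    genomes: dict[str, Genome] = {}
    for i in range(n):
        gid = f"G{i:03d}"
        seq_enc = leaf_seqs[i]
        genome = Genome(
            genome_id=gid,
            seq="",
            taxonomy=taxonomy[i],
            habitat=habitats[i],
        )
        chrom = decode_nt(seq_enc)
        for f, (s, e) in enumerate(cds_bounds):
            nt = chrom[s:e]
            gene_id = f"{gid}_c{f:04d}"
            genome.genes[gene_id] = Gene(
                gene_id=gene_id, genome_id=gid, start=s, end=e, nt=nt,
                protein=translate_codons(nt[:-3]),
                product=f"fam{f:04d} protein",
                functional_category=config.functional_categories[fam_cats[f]],
            )
        # prophage region appended at the chromosome end
        ptype = int(rng.integers(config.n_phage_types))
        pro_id = f"{gid}_pro0"
        pro_start = len(chrom)
        pieces = [chrom]
        cursor = pro_start
        pro = Prophage(prophage_id=pro_id, genome_id=gid, start=pro_start, end=pro_start)
        for vg, anc in enumerate(ancestral_phages[ptype]):
            spacer = _random_dna(10, phage_gc, rng)
            pieces.append(spacer)
            cursor += len(spacer)
            enc = encode_nt(anc)
            nsub = int(rng.poisson(0.01 * enc.size))
            mutated = _evolve_seq(enc, nsub, phage_gc, [(0, enc.size)], rng)
            nt = decode_nt(mutated)
            pieces.append(nt)
            gene_id = f"{gid}_v{vg:02d}"
            genome.genes[gene_id] = Gene(
                gene_id=gene_id, genome_id=gid, start=cursor, end=cursor + len(nt),
                nt=nt, protein=translate_codons(nt[:-3]),
                product=f"phage type {ptype} protein {vg}",
                in_prophage=True, gene_class="viral",
            )
            pro.gene_ids.append(gene_id)
            cursor += len(nt)
        pro.end = cursor
        genome.seq = "".join(pieces)
        genome.prophages.append(pro)
        genomes[gid] = genome

    # planted transduction events
    events: list[LedgerEvent] = []
    if config.n_events > 0:
        if config.allow_family_reuse:
            families = rng.integers(0, config.n_cds_per_genome, size=config.n_events)
        else:
            if config.n_events > config.n_cds_per_genome:
                raise ValueError(
                    f"n_events={config.n_events} exceeds the donor CDS pool "
                    f"({config.n_cds_per_genome} families without reuse)"
                )
            families = rng.permutation(config.n_cds_per_genome)[: config.n_events]
        for e in range(config.n_events):
            donor = int(rng.integers(n))
            if rng.random() < config.autolog_fraction:
                recipient = donor
            else:
                w = np.exp(-config.similarity_kernel_strength * dist[donor])
                w[donor] = 0.0
                recipient = int(rng.choice(n, p=w / w.sum()))
            fam = int(families[e])
            donor_gid = f"G{donor:03d}"
            rec_gid = f"G{recipient:03d}"
            nt = genomes[donor_gid].genes[f"{donor_gid}_c{fam:04d}"].nt
            n_subs = int(rng.poisson(config.n_subs_per_event)) if config.n_subs_per_event > 0 else 0
            mutated = mutate_transferred_gene(nt, n_subs, config.omega_true, rng)
            rec = genomes[rec_gid]
            pro = rec.prophages[0]
            spacer = _random_dna(10, phage_gc, rng)
            start = len(rec.seq) + len(spacer)
            rec.seq = rec.seq + spacer + mutated
            gene_id = f"{rec_gid}_t{e:04d}"
            rec.genes[gene_id] = Gene(
                gene_id=gene_id, genome_id=rec_gid, start=start, end=start + len(mutated),
                nt=mutated, protein=translate_codons(mutated[:-3]),
                product="hypothetical protein",
                functional_category=config.functional_categories[fam_cats[fam]],
                in_prophage=True, gene_class="bacterial",
            )
            pro.gene_ids.append(gene_id)
            pro.end = start + len(mutated)
            events.append(LedgerEvent(
                gene_id=gene_id, donor=donor_gid, recipient=rec_gid,
                phage=pro.prophage_id, family=f"fam{fam:04d}",
                n_substitutions_planted=n_subs,
                is_autolog=donor_gid == rec_gid,
            ))

    ledger = GroundTruthLedger(events=events)
    dataset = Dataset(genomes=genomes, ledger=ledger)
    return dataset, ledger
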