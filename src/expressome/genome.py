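"""Synthetic bacterial genome with operons, regulons and planted ORFs.

The generator builds a genome bottom-up from proteins: each gene's amino
acid sequence is constructed from Lys-C-friendly blocks (so every protein
is guaranteed at least two peptides >= 6 aa), back-translated codon by
codon, and laid onto the chromosome with intergenic spacers.  Unannotated
ORFs are planted both intergenically (flanked by in-frame stops) and
inside an annotated gene on the opposite strand, mirroring how such genes
hide from annotation pipelines in real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .config import ConfigError, SimulationConfig
from .proteogenomics import digest_lysC

AA_ALPHABET = "ACDEFGHILMNPQRSTVWY"  # K added explicitly by block structure

_TABLE = unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

KINETIC_CLASSES = ("rpoe", "rpoh2", "pulse", "repressed", "flat")
DESIGN_CLASSES = KINETIC_CLASSES + ("translational_only", "protein_decline")
POLARITY_CLASSES = ("5prime", "3prime", "translatome_5prime", "none")


@dataclass
class GeneAnnotation:
    gene_id: str
    start: int          # 0-based half-open, forward strand
    end: int
    strand: str
    protein: str
    operon_id: str | None = None
    operon_pos: int | None = None   # 1-based position in transcription order
    regulon: str = "none"           # RpoE | RpoH2 | none
    design_class: str = "flat"


@dataclass
class NovelORF:
    orf_id: str
    start: int
    end: int
    strand: str
    aa: str
    expressed: bool = False
    host_gene: str | None = None    # set for the gene-internal plant


@dataclass
class OperonDefinition:
    """Ordered operon: first gene = 5'-most = first transcribed."""

    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str
    polarity_class: str = "none"

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("an operon needs >= 2 genes")


@dataclass
class SyntheticGenome:
    replicon: str
    sequence: str
    genes: list[GeneAnnotation]
    operons: list[OperonDefinition]
    novel_orfs: list[NovelORF]

    def gene(self, gene_id: str) -> GeneAnnotation:
        return next(g for g in self.genes if g.gene_id == gene_id)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    )


def translate_region(sequence: str, start: int, end: int, strand: str) -> str:
    sub = sequence[start:end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return str(Seq(sub).translate())


def _random_block_protein(
    rng: np.random.Generator, n_blocks: int, tail: bool = True
) -> str:
    """Protein built from blocks of 6-11 non-K residues each ending in K,
    guaranteeing >= n_blocks Lys-C peptides of length >= 7."""
    parts = []
    for _ in range(n_blocks):
        length = int(rng.integers(6, 12))
        seg = "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))
        parts.append(seg + "K")
    if tail:
        tail_len = int(rng.integers(0, 8))
        parts.append("".join(AA_ALPHABET[i]
                             for i in rng.integers(0, len(AA_ALPHABET), tail_len)))
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _assign_unit_classes(
    operon_sizes: list[int], n_singletons: int, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str], list[str]]:
    """Deterministic class assignment at exact configured counts.

    Polar operons draw their (shared) kinetic class from the RpoE/RpoH2
    budgets; remaining budgets and all other classes are filled gene-by-
    gene over shuffled singletons, so totals match the config exactly.
    """
    n_operons = len(operon_sizes)
    n_polar = (config.n_5prime_operons + config.n_3prime_operons
               + config.n_translatome_polar_operons)
    if n_polar > n_operons:
        raise ConfigError("more polar operons requested than operons")
    polarity = (["5prime"] * config.n_5prime_operons
                + ["3prime"] * config.n_3prime_operons
                + ["translatome_5prime"] * config.n_translatome_polar_operons
                + ["none"] * (n_operons - n_polar))
    rng.shuffle(polarity)

    budgets = {"rpoe": config.n_rpoe_genes, "rpoh2": config.n_rpoh2_genes}
    operon_class = []
    for size, pol in zip(operon_sizes, polarity):
        if pol != "none":
            cls = max(budgets, key=lambda k: budgets[k])
            if budgets[cls] < size:
                raise ConfigError(
                    "RpoE/RpoH2 gene budgets too small for the polar operons")
            budgets[cls] -= size
            operon_class.append(cls)
        else:
            operon_class.append("flat")

    fill = (["rpoe"] * budgets["rpoe"]
            + ["rpoh2"] * budgets["rpoh2"]
            + ["pulse"] * config.n_pulse_genes
            + ["repressed"] * config.n_repressed_genes
            + ["translational_only"] * config.n_translational_only
            + ["protein_decline"] * config.n_protein_decline)
    if len(fill) > n_singletons:
        raise ConfigError("planted class counts exceed singleton genes")
    fill += ["flat"] * (n_singletons - len(fill))
    singleton_class = list(fill)
    rng.shuffle(singleton_class)
    return operon_class, polarity, singleton_class


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate the full synthetic genome; byte-identical under a seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    operon_sizes = [int(rng.integers(config.operon_size_min,
                                     config.operon_size_max + 1))
                    for _ in range(config.n_operons)]
    while sum(operon_sizes) > config.n_genes:
        operon_sizes.pop()
    n_operon_genes = sum(operon_sizes)
    n_singletons = config.n_genes - n_operon_genes
    operon_class, operon_polarity, singleton_class = _assign_unit_classes(
        operon_sizes, n_singletons, config, rng)

    # Units: each operon is one unit; each singleton gene is one unit.
    units: list[dict] = []
    for i, size in enumerate(operon_sizes):
        units.append({"kind": "operon", "size": size,
                      "class": operon_class[i], "polarity": operon_polarity[i]})
    for cls in singleton_class:
        units.append({"kind": "gene", "size": 1, "class": cls, "polarity": None})
    rng.shuffle(units)

    # Proteins for the planted novel ORFs (first one goes gene-internal).
    novel_blocks = max(3, round(config.novel_orf_len / 9))
    novel_proteins = [_random_block_protein(rng, novel_blocks, tail=False)
                      for _ in range(config.n_novel_orfs)]
    host_unit_idx = None
    if config.n_novel_orfs:
        flat_singles = [i for i, u in enumerate(units)
                        if u["kind"] == "gene" and u["class"] == "flat"]
        if flat_singles:
            host_unit_idx = flat_singles[int(rng.integers(len(flat_singles)))]
    intergenic = list(range(1 if host_unit_idx is not None else 0,
                            config.n_novel_orfs))
    # spread intergenic plants across unit gaps
    gap_slots = sorted(rng.choice(len(units), size=min(len(intergenic), len(units)),
                                  replace=False).tolist())

    seq_parts: list[str] = []
    pos = 0
    genes: list[GeneAnnotation] = []
    operons: list[OperonDefinition] = []
    novel: list[NovelORF] = []
    gene_counter = 0
    operon_counter = 0
    novel_iter = iter(intergenic)
    slot_iter = iter(gap_slots)
    next_slot = next(slot_iter, None)

    def emit(seg: str) -> None:
        nonlocal pos
        seq_parts.append(seg)
        pos += len(seg)

    def plant_intergenic(orf_idx: int) -> None:
        aa = novel_proteins[orf_idx]
        strand = "+" if rng.random() < 0.5 else "-"
        orf_nt = back_translate(aa, rng)
        stops = STOP_CODONS[int(rng.integers(3))], STOP_CODONS[int(rng.integers(3))]
        cassette = stops[0] + orf_nt + stops[1]
        if strand == "-":
            cassette = str(Seq(cassette).reverse_complement())
        start = pos + 3
        end = start + 3 * len(aa)
        emit(cassette)
        novel.append(NovelORF(f"NORF_{orf_idx + 1:04d}", start, end, strand, aa))

    for unit_idx, unit in enumerate(units):
        emit(_random_dna(rng, int(rng.integers(40, 121))))
        if next_slot is not None and unit_idx == next_slot:
            idx = next(novel_iter, None)
            if idx is not None:
                plant_intergenic(idx)
                emit(_random_dna(rng, int(rng.integers(20, 61))))
            next_slot = next(slot_iter, None)

        strand = "+" if rng.random() < 0.5 else "-"
        members: list[GeneAnnotation] = []
        for k in range(unit["size"]):
            gene_counter += 1
            gene_id = f"RSP_{gene_counter:04d}"
            if unit_idx == host_unit_idx:
                protein, cds, orf_rec = _build_host_gene(
                    novel_proteins[0], rng)
            else:
                n_blocks = max(2, int(round(config.protein_len_mean / 9
                                            + rng.integers(-1, 2))))
                protein = _random_block_protein(rng, n_blocks)
                cds = back_translate(protein, rng) + STOP_CODONS[int(rng.integers(3))]
                orf_rec = None
            gene_strand = strand
            placed = cds if gene_strand == "+" else str(Seq(cds).reverse_complement())
            if k > 0:
                emit(_random_dna(rng, int(rng.integers(10, 31))))
            start = pos
            emit(placed)
            end = pos
            if gene_strand == "+":
                cds_start, cds_end = start, end - 3
            else:
                cds_start, cds_end = start + 3, end
            gene = GeneAnnotation(gene_id, cds_start, cds_end, gene_strand,
                                  protein, design_class=unit["class"])
            if orf_rec is not None:
                # coordinates of the embedded opposite-strand ORF
                off, aa = orf_rec
                if gene_strand == "+":
                    o_start = cds_start + off + 3
                    o_strand = "-"
                else:
                    o_start = cds_end - off - 3 - 3 * len(aa)
                    o_strand = "+"
                novel.append(NovelORF("NORF_0001", o_start,
                                      o_start + 3 * len(aa), o_strand, aa,
                                      host_gene=gene_id))
            members.append(gene)

        if unit["kind"] == "operon":
            operon_counter += 1
            op_id = f"OP_{operon_counter:04d}"
            # transcription order: leftmost gene first on '+', rightmost on '-'
            ordered = members if strand == "+" else list(reversed(members))
            for p, g in enumerate(ordered, start=1):
                g.operon_id = op_id
                g.operon_pos = p
            operons.append(OperonDefinition(
                op_id, tuple(g.gene_id for g in ordered), strand,
                polarity_class=unit["polarity"]))
        genes.extend(members)

    # remaining intergenic plants (if gaps ran out) go at the end
    for idx in novel_iter:
        emit(_random_dna(rng, 50))
        plant_intergenic(idx)
    emit(_random_dna(rng, int(rng.integers(40, 121))))

    sequence = "".join(seq_parts)
    for g in genes:
        g.regulon = {"rpoe": "RpoE", "rpoh2": "RpoH2"}.get(g.design_class, "none")

    novel.sort(key=lambda o: o.orf_id)
    # choose expressed novel ORFs; the gene-internal plant is always
    # expressed (it is transcribed from its own internal promoter)
    internal = [o for o in novel if o.host_gene is not None]
    others = [o for o in novel if o.host_gene is None]
    n_extra = config.n_expressed_novel_orfs - len(internal)
    pick = rng.choice(len(others), size=max(n_extra, 0), replace=False) \
        if others and n_extra > 0 else []
    for o in internal:
        o.expressed = True
    for i in sorted(np.asarray(pick, dtype=int).tolist()):
        others[i].expressed = True

    gg = SyntheticGenome("chr1", sequence, genes, operons, novel)
    _check_genome(gg)
    return gg


def _build_host_gene(orf_aa: str, rng: np.random.Generator):
    """Build a CDS whose reverse strand embeds a stop-flanked novel ORF.

    Returns (host protein, host cds, (nt offset of embedded cassette
    within the cds, orf aa)).  Retries codon choices until the embedded
    segment reads stop-free in the host frame.
    """
    for _ in range(400):
        orf_nt = back_translate(orf_aa, rng)
        cassette = str(Seq("TAA" + orf_nt + "TAA").reverse_complement())
        if "*" not in str(Seq(cassette).translate()):
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not embed opposite-strand ORF")
    prefix = _random_block_protein(rng, 2, tail=False)
    suffix = _random_block_protein(rng, 2)
    cds = (back_translate(prefix, rng) + cassette
           + back_translate(suffix, rng)
           + STOP_CODONS[int(rng.integers(3))])
    host_protein = str(Seq(cds[:-3]).translate())
    offset = 3 * len(prefix)
    return host_protein, cds, (offset, orf_aa)


def _check_genome(g: SyntheticGenome) -> None:
    n = len(g.sequence)
    gene_ids = {x.gene_id for x in g.genes}
    for gene in g.genes:
        assert 0 <= gene.start < gene.end <= n
        assert (gene.end - gene.start) % 3 == 0
        assert translate_region(g.sequence, gene.start, gene.end,
                                gene.strand) == gene.protein
        assert "*" not in gene.protein
    for orf in g.novel_orfs:
        assert len(orf.aa) >= 7
        assert orf.orf_id not in gene_ids
        assert translate_region(g.sequence, orf.start, orf.end,
                                orf.strand) == orf.aa
        assert len(digest_lysC(orf.aa, max_missed=0, min_len=6)) >= 2


# ---------------------------------------------------------------------------
# File output

def write_genome_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.replicon}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_proteome_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genome.genes:
            fh.write(f">{gene.gene_id}\n")
            for i in range(0, len(gene.protein), 70):
                fh.write(gene.protein[i:i + 70] + "\n")


def write_gff3(genome: SyntheticGenome, path: str | Path) -> None:
    """1-based inclusive coordinates; operon/regulon carried as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.replicon} 1 {len(genome.sequence)}\n")
        for gene in genome.genes:
            attrs = [f"ID={gene.gene_id}", f"regulon={gene.regulon}"]
            if gene.operon_id:
                attrs.append(f"operon_id={gene.operon_id}")
                attrs.append(f"operon_pos={gene.operon_pos}")
            fh.write("\t".join([
                genome.replicon, "expressome", "CDS",
                str(gene.start + 1), str(gene.end), ".", gene.strand, "0",
                ";".join(attrs),
            ]) + "\n")


def read_gff3_operons(path: str | Path) -> list[OperonDefinition]:
    """Recover operon definitions from `operon_id`/`operon_pos` attributes."""
    ops: dict[str, list[tuple[int, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            if "operon_id" not in attrs:
                continue
            ops.setdefault(attrs["operon_id"], []).append(
                (int(attrs["operon_pos"]), attrs["ID"], fields[6]))
    out = []
    for op_id, members in sorted(ops.items()):
        members.sort()
        out.append(OperonDefinition(
            op_id, tuple(m[1] for m in members), members[0][2]))
    return out
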