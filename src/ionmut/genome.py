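"""Toy genome and gene models with known structure.

Provides a stand-in reference for pipeline testing: random chromosomes
carrying strand-annotated protein-coding genes whose exon/CDS/UTR layout
is fully known, so that region and coding-effect annotation can be
checked against ground truth. Sequences are written as FASTA and gene
models as GFF3 (gene -> mRNA -> exon/CDS/UTR features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One protein-coding gene; all coordinates 1-based inclusive genomic."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        ex = sorted(self.exons)
        return [(a_end + 1, b_start - 1) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]

    def coding_sequence(self, genome: dict[str, str]) -> str:
        """CDS nucleotides in translation order (reverse-complemented for '-')."""
        chrom = genome[self.chrom]
        parts = [chrom[s - 1 : e] for s, e in sorted(self.cds)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_index(self, pos: int) -> int | None:
        """0-based index of genomic position within the coding sequence, or None."""
        segs = sorted(self.cds)
        offset = 0
        if self.strand == "+":
            for s, e in segs:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(segs):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    gene_density: float = 25e-6,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Simulate ``n_chrom`` chromosomes of ``chrom_len`` bp with embedded genes.

    Parameters
    ----------
    gene_density
        Genes per base pair; the number of genes per chromosome is
        ``round(gene_density * chrom_len)``. Genes are placed left to
        right with intergenic gaps of at least 2.5 kb so that upstream/
        downstream/intergenic annotation classes all occur.
    seed
        Generation is deterministic for a fixed seed.

    Returns
    -------
    (genome, genes)
        ``genome`` maps chromosome name to sequence string; ``genes`` is
        a flat list of :class:`GeneModel`.

    Every gene's total CDS length is a multiple of 3, begins with ATG and
    ends with a stop codon, and contains no in-frame internal stop.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10,000 bp")
    if gene_density < 0:
        raise ValueError("gene_density must be >= 0")

    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    n_genes_per_chrom = int(round(gene_density * chrom_len))

    for ci in range(1, n_chrom + 1):
        chrom = f"chr{ci}"
        seq = rng.choice(list(BASES), size=chrom_len)
        seq = np.asarray(seq, dtype="U1")
        placed = 0
        cursor = int(rng.integers(2_500, 5_000))
        while placed < n_genes_per_chrom:
            region, layout = _build_gene_region(rng)
            if cursor + len(region) + 2_500 > chrom_len:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _layout_to_gene(
                gene_id=f"gene_{chrom}_{placed + 1:04d}",
                chrom=chrom,
                gene_start=cursor + 1,  # 1-based
                region_len=len(region),
                layout=layout,
                strand=strand,
            )
            genomic_region = revcomp(region) if strand == "-" else region
            seq[cursor : cursor + len(region)] = list(genomic_region)
            genes.append(gene)
            placed += 1
            cursor += len(region) + int(rng.integers(2_500, 6_000))
        genome[chrom] = "".join(seq)
    return genome, genes


def _build_gene_region(rng: np.random.Generator) -> tuple[str, dict]:
    """Build one gene's sense-strand sequence plus its internal layout.

    Layout intervals are 0-based half-open in sense-region coordinates.
    """
    n_codons = int(rng.integers(40, 120))  # incl. start and stop
    codons = [
        "ATG",
        *rng.choice(SENSE_CODONS, size=n_codons - 2).tolist(),
        str(rng.choice(STOP_CODONS)),
    ]
    cds_seq = "".join(codons)
    n_exons = int(rng.integers(1, 4))
    # split CDS at arbitrary interior points (phase need not be 0)
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(10, len(cds_seq) - 10), size=n_exons - 1, replace=False).tolist())
    else:
        cuts = []
    bounds = [0, *cuts, len(cds_seq)]
    cds_chunks = [cds_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    utr5 = "".join(rng.choice(list(BASES), size=int(rng.integers(20, 120))))
    utr3 = "".join(rng.choice(list(BASES), size=int(rng.integers(20, 120))))
    introns = ["GT" + "".join(rng.choice(list(BASES), size=int(rng.integers(30, 200)))) + "AG" for _ in range(n_exons - 1)]

    pieces: list[str] = [utr5]
    utr5_iv = (0, len(utr5))
    cds_ivs: list[tuple[int, int]] = []
    intron_ivs: list[tuple[int, int]] = []
    pos = len(utr5)
    for i, chunk in enumerate(cds_chunks):
        pieces.append(chunk)
        cds_ivs.append((pos, pos + len(chunk)))
        pos += len(chunk)
        if i < len(introns):
            pieces.append(introns[i])
            intron_ivs.append((pos, pos + len(introns[i])))
            pos += len(introns[i])
    pieces.append(utr3)
    utr3_iv = (pos, pos + len(utr3))
    pos += len(utr3)

    # exons = everything that is not an intron
    exon_ivs: list[tuple[int, int]] = []
    cut_points = [0] + [x for iv in intron_ivs for x in iv] + [pos]
    for a, b in zip(cut_points[0::2], cut_points[1::2]):
        exon_ivs.append((a, b))

    layout = {"utr5": [utr5_iv], "utr3": [utr3_iv], "cds": cds_ivs, "exons": exon_ivs}
    return "".join(pieces), layout


def _layout_to_gene(
    gene_id: str,
    chrom: str,
    gene_start: int,
    region_len: int,
    layout: dict,
    strand: str,
) -> GeneModel:
    """Map sense-region intervals to genomic 1-based inclusive coordinates."""

    def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv  # 0-based half-open, sense orientation
        if strand == "-":
            a, b = region_len - b, region_len - a
        return gene_start + a, gene_start + b - 1

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        start=gene_start,
        end=gene_start + region_len - 1,
        strand=strand,
        exons=sorted(to_genomic(iv) for iv in layout["exons"]),
        cds=sorted(to_genomic(iv) for iv in layout["cds"]),
        utr5=sorted(to_genomic(iv) for iv in layout["utr5"]),
        utr3=sorted(to_genomic(iv) for iv in layout["utr3"]),
    )


# ---------------------------------------------------------------------------
# IO


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], genome: dict[str, str], path: str | Path) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon/CDS/UTR features."""
    lines = ["##gff-version 3"]
    for chrom, seq in genome.items():
        lines.append(f"##sequence-region {chrom} 1 {len(seq)}")
    for g in genes:
        mrna_id = f"{g.gene_id}.1"
        lines.append(_gff_line(g.chrom, "gene", g.start, g.end, g.strand, ".", f"ID={g.gene_id}"))
        lines.append(_gff_line(g.chrom, "mRNA", g.start, g.end, g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(_gff_line(g.chrom, "exon", s, e, g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"))
        for s, e, phase in _cds_with_phase(g):
            lines.append(_gff_line(g.chrom, "CDS", s, e, g.strand, str(phase), f"ID={mrna_id}.cds;Parent={mrna_id}"))
        for s, e in g.utr5:
            lines.append(_gff_line(g.chrom, "five_prime_UTR", s, e, g.strand, ".", f"Parent={mrna_id}"))
        for s, e in g.utr3:
            lines.append(_gff_line(g.chrom, "three_prime_UTR", s, e, g.strand, ".", f"Parent={mrna_id}"))
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_line(chrom, ftype, start, end, strand, phase, attrs) -> str:
    return "\t".join([chrom, "ionmut", ftype, str(start), str(end), ".", strand, phase, attrs])


def _cds_with_phase(g: GeneModel) -> list[tuple[int, int, int]]:
    segs = sorted(g.cds)
    order = segs if g.strand == "+" else list(reversed(segs))
    out = []
    consumed = 0
    for s, e in order:
        phase = (3 - consumed % 3) % 3
        out.append((s, e, phase))
        consumed += e - s + 1
    return sorted(out)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        g = GeneModel(
            gene_id=gf.id,
            chrom=gf.seqid,
            start=gf.start,
            end=gf.end,
            strand=gf.strand,
        )
        for child in db.children(gf, level=None):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                g.exons.append(iv)
            elif child.featuretype == "CDS":
                g.cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                g.utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                g.utr3.append(iv)
        g.exons.sort()
        g.cds.sort()
        g.utr5.sort()
        g.utr3.sort()
        genes.append(g)
    return genes
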