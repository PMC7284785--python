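"""Region and coding-effect annotation of consensus mutations.

Assigns each mutation exactly one genomic region by the precedence
exonic > splicing > UTR5 > UTR3 > intronic > upstream > downstream >
intergenic (the conventional gene-based annotation hierarchy), where
"exonic" means coding sequence, "splicing" is within 2 bp of an intron
boundary, and upstream/downstream extend 1 kb from the gene span on the
strand-appropriate side. For exonic SBSs the effect is determined by
codon translation (standard genetic code); exonic InDels are frameshift
iff their size is not a multiple of 3, with stop-codon gain/loss also
assessed for in-frame events.
"""

from __future__ import annotations

from dataclasses import replace

from Bio.Seq import Seq

from .genome import GeneModel, revcomp
from .variant_pipeline import MutationRecord

REGION_PRECEDENCE = [
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
]
_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}

FLANK_BP = 1_000  # upstream/downstream window
SPLICE_BP = 2  # intronic bases flanking each exon counted as splicing


def representative_position(record: MutationRecord) -> int:
    """Genomic position used for region assignment.

    SBS and insertion: the record position (the insertion anchor);
    deletion: the first deleted base (pos + 1 after left-normalization).
    """
    if record.mut_class == "deletion":
        return record.pos + 1
    return record.pos


def _in(iv_list, pos: int) -> bool:
    return any(s <= pos <= e for s, e in iv_list)


def region_for_gene(pos: int, gene: GeneModel) -> str | None:
    """Region class of a position relative to one gene, or None if unrelated."""
    if gene.start <= pos <= gene.end:
        if _in(gene.cds, pos):
            return "exonic"
        for istart, iend in gene.introns:
            if istart <= pos <= istart + SPLICE_BP - 1 or iend - SPLICE_BP + 1 <= pos <= iend:
                return "splicing"
        if _in(gene.utr5, pos):
            return "UTR5"
        if _in(gene.utr3, pos):
            return "UTR3"
        return "intronic"
    before = gene.start - FLANK_BP <= pos < gene.start
    after = gene.end < pos <= gene.end + FLANK_BP
    if gene.strand == "+":
        if before:
            return "upstream"
        if after:
            return "downstream"
    else:
        if after:
            return "upstream"
        if before:
            return "downstream"
    return None


def annotate(
    record: MutationRecord,
    genes: list[GeneModel],
    genome: dict[str, str],
) -> MutationRecord:
    """Return a copy of ``record`` with region and effect filled in.

    When several genes overlap the site, the highest-precedence region
    wins. The effect is computed against the gene that supplied the
    winning exonic call; non-exonic records get effect "NA".
    """
    if record.chrom not in genome:
        raise ValueError(f"record chromosome {record.chrom!r} absent from genome")
    pos = representative_position(record)
    best = ("intergenic", None)
    for gene in genes:
        if gene.chrom != record.chrom:
            continue
        reg = region_for_gene(pos, gene)
        if reg is not None and _RANK[reg] < _RANK[best[0]]:
            best = (reg, gene)
    region, gene = best
    effect = "NA"
    if region == "exonic":
        if record.mut_class == "SBS":
            effect = sbs_effect(record, gene, genome)
        else:
            effect = indel_effect(record, gene, genome)
    return replace(record, region=region, effect=effect)


def sbs_effect(record: MutationRecord, gene: GeneModel, genome: dict[str, str]) -> str:
    """Codon-level effect of a coding SBS."""
    idx = gene.cds_index(record.pos)
    if idx is None:
        return "NA"
    cds = gene.coding_sequence(genome)
    alt = record.alt if gene.strand == "+" else revcomp(record.alt)
    codon_start = 3 * (idx // 3)
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        return "NA"
    mutated = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def indel_effect(record: MutationRecord, gene: GeneModel, genome: dict[str, str]) -> str:
    """Effect of a coding InDel: frameshift by size, else stop assessment."""
    size = record.size or abs(len(record.ref) - len(record.alt))
    if size % 3 != 0:
        return "frameshift"
    cds = gene.coding_sequence(genome)
    alt_cds = _apply_indel_to_cds(record, gene, cds)
    if alt_cds is None:
        return "nonframeshift"
    prot_ref = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    prot_alt = str(Seq(alt_cds[: len(alt_cds) - len(alt_cds) % 3]).translate())
    ref_has_stop = prot_ref.endswith("*")
    internal_stop = "*" in prot_alt[:-1]
    if internal_stop and "*" not in prot_ref[:-1]:
        return "stopgain"
    if ref_has_stop and not prot_alt.endswith("*") and not internal_stop:
        return "stoploss"
    return "nonframeshift"


def _apply_indel_to_cds(record: MutationRecord, gene: GeneModel, cds: str) -> str | None:
    """Coding sequence with the InDel applied, or None if it spans a CDS edge."""
    if record.mut_class == "insertion":
        anchor_idx = gene.cds_index(record.pos)
        if anchor_idx is None:
            return None
        ins = record.alt[len(record.ref):]
        if gene.strand == "+":
            return cds[: anchor_idx + 1] + ins + cds[anchor_idx + 1 :]
        return cds[:anchor_idx] + revcomp(ins) + cds[anchor_idx:]
    # deletion: genomic positions pos+1 .. pos+size
    size = len(record.ref) - len(record.alt)
    idxs = [gene.cds_index(record.pos + 1 + i) for i in range(size)]
    if any(i is None for i in idxs):
        return None
    keep = set(idxs)
    return "".join(b for i, b in enumerate(cds) if i not in keep)
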