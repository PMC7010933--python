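"""Gene-model parsing and promoter extraction.

The promoter of a gene is defined here as the up-to-2,000 bp of sequence
immediately upstream of the CDS start (the ATG), on the gene's coding
strand.  Genes whose representative CDS does not begin with ATG are
excluded; promoters truncated by a contig edge keep whatever upstream
sequence exists.  Internal coordinates are 0-based half-open; GFF3 I/O
is 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

#: wheat-style chromosome naming, e.g. "chr1A" -> subgenome "A"
SUBGENOME_PATTERN = r"^chr\d+([ABD])$"

_CLEAN = re.compile(r"[^ACGT]")


class Gff3ParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its representative CDS start.

    ``cds_start`` is the 0-based genomic coordinate of the first base of
    the start codon: on the + strand the leftmost CDS base, on the -
    strand the rightmost CDS base.
    """

    gene_id: str
    seqid: str
    strand: str  # "+" or "-"
    cds_start: int
    subgenome_key: Optional[str] = None


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str  # 5'->3' on the coding strand, ending just before ATG
    genomic_interval: tuple[int, int]  # 0-based half-open
    seqid: str
    strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_subgenome(seqid: str, pattern: str = SUBGENOME_PATTERN) -> Optional[str]:
    m = re.match(pattern, seqid)
    return m.group(1) if m else None


def _validate_gff3(path: Union[str, Path]) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"malformed GFF3 line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if fields[6] not in ("+", "-", ".", "?"):
                raise Gff3ParseError(
                    f"malformed GFF3 line {lineno}: bad strand {fields[6]!r}"
                )


def load_gene_models(
    gff3_path: Union[str, Path],
    subgenome_pattern: Optional[str] = SUBGENOME_PATTERN,
) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    When a gene has several mRNAs the representative transcript is the
    one with the longest total CDS; ties break on the lexicographically
    smallest transcript ID.  Genes with no CDS are skipped with a
    warning.
    """
    _validate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        candidates = []  # (-total_cds_len, transcript_id, [CDS features])
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = list(db.children(mrna, featuretype="CDS"))
            if cds:
                total = sum(c.end - c.start + 1 for c in cds)
                candidates.append((-total, mrna.id, cds))
        direct_cds = list(db.children(gene, featuretype="CDS", level=1))
        if direct_cds:
            total = sum(c.end - c.start + 1 for c in direct_cds)
            candidates.append((-total, gene.id, direct_cds))
        if not candidates:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            continue
        candidates.sort()
        _, _, cds = candidates[0]
        if gene.strand == "+":
            cds_start = min(c.start for c in cds) - 1  # to 0-based
        else:
            cds_start = max(c.end for c in cds) - 1  # rightmost base, 0-based
        subgenome = (
            parse_subgenome(gene.seqid, subgenome_pattern)
            if subgenome_pattern
            else None
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seqid=gene.seqid,
                strand=gene.strand,
                cds_start=cds_start,
                subgenome_key=subgenome,
            )
        )
    return genes


def load_genome(fasta_path: Union[str, Path]) -> dict[str, str]:
    """Read a (small) multi-FASTA into a seqid -> sequence dict."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def clean_sequence(seq: str) -> str:
    """Uppercase and collapse non-ACGT characters to N."""
    return _CLEAN.sub("N", seq.upper())


def _fetch(genome, seqid: str, start: int, end: int) -> str:
    return str(genome[seqid][start:end])


def extract_promoters(
    genes: list[GeneModel],
    genome: Mapping[str, str],
    promoter_length: int = 2000,
) -> list[Promoter]:
    """Extract the up-to-``promoter_length`` bp upstream of each ATG.

    Genes whose codon at ``cds_start`` (read on the coding strand) is
    not ATG are excluded and logged.  Minus-strand promoters are
    reverse-complemented so every returned sequence reads 5'->3' on the
    coding strand and ends immediately before the start codon.
    """
    promoters: list[Promoter] = []
    n_excluded = 0
    for g in genes:
        if g.seqid not in genome:
            raise KeyError(f"seqid {g.seqid!r} not present in genome")
        contig_len = len(genome[g.seqid])
        if g.strand == "+":
            codon = _fetch(genome, g.seqid, g.cds_start, g.cds_start + 3)
        else:
            codon = reverse_complement(
                _fetch(genome, g.seqid, max(g.cds_start - 2, 0), g.cds_start + 1)
            )
        if codon.upper() != "ATG":
            n_excluded += 1
            logger.warning(
                "gene %s excluded: CDS starts with %r, not ATG", g.gene_id, codon
            )
            continue
        if g.strand == "+":
            start = max(0, g.cds_start - promoter_length)
            interval = (start, g.cds_start)
            seq = _fetch(genome, g.seqid, *interval)
        else:
            end = min(contig_len, g.cds_start + 1 + promoter_length)
            interval = (g.cds_start + 1, end)
            seq = reverse_complement(_fetch(genome, g.seqid, *interval))
        promoters.append(
            Promoter(
                gene_id=g.gene_id,
                sequence=clean_sequence(seq),
                genomic_interval=interval,
                seqid=g.seqid,
                strand=g.strand,
            )
        )
    if n_excluded:
        logger.info("excluded %d gene(s) without an ATG start", n_excluded)
    return promoters


def write_promoters_fasta(promoters: list[Promoter], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_promoters_bed(promoters: list[Promoter], path: Union[str, Path]) -> None:
    """BED6 of promoter intervals (0-based half-open, name = gene_id)."""
    with open(path, "w") as fh:
        for p in promoters:
            start, end = p.genomic_interval
            fh.write(
                f"{p.seqid}\t{start}\t{end}\t{p.gene_id}\t0\t{p.strand}\n"
            )


def read_promoters_fasta(path: Union[str, Path]) -> list[Promoter]:
    """Load promoters from FASTA (genomic interval unknown -> (0, len))."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = clean_sequence(str(rec.seq))
        out.append(
            Promoter(
                gene_id=rec.id,
                sequence=seq,
                genomic_interval=(0, len(seq)),
                seqid=rec.id,
                strand="+",
            )
        )
    return out
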