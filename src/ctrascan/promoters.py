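"""Strand-aware promoter window extraction around translation starts.

The regulon scan examines the region from 400 bp upstream to 50 bp downstream
of each gene's translation start, oriented 5'->3' with respect to the gene.
Input coordinates follow the GFF3 convention (1-based, inclusive); oriented
promoter offsets are 0-based.  On linear contigs windows are clamped at the
contig edge and flagged truncated; on circular replicons they wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import reverse_complement

logger = logging.getLogger(__name__)

UPSTREAM_DEFAULT = 400
DOWNSTREAM_DEFAULT = 50


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates, strand, attributes."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class PromoterRegion:
    """An oriented promoter window with its genomic provenance.

    ``sequence`` reads 5'->3' with respect to the gene, so a motif hit offset
    in it is directly comparable between strands.  ``genomic_start/end`` are
    1-based inclusive on the forward strand of the contig; for windows that
    wrap a circular contig they are the unwrapped modular endpoints.
    """

    gene_id: str
    contig_id: str
    genomic_start: int
    genomic_end: int
    strand: str
    sequence: str
    truncated: bool


def extract_promoter(
    genome: Mapping[str, str],
    gene: GeneRecord,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    circular: bool | Mapping[str, bool] = False,
) -> PromoterRegion:
    """Extract one oriented promoter window around a gene's translation start.

    For a + strand gene the genomic window is [start-upstream, start+downstream-1];
    for a - strand gene it is [end-downstream+1, end+upstream], reverse
    complemented.  ``circular`` may be a flag or a per-contig mapping.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if gene.contig_id not in genome:
        raise KeyError(f"gene {gene.gene_id}: unknown contig {gene.contig_id!r}")
    contig = genome[gene.contig_id]
    L = len(contig)
    is_circular = (
        circular.get(gene.contig_id, False) if isinstance(circular, Mapping) else bool(circular)
    )
    gene_length = gene.end - gene.start + 1
    if downstream > gene_length:
        logger.warning(
            "gene %s: downstream window (%d) extends past the gene (length %d)",
            gene.gene_id, downstream, gene_length,
        )

    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream - 1
    else:
        lo, hi = gene.end - downstream + 1, gene.end + upstream

    truncated = False
    if is_circular:
        if hi - lo + 1 > L:
            raise ValueError(
                f"gene {gene.gene_id}: window ({hi - lo + 1} bp) exceeds circular "
                f"contig length {L}"
            )
        seq = "".join(contig[(i - 1) % L] for i in range(lo, hi + 1))
        genomic_start = (lo - 1) % L + 1
        genomic_end = (hi - 1) % L + 1
    else:
        clo, chi = max(lo, 1), min(hi, L)
        if clo > chi:
            raise ValueError(
                f"gene {gene.gene_id}: promoter window {lo}..{hi} lies entirely "
                f"outside contig {gene.contig_id} (length {L})"
            )
        truncated = (clo != lo) or (chi != hi)
        seq = contig[clo - 1 : chi]
        genomic_start, genomic_end = clo, chi

    if gene.strand == "-":
        seq = reverse_complement(seq)

    return PromoterRegion(
        gene_id=gene.gene_id,
        contig_id=gene.contig_id,
        genomic_start=genomic_start,
        genomic_end=genomic_end,
        strand=gene.strand,
        sequence=seq,
        truncated=truncated,
    )


def extract_all_promoters(
    genome: Mapping[str, str],
    genes: Iterable[GeneRecord],
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    circular: bool | Mapping[str, bool] = False,
) -> list[PromoterRegion]:
    """Extract promoters for many genes, skipping (and logging) failures."""
    regions = []
    for gene in genes:
        try:
            regions.append(
                extract_promoter(genome, gene, upstream, downstream, circular)
            )
        except (KeyError, ValueError) as exc:
            logger.warning("skipping gene %s: %s", gene.gene_id, exc)
    return regions


# ---------------------------------------------------------------------------
# File interfaces


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA genome into a contig_id -> sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _attr_scalar(values: list[str]) -> str | list[str]:
    return values[0] if len(values) == 1 else list(values)


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene records from GFF3 (``ID`` attribute becomes gene_id)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        attrs = {k: _attr_scalar(v) for k, v in feat.attributes.items()}
        gene_id = attrs.pop("ID", feat.id)
        genes.append(
            GeneRecord(
                gene_id=str(gene_id),
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                attributes=attrs,
            )
        )
    return genes


def read_genes_tsv(path: str | Path) -> list[GeneRecord]:
    """Tabular fallback: columns gene_id, contig, start, end, strand[, attributes].

    The optional ``attributes`` column holds ``key=value`` pairs separated by
    semicolons.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    genes = []
    for row in df.itertuples(index=False):
        attrs = {}
        raw = getattr(row, "attributes", None)
        if isinstance(raw, str) and raw:
            for pair in raw.split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attrs[k.strip()] = v.strip()
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                contig_id=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                attributes=attrs,
            )
        )
    return genes


def write_promoters_fasta(regions: Iterable[PromoterRegion], path: str | Path) -> None:
    """Write oriented promoters with headers ``gene_id|contig:start-end(strand)``."""
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.gene_id}|{r.contig_id}:{r.genomic_start}-{r.genomic_end}({r.strand})",
            description="",
        )
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")
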