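"""Genome-wide and cross-species CtrA binding-site screens.

``genome_scan`` runs the promoter extraction + PWM scan over every annotated
gene of one genome and summarises how many promoters carry at least one site
(the statistic behind the genome-wide "promoter regions with a CtrA box"
count), how many sites there are in total, and how many are perfect.

``cross_species_screen`` repeats the scan over a collection of strains but
restricted to quorum-sensing genes — those annotated with an autoinducer
synthase (pfam00765) or autoinducer-binding (pfam03475) domain.  Domain
labels are consumed as precomputed annotation; no domain search is run here.
Because it is ambiguous whether a strain's class in such comparative figures
counts QS promoters carrying a site or total sites, both numbers are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motif import DEFAULT_THRESHOLD_FRACTION, MotifHit, MotifModel, scan_sequence
from .promoters import (
    DOWNSTREAM_DEFAULT,
    UPSTREAM_DEFAULT,
    GeneRecord,
    PromoterRegion,
    extract_promoter,
    read_genes_gff3,
    read_genes_tsv,
    read_genome_fasta,
)

logger = logging.getLogger(__name__)

QS_DOMAINS = ("pfam00765", "pfam03475")

#: Attribute keys searched for precomputed protein-domain labels.
DOMAIN_ATTRIBUTE_KEYS = ("domains", "domain", "pfam")


@dataclass
class GenomeScanResult:
    """Per-gene motif hits plus the summary counts of one genome scan."""

    hits_by_gene: dict[str, list[MotifHit]]
    promoters: dict[str, PromoterRegion]
    skipped_genes: list[str] = field(default_factory=list)

    @property
    def n_genes_scanned(self) -> int:
        return len(self.hits_by_gene)

    @property
    def n_promoters_with_hit(self) -> int:
        return sum(1 for hits in self.hits_by_gene.values() if hits)

    @property
    def n_hits_total(self) -> int:
        return sum(len(hits) for hits in self.hits_by_gene.values())

    @property
    def n_perfect(self) -> int:
        return sum(h.perfect for hits in self.hits_by_gene.values() for h in hits)

    @property
    def n_promoters_with_perfect(self) -> int:
        return sum(
            1 for hits in self.hits_by_gene.values() if any(h.perfect for h in hits)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene_id,
                "contig_id": self.promoters[gene_id].contig_id,
                "promoter_offset": h.offset,
                "strand_in_promoter": h.strand,
                "score": h.score,
                "score_fraction": h.score_fraction,
                "perfect": h.perfect,
            }
            for gene_id, hits in self.hits_by_gene.items()
            for h in hits
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "contig_id", "promoter_offset", "strand_in_promoter",
                "score", "score_fraction", "perfect",
            ],
        )


@dataclass(frozen=True)
class SpeciesScreenRecord:
    """Per-strain outcome of the quorum-sensing promoter screen."""

    strain_id: str
    qs_gene_ids: tuple[str, ...]
    n_qs_promoters_with_site: int
    n_sites_total: int
    failed: bool = False


def genome_scan(
    genome: Mapping[str, str],
    genes: Sequence[GeneRecord],
    model: MotifModel,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    strands: str = "both",
    circular: bool | Mapping[str, bool] = False,
) -> GenomeScanResult:
    """Scan every gene's promoter window for motif hits.

    Genes whose promoter cannot be extracted are excluded from all
    denominators and recorded in ``skipped_genes``.
    """
    hits_by_gene: dict[str, list[MotifHit]] = {}
    promoters: dict[str, PromoterRegion] = {}
    skipped: list[str] = []
    for gene in genes:
        try:
            region = extract_promoter(genome, gene, upstream, downstream, circular)
        except (KeyError, ValueError) as exc:
            logger.warning("genome_scan: skipping %s: %s", gene.gene_id, exc)
            skipped.append(gene.gene_id)
            continue
        promoters[gene.gene_id] = region
        hits_by_gene[gene.gene_id] = scan_sequence(
            model, region.sequence, threshold_fraction, strands
        )
    return GenomeScanResult(
        hits_by_gene=hits_by_gene, promoters=promoters, skipped_genes=skipped
    )


def _domain_labels(gene: GeneRecord) -> set[str]:
    labels: set[str] = set()
    for key in DOMAIN_ATTRIBUTE_KEYS:
        value = gene.attributes.get(key)
        if value is None:
            continue
        if isinstance(value, str):
            parts = value.replace(";", ",").split(",")
        else:
            parts = list(value)
        labels.update(p.strip().lower() for p in parts if p.strip())
    return labels


def select_qs_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Return genes labelled with an autoinducer synthesis or binding domain.

    A gene carrying both labels is returned once; genes without any domain
    attribute are treated as unlabelled.
    """
    wanted = {d.lower() for d in QS_DOMAINS}
    return [g for g in genes if _domain_labels(g) & wanted]


def cross_species_screen(
    collection: Mapping[str, tuple[Mapping[str, str], Sequence[GeneRecord]]],
    model: MotifModel,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    strands: str = "both",
) -> list[SpeciesScreenRecord]:
    """Screen each strain's QS gene promoters for motif sites.

    Strains without any QS-labelled gene are reported with an empty gene list
    and a warning; a strain whose inputs fail to scan is recorded as failed
    and the screen continues.  Output order follows sorted strain id, so the
    result is invariant to input ordering.
    """
    records = []
    for strain_id in sorted(collection):
        genome, genes = collection[strain_id]
        try:
            qs_genes = select_qs_genes(genes)
            if not qs_genes:
                logger.warning("strain %s has no QS-labelled genes", strain_id)
                records.append(
                    SpeciesScreenRecord(strain_id, (), 0, 0, failed=False)
                )
                continue
            result = genome_scan(
                genome, qs_genes, model, threshold_fraction,
                upstream, downstream, strands,
            )
            records.append(
                SpeciesScreenRecord(
                    strain_id=strain_id,
                    qs_gene_ids=tuple(g.gene_id for g in qs_genes),
                    n_qs_promoters_with_site=result.n_promoters_with_hit,
                    n_sites_total=result.n_hits_total,
                )
            )
        except Exception as exc:  # noqa: BLE001 - screen must survive bad strains
            logger.error("strain %s failed: %s", strain_id, exc)
            records.append(SpeciesScreenRecord(strain_id, (), 0, 0, failed=True))
    return records


# ---------------------------------------------------------------------------
# File interfaces


def load_collection_manifest(
    manifest_path: str | Path,
) -> dict[str, tuple[dict[str, str], list[GeneRecord]]]:
    """Load a strain collection from a TSV manifest.

    Columns: strain_id, genome_fasta_path, annotation_path.  Relative paths
    are resolved against the manifest's directory; ``.gff``/``.gff3``
    annotations are parsed as GFF3, anything else as the tabular fallback.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    collection = {}
    for row in df.itertuples(index=False):
        genome_path = manifest_path.parent / row.genome_fasta_path
        annot_path = manifest_path.parent / row.annotation_path
        genome = read_genome_fasta(genome_path)
        if annot_path.suffix.lower() in (".gff", ".gff3"):
            genes = read_genes_gff3(annot_path)
        else:
            genes = read_genes_tsv(annot_path)
        collection[str(row.strain_id)] = (genome, genes)
    return collection


def screen_to_frame(records: Iterable[SpeciesScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "n_qs_genes": len(r.qs_gene_ids),
                "n_qs_promoters_with_site": r.n_qs_promoters_with_site,
                "n_sites_total": r.n_sites_total,
                "failed": r.failed,
            }
            for r in records
        ],
        columns=[
            "strain_id", "n_qs_genes", "n_qs_promoters_with_site",
            "n_sites_total", "failed",
        ],
    )
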