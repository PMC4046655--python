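"""Synthetic fixtures with known ground truth for every pipeline stage.

Four generators mirror the four kinds of real input the pipeline consumes:

* ``make_genome`` — a genome (FASTA + GFF3-style gene records) with
  consensus-like motif instances planted at known oriented promoter offsets
  and a background kept free of threshold-passing windows by rejection
  sampling against the live scanner, so planted-site counts are exact truths.
* ``make_species_collection`` — a set of small strain genomes whose
  quorum-sensing genes (pfam-labelled) carry a prescribed number of planted
  promoter sites each, emulating the cross-species screen input.
* ``evolve_proteins`` — protein families evolved along a known tree under the
  substitution process whose pairwise expectation the Poisson correction
  inverts: along a branch of length d each site substitutes with probability
  1 - exp(-d) to a uniformly chosen different residue.
* ``make_de_table`` — differential-expression tables with a prescribed number
  of up/down genes per contrast and a prescribed core shared by all
  contrasts; the generator verifies its own truth by running the caller.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import de_filter
from .motif import (
    CTRA_CONSENSUS,
    MotifModel,
    build_pwm_from_consensus,
    reverse_complement,
    scan_sequence,
)
from .phylo import AMINO_ACIDS, ProteinAlignment
from .promoters import GeneRecord

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# genome layout constants: every gene gets a private block wide enough for a
# full 450 bp promoter on either strand plus a 100 bp gap
GENE_LENGTH = 600
_BLOCK = 400 + 50 + GENE_LENGTH + 100


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for a synthetic genome with planted motif instances.

    ``planted`` lists (gene_index, promoter_offset, n_mismatches) triples;
    the offset is 0-based within the oriented promoter window and the
    mismatches are applied to specified (non-N) consensus positions.
    """

    n_genes: int
    planted: tuple[tuple[int, int, int], ...] = ()
    contig_length: int | None = None
    fraction_minus_strand: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        seen = set()
        for gene_index, offset, _ in self.planted:
            if not 0 <= gene_index < self.n_genes:
                raise ValueError(f"planted gene_index {gene_index} out of range")
            if gene_index in seen:
                raise ValueError("at most one planted site per gene")
            seen.add(gene_index)


def _random_bases(rng: np.random.Generator, n: int, background) -> np.ndarray:
    return rng.choice(np.arange(4), size=n, p=list(background))


def _motif_instance(
    rng: np.random.Generator,
    consensus: str,
    n_mismatches: int,
    background,
) -> tuple[str, int]:
    """A concrete site: N positions random, n_mismatches specified positions broken."""
    specified = [i for i, c in enumerate(consensus) if c != "N"]
    if n_mismatches > len(specified):
        raise ValueError("more mismatches than specified consensus positions")
    chars = [
        c if c != "N" else _BASES[_random_bases(rng, 1, background)[0]]
        for c in consensus
    ]
    for pos in rng.choice(specified, size=n_mismatches, replace=False):
        alternatives = [b for b in "ACGT" if b != consensus[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars), len(specified) - n_mismatches


def make_genome(
    spec: PlantSpec,
    consensus: str = CTRA_CONSENSUS,
    guard_threshold_fraction: float = 0.75,
    upstream: int = 400,
    downstream: int = 50,
) -> tuple[dict[str, str], list[GeneRecord], pd.DataFrame]:
    """Generate (genome, genes, truth) with motif instances at known offsets.

    The background is rejection-sampled against the scanner so that no
    window outside the planted sites (and their deterministic one-base-shift
    opposite-strand shadows) reaches ``guard_threshold_fraction`` of the
    model maximum on either strand.  Promoter-level hit counts and perfect
    -site counts are therefore exact truths for any scan threshold at or
    above the guard; total hit counts include one shadow per strong plant.
    """
    rng = np.random.default_rng(spec.seed)
    model = build_pwm_from_consensus(consensus)
    L = model.length
    window = upstream + downstream
    for _, offset, _ in spec.planted:
        if offset + L > window:
            raise ValueError(
                f"promoter_offset {offset} + motif length {L} exceeds the "
                f"{window} bp promoter window"
            )

    needed = spec.n_genes * _BLOCK + 100
    contig_length = spec.contig_length or needed
    if contig_length < needed:
        raise ValueError(
            f"infeasible packing: {spec.n_genes} genes need a contig of at "
            f"least {needed} bp, got {contig_length}; use a longer contig"
        )

    seq = _random_bases(rng, contig_length, spec.background)

    genes: list[GeneRecord] = []
    strands = np.where(
        rng.random(spec.n_genes) < spec.fraction_minus_strand, "-", "+"
    )
    for i in range(spec.n_genes):
        base = i * _BLOCK
        if strands[i] == "+":
            start = base + upstream + 51
        else:
            start = base + 101
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:04d}",
                contig_id="contig1",
                start=start,
                end=start + GENE_LENGTH - 1,
                strand=strands[i],
                attributes={},
            )
        )

    # Plant sites; remember genomic span + strand, and protect the specified
    # consensus positions from background re-randomisation.  The canonical
    # box is near-palindromic under a one-base shift (the reverse complement
    # of a perfect site contains an 8-of-9 match), so every plant casts a
    # deterministic opposite-strand "shadow" hit one base over; shadows are
    # whitelisted, and the flanking base is pinned so a shadow can never be
    # a perfect match itself.
    protected = np.zeros(contig_length, dtype=bool)
    allowed_lookup: set[tuple[int, str]] = set()
    truth_rows = []
    base_to_idx = {b: k for k, b in enumerate("ACGT")}
    for gene_index, offset, n_mm in spec.planted:
        gene = genes[gene_index]
        instance, score = _motif_instance(rng, consensus, n_mm, spec.background)
        if gene.strand == "+":
            g0 = gene.start - upstream - 1 + offset  # 0-based leftmost
            placed = instance
            shadow = (g0 - 1, "-")
            flank_pos, flank_banned = g0 - 1, "G"
        else:
            g0 = gene.end + upstream - offset - L  # 0-based leftmost
            placed = reverse_complement(instance)
            shadow = (g0 + 1, "+")
            flank_pos, flank_banned = g0 + L, "C"
        seq[g0 : g0 + L] = [base_to_idx[b] for b in placed]
        for k, c in enumerate(consensus):
            if c != "N":
                pos = g0 + k if gene.strand == "+" else g0 + (L - 1 - k)
                protected[pos] = True
        if 0 <= flank_pos < contig_length:
            choices = [base_to_idx[b] for b in "ACGT" if b != flank_banned]
            seq[flank_pos] = choices[rng.integers(3)]
            protected[flank_pos] = True
        allowed_lookup.add((g0, gene.strand))
        allowed_lookup.add(shadow)
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "gene_index": gene_index,
                "contig_id": "contig1",
                "gene_strand": gene.strand,
                "promoter_offset": offset,
                "n_mismatches": n_mm,
                "expected_score": float(score),
                "genomic_start": g0 + 1,
                "genomic_end": g0 + L,
            }
        )

    # rejection sampling: re-randomise background under any spurious hit
    for _ in range(500):
        contig = "".join(_BASES[seq])
        hits = scan_sequence(model, contig, guard_threshold_fraction, "both")
        spurious = [h for h in hits if (h.offset, h.strand) not in allowed_lookup]
        if not spurious:
            break
        for h in spurious:
            free = [
                pos for pos in range(h.offset, h.offset + L) if not protected[pos]
            ]
            if not free:
                raise RuntimeError(
                    "spurious hit entirely within planted positions; "
                    "cannot re-randomise"
                )
            seq[free] = _random_bases(rng, len(free), spec.background)
    else:
        raise RuntimeError("background rejection sampling did not converge")

    genome = {"contig1": "".join(_BASES[seq])}
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "gene_index", "contig_id", "gene_strand",
            "promoter_offset", "n_mismatches", "expected_score",
            "genomic_start", "genomic_end",
        ],
    )
    return genome, genes, truth


def write_genome_files(
    genome: Mapping[str, str],
    genes: Sequence[GeneRecord],
    outdir: str | Path,
    prefix: str = "synthetic",
) -> tuple[Path, Path]:
    """Write a generated genome as FASTA + GFF3; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{prefix}.fasta"
    gff = outdir / f"{prefix}.gff3"
    with open(fasta, "w") as fh:
        for contig_id, seq in genome.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = ";".join(
                [f"ID={g.gene_id}"]
                + [f"{k}={v}" for k, v in sorted(g.attributes.items())]
            )
            fh.write(
                f"{g.contig_id}\tctrascan_sim\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
    return fasta, gff


def make_species_collection(
    n_strains: int,
    qs_sites_per_strain: Sequence[int],
    seed: int = 0,
    n_qs_genes: int | None = None,
    n_other_genes: int = 3,
    decoy_sites_in_non_qs: Sequence[int] | None = None,
    consensus: str = CTRA_CONSENSUS,
) -> tuple[dict[str, tuple[dict[str, str], list[GeneRecord]]], pd.DataFrame]:
    """Strain collection for the QS screen, one planted site per QS promoter.

    Strain i carries ``qs_sites_per_strain[i]`` perfect sites, each in the
    promoter of a distinct pfam-labelled QS gene, so the promoter-level and
    site-level classes coincide by construction.  ``decoy_sites_in_non_qs``
    optionally plants sites upstream of unlabelled genes (which the screen
    must ignore).
    """
    if len(qs_sites_per_strain) != n_strains:
        raise ValueError("qs_sites_per_strain length must equal n_strains")
    decoys = list(decoy_sites_in_non_qs or [0] * n_strains)
    if len(decoys) != n_strains:
        raise ValueError("decoy_sites_in_non_qs length must equal n_strains")
    n_qs = n_qs_genes or max(2, max(qs_sites_per_strain, default=1))
    if max(qs_sites_per_strain, default=0) > n_qs:
        raise ValueError("more sites requested than QS genes available")

    rng = np.random.default_rng(seed)
    collection = {}
    rows = []
    for i in range(n_strains):
        strain_id = f"strain{i + 1:02d}"
        n_sites = qs_sites_per_strain[i]
        n_decoy = decoys[i]
        if n_decoy > n_other_genes:
            raise ValueError("more decoy sites than non-QS genes")
        n_genes = n_qs + n_other_genes
        planted = [
            (j, int(rng.integers(0, 450 - len(consensus))), 0)
            for j in range(n_sites)
        ] + [
            (n_qs + j, int(rng.integers(0, 450 - len(consensus))), 0)
            for j in range(n_decoy)
        ]
        spec = PlantSpec(
            n_genes=n_genes,
            planted=tuple(planted),
            seed=int(rng.integers(2**31)),
        )
        genome, genes, _ = make_genome(spec, consensus=consensus)
        labelled = []
        for j, gene in enumerate(genes):
            attrs = dict(gene.attributes)
            if j < n_qs:
                attrs["domains"] = "pfam00765" if j % 2 == 0 else "pfam03475"
            labelled.append(
                GeneRecord(
                    gene_id=f"{strain_id}_{gene.gene_id}",
                    contig_id=gene.contig_id,
                    start=gene.start,
                    end=gene.end,
                    strand=gene.strand,
                    attributes=attrs,
                )
            )
        collection[strain_id] = (genome, labelled)
        rows.append(
            {
                "strain_id": strain_id,
                "n_qs_genes": n_qs,
                "n_sites_planted": n_sites,
                "n_decoy_sites": n_decoy,
            }
        )
    truth = pd.DataFrame(rows)
    return collection, truth


def write_collection(
    collection: Mapping[str, tuple[Mapping[str, str], Sequence[GeneRecord]]],
    outdir: str | Path,
) -> Path:
    """Write per-strain FASTA/GFF3 files plus a manifest TSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for strain_id in sorted(collection):
        genome, genes = collection[strain_id]
        fasta, gff = write_genome_files(genome, genes, outdir, prefix=strain_id)
        rows.append(
            {
                "strain_id": strain_id,
                "genome_fasta_path": fasta.name,
                "annotation_path": gff.name,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Protein evolution


def random_binary_tree(
    n_taxa: int,
    seed: int = 0,
    edge_length_range: tuple[float, float] = (0.05, 0.5),
) -> TreeNode:
    """Random unrooted binary tree (trifurcating seed node) with uniform edges.

    Built by sequential random edge attachment starting from a three-leaf star.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = [TreeNode(name=f"t{i + 1}") for i in range(n_taxa)]
    root.extend(leaves[:3])
    attachable = list(leaves[:3])
    for leaf in leaves[3:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        new_internal = TreeNode()
        parent.remove(target)
        parent.append(new_internal)
        new_internal.append(target)
        new_internal.append(leaf)
        attachable.extend([new_internal, leaf])
    lo, hi = edge_length_range
    for node in root.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    return root


def evolve_proteins(
    tree: TreeNode | str,
    length: int,
    seed: int = 0,
    gap_columns: int = 0,
) -> tuple[ProteinAlignment, dict]:
    """Evolve a protein alignment along a tree under the Poisson-type process.

    The root sequence is uniform over the 20 amino acids; along each branch of
    length d every site substitutes with probability 1 - exp(-d), to a
    uniformly chosen *different* residue (at most one event per branch per
    site — the idealised process whose pairwise-difference expectation the
    Poisson correction inverts).  ``gap_columns`` distinct columns optionally
    receive a gap in one random row, for complete-deletion testing.
    """
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            raise ValueError("every branch needs a non-negative length")
    if length < 1:
        raise ValueError("length must be >= 1")
    if gap_columns > length:
        raise ValueError("more gap columns than columns")

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    n_aa = len(aa)

    sequences: dict[int, np.ndarray] = {
        id(tree): rng.integers(0, n_aa, size=length)
    }
    for node in tree.preorder(include_self=False):
        parent_seq = sequences[id(node.parent)]
        child = parent_seq.copy()
        p_sub = 1.0 - np.exp(-node.length)
        hit = rng.random(length) < p_sub
        # shift by 1..19 mod 20: uniform over the 19 other residues
        child[hit] = (child[hit] + rng.integers(1, n_aa, size=hit.sum())) % n_aa
        sequences[id(node)] = child

    tips = list(tree.tips())
    rows = ["".join(aa[sequences[id(t)]]) for t in tips]
    gap_cols = sorted(
        int(c) for c in rng.choice(length, size=gap_columns, replace=False)
    )
    if gap_cols:
        rows = [list(r) for r in rows]
        for col in gap_cols:
            rows[rng.integers(len(rows))][col] = "-"
        rows = ["".join(r) for r in rows]
    alignment = ProteinAlignment(
        taxa=tuple(t.name for t in tips), rows=tuple(rows)
    )
    truth = {"tree": tree, "gap_columns": gap_cols}
    return alignment, truth


# ---------------------------------------------------------------------------
# Differential-expression tables


def make_de_table(
    n_genes: int,
    per_contrast_truth: Mapping[str, tuple[int, int]],
    shared: tuple[int, int] = (0, 0),
    effect_size_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """DE table with exact per-contrast up/down truth and a shared core.

    ``shared`` = (n_up, n_down) genes differentially expressed with the same
    direction in *every* contrast; the remaining per-contrast calls come from
    contrast-private gene pools, so with >= 2 contrasts the all-contrast
    intersection equals sum(shared) exactly.  True calls get |log2FC| >= 1
    drawn from ``effect_size_range`` and near-zero raw p-values; null genes
    get |log2FC| < 1.  The generated calls are verified by running the DE
    caller before returning.
    """
    lo, hi = effect_size_range
    if lo < 1.0:
        raise ValueError("effect sizes below 1 cannot satisfy the calling rule")
    shared_up, shared_down = shared
    extras = {
        c: (nu - shared_up, nd - shared_down)
        for c, (nu, nd) in per_contrast_truth.items()
    }
    if any(eu < 0 or ed < 0 for eu, ed in extras.values()):
        raise ValueError("shared core larger than a contrast's truth")
    n_needed = shared_up + shared_down + sum(eu + ed for eu, ed in extras.values())
    if n_needed > n_genes:
        raise ValueError(
            f"infeasible truth: need {n_needed} distinct DE genes, have {n_genes}"
        )

    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"Dsyn_{i + 1:04d}" for i in range(n_genes)])
    order = rng.permutation(n_genes)
    cursor = 0

    def _take(k: int) -> list[str]:
        nonlocal cursor
        picked = gene_ids[order[cursor : cursor + k]]
        cursor += k
        return list(picked)

    shared_up_genes = _take(shared_up)
    shared_down_genes = _take(shared_down)
    truth: dict[str, dict[str, set[str]]] = {}
    for contrast, (eu, ed) in extras.items():
        truth[contrast] = {
            "up": set(shared_up_genes) | set(_take(eu)),
            "down": set(shared_down_genes) | set(_take(ed)),
        }

    frames = []
    for contrast in per_contrast_truth:
        lfc = rng.uniform(-0.9, 0.9, size=n_genes)
        pval = rng.uniform(0.0, 1.0, size=n_genes)
        up = np.isin(gene_ids, list(truth[contrast]["up"]))
        down = np.isin(gene_ids, list(truth[contrast]["down"]))
        lfc[up] = rng.uniform(lo, hi, size=up.sum())
        lfc[down] = -rng.uniform(lo, hi, size=down.sum())
        de = up | down
        pval[de] = rng.uniform(1e-12, 1e-8, size=de.sum())
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "contrast": contrast,
                    "log2fc": lfc,
                    "pvalue": pval,
                    "adj_pvalue": de_filter.bh_adjust(pval),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    # generation-time self-check: the caller must reproduce the truth exactly
    for contrast in per_contrast_truth:
        call = de_filter.call_de(table, contrast)
        if set(call.up) != truth[contrast]["up"] or set(call.down) != truth[contrast]["down"]:
            raise RuntimeError(
                f"generator self-check failed for contrast {contrast!r}"
            )
    truth_out = {
        "per_contrast": truth,
        "shared_up": set(shared_up_genes),
        "shared_down": set(shared_down_genes),
    }
    return table, truth_out
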