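"""Differential-expression calling, regulon overlaps and category tallies.

The knockout transcriptomes (each mutant vs. wild type, per growth phase)
arrive as processed per-gene statistics: log2 fold change and a raw and/or
Benjamini-Hochberg-adjusted p-value per contrast.  A gene is called
differentially expressed when |log2FC| >= 1 and adjusted p < 0.05 (the
inclusive fold-change rule is the default; ``strict_gt`` switches to a strict
inequality).  BH adjustment is applied per contrast.  Downstream utilities
partition the calls of several contrasts into Venn cells and tally calls
against a user-supplied gene -> functional-category map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LFC_MIN_DEFAULT = 1.0
ALPHA_DEFAULT = 0.05

DE_COLUMNS = ["gene_id", "contrast", "log2fc", "pvalue"]


@dataclass(frozen=True)
class ContrastCall:
    """Up- and down-regulated gene sets for one contrast (disjoint by rule)."""

    contrast_id: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")

    @property
    def either(self) -> frozenset[str]:
        return self.up | self.down


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (gene_id, contrast) uniqueness and p-value range invariants."""
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table lacks columns {missing}")
    if table.duplicated(["gene_id", "contrast"]).any():
        raise ValueError("(gene_id, contrast) pairs are not unique")
    for col in ("pvalue", "adj_pvalue"):
        if col in table.columns:
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
    return table


def read_de_table(
    path: str | Path,
    sep: str = "\t",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a DE table (TSV/CSV), optionally renaming columns via ``column_map``.

    ``column_map`` maps file column names to the canonical names
    gene_id/contrast/log2fc/pvalue/adj_pvalue, supporting spreadsheet exports
    with arbitrary headers.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_de_table(df)


def call_de(
    table: pd.DataFrame,
    contrast_id: str,
    lfc_min: float = LFC_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    use_precomputed_adj: bool = False,
    strict_gt: bool = False,
) -> ContrastCall:
    """Apply the DE rule to one contrast.

    up: log2fc >= lfc_min (or > with ``strict_gt``) and adjusted p < alpha;
    down: the mirror image.  With ``use_precomputed_adj`` the table's
    ``adj_pvalue`` column is used; otherwise BH is applied to the contrast's
    raw p-values.  Genes with missing statistics are excluded (and counted in
    a log message).
    """
    validate_de_table(table)
    sub = table[table["contrast"] == contrast_id]
    if sub.empty:
        raise ValueError(f"contrast {contrast_id!r} not present in table")

    if use_precomputed_adj:
        if "adj_pvalue" not in sub.columns or sub["adj_pvalue"].isna().all():
            raise ValueError(
                f"contrast {contrast_id!r}: adj_pvalue required but absent"
            )
        adj = sub["adj_pvalue"].to_numpy(dtype=float)
    else:
        usable = sub["pvalue"].notna()
        adj = np.full(len(sub), np.nan)
        adj[usable.to_numpy()] = bh_adjust(sub.loc[usable, "pvalue"].to_numpy())

    lfc = sub["log2fc"].to_numpy(dtype=float)
    ok = np.isfinite(lfc) & np.isfinite(adj)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "contrast %s: %d genes with missing statistics excluded",
            contrast_id, n_dropped,
        )
    genes = sub["gene_id"].to_numpy()
    if lfc_min < 0:
        raise ValueError("lfc_min must be non-negative")
    # the lfc > 0 / lfc < 0 guards keep a gene with log2fc exactly 0 out of
    # both sets when lfc_min is 0
    if strict_gt:
        up_mask = ok & (lfc > lfc_min) & (adj < alpha)
        down_mask = ok & (lfc < -lfc_min) & (adj < alpha)
    else:
        up_mask = ok & (lfc >= lfc_min) & (lfc > 0) & (adj < alpha)
        down_mask = ok & (lfc <= -lfc_min) & (lfc < 0) & (adj < alpha)
    return ContrastCall(
        contrast_id=contrast_id,
        up=frozenset(genes[up_mask]),
        down=frozenset(genes[down_mask]),
    )


def venn_partition(
    calls: Sequence[ContrastCall], direction: str = "either"
) -> dict[frozenset[str], int]:
    """Partition the union of called genes into exclusive Venn cells.

    Keys are frozensets of contrast ids (every non-empty subset of the k
    contrasts, zero counts included); each gene in the union contributes to
    exactly one cell, so the counts sum to the union cardinality.
    ``direction`` selects which gene set represents each contrast: up, down,
    or their union.
    """
    if len(calls) < 2:
        raise ValueError("venn_partition needs at least 2 contrasts")
    if direction not in ("up", "down", "either"):
        raise ValueError("direction must be 'up', 'down' or 'either'")
    sets = {c.contrast_id: frozenset(getattr(c, direction)) for c in calls}
    if len(sets) != len(calls):
        raise ValueError("contrast ids are not unique")
    names = list(sets)
    cells: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for k in range(1, len(names) + 1)
        for combo in combinations(names, k)
    }
    union = frozenset().union(*sets.values())
    for gene in union:
        members = frozenset(n for n in names if gene in sets[n])
        cells[members] += 1
    return cells


def venn_to_frame(cells: Mapping[frozenset[str], int]) -> pd.DataFrame:
    rows = [
        {"contrasts": "&".join(sorted(sig)), "n_genes": count}
        for sig, count in sorted(cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["contrasts", "n_genes"])


UNASSIGNED = "unassigned"


def category_tally(
    call: ContrastCall, gene_to_category: Mapping[str, str]
) -> pd.DataFrame:
    """Count up/down calls per functional category (e.g. COG letters).

    Genes absent from the map fall under ``unassigned``; column totals equal
    |up| and |down|.
    """
    counts: dict[str, list[int]] = {}
    for gene_set, col in ((call.up, 0), (call.down, 1)):
        for gene in gene_set:
            cat = gene_to_category.get(gene, UNASSIGNED)
            counts.setdefault(cat, [0, 0])[col] += 1
    df = pd.DataFrame(
        [
            {"category": cat, "n_up": up, "n_down": down}
            for cat, (up, down) in sorted(counts.items())
        ],
        columns=["category", "n_up", "n_down"],
    )
    return df
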