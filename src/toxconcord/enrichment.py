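"""Hypergeometric overrepresentation of DEGs in gene-set collections.

For a contrast with N testable genes (the universe), K of them in a set,
and n DEGs of one direction, the enrichment p-value is the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n).  Up- and down-regulated DEGs are
tested separately and BH-adjusted within one (contrast, direction); sets
with adjusted p < 0.05 are called significantly enriched.

Sets are intersected with the universe first; sets left with fewer than
``min_set_size`` genes (default 3) are dropped and logged — degenerate
tails carry no information.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ENRICH_FDR = 0.05
DEFAULT_MIN_SET_SIZE = 3


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(degs, collection: GeneSetCollection, universe,
                     direction: str = "up",
                     fdr: float = DEFAULT_ENRICH_FDR,
                     min_set_size: int = DEFAULT_MIN_SET_SIZE) -> pd.DataFrame:
    """One enrichment table for one contrast and direction."""
    universe = set(universe)
    degs = set(degs)
    outside = degs - universe
    if outside:
        raise ValueError(
            f"DEGs outside the universe: {sorted(outside)[:10]}")
    N, n = len(universe), len(degs)
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe
        if len(members) < min_set_size:
            logger.debug("dropping set %s (%d genes after universe "
                         "intersection)", name, len(members))
            continue
        K = len(members)
        k = len(members & degs)
        rows.append((name, direction, k, K, n, N,
                     hypergeom_pvalue(N, K, n, k)))
    table = pd.DataFrame(rows, columns=["gene_set", "direction", "k", "K",
                                        "n_deg", "N_universe", "p"])
    table["padj"] = np.nan if table.empty else _bh(table["p"].to_numpy())
    table["significant"] = table["padj"] < fdr
    return table.sort_values(["padj", "p", "gene_set"],
                             kind="mergesort").reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    from .diffexpr import bh_adjust
    return bh_adjust(p)


def enrich_all_contrasts(de_results: pd.DataFrame,
                         collection: GeneSetCollection,
                         fdr: float = DEFAULT_ENRICH_FDR,
                         min_set_size: int = DEFAULT_MIN_SET_SIZE,
                         directions: tuple[str, ...] = ("up", "down"),
                         ) -> pd.DataFrame:
    """Enrichment per (genotype, chemical, concentration, timepoint,
    direction) from the tidy probe-level DE table.

    Universe per contrast = genes with >=1 tested probe in that contrast;
    DEGs of a direction = genes with >=1 DEP of that sign.
    """
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h"]
    frames = []
    tested = de_results[de_results.get("skipped", False) == False]  # noqa: E712
    for cell, sub in tested.groupby(cell_cols, sort=True):
        ok = sub[~sub["p"].isna()]
        universe = set(ok["gene"])
        if not universe:
            continue
        dep = ok[ok["dep"].astype("boolean").fillna(False).astype(bool)]
        for direction in directions:
            degs = set(dep.loc[dep["direction"] == direction, "gene"])
            table = hypergeom_enrich(degs, collection, universe,
                                     direction=direction, fdr=fdr,
                                     min_set_size=min_set_size)
            for col, val in zip(cell_cols, cell):
                table.insert(0, col, val)
            table = table[cell_cols + [c for c in table.columns
                                       if c not in cell_cols]]
            frames.append(table)
    if not frames:
        return pd.DataFrame(columns=cell_cols + [
            "gene_set", "direction", "k", "K", "n_deg", "N_universe",
            "p", "padj", "significant"])
    return pd.concat(frames, ignore_index=True)


def count_enriched(tables: pd.DataFrame) -> pd.DataFrame:
    """Per-cell count of significantly enriched sets by direction; cells
    with zero significant sets are reported (the grid's 'NS' entries)."""
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h",
                 "direction"]
    if tables.empty:
        return pd.DataFrame(columns=cell_cols + ["n_enriched"])
    out = (tables.assign(sig=tables["significant"].fillna(False))
                 .groupby(cell_cols, as_index=False)["sig"].sum()
                 .rename(columns={"sig": "n_enriched"}))
    out["n_enriched"] = out["n_enriched"].astype(int)
    return out
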