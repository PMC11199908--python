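"""Targeted gene-set aggregation into ToxPi-style profiles.

The scoring walks the enrichment tables of one genotype (upregulated
direction by default):

1. restrict to the *targeted* sets — those containing at least one of the
   top interacting genes of any chemical in the interaction map;
2. reverse-log-scale adjusted p-values: nonsignificant sets score 0, the
   most significant set in scope scores 1, every other significant set
   scores -log10(padj) / -log10(padj_min) (padj clipped at 1e-300);
3. per (chemical, concentration, timepoint), sum the scores of the
   significant sets containing each interacting gene — a set containing
   two interacting genes contributes its full score to both slices;
4. scale the summed totals to [0, 1]: *internal* divides each treatment
   group's vector by its own max, *external* divides each gene's slice by
   that gene's max across all treatment groups and timepoints within the
   genotype.  All-zero vectors stay zero (an "empty ToxPi").
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

PADJ_CLIP = 1e-300
CELL_COLS = ["genotype", "chemical", "concentration", "timepoint_h"]


def targeted_sets(collection: GeneSetCollection,
                  interaction_map: pd.DataFrame) -> GeneSetCollection:
    """Sets containing >=1 interacting gene (union over all chemicals)."""
    genes = set(interaction_map["gene"])
    out = GeneSetCollection()
    for name, members in collection.items():
        if genes & set(members):
            out[name] = list(members)
    return out


def reverse_log_scale(table: pd.DataFrame,
                      scope: str = "global") -> pd.DataFrame:
    """Score each enrichment row in [0, 1] against the scope's minimum
    adjusted p-value.

    ``scope='global'`` uses one reference per (genotype, direction) across
    all treatment groups and timepoints; ``scope='per-timepoint'`` finds
    the reference within each (genotype, direction, timepoint).
    """
    if scope not in ("global", "per-timepoint"):
        raise ValueError(f"unknown scope {scope!r}")
    t = table.copy()
    t["score"] = 0.0
    sig = t["significant"].fillna(False).astype(bool)
    if not sig.any():
        logger.info("reverse_log_scale: no significant sets in scope; "
                    "all scores zero")
        return t
    keys = ["genotype", "direction"]
    if scope == "per-timepoint":
        keys = keys + ["timepoint_h"]
    for _, idx in t.groupby(keys).groups.items():
        rows = t.loc[idx]
        s = rows["significant"].fillna(False).astype(bool)
        if not s.any():
            continue
        padj = np.clip(rows.loc[s, "padj"].to_numpy(float), PADJ_CLIP, 1.0)
        ref = -np.log10(padj.min())
        scores = -np.log10(padj) / ref if ref > 0 else np.ones(padj.size)
        t.loc[rows.index[s], "score"] = scores
    return t


def aggregate_by_gene(scored: pd.DataFrame, collection: GeneSetCollection,
                      interaction_map: pd.DataFrame) -> pd.DataFrame:
    """Sum set scores per interacting gene within each treatment group.

    Returns a long table (cell columns + gene + raw_sum).  Genes absent
    from every set get an all-zero slice (with a warning).
    """
    genes = list(dict.fromkeys(interaction_map["gene"]))
    # sorted membership keeps float summation order (and output bytes)
    # independent of hash seeding
    membership = {g: sorted(name for name, mem in collection.items()
                            if g in mem)
                  for g in genes}
    orphans = [g for g, s in membership.items() if not s]
    if orphans:
        warnings.warn(f"interacting genes absent from every set: {orphans}",
                      stacklevel=2)
    sig = scored[scored["significant"].fillna(False).astype(bool)]
    rows = []
    for cell, sub in scored.groupby(CELL_COLS, sort=True):
        subsig = sig.loc[sig.index.intersection(sub.index)]
        per_set = dict(zip(subsig["gene_set"], subsig["score"]))
        for g in genes:
            total = sum(per_set.get(s, 0.0) for s in membership[g])
            rows.append((*cell, g, total))
    return pd.DataFrame(rows, columns=CELL_COLS + ["gene", "raw_sum"])


def scale_profiles(sums: pd.DataFrame, mode: str = "internal") -> pd.DataFrame:
    """0-1 scaling of raw per-gene sums into ToxPi profiles."""
    if mode not in ("internal", "external"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    out = sums.copy()
    if (out["raw_sum"] < 0).any():
        raise ValueError("raw sums must be nonnegative")
    if mode == "internal":
        grp = out.groupby(CELL_COLS)["raw_sum"].transform("max")
    else:
        grp = out.groupby(["genotype", "gene"])["raw_sum"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["score"] = np.where(grp > 0, out["raw_sum"] / grp, 0.0)
    out["mode"] = mode
    return out


def profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix: one row per treatment group, one column per gene."""
    return profiles.pivot_table(index=CELL_COLS, columns="gene",
                                values="score", sort=True).fillna(0.0)


def profile_concordance(profiles: pd.DataFrame,
                        n_components: int = 2) -> dict:
    """PCA coordinates, pairwise Euclidean distances, and per-chemical
    covariance ellipses over the profile vectors."""
    wide = profile_matrix(profiles)
    nonempty = wide.loc[(wide > 0).any(axis=1)]
    if len(nonempty) < 2:
        raise ValueError("need >=2 nonempty profiles for concordance")
    from scipy.spatial.distance import pdist, squareform
    from sklearn.decomposition import PCA

    X = nonempty.to_numpy(float)
    ncomp = min(n_components, min(X.shape) - 1, X.shape[1])
    ncomp = max(ncomp, 1)
    pca = PCA(n_components=ncomp, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0) + X.mean(axis=0))
    coord_df = pd.DataFrame(
        coords, index=nonempty.index,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])]).reset_index()

    dist = pd.DataFrame(squareform(pdist(X)), index=nonempty.index,
                        columns=nonempty.index)

    ellipses = {}
    if coords.shape[1] >= 2:
        chem = coord_df["chemical"]
        for c in chem.unique():
            pts = coords[chem.to_numpy() == c, :2]
            if len(pts) < 3:
                continue
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(cov)
            ellipses[c] = {
                "center": pts.mean(axis=0).tolist(),
                "axes": np.sqrt(np.maximum(evals, 0.0)).tolist(),
                "rotation": evecs.tolist(),
            }
    return {"coords": coord_df, "distances": dist, "ellipses": ellipses,
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist()}


def chemical_mean_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average profile vector per (genotype, chemical) over all
    concentrations and timepoints — one summary point per chemical."""
    wide = profile_matrix(profiles).reset_index()
    return (wide.drop(columns=["concentration", "timepoint_h"])
                .groupby(["genotype", "chemical"], sort=True)
                .mean())


def plot_toxpi_grid(profiles: pd.DataFrame, path, genotype: str | None = None,
                    mode_label: str = "") -> None:
    """Polar bar ("ToxPi") grid: one wedge per interacting gene, radius =
    scaled score; rows are chemicals, columns concentration x timepoint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = profiles if genotype is None else profiles[
        profiles["genotype"] == genotype]
    genes = sorted(data["gene"].unique())
    cells = data[CELL_COLS].drop_duplicates().sort_values(CELL_COLS)
    chems = cells["chemical"].unique()
    conds = (cells[["concentration", "timepoint_h"]]
             .drop_duplicates().sort_values(["timepoint_h", "concentration"]))
    nrow, ncol = len(chems), len(conds)
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.0 * ncol, 2.0 * nrow),
                             subplot_kw={"projection": "polar"},
                             squeeze=False)
    theta = np.linspace(0, 2 * np.pi, len(genes), endpoint=False)
    width = 2 * np.pi / max(len(genes), 1)
    cmap = plt.get_cmap("tab20")
    for i, chem in enumerate(chems):
        for j, (_, cond) in enumerate(conds.iterrows()):
            ax = axes[i][j]
            sub = data[(data["chemical"] == chem)
                       & (data["concentration"] == cond["concentration"])
                       & (data["timepoint_h"] == cond["timepoint_h"])]
            radii = (sub.set_index("gene")["score"]
                        .reindex(genes).fillna(0.0).to_numpy())
            ax.bar(theta, radii, width=width, bottom=0.0,
                   color=[cmap(k % 20) for k in range(len(genes))],
                   edgecolor="white", linewidth=0.3)
            ax.set_ylim(0, 1)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(f"{cond['concentration']:g} @ "
                             f"{cond['timepoint_h']:g}h", fontsize=7)
            if j == 0:
                ax.set_ylabel(chem, fontsize=7)
    fig.suptitle(f"ToxPi profiles {mode_label}".strip(), fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
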