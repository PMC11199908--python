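"""Pipeline orchestration, sample-level overviews, and the run manifest.

``run_pipeline`` executes simulate -> qc -> de -> enrich -> toxpi -> bmc
and writes a tidy TSV tree plus a JSON manifest (config snapshot, seed,
output digests, per-stage row counts).  Identical config + seed reproduce
every output byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (aggregate_by_gene, chemical_mean_profiles,
                          reverse_log_scale, scale_profiles, targeted_sets)
from .containers import CountMatrix, GeneSetCollection, write_tsv
from .diffexpr import count_deps, run_all_contrasts, size_factors_by_stratum
from .enrichment import count_enriched, enrich_all_contrasts
from .qc import drop_depleted_groups, qc_filter
from .simulate import (PRESETS, generate_design, generate_genesets,
                       generate_interaction_map, generate_truth,
                       simulate_counts)


# ---- sample-level overviews ---------------------------------------------

def _log_normalized(counts: CountMatrix, size_factors: pd.Series,
                    top_k: int = 500) -> pd.DataFrame:
    mat = np.log2(counts.counts.to_numpy(float)
                  / size_factors.loc[counts.sample_ids].to_numpy(float)
                  + 1.0)
    order = np.argsort(mat.var(axis=1))[::-1][:top_k]
    return pd.DataFrame(mat[np.sort(order)],
                        index=counts.counts.index[np.sort(order)],
                        columns=counts.sample_ids)


def sample_pca(counts: CountMatrix, size_factors: pd.Series,
               top_k: int = 500, n_components: int = 2) -> pd.DataFrame:
    """PCA of samples on log2 normalized counts (top-k variable probes)."""
    if len(counts.sample_ids) < 3:
        raise ValueError("need >=3 samples for a sample PCA")
    from sklearn.decomposition import PCA

    X = _log_normalized(counts, size_factors, top_k).to_numpy().T
    ncomp = min(n_components, min(X.shape))
    pca = PCA(n_components=ncomp, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    out = pd.DataFrame(coords,
                       columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    out.insert(0, "sample_id", counts.sample_ids)
    out.attrs["explained_variance_ratio"] = \
        pca.explained_variance_ratio_.tolist()
    return out


def sample_hclust(counts: CountMatrix, size_factors: pd.Series | None = None,
                  top_k: int = 500):
    """Average-linkage hierarchical clustering on Euclidean distances of
    log2 normalized samples; returns (linkage matrix, sample order)."""
    if len(counts.sample_ids) < 3:
        raise ValueError("need >=3 samples for clustering")
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if size_factors is None:
        size_factors = pd.Series(1.0, index=counts.sample_ids)
    X = _log_normalized(counts, size_factors, top_k).to_numpy().T
    Z = hierarchy.linkage(pdist(X), method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [counts.sample_ids[i] for i in order]


# ---- pipeline ------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    preset: str = "tiny"
    seed: int = 0
    out_dir: str = "toxconcord_run"
    fdr_dep: float = 0.10
    fdr_enrich: float = 0.05
    min_set_size: int = 3
    sd_mult: float = 2.0
    min_reps: int = 2
    scaling_scope: str = "global"
    bmr_factor: float = 1.0
    prefilter_alpha: float = 0.05
    fit_pmin: float = 0.1
    ratio_filters: tuple = (20.0, 20.0, 40.0)
    bmc_timepoint_h: float = 24.0
    gmt_path: str | None = None        # optional external collection
    interaction_map_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "ratio_filters" in raw:
            raw["ratio_filters"] = tuple(raw["ratio_filters"])
        return cls(**raw)


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict          # path -> sha256
    row_counts: dict       # stage -> rows

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    if config.gmt_path is not None and not Path(config.gmt_path).exists():
        raise FileNotFoundError(f"gene-set GMT not found: {config.gmt_path}")
    if (config.interaction_map_path is not None
            and not Path(config.interaction_map_path).exists()):
        raise FileNotFoundError(
            f"interaction map not found: {config.interaction_map_path}")

    row_counts: dict[str, int] = {}

    # -- simulate ---------------------------------------------------------
    spec = PRESETS[config.preset](seed=config.seed)
    sheet = generate_design(spec)
    truth = generate_truth(spec, sheet)
    counts = simulate_counts(sheet, truth)
    if config.gmt_path:
        collection = GeneSetCollection.from_gmt(config.gmt_path)
    else:
        collection = generate_genesets(truth)
    if config.interaction_map_path:
        from .containers import read_interaction_map
        imap = read_interaction_map(config.interaction_map_path)
    else:
        imap = generate_interaction_map(truth.chemicals, truth)

    write_tsv(sheet, out / "sample_sheet.tsv")
    counts.to_tsv(out / "counts.tsv")
    truth.to_tsv(out / "truth_genes.tsv")
    collection.to_gmt(out / "gene_sets.gmt")
    write_tsv(imap, out / "interaction_map.tsv")
    row_counts["simulate_samples"] = len(sheet)
    row_counts["simulate_probes"] = len(counts.counts)

    # -- qc ----------------------------------------------------------------
    counts_qc, report = qc_filter(counts, sheet, sd_mult=config.sd_mult)
    sheet_qc = drop_depleted_groups(sheet, counts_qc.sample_ids,
                                    min_reps=config.min_reps)
    report.to_tsv(out / "qc_report.tsv")
    write_tsv(sheet_qc, out / "sample_sheet_qc.tsv")
    row_counts["qc_excluded"] = len(report.excluded_samples)

    # -- overview ----------------------------------------------------------
    sf = size_factors_by_stratum(counts_qc, sheet_qc)
    write_tsv(sf.rename_axis("sample_id").reset_index(),
              out / "size_factors.tsv")
    pca = sample_pca(counts_qc, sf)
    write_tsv(pca, out / "sample_pca.tsv")

    # -- differential expression -------------------------------------------
    de = run_all_contrasts(counts_qc, sheet_qc, sf, fdr=config.fdr_dep)
    write_tsv(de, out / "de_results.tsv")
    dep_grid = count_deps(de)
    write_tsv(dep_grid, out / "dep_counts.tsv")
    row_counts["de_rows"] = len(de)

    # -- enrichment ---------------------------------------------------------
    enr = enrich_all_contrasts(de, collection, fdr=config.fdr_enrich,
                               min_set_size=config.min_set_size)
    write_tsv(enr, out / "enrichment.tsv")
    write_tsv(count_enriched(enr), out / "enriched_counts.tsv")
    row_counts["enrichment_rows"] = len(enr)

    # -- targeted aggregation ----------------------------------------------
    tsets = targeted_sets(collection, imap)
    enr_t = enr[enr["gene_set"].isin(tsets)
                & enr["direction"].eq("up")].copy()
    scored = reverse_log_scale(enr_t, scope=config.scaling_scope)
    sums = aggregate_by_gene(scored, tsets, imap)
    profiles = {}
    for mode in ("internal", "external"):
        prof = scale_profiles(sums, mode=mode)
        profiles[mode] = prof
        write_tsv(prof, out / f"toxpi_{mode}.tsv")
    write_tsv(chemical_mean_profiles(profiles["internal"]).reset_index(),
              out / "toxpi_chemical_means_internal.tsv")
    row_counts["toxpi_rows"] = len(profiles["internal"])

    # -- benchmark concentrations ------------------------------------------
    from .bmc import bmc_analysis, gene_best_bmc, pathway_bmc

    bmc_frames = []
    pathway_frames = []
    for gt in spec.genotypes:
        for ch in spec.chemicals:
            try:
                tab = bmc_analysis(
                    counts_qc, sheet_qc, sf, gt, ch.name,
                    config.bmc_timepoint_h, bmr_factor=config.bmr_factor,
                    prefilter_alpha=config.prefilter_alpha,
                    fit_pmin=config.fit_pmin,
                    ratio_filters=config.ratio_filters, seed=config.seed)
            except ValueError:
                continue
            bmc_frames.append(tab)
            universe = set(counts_qc.gene_of_probe)
            ps = pathway_bmc(tab, collection, universe)
            ps.insert(0, "genotype", gt)
            ps.insert(1, "chemical", ch.name)
            ps.insert(2, "timepoint_h", config.bmc_timepoint_h)
            pathway_frames.append(ps)
    bmc_all = (pd.concat(bmc_frames, ignore_index=True)
               if bmc_frames else pd.DataFrame())
    write_tsv(bmc_all, out / "bmc_probes.tsv")
    if not bmc_all.empty:
        genes_bmc = (bmc_all.groupby(["genotype", "chemical"],
                                     as_index=False)
                     .apply(gene_best_bmc, include_groups=False))
        write_tsv(genes_bmc.reset_index(drop=True), out / "bmc_genes.tsv")
    write_tsv(pd.concat(pathway_frames, ignore_index=True)
              if pathway_frames else pd.DataFrame(),
              out / "bmc_pathways.tsv")
    row_counts["bmc_probe_rows"] = len(bmc_all)

    # -- manifest -----------------------------------------------------------
    outputs = {p.name: _sha256(p) for p in sorted(out.iterdir())
               if p.is_file() and p.suffix in (".tsv", ".gmt")}
    manifest = RunManifest(config=dataclasses.asdict(config),
                           version=__version__, outputs=outputs,
                           row_counts=row_counts)
    manifest.write(out / "manifest.json")
    return manifest
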