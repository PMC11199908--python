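"""Planted-truth recovery experiments on the synthetic study generator.

Each function runs one self-contained simulate -> analyze workflow at a
reduced, focused design and returns the quantity the experiment measures:
null p-value calibration, false-discovery control, BMC parameter recovery,
the knockout potency-shift ratio, the knockout temporal delay, and the
ToxPi concordance separation.  They are the package's own reproducibility
checks and power the test suite and the results-reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import bmc as bmcmod
from . import diffexpr, enrichment, simulate
from .aggregation import (aggregate_by_gene, chemical_mean_profiles,
                          reverse_log_scale, scale_profiles, targeted_sets)
from .simulate import KO, WT, ChemicalSpec, DesignSpec


def _single_chem_design(n_genes: int, reps: int, seed: int, *,
                        genotypes=(WT,), timepoints=(24.0,),
                        probes_per_gene=(2, 2)) -> DesignSpec:
    chem = ChemicalSpec("HFPO-DA", (0.1, 5.0, 50.0, 500.0), "uM", "water",
                        "ppara", ref_ec50=5.0)
    return DesignSpec(genotypes=genotypes, chemicals=(chem,),
                      timepoints_h=timepoints,
                      replicates=(reps,) * len(timepoints),
                      n_genes=n_genes, probes_per_gene=probes_per_gene,
                      lowq_per_genotype=(0,), seed=seed)


def _top_dose_contrast(counts, sheet, sf, conc=500.0):
    grp = list(sheet.loc[sheet.concentration.eq(conc), "sample_id"])
    ctl = list(sheet.loc[sheet.chemical.eq("control"), "sample_id"])
    return diffexpr.NBContrastModel(counts, sf, grp, ctl).fit()


def null_pvalues(seed: int, n_probes: int = 5000,
                 reps: int = 4) -> np.ndarray:
    """P-values of a top-dose contrast on an all-null simulated study."""
    spec = _single_chem_design(n_probes // 2, reps, seed)
    sheet = simulate.generate_design(spec)
    truth = simulate.generate_truth(spec, sheet, null_only=True)
    counts = simulate.simulate_counts(sheet, truth)
    sf = diffexpr.estimate_size_factors(counts.counts)
    res = _top_dose_contrast(counts, sheet, sf)
    return res.table["p"].dropna().to_numpy()


def empirical_fdp(seed: int, n_probes: int = 5000, reps: int = 4,
                  frac_responsive: float = 0.10,
                  fdr: float = 0.10) -> tuple[float, int]:
    """False-discovery proportion among DEPs on a 90%-null study.

    One gene in ten carries a saturating planted response at the top dose;
    returns (FDP among DEP calls, number of DEP calls).
    """
    spec = _single_chem_design(n_probes // 2, reps, seed)
    sheet = simulate.generate_design(spec)
    truth = simulate.generate_truth(
        spec, sheet, module_fractions={"ppara": frac_responsive})
    counts = simulate.simulate_counts(sheet, truth)
    sf = diffexpr.estimate_size_factors(counts.counts)
    res = _top_dose_contrast(counts, sheet, sf)

    responsive_genes = set(truth.genes.index[truth.genes.max_l2fc != 0])
    t = res.table
    dep = t["dep"].astype("boolean").fillna(False).to_numpy(bool)
    is_true = t["gene"].isin(responsive_genes).to_numpy()
    n_dep = int(dep.sum())
    fdp = float((dep & ~is_true).sum() / max(n_dep, 1))
    return fdp, n_dep


def hill_bmc_recovery(seed: int, n_probes: int = 200, reps: int = 4,
                      sigma: float = 0.1) -> float:
    """Median |log10(BMC_est / BMC_true)| over Hill-generated probes.

    Gaussian responses on the log2 scale drawn from Hill curves with
    known parameters; the true BMC solves the curve against the true
    response SD, the estimate uses the fitted curve and the pooled SD.
    Planted EC50s sit inside the tested ladder (the regime the range
    filters are designed to keep); half-maximal slopes use the standard
    hyperbolic (h = 1) shape.
    """
    rng = np.random.default_rng(seed)
    conc = np.array([0.0, 0.5, 5.0, 50.0, 500.0])
    errors = []
    for _ in range(n_probes):
        a = rng.uniform(5.0, 10.0)
        span = rng.uniform(2.0, 4.0)
        ec50 = 10.0 ** rng.uniform(0.5, 1.5)  # centered in the ladder
        h = 1.0
        true = bmcmod._f_hill(conc, a, span, ec50, h)
        draws = true[:, None] + rng.normal(0, sigma, (len(conc), reps))
        means = draws.mean(axis=1)
        pooled_sd = np.sqrt(((draws - means[:, None]) ** 2).sum()
                            / (draws.size - len(conc)))
        se = np.full(len(conc), pooled_sd / np.sqrt(reps))
        res = bmcmod.DoseResponseModel(conc, means, se).fit()
        if res.winner is None:
            continue
        est = res.bmc(control_sd=pooled_sd, ci="none")
        # planted BMC from the true curve and the true sigma
        bmr = 1.0 * sigma
        bmc_true = ec50 * (bmr / (span - bmr)) ** (1.0 / h)
        if np.isfinite(est.bmc) and bmc_true > 0:
            errors.append(abs(np.log10(est.bmc / bmc_true)))
    return float(np.median(errors))


def genotype_shift_ratio(seed: int, n_genes: int = 400,
                         reps: int = 4) -> float:
    """KO/WT ratio of the PPARα marker-set median gene-level BMC.

    The generator plants a 10x EC50 shift for PPARα-module genes in the
    knockout; recovering a ratio near 10 is the synthetic analogue of the
    receptor-dependence potency shift.  The gene count keeps ~50 marker
    genes in the set so the Monte-Carlo error of the median stays small
    against the recovery band; dose-ladder placement relative to the
    shifted EC50 leaves a modest upward interpolation bias in the ratio
    (see the methods note), which the band is wide enough to absorb.
    """
    spec = _single_chem_design(n_genes, reps, seed, genotypes=(WT, KO))
    sheet = simulate.generate_design(spec)
    truth = simulate.generate_truth(spec, sheet)
    counts = simulate.simulate_counts(sheet, truth)
    sf = diffexpr.size_factors_by_stratum(counts, sheet)
    marker = set(truth.module_genes("ppara"))
    medians = {}
    for gt in (WT, KO):
        tab = bmcmod.bmc_analysis(counts, sheet, sf, gt, "HFPO-DA", 24.0,
                                  seed=seed)
        genes = bmcmod.gene_best_bmc(tab)
        medians[gt] = genes[genes.gene.isin(marker)].bmc.median()
    return float(medians[KO] / medians[WT])


def temporal_delay_counts(seed: int, n_genes: int = 300,
                          reps: int = 3) -> tuple[int, int]:
    """Significant upregulated gene sets at 12 h in (WT, KO).

    PPARα-module genes switch on at 12 h in WT but only at 24 h in KO, so
    the knockout arm is expected to show no enrichment at 12 h.
    """
    spec = _single_chem_design(n_genes, reps, seed, genotypes=(WT, KO),
                               timepoints=(12.0,), probes_per_gene=(1, 3))
    sheet = simulate.generate_design(spec)
    truth = simulate.generate_truth(spec, sheet)
    counts = simulate.simulate_counts(sheet, truth)
    sf = diffexpr.size_factors_by_stratum(counts, sheet)
    de = diffexpr.run_all_contrasts(counts, sheet, sf)
    coll = simulate.generate_genesets(truth)
    enr = enrichment.enrich_all_contrasts(de, coll, directions=("up",))
    cnt = enrichment.count_enriched(enr)
    out = []
    for gt in (WT, KO):
        sub = cnt[cnt.genotype.eq(gt) & cnt.direction.eq("up")]
        out.append(int(sub.n_enriched.sum()))
    return out[0], out[1]


def concordance_distances(seed: int, n_genes: int = 300,
                          reps: int = 4) -> dict:
    """ToxPi profile distances between chemical classes in WT.

    Returns, per scaling mode, the Euclidean distance between the two
    PPARα-type chemical mean profiles and the smallest distance from
    either to a cytotoxicant profile.
    """
    chems = (
        ChemicalSpec("HFPO-DA", (0.1, 5.0, 50.0, 500.0), "uM", "water",
                     "ppara", ref_ec50=5.0),
        ChemicalSpec("GW7647", (0.01, 0.1, 1.0, 10.0), "uM", "DMSO",
                     "ppara", ref_ec50=0.2),
        ChemicalSpec("acetaminophen", (0.3, 1.0, 3.0, 10.0), "mM", "DMSO",
                     "cytotox", ref_ec50=4.0),
        ChemicalSpec("d-galactosamine", (0.3, 1.0, 3.0, 10.0), "mM",
                     "DMSO", "cytotox", ref_ec50=4.0),
    )
    spec = DesignSpec(genotypes=(WT,), chemicals=chems,
                      timepoints_h=(24.0,), replicates=(reps,),
                      n_genes=n_genes, probes_per_gene=(1, 3),
                      lowq_per_genotype=(0,), seed=seed)
    sheet = simulate.generate_design(spec)
    truth = simulate.generate_truth(spec, sheet)
    counts = simulate.simulate_counts(sheet, truth)
    sf = diffexpr.size_factors_by_stratum(counts, sheet)
    de = diffexpr.run_all_contrasts(counts, sheet, sf)
    coll = simulate.generate_genesets(truth)
    enr = enrichment.enrich_all_contrasts(de, coll, directions=("up",))
    imap = simulate.generate_interaction_map(truth.chemicals, truth)
    tsets = targeted_sets(coll, imap)
    enr_t = enr[enr.gene_set.isin(tsets) & enr.direction.eq("up")].copy()
    scored = reverse_log_scale(enr_t)
    sums = aggregate_by_gene(scored, tsets, imap)
    out = {}
    for mode in ("internal", "external"):
        prof = scale_profiles(sums, mode=mode)
        mp = chemical_mean_profiles(prof).loc[WT]

        def dist(a, b):
            return float(np.linalg.norm(mp.loc[a] - mp.loc[b]))

        d_pp = dist("HFPO-DA", "GW7647")
        d_cross = min(dist(p, c)
                      for p in ("HFPO-DA", "GW7647")
                      for c in ("acetaminophen", "d-galactosamine"))
        out[mode] = {"ppar_pair": d_pp, "min_cross": d_cross}
    return out
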