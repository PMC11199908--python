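import warnings

import numpy as np
import pandas as pd
import pytest

import toxconcord as tc

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def tiny_study():
    """One simulated desk-scale study shared by read-only tests."""
    spec = tc.tiny_design(seed=11)
    sheet = tc.generate_design(spec)
    truth = tc.generate_truth(spec, sheet)
    counts = tc.simulate_counts(sheet, truth)
    return spec, sheet, truth, counts


@pytest.fixture(scope="session")
def tiny_qc(tiny_study):
    spec, sheet, truth, counts = tiny_study
    filtered, report = tc.qc_filter(counts, sheet)
    sheet_qc = tc.drop_depleted_groups(sheet, filtered.sample_ids)
    sf = tc.size_factors_by_stratum(filtered, sheet_qc)
    return filtered, report, sheet_qc, sf


def two_group_design(n_genes: int, reps: int, seed: int,
                     probes_per_gene=(1, 3)) -> tc.DesignSpec:
    """Single-chemical, single-timepoint design for focused contrasts."""
    chem = tc.ChemicalSpec("drugA", (0.5, 5.0, 50.0, 500.0), "uM", "water",
                           "ppara", ref_ec50=5.0)
    return tc.DesignSpec(genotypes=("WT",), chemicals=(chem,),
                         timepoints_h=(24.0,), replicates=(reps,),
                         n_genes=n_genes, probes_per_gene=probes_per_gene,
                         lowq_per_genotype=(0,), seed=seed)


def contrast_arms(sheet: pd.DataFrame, conc: float):
    grp = list(sheet.loc[sheet.concentration.eq(conc), "sample_id"])
    ctl = list(sheet.loc[sheet.chemical.eq("control"), "sample_id"])
    return grp, ctl
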