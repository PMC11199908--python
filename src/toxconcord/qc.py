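"""Sample-level quality control on probe-count matrices.

Two exclusion rules, each evaluated within genotype in a single pass over
the full cohort (thresholds are not re-computed after removals):

1. total reads across probes below mean - sd_mult * SD of the genotype;
2. probes detected (>=1 read) below mean - sd_mult * SD of the genotype.

SDs use the n-1 (sample) denominator; comparisons are strict, so a
degenerate cohort with zero SD excludes nothing.  "Probes detected" counts
probes with at least one read — the count table carries no deeper
sequencing evidence to apply a depth threshold per probe.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import CountMatrix, validate_sample_sheet

QC_HEADER_NOTE = ("probes_detected counts probes with >=1 read; "
                  "thresholds are single-pass per genotype, SD uses n-1")


@dataclasses.dataclass
class QCReport:
    table: pd.DataFrame  # one row per input sample
    sd_mult: float

    @property
    def excluded_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["excluded"], "sample_id"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {QC_HEADER_NOTE}; sd_mult={self.sd_mult:g}\n")
            self.table.to_csv(fh, sep="\t", index=False,
                              float_format="%.6g")


def qc_filter(counts: CountMatrix, sheet: pd.DataFrame,
              sd_mult: float = 2.0) -> tuple[CountMatrix, QCReport]:
    """Apply both exclusion rules; return the surviving matrix + report."""
    validate_sample_sheet(sheet)
    sheet = sheet.set_index("sample_id", drop=False)
    missing = [s for s in counts.sample_ids if s not in sheet.index]
    if missing:
        raise KeyError(f"samples missing from sample sheet: {missing[:5]}")

    mat = counts.counts
    total_reads = mat.sum(axis=0)
    probes_detected = (mat > 0).sum(axis=0)
    genotype = sheet.loc[counts.sample_ids, "genotype"]

    rows = []
    for gt, samples in genotype.groupby(genotype):
        ids = list(samples.index)
        if len(ids) < 3:
            raise ValueError(
                f"genotype {gt!r} has only {len(ids)} samples; need >=3")
        tr = total_reads[ids].to_numpy(dtype=float)
        pd_ = probes_detected[ids].to_numpy(dtype=float)
        tr_mean, tr_sd = tr.mean(), tr.std(ddof=1)
        pd_mean, pd_sd = pd_.mean(), pd_.std(ddof=1)
        tr_cut = tr_mean - sd_mult * tr_sd
        pd_cut = pd_mean - sd_mult * pd_sd
        for sid, t, p in zip(ids, tr, pd_):
            r1 = t < tr_cut
            r2 = p < pd_cut
            rule = ";".join(
                n for n, hit in (("low_depth", r1), ("low_probes", r2)) if hit)
            rows.append((sid, gt, t, p, tr_mean, tr_sd, tr_cut,
                         pd_mean, pd_sd, pd_cut, r1 or r2, rule))
    table = pd.DataFrame(rows, columns=[
        "sample_id", "genotype", "total_reads", "probes_detected",
        "depth_mean", "depth_sd", "depth_cutoff",
        "probes_mean", "probes_sd", "probes_cutoff", "excluded", "rule"])
    table = (table.set_index("sample_id")
                  .loc[counts.sample_ids]
                  .reset_index())
    report = QCReport(table=table, sd_mult=sd_mult)
    keep = [s for s in counts.sample_ids
            if not table.set_index("sample_id").loc[s, "excluded"]]
    return counts.subset_samples(keep), report


def drop_depleted_groups(sheet: pd.DataFrame, surviving_samples: list[str],
                         min_reps: int = 2) -> pd.DataFrame:
    """Flag design cells left with fewer than ``min_reps`` surviving wells.

    Returns the sheet restricted to surviving samples with an added boolean
    ``excluded_from_de`` marking depleted (genotype, chemical,
    concentration, timepoint) cells.
    """
    validate_sample_sheet(sheet)
    out = sheet[sheet["sample_id"].isin(surviving_samples)].copy()
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h"]
    n_surv = out.groupby(cell_cols)["sample_id"].transform("size")
    out["excluded_from_de"] = n_surv < min_reps
    return out
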