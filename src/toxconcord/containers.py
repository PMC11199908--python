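"""Core data containers and plain-text I/O.

The pipeline's tabular currencies are deliberately simple: a probe-level
count matrix with a probe->gene annotation, a per-well sample sheet, and
named gene-set collections.  Everything round-trips through uncompressed
TSV / MTX / GMT so that runs diff cleanly.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "genotype",
    "chemical",
    "concentration",
    "conc_units",
    "timepoint_h",
    "vehicle",
    "replicate",
    "planted_lowq",
]

CONTROL_LABEL = "control"


@dataclasses.dataclass
class CountMatrix:
    """Probe-level read counts (probes x samples) with probe annotation.

    ``counts`` is indexed by probe_id; ``probes`` maps probe_id to
    gene_symbol (one row per probe; genes may own several probes, as in
    targeted probe-based expression assays).
    """

    counts: pd.DataFrame
    probes: pd.DataFrame  # index probe_id, column gene_symbol

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probes.index):
            self.probes = self.probes.reindex(self.counts.index)
            if self.probes["gene_symbol"].isna().any():
                missing = self.probes.index[self.probes["gene_symbol"].isna()]
                raise ValueError(
                    f"probes without gene annotation: {list(missing[:5])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_of_probe(self) -> pd.Series:
        return self.probes["gene_symbol"]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.probes.copy())

    # ---- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.probes.copy()
        out.insert(0, "probe_id", out.index)
        df = pd.concat([out.reset_index(drop=True),
                        self.counts.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        probes = df[["probe_id", "gene_symbol"]].set_index("probe_id")
        counts = df.drop(columns=["gene_symbol"]).set_index("probe_id")
        return cls(counts, probes)

    def to_mtx(self, prefix: str | Path) -> None:
        """Write a coordinate MTX triplet plus row/column sidecar TSVs."""
        from scipy import io as spio
        from scipy import sparse

        prefix = Path(prefix)
        spio.mmwrite(str(prefix) + ".mtx",
                     sparse.csr_matrix(self.counts.to_numpy()))
        rows = self.probes.copy()
        rows.insert(0, "probe_id", rows.index)
        rows.to_csv(str(prefix) + ".rows.tsv", sep="\t", index=False)
        pd.DataFrame({"sample_id": self.counts.columns}).to_csv(
            str(prefix) + ".cols.tsv", sep="\t", index=False)

    @classmethod
    def from_mtx(cls, prefix: str | Path) -> "CountMatrix":
        from scipy import io as spio

        prefix = Path(prefix)
        mat = spio.mmread(str(prefix) + ".mtx").toarray()
        rows = pd.read_csv(str(prefix) + ".rows.tsv", sep="\t").set_index("probe_id")
        cols = pd.read_csv(str(prefix) + ".cols.tsv", sep="\t")["sample_id"]
        counts = pd.DataFrame(mat, index=rows.index, columns=cols.to_list())
        return cls(counts, rows)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {list(dup[:5])}")
    return sheet


def is_control(sheet: pd.DataFrame) -> pd.Series:
    return sheet["chemical"].eq(CONTROL_LABEL)


# ---- GMT gene-set collections -------------------------------------------

class GeneSetCollection(dict):
    """Named gene sets; values are lists of gene symbols (order preserved)."""

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.values():
            out.update(genes)
        return out

    def to_gmt(self, path: str | Path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name, genes in self.items():
                fh.write("\t".join([name, description, *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        coll = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                coll[parts[0]] = [g for g in parts[2:] if g]
        return coll


def read_interaction_map(path: str | Path) -> pd.DataFrame:
    """TSV with columns chemical, gene, rank (the per-chemical top list)."""
    df = pd.read_csv(path, sep="\t")
    need = {"chemical", "gene", "rank"}
    if not need.issubset(df.columns):
        raise ValueError(f"interaction map needs columns {sorted(need)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Stable TSV writer used by every stage (fixed float formatting so
    re-runs are byte-identical)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
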