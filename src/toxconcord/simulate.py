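"""Synthetic TempO-Seq-like study generator with planted ground truth.

Emulates a two-genotype (wild-type vs receptor-knockout) primary-hepatocyte
concentration-response study: five chemicals with four-point concentration
ladders plus vehicle controls, three exposure durations, replicate wells,
and negative-binomial probe counts.  Gene "modules" (PPARα-responsive,
PPARγ-responsive, cytotoxic-stress, null) carry sigmoidal concentration-
response effects; the knockout genotype shifts the PPARα module's potency
(default 10-fold) and delays its onset, which is the planted analogue of
the receptor-dependence signal the downstream stages are meant to recover.

All randomness flows through a single integer seed; identical seed + spec
give bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (CONTROL_LABEL, CountMatrix, GeneSetCollection,
                         validate_sample_sheet)

WT = "WT"
KO = "KO"

# marker symbols lend the synthetic truth a recognizable toxicogenomic face;
# they are labels only, not curated interaction data
PPARA_MARKERS = ["Acox1", "Cpt1a", "Cyp4a10", "Ehhadh", "Fabp1",
                 "Acadm", "Hmgcs2", "Pdk4", "Angptl4", "Plin2"]
PPARG_MARKERS = ["Cd36", "Fabp4", "Lpl", "Adipoq", "Pparg",
                 "Cidec", "Mogat1", "Ucp2", "Scd1", "Acsl1"]
CYTOTOX_MARKERS = ["Hmox1", "Atf3", "Gadd45a", "Ddit3", "Fos",
                   "Jun", "Hspa1a", "Mt1", "Mt2", "Cdkn1a"]


@dataclasses.dataclass
class ChemicalSpec:
    """One test chemical: its concentration ladder and solvent."""

    name: str
    concentrations: tuple[float, ...]
    units: str
    vehicle: str
    target_module: str  # 'ppara' | 'pparg' | 'cytotox' | 'null'
    ref_ec50: float     # potency anchor in the chemical's own units

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        if len(conc) < 3:
            raise ValueError(
                f"{self.name}: need >=3 nonzero concentrations, got {conc}")
        if any(c <= 0 for c in conc):
            raise ValueError(f"{self.name}: concentrations must be positive")
        if list(conc) != sorted(conc):
            raise ValueError(f"{self.name}: concentrations must be ascending")
        self.concentrations = conc


@dataclasses.dataclass
class DesignSpec:
    """Factorial design of the synthetic study."""

    genotypes: tuple[str, ...] = (WT, KO)
    chemicals: tuple[ChemicalSpec, ...] = ()
    timepoints_h: tuple[float, ...] = (12.0, 24.0, 72.0)
    replicates: tuple[int, ...] = (3, 4, 3)  # per timepoint
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive range
    lowq_per_genotype: tuple[int, ...] = (7, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chemicals) == 0:
            raise ValueError("design needs at least one chemical")
        if len(self.replicates) != len(self.timepoints_h):
            raise ValueError("one replicate count per timepoint required")
        if any(r < 2 for r in self.replicates):
            raise ValueError("replicate count must be >=2 per design cell")
        if len(self.lowq_per_genotype) not in (1, len(self.genotypes)):
            raise ValueError("lowq_per_genotype must match genotypes")

    @property
    def vehicles(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch in self.chemicals:
            if ch.vehicle not in seen:
                seen.append(ch.vehicle)
        return tuple(seen)

    def n_samples(self) -> int:
        per_tp = sum(len(ch.concentrations) for ch in self.chemicals)
        per_tp += len(self.vehicles)  # one control group per vehicle
        return len(self.genotypes) * per_tp * int(np.sum(self.replicates))


def _default_chemicals() -> tuple[ChemicalSpec, ...]:
    return (
        ChemicalSpec("HFPO-DA", (0.1, 5.0, 50.0, 500.0), "uM", "water",
                     "ppara", ref_ec50=5.0),
        ChemicalSpec("GW7647", (0.01, 0.1, 1.0, 10.0), "uM", "DMSO",
                     "ppara", ref_ec50=0.2),
        ChemicalSpec("rosiglitazone", (0.01, 0.1, 1.0, 10.0), "uM", "DMSO",
                     "pparg", ref_ec50=0.3),
        ChemicalSpec("acetaminophen", (0.3, 1.0, 3.0, 10.0), "mM", "DMSO",
                     "cytotox", ref_ec50=4.0),
        ChemicalSpec("d-galactosamine", (0.3, 1.0, 3.0, 10.0), "mM", "DMSO",
                     "cytotox", ref_ec50=4.0),
    )


def paper_like_design(seed: int = 0, n_genes: int = 2000) -> DesignSpec:
    """The full emulated study: 2 genotypes x 5 chemicals x 3 timepoints."""
    return DesignSpec(chemicals=_default_chemicals(), n_genes=n_genes,
                      seed=seed)


def tiny_design(seed: int = 0, n_genes: int = 300) -> DesignSpec:
    """Same factorial structure at desk scale (fewer genes)."""
    return DesignSpec(chemicals=_default_chemicals(), n_genes=n_genes,
                      lowq_per_genotype=(2, 3), seed=seed)


PRESETS = {"paper-like": paper_like_design, "tiny": tiny_design}

MODULE_FRACTIONS = {"ppara": 0.12, "pparg": 0.08, "cytotox": 0.10}


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a DesignSpec into a per-well sample sheet.

    Rows: every (genotype, chemical, concentration, timepoint, replicate)
    plus vehicle-control wells per (genotype, timepoint, vehicle).
    """
    rows = []
    for gt in spec.genotypes:
        for tp, reps in zip(spec.timepoints_h, spec.replicates):
            for veh in spec.vehicles:
                for r in range(1, reps + 1):
                    rows.append((gt, CONTROL_LABEL, 0.0, "", tp, veh, r))
            for ch in spec.chemicals:
                for conc in ch.concentrations:
                    for r in range(1, reps + 1):
                        rows.append((gt, ch.name, conc, ch.units, tp,
                                     ch.vehicle, r))
    sheet = pd.DataFrame(rows, columns=["genotype", "chemical",
                                        "concentration", "conc_units",
                                        "timepoint_h", "vehicle",
                                        "replicate"])
    sheet.insert(0, "sample_id", [
        f"{g}_{c}_{conc:g}_{tp:g}h_{veh}_r{r}" if c == CONTROL_LABEL else
        f"{g}_{c}_{conc:g}_{tp:g}h_r{r}"
        for g, c, conc, tp, veh, r in zip(
            sheet.genotype, sheet.chemical, sheet.concentration,
            sheet.timepoint_h, sheet.vehicle, sheet.replicate)
    ])
    sheet["planted_lowq"] = False

    # plant low-quality wells (depth collapsed 50-fold downstream)
    rng = np.random.default_rng(spec.seed)
    lowq = spec.lowq_per_genotype
    if len(lowq) == 1:
        lowq = lowq * len(spec.genotypes)
    for gt, n_lowq in zip(spec.genotypes, lowq):
        idx = sheet.index[sheet.genotype == gt].to_numpy()
        pick = rng.choice(idx, size=min(n_lowq, len(idx)), replace=False)
        sheet.loc[pick, "planted_lowq"] = True
    return validate_sample_sheet(sheet)


# ---- ground truth --------------------------------------------------------

@dataclasses.dataclass
class GroundTruth:
    """Planted per-gene dose-response parameters and per-sample factors."""

    genes: pd.DataFrame       # index gene; module, baseline, max_l2fc, hill,
                              # potency_factor, onset_h_wt, onset_h_ko, dispersion
    chemicals: pd.DataFrame   # index chemical; target_module, ref_ec50, units
    probes: pd.DataFrame      # index probe_id; gene_symbol, probe_baseline
    sample_factors: pd.Series  # size factor per sample_id (lowq already folded in)
    shift_factor: float
    seed: int

    def ec50(self, gene: str, chemical: str, genotype: str) -> float:
        g = self.genes.loc[gene]
        ch = self.chemicals.loc[chemical]
        if ch["target_module"] != g["module"]:
            return np.nan
        ec50 = float(ch["ref_ec50"]) * float(g["potency_factor"])
        if genotype == KO and g["module"] == "ppara":
            ec50 *= self.shift_factor
        return ec50

    def log2_effect(self, gene: str, chemical: str, genotype: str,
                    concentration: float, timepoint_h: float) -> float:
        """Planted log2 fold change for one design cell (0 off-module,
        0 before onset, Hill in concentration otherwise)."""
        g = self.genes.loc[gene]
        ch = self.chemicals.loc[chemical] if chemical in self.chemicals.index else None
        if ch is None or ch["target_module"] != g["module"]:
            return 0.0
        onset = g["onset_h_ko"] if genotype == KO else g["onset_h_wt"]
        if timepoint_h < onset:
            return 0.0
        ec50 = self.ec50(gene, chemical, genotype)
        h = float(g["hill"])
        c = float(concentration)
        return float(g["max_l2fc"]) * c**h / (ec50**h + c**h)

    def module_genes(self, module: str) -> list[str]:
        return list(self.genes.index[self.genes["module"] == module])

    def to_tsv(self, path) -> None:
        out = self.genes.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _gene_symbols(n_genes: int, module_of: np.ndarray) -> list[str]:
    """Marker symbols head each module; the rest are synthetic Gene%04d."""
    names = [f"Gene{i:04d}" for i in range(n_genes)]
    for module, markers in (("ppara", PPARA_MARKERS),
                            ("pparg", PPARG_MARKERS),
                            ("cytotox", CYTOTOX_MARKERS)):
        idx = np.flatnonzero(module_of == module)
        for j, sym in zip(idx, markers):
            names[j] = sym
    return names


def generate_truth(spec: DesignSpec, sheet: pd.DataFrame | None = None, *,
                   shift_factor: float = 10.0,
                   ko_onset_delay: bool = True,
                   effect_scale: float = 1.0,
                   null_only: bool = False,
                   module_fractions: dict | None = None) -> GroundTruth:
    """Draw the planted truth for a design.

    ``effect_scale`` multiplies every max log2 fold change (0 gives a global
    null); ``null_only`` forces the all-null truth regardless of modules;
    ``module_fractions`` overrides the default module sizes (fraction of
    genes per responsive module; the remainder is null).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_genes

    fractions = (MODULE_FRACTIONS if module_fractions is None
                 else module_fractions)
    module_of = np.array(["null"] * n, dtype=object)
    start = 0
    for module, frac in fractions.items():
        k = int(round(frac * n))
        if module_fractions is None:
            k = max(k, 10)
        module_of[start:start + k] = module
        start += k
    symbols = _gene_symbols(n, module_of)

    baseline = np.exp(rng.normal(np.log(150.0), 1.0, n))
    max_l2fc = np.where(module_of == "null", 0.0,
                        rng.uniform(1.0, 3.0, n) *
                        np.where(rng.random(n) < 0.85, 1.0, -1.0))
    max_l2fc = max_l2fc * effect_scale
    if null_only:
        max_l2fc = np.zeros(n)
    hill = rng.uniform(1.0, 2.0, n)
    potency = np.exp(rng.normal(0.0, 0.3, n))
    dispersion = np.exp(rng.normal(np.log(0.05), 0.5, n))

    onset_wt = np.full(n, 12.0)
    onset_ko = np.where((module_of == "ppara") & ko_onset_delay, 24.0, 12.0)

    genes = pd.DataFrame({
        "module": module_of, "baseline": baseline, "max_l2fc": max_l2fc,
        "hill": hill, "potency_factor": potency, "onset_h_wt": onset_wt,
        "onset_h_ko": onset_ko, "dispersion": dispersion,
    }, index=pd.Index(symbols, name="gene"))

    chemicals = pd.DataFrame({
        "target_module": [ch.target_module for ch in spec.chemicals],
        "ref_ec50": [ch.ref_ec50 for ch in spec.chemicals],
        "units": [ch.units for ch in spec.chemicals],
    }, index=pd.Index([ch.name for ch in spec.chemicals], name="chemical"))

    # probes: 1..k per gene with mild probe-level baseline wobble
    lo, hi = spec.probes_per_gene
    n_probes_per = rng.integers(lo, hi + 1, n)
    probe_rows = []
    for gi, (sym, k) in enumerate(zip(symbols, n_probes_per)):
        for p in range(1, k + 1):
            probe_rows.append((f"{sym}_P{p}", sym))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol"])
    probes["probe_baseline"] = np.exp(
        rng.normal(0.0, 0.3, len(probes)))
    probes = probes.set_index("probe_id")

    if sheet is None:
        sheet = generate_design(spec)
    sf = np.exp(rng.normal(0.0, 0.2, len(sheet)))
    sf = sf / np.exp(np.mean(np.log(sf)))
    sf = np.where(sheet["planted_lowq"].to_numpy(), sf * 0.02, sf)
    sample_factors = pd.Series(sf, index=sheet["sample_id"].to_numpy(),
                               name="size_factor")

    return GroundTruth(genes=genes, chemicals=chemicals, probes=probes,
                       sample_factors=sample_factors,
                       shift_factor=shift_factor, seed=spec.seed)


def simulate_counts(sheet: pd.DataFrame, truth: GroundTruth,
                    seed: int | None = None) -> CountMatrix:
    """Draw NB counts for every (probe, well).

    mean_ij = size_factor_j * probe_baseline_i * 2**delta(cell_j, gene_i);
    Var = mu + dispersion * mu^2 (dispersion shared across a gene's probes).
    """
    validate_sample_sheet(sheet)
    sheet = sheet.reset_index(drop=True)
    missing = set(sheet["sample_id"]) - set(truth.sample_factors.index)
    if missing:
        raise KeyError(f"samples without size factors: {sorted(missing)[:5]}")
    genes = truth.genes
    probes = truth.probes
    unknown = set(probes["gene_symbol"]) - set(genes.index)
    if unknown:
        raise KeyError(f"probes reference unknown genes: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 202]))

    gene_idx = genes.index.get_indexer(probes["gene_symbol"])
    base = (genes["baseline"].to_numpy()[gene_idx] *
            probes["probe_baseline"].to_numpy())
    alpha = genes["dispersion"].to_numpy()[gene_idx]

    # per-sample planted log2 effect per gene, built per design cell
    n_probes = len(probes)
    n_samples = len(sheet)
    delta = np.zeros((len(genes), n_samples))
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h"]
    for (gt, chem, conc, tp), sub in sheet.groupby(cell_cols, sort=False):
        if chem == CONTROL_LABEL or chem not in truth.chemicals.index:
            continue
        ch = truth.chemicals.loc[chem]
        mod = ch["target_module"]
        sel = genes["module"] == mod
        if not sel.any():
            continue
        g = genes.loc[sel]
        onset = g["onset_h_ko"] if gt == KO else g["onset_h_wt"]
        active = (tp >= onset).to_numpy()
        ec50 = ch["ref_ec50"] * g["potency_factor"].to_numpy()
        if gt == KO and mod == "ppara":
            ec50 = ec50 * truth.shift_factor
        h = g["hill"].to_numpy()
        eff = g["max_l2fc"].to_numpy() * conc**h / (ec50**h + conc**h)
        eff = np.where(active, eff, 0.0)
        cols = sheet.index.get_indexer(sub.index)
        delta[np.flatnonzero(sel.to_numpy())[:, None], cols] = eff[:, None]

    sf = truth.sample_factors.loc[sheet["sample_id"]].to_numpy()
    mu = base[:, None] * np.exp2(delta[gene_idx, :]) * sf[None, :]

    alpha2 = np.broadcast_to(alpha[:, None], mu.shape)
    counts = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha2 < 1e-8
    if tiny.any():
        counts[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    r = 1.0 / alpha2[big]
    counts[big] = rng.negative_binomial(r, r / (r + mu[big]))

    cm = pd.DataFrame(counts, index=probes.index,
                      columns=sheet["sample_id"].to_list())
    return CountMatrix(cm, probes[["gene_symbol"]].copy())


# ---- gene sets and interaction map ---------------------------------------

def generate_genesets(truth: GroundTruth, n_random_sets: int = 25,
                      sets_per_module: int = 5, set_size: int = 30,
                      module_purity: float = 0.8,
                      overlap_spec: float | None = None,
                      seed: int | None = None) -> GeneSetCollection:
    """Build a GMT-writable collection: per-module marker sets (drawn
    ``module_purity`` from the module, rest from the null pool) plus random
    null sets.  ``overlap_spec=0`` forces pairwise-disjoint random sets."""
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 303]))
    genes = truth.genes
    universe = np.array(genes.index)
    null_pool = np.array(genes.index[genes["module"] == "null"])
    if set_size > len(universe):
        raise ValueError("requested set size exceeds gene universe")

    coll = GeneSetCollection()
    for module in ("ppara", "pparg", "cytotox"):
        members = np.array(truth.module_genes(module))
        if len(members) == 0:
            raise ValueError(f"module {module} is empty")
        n_mod = min(int(round(module_purity * set_size)), len(members))
        for s in range(1, sets_per_module + 1):
            picked = list(rng.choice(members, n_mod, replace=False))
            filler = list(rng.choice(null_pool, set_size - n_mod,
                                     replace=False))
            coll[f"{module}_signaling_{s}"] = picked + filler

    if overlap_spec == 0:
        # carve disjoint random sets out of the null pool
        pool = list(rng.permutation(null_pool))
        for s in range(1, n_random_sets + 1):
            if len(pool) < set_size:
                break
            coll[f"random_{s}"] = [pool.pop() for _ in range(set_size)]
    else:
        for s in range(1, n_random_sets + 1):
            coll[f"random_{s}"] = list(rng.choice(universe, set_size,
                                                  replace=False))
    return coll


def generate_interaction_map(chemicals: Sequence[ChemicalSpec] | pd.DataFrame,
                             truth: GroundTruth,
                             top_n: int = 10) -> pd.DataFrame:
    """Per-chemical ranked top interacting genes (default 10), emulating a
    curated chemical-gene interaction lookup: each chemical lists the
    leading marker genes of its target module."""
    if isinstance(chemicals, pd.DataFrame):
        items = [(name, row["target_module"])
                 for name, row in chemicals.iterrows()]
    else:
        items = [(ch.name, ch.target_module) for ch in chemicals]
    rows = []
    for name, module in items:
        members = truth.module_genes(module)
        if not members:
            members = truth.module_genes("null")
        for rank, gene in enumerate(members[:top_n], start=1):
            rows.append((name, gene, rank))
    return pd.DataFrame(rows, columns=["chemical", "gene", "rank"])
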