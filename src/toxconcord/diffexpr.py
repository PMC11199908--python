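"""Normalization and per-probe differential expression.

Counts are normalized by median-of-ratios size factors (geometric mean 1
within the stratum they are computed on).  Each treatment-vs-control
contrast is tested with a negative-binomial GLM (log link) per probe:

* a mean-dispersion trend is estimated across probes by binned method of
  moments (Var = mu + alpha * mu^2);
* per-probe departure from the trend is captured by a quasi-likelihood
  dispersion estimated from Pearson residuals and shrunk toward its
  empirical-Bayes prior (moment-matched scaled-F, limma style);
* the Wald statistic on the group coefficient is referred to a moderated
  t distribution with prior + residual degrees of freedom.

This small-sample moderation is what keeps null p-values uniform at
3-4 replicates per arm, where an unmoderated Wald z is anti-conservative.
Differentially expressed probes (DEPs) are those with BH-adjusted p below
the FDR threshold (default 10%); a gene is differentially expressed (DEG)
if any of its probes is a DEP.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CONTROL_LABEL, CountMatrix, validate_sample_sheet

DEFAULT_FDR = 0.10


# ---- size factors --------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Probes with a zero count in any sample drop out of the reference (their
    geometric mean is zero); all-zero probes never contribute.
    """
    if isinstance(counts, np.ndarray):
        counts = pd.DataFrame(counts)
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no probe has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples first")
    ref = logs[usable].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs[usable] - ref, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def size_factors_by_stratum(counts: CountMatrix, sheet: pd.DataFrame,
                            stratum: str = "genotype") -> pd.Series:
    """Size factors computed separately within each stratum (genotype)."""
    sheet = sheet.set_index("sample_id")
    out = []
    for _, ids in sheet.loc[counts.sample_ids].groupby(stratum).groups.items():
        out.append(estimate_size_factors(counts.counts[list(ids)]))
    return pd.concat(out).loc[counts.sample_ids]


# ---- BH adjustment -------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotone enforcement.

    NaNs pass through unchanged and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


# ---- moderated NB Wald machinery ----------------------------------------

def _group_fit(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
               n_iter: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe MLE of the group mean q (mean_ij = sf_j * q_i) via Newton
    steps on beta = log q; returns (q, Var(log q) from Fisher info)."""
    q = np.maximum((y / sf).mean(axis=1, keepdims=True), 1e-10)
    for _ in range(n_iter):
        mu = sf * q
        denom = 1.0 + alpha * mu
        score = ((y - mu) / denom).sum(axis=1, keepdims=True)
        info = (mu / denom).sum(axis=1, keepdims=True)
        q = np.exp(np.clip(np.log(q) + score / np.maximum(info, 1e-12),
                           -60, 60))
    mu = sf * q
    info = (mu / (1.0 + alpha * mu)).sum(axis=1, keepdims=True)
    return q, 1.0 / np.maximum(info, 1e-12)


def _trended_dispersion(y: np.ndarray, sf: np.ndarray, groups: np.ndarray,
                        n_bins: int = 20) -> np.ndarray:
    """Binned method-of-moments dispersion trend over mean expression."""
    m_all = (y / sf).mean(axis=1)
    resid_var = np.zeros(y.shape[0])
    shot = np.zeros(y.shape[0])
    dfsum = 0
    for g in np.unique(groups):
        idx = groups == g
        yn = y[:, idx] / sf[idx]
        w = idx.sum() - 1
        resid_var += yn.var(axis=1, ddof=1) * w
        shot += yn.mean(axis=1) * np.mean(1.0 / sf[idx]) * w
        dfsum += w
    resid_var /= max(dfsum, 1)
    shot /= max(dfsum, 1)
    a_raw = (resid_var - shot) / np.maximum(m_all, 1e-8) ** 2

    n_bins = int(np.clip(y.shape[0] // 50, 4, n_bins))
    order = np.argsort(m_all)
    bins = np.array_split(order, n_bins)
    bm = np.array([m_all[b].mean() for b in bins])
    # median of raw estimates per bin, inflated toward the mean (the median
    # of the skewed MoM estimator under-shoots its expectation)
    ba = np.maximum(np.array([np.median(a_raw[b]) for b in bins]) * 1.2,
                    1e-6)
    la = np.interp(np.log(np.maximum(m_all, 1e-8)), np.log(bm), np.log(ba))
    return np.exp(la)


def _trigamma_inverse(x: float) -> float:
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s2 ~ s0 * F(df, d0) on the log scale -> (d0, s0)."""
    z = np.log(np.maximum(s2, 1e-12))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 1e-8:
        d0 = 2 * _trigamma_inverse(float(evar))
        s0 = float(np.exp(e.mean() + special.digamma(d0 / 2)
                          - np.log(d0 / 2)))
    else:
        d0, s0 = np.inf, float(np.exp(e.mean()))
    return d0, s0


@dataclasses.dataclass
class DEResult:
    """Per-probe contrast statistics plus the per-gene collapse."""

    table: pd.DataFrame        # probe-level
    genes: pd.DataFrame        # gene-level (DEG flag + representative probe)
    fdr: float
    meta: dict

    def n_dep(self, direction: str | None = None) -> int:
        t = self.table
        sel = t["dep"].fillna(False)
        if direction is not None:
            sel = sel & (t["direction"] == direction)
        return int(sel.sum())

    def degs(self, direction: str | None = None) -> list[str]:
        g = self.genes
        sel = g["deg"]
        if direction is not None:
            sel = sel & (g["direction"] == direction)
        return list(g.loc[sel, "gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


class NBContrastModel:
    """Moderated NB Wald test of one treatment group against its control.

    Parameters
    ----------
    counts : CountMatrix
    size_factors : per-sample size factors covering both arms
    group, control : sample-id lists for the two arms (>=2 each)
    """

    def __init__(self, counts: CountMatrix, size_factors: pd.Series,
                 group: list[str], control: list[str]):
        if len(group) < 2 or len(control) < 2:
            raise ValueError("each arm needs >=2 samples")
        overlap = set(group) & set(control)
        if overlap:
            raise ValueError(f"arms overlap: {sorted(overlap)[:3]}")
        self.counts = counts
        self.group = list(group)
        self.control = list(control)
        self.sf = size_factors.loc[self.control + self.group].to_numpy(float)
        self.y = counts.counts[self.control + self.group].to_numpy(float)
        self.groups = np.array([0] * len(control) + [1] * len(group))

    def fit(self, fdr: float = DEFAULT_FDR) -> DEResult:
        y, sf, groups = self.y, self.sf, self.groups
        informative = y.sum(axis=1) > 0

        alpha_tr = _trended_dispersion(y[informative], sf, groups)
        a = alpha_tr[:, None]
        i_ctl, i_trt = groups == 0, groups == 1
        q1, v1 = _group_fit(y[informative][:, i_ctl], sf[i_ctl], a)
        q2, v2 = _group_fit(y[informative][:, i_trt], sf[i_trt], a)

        # quasi-dispersion from Pearson residuals under the trended alpha
        X2 = np.zeros(informative.sum())
        for q, idx in ((q1, i_ctl), (q2, i_trt)):
            mu = sf[idx] * q
            X2 += ((y[informative][:, idx] - mu) ** 2
                   / (mu * (1 + a * mu))).sum(axis=1)
        df_res = len(self.group) + len(self.control) - 2
        s2 = X2 / df_res
        d0, s0 = _squeeze_var(s2, df_res)
        d0 = min(d0, 1e6)
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)

        log2fc = (np.log(q2) - np.log(q1)).ravel() / np.log(2.0)
        wald = ((np.log(q2) - np.log(q1)) / np.sqrt(v1 + v2)).ravel()
        t = wald / np.sqrt(s2_post)
        p = 2 * stats.t.sf(np.abs(t), d0 + df_res)

        probe_ids = np.array(self.counts.counts.index)
        full = pd.DataFrame({
            "probe_id": probe_ids,
            "gene": self.counts.gene_of_probe.to_numpy(),
            "base_mean": np.nan, "log2fc": np.nan, "stat": np.nan,
            "p": np.nan,
        })
        full.loc[informative, "base_mean"] = ((y[informative] / sf)
                                              .mean(axis=1))
        full.loc[informative, "log2fc"] = log2fc
        full.loc[informative, "stat"] = t
        full.loc[informative, "p"] = p
        full["padj"] = bh_adjust(full["p"].to_numpy())
        full["dep"] = pd.array(full["padj"] < fdr, dtype="boolean")
        full.loc[full["p"].isna(), "dep"] = pd.NA
        full["direction"] = np.where(full["log2fc"] > 0, "up",
                                     np.where(full["log2fc"] < 0, "down",
                                              "none"))
        full.loc[full["p"].isna(), "direction"] = pd.NA

        genes = _collapse_genes(full)
        meta = {"d0": float(d0), "s0": float(s0), "df_res": df_res,
                "n_group": len(self.group), "n_control": len(self.control)}
        return DEResult(table=full, genes=genes, fdr=fdr, meta=meta)


def _collapse_genes(table: pd.DataFrame) -> pd.DataFrame:
    """DEG if any probe is a DEP; representative probe = smallest padj,
    ties -> larger |log2fc|, then lexical probe id."""
    t = table.copy()
    t["_dep"] = t["dep"].astype("boolean").fillna(False).astype(bool)
    t["_absfc"] = t["log2fc"].abs()
    t = t.sort_values(["gene", "padj", "_absfc", "probe_id"],
                      ascending=[True, True, False, True],
                      kind="mergesort", na_position="last")
    rep = t.groupby("gene", sort=True).first()
    deg = t.groupby("gene", sort=True)["_dep"].any()
    out = pd.DataFrame({
        "gene": rep.index,
        "deg": deg.to_numpy(),
        "representative_probe": rep["probe_id"].to_numpy(),
        "log2fc": rep["log2fc"].to_numpy(),
        "padj": rep["padj"].to_numpy(),
        "direction": rep["direction"].to_numpy(),
    }).reset_index(drop=True)
    return out


# ---- contrast enumeration over a study ----------------------------------

def vehicle_matched_control(sheet: pd.DataFrame, genotype: str,
                            vehicle: str, timepoint_h: float) -> list[str]:
    sel = (sheet["chemical"].eq(CONTROL_LABEL)
           & sheet["genotype"].eq(genotype)
           & sheet["vehicle"].eq(vehicle)
           & sheet["timepoint_h"].eq(timepoint_h))
    return list(sheet.loc[sel, "sample_id"])


def run_all_contrasts(counts: CountMatrix, sheet: pd.DataFrame,
                      size_factors: pd.Series,
                      fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Test every (genotype, chemical, concentration, timepoint) cell
    against its vehicle-matched control; skipped cells are logged with a
    reason.  Returns a tidy long table of probe-level results."""
    validate_sample_sheet(sheet)
    use = sheet
    if "excluded_from_de" in use.columns:
        use = use[~use["excluded_from_de"]]
    use = use[use["sample_id"].isin(counts.sample_ids)]

    frames = []
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h"]
    for (gt, chem, conc, tp), sub in use.groupby(cell_cols, sort=True):
        if chem == CONTROL_LABEL:
            continue
        vehicle = sub["vehicle"].iloc[0]
        ctl = vehicle_matched_control(use, gt, vehicle, tp)
        grp = list(sub["sample_id"])
        if len(grp) < 2 or len(ctl) < 2:
            frames.append(pd.DataFrame({
                "genotype": [gt], "chemical": [chem],
                "concentration": [conc], "timepoint_h": [tp],
                "skipped": [True],
                "skip_reason": [f"insufficient replicates "
                                f"(group={len(grp)}, control={len(ctl)})"]}))
            continue
        res = NBContrastModel(counts, size_factors, grp, ctl).fit(fdr=fdr)
        t = res.table.copy()
        t.insert(0, "genotype", gt)
        t.insert(1, "chemical", chem)
        t.insert(2, "concentration", conc)
        t.insert(3, "timepoint_h", tp)
        t["skipped"] = False
        t["skip_reason"] = ""
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=cell_cols + ["skipped", "skip_reason"])
    return pd.concat(frames, ignore_index=True)


def count_deps(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell up/down DEP counts (the study's summary-grid numbers)."""
    cell_cols = ["genotype", "chemical", "concentration", "timepoint_h"]
    if results.empty:
        return pd.DataFrame(columns=cell_cols + ["n_up", "n_down"])
    t = results[results.get("skipped", False) == False]  # noqa: E712
    if t.empty or "dep" not in t.columns:
        return pd.DataFrame(columns=cell_cols + ["n_up", "n_down"])
    dep = t["dep"].astype("boolean").fillna(False).astype(bool)
    up = dep & t["direction"].eq("up")
    down = dep & t["direction"].eq("down")
    out = (t.assign(n_up=up, n_down=down)
            .groupby(cell_cols, as_index=False)[["n_up", "n_down"]]
            .sum())
    out[["n_up", "n_down"]] = out[["n_up", "n_down"]].astype(int)
    return out
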