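"""Concentration-response modeling and benchmark concentrations (BMC).

Per probe, group-mean log2 normalized expression is fitted against
concentration with a small family of least-squares models (linear,
quadratic, power, Hill, saturating exponential).  The winning model is the
lowest-AIC converged fit (ties favor fewer parameters, then a fixed family
order); its goodness-of-fit p-value comes from the residual chi-square of
the weighted fit.  The BMC is the lowest concentration at which the fitted
curve departs from its control response by the benchmark response
BMR = bmr_factor * control SD (default factor 1.0 on the log2 scale);
BMCL/BMCU are 95% bounds from a delta-method interval on log BMC, with a
seeded parametric bootstrap available as a fallback.

Probes are retained only when the winning fit has p >= 0.1, the BMC lies
between lowest_conc/10 and the highest tested concentration, and
BMC/BMCL <= 20, BMCU/BMC <= 20, BMCU/BMCL <= 40.  Pathway summaries report
Fisher's exact (two-tail) enrichment of responsive genes per set plus
median BMC/BMCL/BMCU over responsive member genes; no set-size filters are
applied at this stage.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CONTROL_LABEL, CountMatrix, GeneSetCollection

DEFAULT_BMR_FACTOR = 1.0
DEFAULT_FIT_PMIN = 0.1
DEFAULT_RATIO_FILTERS = (20.0, 20.0, 40.0)
DEFAULT_PREFILTER_ALPHA = 0.05
PATHWAY_P_THRESH = 0.1


# ---- model families ------------------------------------------------------

def _f_linear(c, a, b):
    return a + b * c


def _f_poly2(c, a, b, d):
    return a + b * c + d * c * c


def _f_power(c, a, b, p):
    return a + b * np.power(np.maximum(c, 0.0), p)


def _f_hill(c, a, s, e, h):
    c = np.maximum(c, 0.0)
    return a + s * c**h / (e**h + c**h)


def _f_exp(c, a, d, b):
    return a + d * (1.0 - np.exp(-c / b))


@dataclasses.dataclass
class ModelFamily:
    name: str
    fun: object
    n_params: int
    p0: object        # (conc, y) -> initial params
    bounds: object    # (conc, y) -> (lower, upper)


def _family_list(conc: np.ndarray, y: np.ndarray) -> list[ModelFamily]:
    cmax = conc.max()
    cmin_pos = conc[conc > 0].min()
    span0 = y[-1] - y[0]
    inf = np.inf
    return [
        ModelFamily("linear", _f_linear, 2,
                    lambda c, y: [y[0], span0 / max(cmax, 1e-12)],
                    lambda c, y: ([-inf, -inf], [inf, inf])),
        ModelFamily("poly2", _f_poly2, 3,
                    lambda c, y: [y[0], span0 / max(cmax, 1e-12), 0.0],
                    lambda c, y: ([-inf] * 3, [inf] * 3)),
        ModelFamily("power", _f_power, 3,
                    lambda c, y: [y[0], span0 / max(cmax, 1e-12), 1.0],
                    lambda c, y: ([-inf, -inf, 0.1], [inf, inf, 4.0])),
        ModelFamily("hill", _f_hill, 4,
                    lambda c, y: [y[0], span0 if span0 != 0 else 0.1,
                                  np.sqrt(cmin_pos * cmax), 1.0],
                    lambda c, y: ([-inf, -inf, cmin_pos / 100.0, 0.5],
                                  [inf, inf, cmax * 100.0, 8.0])),
        ModelFamily("exp", _f_exp, 3,
                    lambda c, y: [y[0], span0 if span0 != 0 else 0.1,
                                  np.sqrt(cmin_pos * cmax)],
                    lambda c, y: ([-inf, -inf, cmin_pos / 1000.0],
                                  [inf, inf, cmax * 1000.0])),
    ]


FAMILY_ORDER = ["linear", "poly2", "power", "hill", "exp"]


@dataclasses.dataclass
class DoseResponseFit:
    family: str
    params: np.ndarray
    cov: np.ndarray | None
    chi2: float
    df: int
    aic: float
    fit_p: float
    fun: object

    def predict(self, c) -> np.ndarray:
        return self.fun(np.asarray(c, dtype=float), *self.params)


@dataclasses.dataclass
class BMCEstimate:
    bmc: float
    bmcl: float
    bmcu: float
    flags: list[str]


class DoseResponseModel:
    """Summary-data concentration-response model for one probe.

    Parameters
    ----------
    conc : concentration per group (control = 0), ascending
    mean : group mean log2 normalized expression
    se : standard error of each group mean
    """

    def __init__(self, conc, mean, se):
        conc = np.asarray(conc, dtype=float)
        order = np.argsort(conc)
        self.conc = conc[order]
        self.mean = np.asarray(mean, dtype=float)[order]
        self.se = np.maximum(np.asarray(se, dtype=float)[order], 1e-6)
        if self.conc[0] != 0:
            raise ValueError("a control group (concentration 0) is required")
        if len(self.conc) < 4:
            raise ValueError(">=4 concentration groups required (incl. control)")

    def fit(self, families: list[str] | None = None) -> "DoseResponseResults":
        fits: dict[str, DoseResponseFit] = {}
        for fam in _family_list(self.conc, self.mean):
            if families is not None and fam.name not in families:
                continue
            df = len(self.conc) - fam.n_params
            if df < 1:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = optimize.curve_fit(
                        fam.fun, self.conc, self.mean,
                        p0=fam.p0(self.conc, self.mean),
                        sigma=self.se, absolute_sigma=True,
                        bounds=fam.bounds(self.conc, self.mean),
                        maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            resid = (self.mean - fam.fun(self.conc, *popt)) / self.se
            chi2 = float(np.sum(resid**2))
            if not np.isfinite(chi2):
                continue
            aic = chi2 + 2 * fam.n_params
            fit_p = float(stats.chi2.sf(chi2, df))
            if not np.all(np.isfinite(pcov)):
                pcov = None
            fits[fam.name] = DoseResponseFit(
                family=fam.name, params=np.asarray(popt), cov=pcov,
                chi2=chi2, df=df, aic=aic, fit_p=fit_p, fun=fam.fun)
        return DoseResponseResults(self, fits)


class DoseResponseResults:
    """Converged family fits plus winner selection and BMC estimation."""

    def __init__(self, model: DoseResponseModel,
                 fits: dict[str, DoseResponseFit]):
        self.model = model
        self.fits = fits
        self.winner = select_winner(fits)

    def bmc(self, control_sd: float,
            bmr_factor: float = DEFAULT_BMR_FACTOR,
            ci: str = "delta", n_boot: int = 250,
            seed: int = 0) -> BMCEstimate:
        if self.winner is None:
            return BMCEstimate(np.nan, np.nan, np.nan, ["fit-fail"])
        return compute_bmc(self.winner, bmr_factor * control_sd,
                           self.model.conc, ci=ci, n_boot=n_boot,
                           seed=seed, se=self.model.se,
                           mean=self.model.mean)

    def summary(self) -> pd.DataFrame:
        rows = [(f.family, f.n_params if hasattr(f, "n_params")
                 else len(f.params), f.chi2, f.df, f.aic, f.fit_p,
                 f is self.winner)
                for f in self.fits.values()]
        return pd.DataFrame(rows, columns=["family", "n_params", "chi2",
                                           "df", "aic", "fit_p", "winner"])


def select_winner(fits: dict[str, DoseResponseFit]) -> DoseResponseFit | None:
    """Lowest AIC; ties (within 1e-9) -> fewer parameters, then the fixed
    family order."""
    if not fits:
        return None
    items = sorted(fits.values(),
                   key=lambda f: (round(f.aic, 9), len(f.params),
                                  FAMILY_ORDER.index(f.family)))
    return items[0]


# ---- BMC computation -----------------------------------------------------

def _solve_crossing(fun, params, bmr: float, c_lo: float,
                    c_hi: float) -> float:
    """Lowest c in [c_lo, c_hi] with |f(c) - f(0)| = bmr, or nan."""
    f0 = float(fun(np.array([0.0]), *params)[0])

    def g(c):
        return abs(float(fun(np.array([c]), *params)[0]) - f0) - bmr

    grid = np.geomspace(c_lo, c_hi, 400)
    vals = np.abs(fun(grid, *params) - f0) - bmr
    if vals[0] >= 0:
        return c_lo  # departure exceeds BMR already at the scan floor
    idx = np.flatnonzero(vals >= 0)
    if idx.size == 0:
        return np.nan
    i = idx[0]
    return float(optimize.brentq(g, grid[i - 1], grid[i], xtol=1e-12,
                                 rtol=1e-12))


def compute_bmc(fit: DoseResponseFit, bmr: float, conc: np.ndarray,
                ci: str = "delta", n_boot: int = 250, seed: int = 0,
                se: np.ndarray | None = None,
                mean: np.ndarray | None = None) -> BMCEstimate:
    """BMC solving |f(c) - f(0)| = bmr, with 95% bounds.

    The crossing is searched from lowest_conc/1e4 up to the highest tested
    concentration so that the below-range filter can see how far below the
    ladder the estimate falls; no crossing at all flags 'above-range'.
    """
    if bmr <= 0:
        raise ValueError("benchmark response must be positive")
    cpos = conc[conc > 0]
    c_lo, c_hi = cpos.min() / 1e4, cpos.max()
    bmc = _solve_crossing(fit.fun, fit.params, bmr, c_lo, c_hi)
    if not np.isfinite(bmc):
        return BMCEstimate(np.nan, np.nan, np.nan, ["above-range"])

    bmcl = bmcu = np.nan
    flags: list[str] = []
    if ci == "none":
        return BMCEstimate(bmc, bmcl, bmcu, flags)
    if ci == "delta" and fit.cov is not None:
        grad = _bmc_gradient(fit, bmr, c_lo, c_hi, bmc)
        if grad is not None:
            var = float(grad @ fit.cov @ grad)
            if np.isfinite(var) and var >= 0:
                se_log = min(np.sqrt(var) / max(bmc, 1e-300), 200.0)
                bmcl = bmc * np.exp(-1.959964 * se_log)
                bmcu = bmc * np.exp(1.959964 * se_log)
    if not np.isfinite(bmcl) and mean is not None and se is not None:
        bmcl, bmcu = _bootstrap_ci(fit, bmr, conc, mean, se, c_lo, c_hi,
                                   n_boot, seed)
        if np.isfinite(bmcl):
            flags.append("ci-bootstrap")
    return BMCEstimate(bmc, bmcl, bmcu, flags)


def _bmc_gradient(fit: DoseResponseFit, bmr: float, c_lo: float,
                  c_hi: float, bmc: float) -> np.ndarray | None:
    """Numerical gradient of the BMC with respect to model parameters."""
    grad = np.zeros(len(fit.params))
    for i in range(len(fit.params)):
        step = 1e-4 * max(abs(fit.params[i]), 1e-4)
        lo, hi = fit.params.copy(), fit.params.copy()
        lo[i] -= step
        hi[i] += step
        b_lo = _solve_crossing(fit.fun, lo, bmr, c_lo, c_hi * 10)
        b_hi = _solve_crossing(fit.fun, hi, bmr, c_lo, c_hi * 10)
        if not (np.isfinite(b_lo) and np.isfinite(b_hi)):
            return None
        grad[i] = (b_hi - b_lo) / (2 * step)
    return grad


def _bootstrap_ci(fit: DoseResponseFit, bmr: float, conc: np.ndarray,
                  mean: np.ndarray, se: np.ndarray, c_lo: float,
                  c_hi: float, n_boot: int, seed: int) -> tuple[float, float]:
    """Seeded parametric bootstrap on the group means (winner family only)."""
    rng = np.random.default_rng(seed)
    fitted = fit.predict(conc)
    draws = []
    for _ in range(n_boot):
        yb = fitted + rng.normal(0.0, se)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    fit.fun, conc, yb, p0=fit.params, sigma=se,
                    absolute_sigma=True, maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        b = _solve_crossing(fit.fun, popt, bmr, c_lo, c_hi * 10)
        if np.isfinite(b):
            draws.append(b)
    if len(draws) < max(20, n_boot // 5):
        return np.nan, np.nan
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


# ---- filters -------------------------------------------------------------

def apply_bmc_filters(results: pd.DataFrame, conc_ladder,
                      fit_pmin: float = DEFAULT_FIT_PMIN,
                      ratio_filters=DEFAULT_RATIO_FILTERS) -> pd.DataFrame:
    """Annotate each probe row with the specific failed rules and a
    ``retained`` flag.  Expects columns winner, fit_p, bmc, bmcl, bmcu."""
    ladder = np.asarray([c for c in conc_ladder if c > 0], dtype=float)
    lo, hi = ladder.min(), ladder.max()
    r1, r2, r3 = ratio_filters
    out = results.copy()
    failed = []
    for _, row in out.iterrows():
        rules = []
        if not isinstance(row.get("winner"), str) or row.get("winner") in ("", "none"):
            rules.append("fit-fail")
        elif not np.isfinite(row["bmc"]):
            rules.append("above-range")
        else:
            if row["fit_p"] < fit_pmin:
                rules.append("gof-fail")
            if row["bmc"] < lo / 10.0:
                rules.append("below-range")
            if row["bmc"] > hi:
                rules.append("above-range")
            bmc, bmcl, bmcu = row["bmc"], row["bmcl"], row["bmcu"]
            if np.isfinite(bmcl) and bmcl > 0 and bmc / bmcl > r1:
                rules.append("ratio-bmc-bmcl")
            if np.isfinite(bmcu) and np.isfinite(bmc) and bmcu / bmc > r2:
                rules.append("ratio-bmcu-bmc")
            if (np.isfinite(bmcu) and np.isfinite(bmcl) and bmcl > 0
                    and bmcu / bmcl > r3):
                rules.append("ratio-bmcu-bmcl")
            if not (np.isfinite(bmcl) and np.isfinite(bmcu)):
                rules.append("ci-fail")
        failed.append(";".join(rules))
    out["failed_rules"] = failed
    out["retained"] = out["failed_rules"].eq("")
    return out


# ---- prefilter -----------------------------------------------------------

def prefilter_trend(log2_expr: np.ndarray, group_labels: np.ndarray,
                    alpha: float = DEFAULT_PREFILTER_ALPHA) -> np.ndarray:
    """One-way ANOVA across concentration groups on log2 normalized
    expression; returns a boolean keep-mask (p < alpha).  Zero-variance
    probes are excluded."""
    groups = np.unique(group_labels)
    k = len(groups)
    n = log2_expr.shape[1]
    grand = log2_expr.mean(axis=1)
    ss_between = np.zeros(log2_expr.shape[0])
    ss_within = np.zeros(log2_expr.shape[0])
    for g in groups:
        idx = group_labels == g
        m = log2_expr[:, idx].mean(axis=1)
        ss_between += idx.sum() * (m - grand) ** 2
        ss_within += ((log2_expr[:, idx] - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    keep = np.isfinite(p) & (p < alpha)
    return keep


# ---- per-study orchestration --------------------------------------------

def bmc_analysis(counts: CountMatrix, sheet: pd.DataFrame,
                 size_factors: pd.Series, genotype: str, chemical: str,
                 timepoint_h: float, *,
                 bmr_factor: float = DEFAULT_BMR_FACTOR,
                 prefilter_alpha: float = DEFAULT_PREFILTER_ALPHA,
                 fit_pmin: float = DEFAULT_FIT_PMIN,
                 ratio_filters=DEFAULT_RATIO_FILTERS,
                 seed: int = 0) -> pd.DataFrame:
    """Full per-probe BMC table for one (genotype, chemical, timepoint).

    Control wells are the vehicle-matched vehicle controls; responses are
    group means of log2(normalized count + 1); the BMR uses the pooled
    within-group SD (constant-variance assumption on the log2 scale).
    """
    sel_t = (sheet["genotype"].eq(genotype)
             & sheet["chemical"].eq(chemical)
             & sheet["timepoint_h"].eq(timepoint_h)
             & sheet["sample_id"].isin(counts.sample_ids))
    if not sel_t.any():
        raise ValueError(f"no samples for {genotype}/{chemical}/"
                         f"{timepoint_h}h")
    vehicle = sheet.loc[sel_t, "vehicle"].iloc[0]
    sel_c = (sheet["genotype"].eq(genotype)
             & sheet["chemical"].eq(CONTROL_LABEL)
             & sheet["vehicle"].eq(vehicle)
             & sheet["timepoint_h"].eq(timepoint_h)
             & sheet["sample_id"].isin(counts.sample_ids))
    sub = pd.concat([sheet[sel_c], sheet[sel_t]])
    ids = list(sub["sample_id"])
    conc_of = sub.set_index("sample_id")["concentration"]

    y = counts.counts[ids].to_numpy(float)
    sf = size_factors.loc[ids].to_numpy(float)
    log2e = np.log2(y / sf + 1.0)
    labels = conc_of.loc[ids].to_numpy(float)
    ladder = np.unique(labels)
    if len(ladder) < 4:
        raise ValueError("need >=3 nonzero concentrations plus control")

    keep = prefilter_trend(log2e, labels, alpha=prefilter_alpha)

    means = np.stack([log2e[:, labels == c].mean(axis=1) for c in ladder],
                     axis=1)
    # pooled within-group SD per probe (constant variance on log2 scale)
    ss = np.zeros(log2e.shape[0])
    dfw = 0
    for c in ladder:
        idx = labels == c
        m = log2e[:, idx].mean(axis=1)
        ss += ((log2e[:, idx] - m[:, None]) ** 2).sum(axis=1)
        dfw += idx.sum() - 1
    pooled_sd = np.sqrt(ss / max(dfw, 1))
    ns = np.array([(labels == c).sum() for c in ladder])

    rows = []
    gene_of = counts.gene_of_probe
    for i in np.flatnonzero(keep):
        sd_i = max(pooled_sd[i], 1e-3)
        se_i = sd_i / np.sqrt(ns)
        res = DoseResponseModel(ladder, means[i], se_i).fit()
        if res.winner is None:
            rows.append((counts.counts.index[i], gene_of.iloc[i], "none",
                         np.nan, np.nan, np.nan, np.nan, sd_i, ""))
            continue
        est = res.bmc(control_sd=sd_i, bmr_factor=bmr_factor,
                      seed=seed + i)
        rows.append((counts.counts.index[i], gene_of.iloc[i],
                     res.winner.family, res.winner.fit_p, est.bmc,
                     est.bmcl, est.bmcu, sd_i, ";".join(est.flags)))
    table = pd.DataFrame(rows, columns=["probe_id", "gene", "winner",
                                        "fit_p", "bmc", "bmcl", "bmcu",
                                        "control_sd", "bmc_flags"])
    table.insert(0, "genotype", genotype)
    table.insert(1, "chemical", chemical)
    table.insert(2, "timepoint_h", timepoint_h)
    return apply_bmc_filters(table, ladder, fit_pmin=fit_pmin,
                             ratio_filters=ratio_filters)


def gene_best_bmc(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level best BMC = minimum retained probe BMC per gene."""
    ret = probe_table[probe_table["retained"]]
    if ret.empty:
        return pd.DataFrame(columns=["gene", "bmc", "bmcl", "bmcu"])
    idx = ret.groupby("gene")["bmc"].idxmin()
    out = ret.loc[idx, ["gene", "bmc", "bmcl", "bmcu"]]
    return out.sort_values("gene").reset_index(drop=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def pathway_bmc(probe_table: pd.DataFrame, collection: GeneSetCollection,
                universe_genes, p_thresh: float = PATHWAY_P_THRESH,
                ) -> pd.DataFrame:
    """Per-set Fisher enrichment of responsive genes + median BMC/BMCL/BMCU.

    ``universe_genes``: all genes analyzed for this cell (responsive or
    not).  No minimum/maximum set-size filters are applied here.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    universe = set(universe_genes)
    genes = gene_best_bmc(probe_table).set_index("gene")
    responsive = set(genes.index) & universe
    rows = []
    for name, members in collection.items():
        inset = set(members) & universe
        a = len(inset & responsive)
        b = len(inset) - a
        c = len(responsive) - a
        d = len(universe) - len(inset) - c
        p = fisher_exact_2x2(a, b, c, d)
        hit = sorted(inset & responsive)
        med = genes.loc[hit] if hit else None
        rows.append((name, len(inset), a, p, p < p_thresh,
                     med["bmc"].median() if hit else np.nan,
                     med["bmcl"].median() if hit else np.nan,
                     med["bmcu"].median() if hit else np.nan))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size",
                                      "n_responsive", "fisher_p",
                                      "significant", "median_bmc",
                                      "median_bmcl", "median_bmcu"])
    return out.sort_values(["fisher_p", "gene_set"],
                           kind="mergesort").reset_index(drop=True)


def accumulation_data(values) -> pd.DataFrame:
    """Sorted values vs cumulative count (accumulation-plot coordinates)."""
    v = np.sort(np.asarray([x for x in values if np.isfinite(x)],
                           dtype=float))
    return pd.DataFrame({"value": v,
                         "cumulative_count": np.arange(1, v.size + 1)})
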