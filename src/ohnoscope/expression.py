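"""Expression divergence of duplicate gene pairs.

Covers count normalization, four-contrast differential expression with a
negative-binomial GLM, the expressed-pair filter, the five-group
classification of duplicate-pair DE behaviour, pair expression correlation,
the tau expression-specificity index, and the categorical preference tests
(chi-square with standardized-residual post hoc, Kruskal-Wallis/Wilcoxon).

The experiment is a 2x2 design: lifestyle (free-living vs symbiotic) crossed
with temperature (28 vs 34 degrees C).  The four contrasts are
  L-28  symbiotic vs free-living at 28
  L-34  symbiotic vs free-living at 34
  T-Fr  34 vs 28 within free-living cells
  T-Sy  34 vs 28 within symbiosis
A gene is differentially expressed when BH FDR < 0.01 and |log2FC| > 1.

The DE engine is a self-contained re-implementation of the standard NB GLM
approach: per-condition means fitted by Newton iteration with size-factor
offsets, gene-wise dispersion by Cox-Reid adjusted profile likelihood on a
grid, shrunk 50/50 toward a lowess mean-dispersion trend, and a Wald test on
the contrast with small-sample t reference (residual degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .collinearity import OhnologPair
from .io import condition_of

logger = logging.getLogger(__name__)

CONTRASTS = ("L-28", "L-34", "T-Fr", "T-Sy")

#: contrast -> (target condition, reference condition); log2FC = target - reference
CONTRAST_CONDITIONS = {
    "L-28": ("symbiotic:28", "free:28"),
    "L-34": ("symbiotic:34", "free:34"),
    "T-Fr": ("free:34", "free:28"),
    "T-Sy": ("symbiotic:34", "symbiotic:28"),
}

FDR_CUTOFF = 0.01
LFC_CUTOFF = 1.0


@dataclass
class PosthocResult:
    table: pd.DataFrame
    chi2: float
    pvalue: float
    residuals: pd.DataFrame
    cell_pvalues: pd.DataFrame


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(counts: pd.DataFrame, gene_lengths: dict[str, int] | None = None):
    """Median-of-ratios size factors plus CPM/FPKM/log2(FPKM+1) matrices.

    The reference profile is the per-gene geometric mean over samples,
    computed from genes with no zero count.  The effective library size of a
    sample is its size factor times the mean raw library size; FPKM divides
    the count by effective library (in millions) and gene length (in kb).
    """
    if (counts.to_numpy() == 0).all():
        raise ValueError("all-zero count matrix")
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if nonzero.any():
        logref = np.log(mat[nonzero]).mean(axis=1)
        ratios = np.log(mat[nonzero]) - logref[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no gene without zeros; falling back to library-size factors")
        libs = mat.sum(axis=0)
        size_factors = libs / np.exp(np.mean(np.log(libs)))
    size_factors = pd.Series(size_factors, index=counts.columns, name="size_factor")

    eff_lib = size_factors * counts.sum(axis=0).mean()
    cpm = counts / (eff_lib / 1e6)
    out = {"size_factors": size_factors, "cpm": cpm}
    if gene_lengths is not None:
        lengths = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
        fpkm = cpm.div(lengths / 1e3, axis=0)
        out["fpkm"] = fpkm
        out["log2fpkm"] = np.log2(fpkm + 1.0)
    return out


# ---------------------------------------------------------------------------
# NB GLM differential expression
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    """NB2 log-likelihood, summed over the sample axis."""
    a = np.maximum(alpha, 1e-10)
    inv = 1.0 / a
    mu = np.maximum(mu, 1e-10)
    return (gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(a * mu / (1 + a * mu))
            - inv * np.log1p(a * mu)).sum(axis=-1)


def _fit_condition_means(y, sf, groups, alpha, n_iter=8):
    """MLE of per-condition means for every gene, by Newton on log mean.

    y: genes x samples; sf: per-sample size factors; groups: list of sample
    index arrays, one per condition; alpha: per-gene dispersion (scalar or
    genes vector).  Returns (beta, info): genes x conditions arrays of log
    means and Fisher information.
    """
    n_genes = y.shape[0]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float).reshape(-1, 1),
                            (n_genes, 1))
    beta = np.empty((n_genes, len(groups)))
    info = np.empty((n_genes, len(groups)))
    for c, idx in enumerate(groups):
        yc = y[:, idx]
        sc = sf[idx]
        m0 = yc.sum(axis=1) / sc.sum()
        b = np.log(np.maximum(m0, 1e-8))
        for _ in range(n_iter):
            mu = np.exp(b)[:, None] * sc
            w = mu / (1 + alpha * mu)
            score = ((yc - mu) / (1 + alpha * mu)).sum(axis=1)
            fisher = np.maximum(w.sum(axis=1), 1e-12)
            step = np.clip(score / fisher, -5, 5)
            b = b + step
            b = np.clip(b, np.log(1e-8), 50)
        mu = np.exp(b)[:, None] * sc
        beta[:, c] = b
        info[:, c] = np.maximum((mu / (1 + alpha * mu)).sum(axis=1), 1e-12)
    return beta, info


def _profile_dispersion(y, sf, groups, grid=None):
    """Cox-Reid adjusted profile-likelihood dispersion per gene, on a grid."""
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-3), np.log(10.0), 25))
    n_genes = y.shape[0]
    apl = np.empty((len(grid), n_genes))
    for gi, a in enumerate(grid):
        beta, info = _fit_condition_means(y, sf, groups, a)
        ll = np.zeros(n_genes)
        for c, idx in enumerate(groups):
            mu = np.exp(beta[:, c])[:, None] * sf[idx]
            ll += _nb_loglik(y[:, idx], mu, a)
        apl[gi] = ll - 0.5 * np.log(info).sum(axis=1)
    best = apl.argmax(axis=0)
    return grid[best]


def estimate_dispersions(counts: pd.DataFrame, samples: pd.DataFrame,
                         size_factors: pd.Series) -> pd.Series:
    """Gene-wise dispersions shrunk 50/50 (log scale) toward a lowess trend
    over the mean-dispersion relationship."""
    cond = condition_of(samples).loc[counts.columns]
    groups = [np.flatnonzero((cond == c).to_numpy()) for c in sorted(cond.unique())]
    y = counts.to_numpy(dtype=float)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    genewise = _profile_dispersion(y, sf, groups)
    log_mean = np.log((y / sf).mean(axis=1) + 1e-8)
    log_disp = np.log(genewise)
    trend = lowess(log_disp, log_mean, frac=0.5, return_sorted=False)
    shrunk = np.exp(0.5 * log_disp + 0.5 * trend)
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def prefilter_genes(counts: pd.DataFrame, min_count: int = 5,
                    min_frac: float = 0.25) -> pd.DataFrame:
    """Drop genes without ``min_count`` reads in at least ``min_frac`` of samples."""
    ok = (counts >= min_count).mean(axis=1) >= min_frac
    return counts.loc[ok]


def test_de(counts: pd.DataFrame, samples: pd.DataFrame, contrast: str,
            dispersions: pd.Series | None = None,
            size_factors: pd.Series | None = None,
            prefilter: bool = True) -> pd.DataFrame:
    """Negative-binomial Wald test for one of the four contrasts.

    Returns a per-gene frame with log2fc, pvalue, fdr (BH within contrast)
    and status in {up, down, ns}: up iff fdr < 0.01 and log2fc > 1, down iff
    fdr < 0.01 and log2fc < -1.
    """
    if contrast not in CONTRAST_CONDITIONS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    if prefilter:
        counts = prefilter_genes(counts)
    if counts.empty:
        raise ValueError("no genes left after expression pre-filter")
    if size_factors is None:
        size_factors = normalize_counts(counts)["size_factors"]
    if dispersions is None:
        dispersions = estimate_dispersions(counts, samples, size_factors)
    dispersions = dispersions.loc[counts.index]

    cond = condition_of(samples).loc[counts.columns]
    cond_names = sorted(cond.unique())
    for needed in CONTRAST_CONDITIONS[contrast]:
        if needed not in cond_names:
            raise ValueError(f"condition {needed} absent from sample sheet")
        if (cond == needed).sum() < 2:
            raise ValueError(f"condition {needed} has < 2 replicates")
    groups = [np.flatnonzero((cond == c).to_numpy()) for c in cond_names]
    y = counts.to_numpy(dtype=float)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)

    beta, info = _fit_condition_means(y, sf, groups,
                                      dispersions.to_numpy(dtype=float))
    target, ref = CONTRAST_CONDITIONS[contrast]
    it, ir = cond_names.index(target), cond_names.index(ref)
    est = beta[:, it] - beta[:, ir]
    se = np.sqrt(1.0 / info[:, it] + 1.0 / info[:, ir])
    df = y.shape[1] - len(groups)
    tstat = est / se
    pvalue = 2 * stats.t.sf(np.abs(tstat), df=df)
    fdr = multipletests(pvalue, method="fdr_bh")[1]
    log2fc = est / np.log(2)

    status = np.where((fdr < FDR_CUTOFF) & (log2fc > LFC_CUTOFF), "up",
                      np.where((fdr < FDR_CUTOFF) & (log2fc < -LFC_CUTOFF),
                               "down", "ns"))
    return pd.DataFrame({"gene_id": counts.index, "contrast": contrast,
                         "log2fc": log2fc, "pvalue": pvalue, "fdr": fdr,
                         "status": status}).set_index("gene_id")


def test_all_contrasts(counts: pd.DataFrame, samples: pd.DataFrame,
                       prefilter: bool = True) -> dict[str, pd.DataFrame]:
    """All four contrasts with a single shared dispersion estimation pass."""
    if prefilter:
        counts = prefilter_genes(counts)
    size_factors = normalize_counts(counts)["size_factors"]
    dispersions = estimate_dispersions(counts, samples, size_factors)
    return {c: test_de(counts, samples, c, dispersions=dispersions,
                       size_factors=size_factors, prefilter=False)
            for c in CONTRASTS}


# ---------------------------------------------------------------------------
# Pair-level classification
# ---------------------------------------------------------------------------

def filter_expressed_pairs(counts: pd.DataFrame, pairs: list[OhnologPair],
                           min_count: int = 10,
                           min_sample_frac: float = 0.5) -> list[OhnologPair]:
    """Keep pairs whose BOTH genes have >= min_count raw reads in at least
    min_sample_frac of all samples."""
    frac = (counts >= min_count).mean(axis=1)
    ok = set(frac.index[frac >= min_sample_frac])
    return [p for p in pairs if p.gene_a in ok and p.gene_b in ok]


def classify_pair_groups(de: dict[str, pd.DataFrame],
                         pairs: list[OhnologPair]) -> pd.DataFrame:
    """Assign each duplicate pair one of five DE-behaviour groups.

    With D(g) the set of contrasts where gene g is DE (up or down):
    group 1 - neither copy DE; group 2 - exactly one copy DE; group 5 - some
    shared contrast with opposite directions; group 3 - some shared contrast
    with the same direction; group 4 - both DE in disjoint contrast sets.
    Opposing behaviour takes precedence over parallel behaviour when a pair
    shows both.
    """
    for c in CONTRASTS:
        if c not in de:
            raise ValueError(f"missing DE results for contrast {c}")
    rows = []
    for p in pairs:
        status = {}
        for c in CONTRASTS:
            for g in (p.gene_a, p.gene_b):
                if g not in de[c].index:
                    raise ValueError(f"gene {g} missing from DE table for {c}")
            status[c] = (de[c].loc[p.gene_a, "status"],
                         de[c].loc[p.gene_b, "status"])
        da = {c for c in CONTRASTS if status[c][0] != "ns"}
        db = {c for c in CONTRASTS if status[c][1] != "ns"}
        shared = da & db
        if not da and not db:
            group = 1
        elif not da or not db:
            group = 2
        elif any(status[c][0] != status[c][1] for c in shared):
            group = 5
        elif shared:
            group = 3
        else:
            group = 4
        rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b, "group": group,
                     **{f"status_{c}": f"{status[c][0]}/{status[c][1]}"
                        for c in CONTRASTS}})
    return pd.DataFrame(rows)


def pair_correlation(log2fpkm: pd.DataFrame, pair: OhnologPair) -> float:
    """Pearson correlation of the two copies' expression profiles across all
    samples; NaN (flagged undefined) when either profile has zero variance."""
    a = log2fpkm.loc[pair.gene_a].to_numpy(dtype=float)
    b = log2fpkm.loc[pair.gene_b].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Expression specificity (tau)
# ---------------------------------------------------------------------------

def tau_index(log2fpkm: pd.DataFrame, samples: pd.DataFrame,
              eligibility_cutoff: float = 1.0) -> pd.DataFrame:
    """Tau specificity index per gene over the four lifestyle x temperature
    conditions.

    Replicates are averaged per condition on the log2(FPKM+1) scale; a gene
    is eligible when its maximal condition mean exceeds the cutoff.  tau =
    sum_i (1 - x_i/x_max) / (N-1) ranges from 0 (uniform expression) to 1
    (expression confined to one condition).
    """
    cond = condition_of(samples).loc[log2fpkm.columns]
    means = log2fpkm.T.groupby(cond.to_numpy()).mean().T
    x = np.clip(means.to_numpy(dtype=float), 0, None)
    xmax = x.max(axis=1)
    eligible = xmax > eligibility_cutoff
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau = np.where(xmax > 0, tau, np.nan)
    peak = means.columns.to_numpy()[x.argmax(axis=1)]
    return pd.DataFrame({"tau": np.where(eligible, tau, np.nan),
                         "eligible": eligible,
                         "peak_condition": peak}, index=log2fpkm.index)


def tau_class_tests(tau: pd.DataFrame, classes: pd.DataFrame) -> dict:
    """Kruskal-Wallis over duplication categories plus pairwise Wilcoxon
    rank-sum tests (normal approximation with continuity correction) under
    Holm adjustment.  Categories with < 2 eligible members are excluded with
    a warning."""
    merged = classes.set_index("gene_id").join(tau, how="inner")
    merged = merged[merged["eligible"] & merged["tau"].notna()]
    by_class = {c: g["tau"].to_numpy() for c, g in merged.groupby("category")}
    usable = {}
    for c, v in by_class.items():
        if len(v) < 2:
            logger.warning("category %s has < 2 eligible genes - excluded", c)
        else:
            usable[c] = v
    if len(usable) < 2:
        raise ValueError("need >= 2 categories with >= 2 eligible genes")
    kw_stat, kw_p = stats.kruskal(*usable.values())
    names = sorted(usable)
    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.mannwhitneyu(usable[names[i]], usable[names[j]],
                                     alternative="two-sided", use_continuity=True)
            pairs.append((names[i], names[j]))
            raw.append(res.pvalue)
    adj = multipletests(raw, method="holm")[1] if raw else []
    return {"kruskal_statistic": float(kw_stat), "kruskal_p": float(kw_p),
            "pairwise": [{"a": a, "b": b, "p_raw": float(p), "p_holm": float(q)}
                         for (a, b), p, q in zip(pairs, raw, adj)]}


# ---------------------------------------------------------------------------
# Categorical preference (chi-square + post hoc residuals)
# ---------------------------------------------------------------------------

def categorical_preference(table: pd.DataFrame) -> PosthocResult:
    """Pearson chi-square on a category x level contingency table with a
    standardized-residual post hoc.

    residual = (obs - exp) / sqrt(exp * (1 - row/N) * (1 - col/N)); per-cell
    two-sided p-values from the normal distribution, Bonferroni-adjusted over
    all cells.  Expected counts of zero are an error.
    """
    obs = table.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / n
    if (exp <= 0).any():
        raise ValueError("expected cell count of 0; merge sparse levels")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    pvalue = float(stats.chi2.sf(chi2, dof))
    resid = (obs - exp) / np.sqrt(exp * (1 - row / n) * (1 - col / n))
    cell_p = 2 * stats.norm.sf(np.abs(resid))
    cell_p = np.minimum(cell_p * obs.size, 1.0)
    return PosthocResult(
        table=table,
        chi2=chi2,
        pvalue=pvalue,
        residuals=pd.DataFrame(resid, index=table.index, columns=table.columns),
        cell_pvalues=pd.DataFrame(cell_p, index=table.index, columns=table.columns),
    )
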