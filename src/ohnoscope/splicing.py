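"""Differential exon usage and splice-junction conservation in duplicate pairs.

Gene models are flattened into disjoint exon "counting bins"; the relative
usage of a bin (bin reads over gene reads) is compared between the two
conditions of a contrast with a quasi-binomial score test, and significance
is corrected at the gene level (Sidak combination of bin p-values, then BH
across genes).

Splice junctions are compared between the two copies of a duplicate pair by
their flanking sequence, not by coordinates, since the copies live at
different loci: a junction is conserved when BOTH its upstream and downstream
300-bp flanks align significantly to the counterpart's.  The per-pair binary
presence/absence profiles feed a Kendall tau-b correlation and an exact
binomial test of junction-count divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .divergence import local_nt_match
from .io import GeneCatalog, condition_of
from .expression import CONTRAST_CONDITIONS

logger = logging.getLogger(__name__)

JUNCTION_TYPES = ("alternative_acceptor", "alternative_donor",
                  "alternative_exon", "retained_exon", "skipped_exon")


@dataclass
class PairDeuSummary:
    gene_a: str
    gene_b: str
    overall_deu: float
    proportion_deu: float
    n_matched_bins: int
    comparable: bool = True


@dataclass
class JunctionProfilePair:
    gene_a: str
    gene_b: str
    junction_ids: list[str] = field(default_factory=list)
    profile_a: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    profile_b: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def conserved_fraction(self) -> float:
        """Fraction of the profiled junctions present in both copies."""
        n = len(self.profile_a)
        if n == 0:
            return float("nan")
        return float(((self.profile_a == 1) & (self.profile_b == 1)).sum() / n)


# ---------------------------------------------------------------------------
# Exon counting bins
# ---------------------------------------------------------------------------

def make_exon_bins(exons_by_gene) -> pd.DataFrame:
    """Flatten (possibly overlapping) exon intervals into disjoint bins.

    Accepts a GeneCatalog or a mapping gene_id -> list of 1-based inclusive
    (start, end) intervals pooled over isoforms.  Boundaries of every variant
    split the exonic footprint; each elementary interval covered by at least
    one exon becomes a bin (0-based half-open coordinates) with its overlap
    count recorded as support.
    """
    if isinstance(exons_by_gene, GeneCatalog):
        exons_by_gene = {gid: list(g.exons) or [(g.start, g.end)]
                         for gid, g in exons_by_gene.genes.items()}
    rows = []
    for gid in sorted(exons_by_gene):
        intervals = [(s - 1, e) for s, e in exons_by_gene[gid]]  # to half-open
        if not intervals:
            continue
        bounds = sorted({b for iv in intervals for b in iv})
        k = 0
        for lo, hi in zip(bounds, bounds[1:]):
            support = sum(1 for s, e in intervals if s <= lo and hi <= e)
            if support > 0:
                rows.append((f"{gid}:bin{k:03d}", gid, lo, hi, support))
                k += 1
    return pd.DataFrame(rows, columns=["bin_id", "gene_id", "start", "end",
                                       "support"])


# ---------------------------------------------------------------------------
# Differential exon usage
# ---------------------------------------------------------------------------

def relative_usage(bin_counts: pd.DataFrame, gene_totals: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative usage of each bin (bin reads / gene reads).

    ``bin_counts`` is indexed by (gene_id, bin_id); samples where the gene
    total is 0 yield NaN usage.
    """
    totals = gene_totals.loc[bin_counts.index.get_level_values("gene_id")]
    totals.index = bin_counts.index
    with np.errstate(invalid="ignore", divide="ignore"):
        u = bin_counts / totals.replace(0, np.nan)
    return u


def test_deu(bin_counts: pd.DataFrame, gene_totals: pd.DataFrame,
             samples: pd.DataFrame, contrast: str,
             gene_alpha: float = 0.05,
             min_delta_usage: float = 0.1) -> pd.DataFrame:
    """Quasi-binomial score test of relative bin usage for one contrast.

    Per bin, usage pooled within each of the contrast's two conditions is
    compared with a score statistic on the binomial scale; overdispersion is
    estimated per gene from within-condition Pearson residuals and the
    statistic referred to F(1, df).  Bin p-values are combined per gene
    (Sidak on the minimum), BH-adjusted across genes, and a bin is flagged
    significant when its gene passes ``gene_alpha`` and |delta_usage| exceeds
    ``min_delta_usage``.
    """
    if contrast not in CONTRAST_CONDITIONS:
        raise ValueError(f"unknown contrast {contrast!r}")
    cond = condition_of(samples).loc[bin_counts.columns]
    c1, c2 = CONTRAST_CONDITIONS[contrast]
    idx1 = np.flatnonzero((cond == c1).to_numpy())
    idx2 = np.flatnonzero((cond == c2).to_numpy())
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("need >= 2 replicates per condition")

    b = bin_counts.to_numpy(dtype=float)
    totals = gene_totals.loc[
        bin_counts.index.get_level_values("gene_id")].to_numpy(dtype=float)
    if (b > totals + 1e-9).any():
        raise ValueError("bin count exceeds its gene total")

    rows = []
    gene_ids = bin_counts.index.get_level_values("gene_id")
    for gid in gene_ids.unique():
        sel = np.flatnonzero(np.asarray(gene_ids == gid))
        bg = b[sel]
        ng = totals[sel]
        # per-gene overdispersion from within-condition Pearson residuals
        x2 = 0.0
        df_within = 0
        for idx in (idx1, idx2):
            bb, nn = bg[:, idx], ng[:, idx]
            ok = nn > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                phat = np.where(nn.sum(axis=1) > 0,
                                bb.sum(axis=1) / np.maximum(nn.sum(axis=1), 1),
                                np.nan)[:, None]
            var = nn * phat * (1 - phat)
            good = ok & (var > 0)
            x2 += np.nansum(((bb - nn * phat) ** 2 / np.where(good, var, np.nan))[good])
            df_within += int(good.sum()) - int((good.any(axis=1)).sum())
        phi = max(1.0, x2 / df_within) if df_within > 0 else 1.0

        for r, i in enumerate(sel):
            n1, n2 = ng[r, idx1], ng[r, idx2]
            b1, b2 = bg[r, idx1], bg[r, idx2]
            N1, N2 = n1.sum(), n2.sum()
            if N1 == 0 or N2 == 0:
                rows.append((bin_counts.index[i][1], gid, np.nan, np.nan))
                continue
            p1, p2 = b1.sum() / N1, b2.sum() / N2
            pbar = (b1.sum() + b2.sum()) / (N1 + N2)
            delta = p1 - p2
            if pbar <= 0 or pbar >= 1:
                rows.append((bin_counts.index[i][1], gid, delta, 1.0))
                continue
            score = delta ** 2 / (pbar * (1 - pbar) * (1 / N1 + 1 / N2))
            fstat = score / phi
            dfree = max(df_within, 1)
            pval = float(stats.f.sf(fstat, 1, dfree))
            rows.append((bin_counts.index[i][1], gid, delta, pval))

    out = pd.DataFrame(rows, columns=["bin_id", "gene_id", "delta_usage",
                                      "pvalue"])
    # gene-level correction: Sidak-combine the minimum bin p, BH across genes
    def _sidak(g):
        p = g["pvalue"].dropna()
        if p.empty:
            return np.nan
        return 1 - (1 - p.min()) ** len(p)

    gene_p = out.groupby("gene_id").apply(_sidak, include_groups=False)
    valid = gene_p.dropna()
    gene_fdr = pd.Series(np.nan, index=gene_p.index)
    if len(valid):
        gene_fdr.loc[valid.index] = multipletests(valid.to_numpy(),
                                                  method="fdr_bh")[1]
    out["gene_fdr"] = gene_fdr.loc[out["gene_id"]].to_numpy()
    out["significant"] = ((out["gene_fdr"] < gene_alpha)
                          & (out["delta_usage"].abs() > min_delta_usage))
    out["contrast"] = contrast
    return out.set_index("bin_id")


def pair_deu_summary(deu_a: pd.DataFrame, deu_b: pd.DataFrame,
                     matched_bins: list[tuple[str, str]],
                     gene_a: str = "a", gene_b: str = "b") -> PairDeuSummary:
    """Per-pair DEU summary over one contrast.

    overall_deu sums |delta_usage(A) - delta_usage(B)| over matched bins;
    proportion_deu counts significant matched bins over ALL bins of the pair
    (unmatched bins enter the denominator only).  Pairs without matched bins
    are flagged incomparable.
    """
    n_bins = len(deu_a) + len(deu_b)
    if not matched_bins:
        return PairDeuSummary(gene_a, gene_b, float("nan"), float("nan"), 0,
                              comparable=False)
    overall = 0.0
    n_sig = 0
    for ba, bb in matched_bins:
        da = deu_a.loc[ba]
        db = deu_b.loc[bb]
        if np.isfinite(da["delta_usage"]) and np.isfinite(db["delta_usage"]):
            overall += abs(da["delta_usage"] - db["delta_usage"])
        n_sig += int(bool(da["significant"])) + int(bool(db["significant"]))
    return PairDeuSummary(gene_a, gene_b, overall, n_sig / n_bins,
                          len(matched_bins))


# ---------------------------------------------------------------------------
# Splice-junction conservation
# ---------------------------------------------------------------------------

def extract_junction_flanks(events: pd.DataFrame, genome: dict[str, str],
                            flank_bp: int = 300) -> pd.DataFrame:
    """Upstream/downstream flank sequences of each splice event.

    ``events`` columns: event_id, gene_id, scaffold_id, start, end, type with
    [start, end) the 0-based half-open junction span.  Flanks are
    [start-flank_bp, start) and [end, end+flank_bp), truncated at scaffold
    bounds with a flag; events outside their scaffold are skipped with a
    warning.
    """
    rows = []
    for ev in events.itertuples(index=False):
        seq = genome.get(ev.scaffold_id)
        if seq is None or ev.start < 0 or ev.end > len(seq) or ev.end < ev.start:
            logger.warning("event %s outside scaffold %s - skipped",
                           ev.event_id, ev.scaffold_id)
            continue
        up_lo = max(0, ev.start - flank_bp)
        down_hi = min(len(seq), ev.end + flank_bp)
        truncated = (up_lo > ev.start - flank_bp) or (down_hi < ev.end + flank_bp)
        rows.append((ev.event_id, ev.gene_id, ev.type,
                     seq[up_lo:ev.start], seq[ev.end:down_hi],
                     up_lo, ev.start, ev.end, down_hi, truncated))
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "type", "upstream_seq", "downstream_seq",
        "up_start", "up_end", "down_start", "down_end", "truncated"])


def match_junctions(flanks_a: pd.DataFrame, flanks_b: pd.DataFrame,
                    max_evalue: float = 1e-5) -> dict[str, str]:
    """One-to-one map of conserved junctions between two gene copies.

    A junction in copy A is conserved with one in copy B iff BOTH its
    upstream and downstream flanks align significantly (E <= max_evalue) to
    the counterpart's; candidates are resolved one-to-one by best combined
    alignment score.
    """
    ids_a = flanks_a["event_id"].tolist()
    ids_b = flanks_b["event_id"].tolist()
    if not ids_a or not ids_b:
        return {}
    score = np.zeros((len(ids_a), len(ids_b)))
    passes = np.zeros_like(score, dtype=bool)
    for i, ea in enumerate(flanks_a.itertuples(index=False)):
        for j, eb in enumerate(flanks_b.itertuples(index=False)):
            ok_u, s_u, _ = local_nt_match(ea.upstream_seq, eb.upstream_seq,
                                          0.0, max_evalue)
            if not ok_u:
                continue
            ok_d, s_d, _ = local_nt_match(ea.downstream_seq, eb.downstream_seq,
                                          0.0, max_evalue)
            if ok_d:
                passes[i, j] = True
                score[i, j] = s_u + s_d
    big = score.max() * max(len(ids_a), len(ids_b)) + 1.0
    benefit = np.where(passes, big + score, 0.0)
    rows, cols = linear_sum_assignment(-benefit)
    return {ids_a[i]: ids_b[j] for i, j in zip(rows, cols) if passes[i, j]}


def build_junction_profiles(events_a: pd.DataFrame, events_b: pd.DataFrame,
                            matches: dict[str, str],
                            gene_a: str = "a", gene_b: str = "b",
                            ) -> JunctionProfilePair:
    """Binary presence/absence profiles over the union of junction identities.

    Matched junctions collapse to one shared identity (1 in both profiles);
    unmatched junctions are 1 in their own copy only.
    """
    ids, pa, pb = [], [], []
    matched_b = set(matches.values())
    for ea in events_a["event_id"]:
        if ea in matches:
            ids.append(f"{ea}|{matches[ea]}")
            pa.append(1)
            pb.append(1)
        else:
            ids.append(ea)
            pa.append(1)
            pb.append(0)
    for eb in events_b["event_id"]:
        if eb not in matched_b:
            ids.append(eb)
            pa.append(0)
            pb.append(1)
    return JunctionProfilePair(gene_a=gene_a, gene_b=gene_b, junction_ids=ids,
                               profile_a=np.array(pa, dtype=int),
                               profile_b=np.array(pb, dtype=int))


def junction_conservation_stats(pair: JunctionProfilePair) -> dict:
    """Kendall tau-b and exact binomial divergence test on a profile pair.

    tau-b (tie-corrected) is undefined (NaN, flagged) for constant profiles.
    The binomial test takes k = junctions present only in copy A, n =
    junctions present in exactly one copy, null proportion 0.5, two-sided.
    """
    a, b = pair.profile_a, pair.profile_b
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("profiles must have equal length >= 2")
    if len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        tau, tau_p, constant = float("nan"), float("nan"), True
    else:
        res = stats.kendalltau(a, b)
        tau, tau_p, constant = float(res.statistic), float(res.pvalue), False
    only_a = int(((a == 1) & (b == 0)).sum())
    only_b = int(((a == 0) & (b == 1)).sum())
    n = only_a + only_b
    binom_p = float(stats.binomtest(only_a, n, 0.5).pvalue) if n > 0 else 1.0
    return {"kendall_tau": tau, "kendall_p": tau_p, "tau_undefined": constant,
            "binom_k": only_a, "binom_n": n, "binom_p": binom_p,
            "conserved_fraction": pair.conserved_fraction}
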