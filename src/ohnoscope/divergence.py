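"""Pairwise Ka/Ks estimation and WGD-peak detection in the Ks distribution.

Synonymous/nonsynonymous rates are estimated with the Nei-Gojobori (1986)
counting method: degeneracy-based site counts averaged over both sequences,
differences averaged over all minimal mutation paths, and a Jukes-Cantor
multiple-hit correction.  A burst of duplication such as WGD shows up as a
peak in the distribution of Ks over duplicate pairs; the peak is located by
fitting one-dimensional Gaussian mixtures and selecting the component count
by AIC.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy.cluster.hierarchy import linkage
from scipy.optimize import brentq
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

CODON_TABLE = standard_dna_table.forward_table
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, None for stop."""
    return CODON_TABLE.get(codon)


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    S: float            # synonymous sites
    N: float            # nonsynonymous sites
    Sd: float           # synonymous differences
    Nd: float           # nonsynonymous differences
    Ks: float | None
    Ka: float | None
    omega: float | None
    saturated: bool = False
    n_codons: int = 0


@dataclass
class GmmFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    aic_by_k: dict[int, float]
    n_points: int


@dataclass
class ExonConservation:
    gene_a: str
    gene_b: str
    n_exons_a: int
    n_exons_b: int
    n_matched: int
    shared_pct: float
    gain_loss: int


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair_codons(cds_a: str, cds_b: str,
                      protein_a: str | None = None,
                      protein_b: str | None = None,
                      gene_a: str = "a", gene_b: str = "b",
                      ) -> list[tuple[str, str]]:
    """Codon alignment of two CDS via a global protein alignment.

    Trailing partial codons are trimmed with a warning; an internal stop codon
    is a hard error naming the gene.  Returns the list of aligned codon pairs
    with gap codons ('---') where one protein has a gap; gap columns are
    excluded from site counting downstream.
    """
    seqs = {}
    for name, cds in ((gene_a, cds_a), (gene_b, cds_b)):
        cds = cds.upper()
        if len(cds) % 3:
            logger.warning("%s: trimming %d trailing nt (partial codon)",
                           name, len(cds) % 3)
            cds = cds[: len(cds) - len(cds) % 3]
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for i, c in enumerate(codons):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon in {name} at codon {i}")
        seqs[name] = codons
    codons_a, codons_b = seqs[gene_a], seqs[gene_b]
    prot_a = protein_a or str(Seq("".join(codons_a)).translate())
    prot_b = protein_b or str(Seq("".join(codons_b)).translate())

    aln = _protein_aligner().align(prot_a, prot_b)[0]
    out: list[tuple[str, str]] = []
    ia = ib = 0
    for col_a, col_b in zip(*aln):
        ca = codons_a[ia] if col_a != "-" else "---"
        cb = codons_b[ib] if col_b != "-" else "---"
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        out.append((ca, cb))
    return out


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes creating a stop codon count as nonsynonymous.
    """
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} in site counting")
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _translate(alt) == aa:
                syn += 1 / 3
    return syn, 3 - syn


@functools.lru_cache(maxsize=None)
def _path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal mutation paths.

    Paths passing through stop codons are excluded; if every path hits a stop,
    all paths are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if _translate(nxt) is None:
                hit_stop = True
            if _translate(cur) is not None and _translate(nxt) is not None \
                    and _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, hit_stop))
    usable = [(s, n) for s, n, h in paths if not h]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(alignment: list[tuple[str, str]], gene_a: str = "a",
         gene_b: str = "b", min_codons: int = 10) -> KsEstimate:
    """Nei-Gojobori Ka/Ks over an aligned codon pair list.

    Site counts are averaged over the two sequences; proportions of
    differences are Jukes-Cantor corrected.  ``omega`` is None (not 0, not
    inf) when Ks is 0 or unavailable; the estimate is flagged ``saturated``
    when either corrected proportion is out of the correction's domain.
    """
    codons = [(a, b) for a, b in alignment if "-" not in a and "-" not in b
              and "N" not in a and "N" not in b]
    if len(codons) < min_codons:
        raise ValueError(
            f"{gene_a}/{gene_b}: {len(codons)} ungapped codons < {min_codons}")
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(ps)
    Ka = _jc_correct(pn)
    saturated = Ks is None or Ka is None
    omega = None
    if not saturated and Ks and Ks > 0:
        omega = Ka / Ks
    return KsEstimate(gene_a=gene_a, gene_b=gene_b, S=S, N=N, Sd=Sd, Nd=Nd,
                      Ks=Ks, Ka=Ka, omega=omega, saturated=saturated,
                      n_codons=len(codons))


# ---------------------------------------------------------------------------
# Node-averaged Ks distribution
# ---------------------------------------------------------------------------

def node_average_ks(clusters: list[dict[tuple[str, str], float]]) -> np.ndarray:
    """De-redundantized Ks values, one per duplication node.

    Each cluster of homologous genes carries pairwise Ks values; pairs are
    consolidated by average-linkage hierarchical clustering on Ks distance and
    every internal node contributes one value, the mean Ks of the pairs it
    joins (the average-linkage merge height).  A redundant set of n*(n-1)/2
    pairwise values thus collapses to n-1 per cluster.
    """
    values: list[float] = []
    for pair_ks in clusters:
        genes = sorted({g for pair in pair_ks for g in pair})
        if len(genes) < 2:
            continue
        if len(genes) == 2:
            values.extend(pair_ks.values())
            continue
        idx = {g: i for i, g in enumerate(genes)}
        mat = np.full((len(genes), len(genes)), np.nan)
        for (a, b), ks in pair_ks.items():
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = ks
        np.fill_diagonal(mat, 0.0)
        if np.isnan(mat).any():
            # incomplete matrix (saturated pairs dropped): keep complete subset
            ok = ~np.isnan(mat).any(axis=1)
            mat = mat[np.ix_(ok, ok)]
            if mat.shape[0] < 2:
                continue
        Z = linkage(squareform(mat, checks=False), method="average")
        values.extend(Z[:, 2].tolist())
    return np.asarray(values, dtype=float)


def fit_ks_gmm(ks_values, k_max: int = 4, ks_min: float = 0.001,
               ks_max_cut: float = 3.0, seed: int = 0,
               min_points: int = 50) -> GmmFit:
    """Gaussian-mixture fit to the Ks distribution with AIC model selection.

    Values outside [ks_min, ks_max_cut] are discarded; mixtures with
    k = 1..k_max components are fitted by EM (k-means init, 10 restarts,
    fixed seed) and the smallest-AIC k is returned
    (AIC = 2*(3k-1) - 2*logL for a 1-D mixture).
    """
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x)]
    x = x[(x >= ks_min) & (x <= ks_max_cut)]
    if x.size < min_points:
        raise ValueError(
            f"only {x.size} Ks values in [{ks_min}, {ks_max_cut}]; "
            f"need >= {min_points} - provide more pairs")
    X = x[:, None]
    aic_by_k: dict[int, float] = {}
    fits = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=10, init_params="kmeans",
                             random_state=seed)
        gm.fit(X)
        aic_by_k[k] = float(gm.aic(X))
        fits[k] = gm
    best_k = min(aic_by_k, key=lambda k: (aic_by_k[k], k))
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    return GmmFit(k=best_k,
                  weights=gm.weights_[order],
                  means=gm.means_.ravel()[order],
                  sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
                  aic_by_k=aic_by_k, n_points=int(x.size))


# ---------------------------------------------------------------------------
# Exon-level conservation
# ---------------------------------------------------------------------------

def _nucleotide_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Karlin-Altschul lambda for an ungapped +match/mismatch scheme at
    uniform base composition."""
    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1
    return brentq(f, 1e-6, 10)


_LAMBDA_NT = _nucleotide_lambda()
_KA_K = 0.1  # conservative Karlin-Altschul K for the +1/-2 scheme


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    return aligner


def local_nt_match(seq_a: str, seq_b: str, min_cov_pct: float,
                   max_evalue: float) -> tuple[bool, float, float]:
    """Local alignment of two nucleotide sequences against coverage and
    significance thresholds.

    Returns (passes, score, evalue); significance from the Karlin-Altschul
    formula E = K*m*n*exp(-lambda*S). Coverage is the aligned span over the
    full length, per side, with the thresholds combined as OR.
    """
    if not seq_a or not seq_b:
        return False, 0.0, math.inf
    aln = _local_aligner().align(seq_a.upper(), seq_b.upper())
    if len(aln) == 0:
        return False, 0.0, math.inf
    best = aln[0]
    score = float(best.score)
    evalue = _KA_K * len(seq_a) * len(seq_b) * math.exp(-_LAMBDA_NT * score)
    span_a = best.aligned[0][-1][1] - best.aligned[0][0][0] if len(best.aligned[0]) else 0
    span_b = best.aligned[1][-1][1] - best.aligned[1][0][0] if len(best.aligned[1]) else 0
    cov_a = 100.0 * span_a / len(seq_a)
    cov_b = 100.0 * span_b / len(seq_b)
    passes = (cov_a > min_cov_pct or cov_b > min_cov_pct) and evalue <= max_evalue
    return passes, score, evalue


def exon_conservation(gene_a: str, gene_b: str,
                      exon_seqs_a: list[str], exon_seqs_b: list[str],
                      min_cov_pct: float = 50.0,
                      max_evalue: float = 1e-20) -> ExonConservation | None:
    """Count exons shared between two gene copies.

    Every exon of copy A is locally aligned to every exon of copy B; pairs
    passing the coverage/significance thresholds enter a maximum one-to-one
    matching (highest total score).  shared_pct = 100 * 2*matched / (nA + nB).
    """
    if not exon_seqs_a or not exon_seqs_b:
        logger.warning("pair %s/%s: missing exon sequences - skipped",
                       gene_a, gene_b)
        return None
    na, nb = len(exon_seqs_a), len(exon_seqs_b)
    scores = np.zeros((na, nb))
    passes = np.zeros((na, nb), dtype=bool)
    for i, ea in enumerate(exon_seqs_a):
        for j, eb in enumerate(exon_seqs_b):
            ok, score, _ = local_nt_match(ea, eb, min_cov_pct, max_evalue)
            passes[i, j] = ok
            scores[i, j] = score if ok else 0.0
    # maximize matched count first, then total score
    big = scores.max() * max(na, nb) + 1.0
    benefit = np.where(passes, big + scores, 0.0)
    rows, cols = linear_sum_assignment(-benefit)
    n_matched = int(passes[rows, cols].sum())
    shared_pct = 100.0 * 2 * n_matched / (na + nb)
    return ExonConservation(gene_a=gene_a, gene_b=gene_b, n_exons_a=na,
                            n_exons_b=nb, n_matched=n_matched,
                            shared_pct=shared_pct,
                            gain_loss=(na - n_matched) + (nb - n_matched))
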