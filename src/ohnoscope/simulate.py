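"""Synthetic post-WGD genome and lifestyle x temperature expression data.

The generator emulates a haploid genome that recently duplicated wholesale:
every scaffold is copied, duplicated gene copies survive with a retention
probability (losses are deleted outright, compacting gene ranks), and
surviving WGD pairs are mutated so their synonymous divergence concentrates
in a narrow low-Ks peak.  Small-scale duplications (tandem, proximal,
dispersed) are planted at low per-gene rates with much older divergence, so
the Ks distribution carries a WGD peak over a diffuse background.

The expression generator emulates the paired-design RNA-seq experiment of a
facultative symbiont: free-living vs symbiotic lifestyle crossed with 28 vs
34 degrees C, with negative-binomial counts.  Duplicate-pair DE behaviour is
planted per group (1: no DE; 2: one copy; 3: both, same contrast and
direction; 4: both, disjoint contrasts; 5: both, same contrast, opposite
directions), along with condition-specific (tau ~ 1) genes, exon-usage
shifts, and junction presence sampled at a configurable conservation
probability.  All ground truth is returned in a TruthTable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import CODON_TABLE, STOP_CODONS, _codon_sites
from .io import GeneCatalog, GeneModel, HomologyHitSet, HIT_COLUMNS

BASES = "ACGT"
SENSE_CODONS = sorted(CODON_TABLE)

#: condition cells of the 2x2 design
CELLS = ("free:28", "free:34", "symbiotic:28", "symbiotic:34")


@dataclass
class GenomeSimParams:
    n_ancestral_genes: int = 300
    n_scaffolds: int = 4
    wgd_retention: float = 0.85
    tandem_rate: float = 0.02
    proximal_rate: float = 0.02
    dispersed_rate: float = 0.02
    ks_peak_mean: float = 0.3
    ks_peak_sd: float = 0.05
    background_ks_mean: float = 1.5
    codons_per_gene: int = 420
    exons_per_gene: tuple[int, int] = (3, 4)
    min_exon_bp: int = 310
    intron_bp: int = 120
    spacer_bp: int = 150
    seed: int = 0

    def validate(self) -> None:
        for name in ("wgd_retention", "tandem_rate", "proximal_rate",
                     "dispersed_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.ks_peak_mean <= 0 or self.ks_peak_sd <= 0 \
                or self.background_ks_mean <= 0:
            raise ValueError("ks parameters must be > 0")


@dataclass
class ExprSimParams:
    group_fractions: dict[int, float] = field(default_factory=lambda: {
        1: 0.35, 2: 0.35, 3: 0.12, 4: 0.12, 5: 0.06})
    de_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    mean_library_factor: float = 1.0
    library_sd: float = 0.15
    n_replicates: int = 3
    base_mean: float = 100.0
    tau_specific_fraction: float = 0.1
    deu_fraction: float = 0.3
    deu_shift: float = 0.5
    junction_conservation_p: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_fractions sum to {total}, expected 1")
        if set(self.group_fractions) - {1, 2, 3, 4, 5}:
            raise ValueError("group_fractions keys must be 1..5")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass
class TruthTable:
    """Planted ground truth, grown as the generators run."""
    gene_classes: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    pair_groups: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    tau_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    junction_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    deu_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def wgd_pairs(self) -> pd.DataFrame:
        if self.pairs.empty:
            return self.pairs
        return self.pairs[self.pairs["kind"] == "wgd"]


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _jc_p(k: float) -> float:
    """Expected proportion of differing sites at divergence k (Jukes-Cantor)."""
    return 0.75 * (1 - np.exp(-4 * k / 3))


def mutate_cds(cds: str, ks_target: float, rng: np.random.Generator,
               omega: float = 0.2) -> str:
    """Mutate a CDS toward a target synonymous divergence.

    Synonymous and nonsynonymous substitutions are planted at distinct codon
    positions so that the counting-method estimate concentrates near the
    target: the number of synonymous changes is the Jukes-Cantor expected
    proportion at ``ks_target`` times the synonymous site count, and
    nonsynonymous changes follow Ka = omega * Ks.  Stops are never created.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    sites = np.array([_codon_sites(c) for c in codons])
    S, N = sites[:, 0].sum(), sites[:, 1].sum()
    n_syn = min(len(codons), rng.poisson(_jc_p(ks_target) * S))
    n_non = min(len(codons), rng.poisson(_jc_p(omega * ks_target) * N))

    order = rng.permutation(len(codons))
    taken = 0
    for want_syn, n_want in ((True, n_syn), (False, n_non)):
        done = 0
        while done < n_want and taken < len(order):
            ci = order[taken]
            taken += 1
            cod = codons[ci]
            aa = CODON_TABLE[cod]
            options = []
            for pos in range(3):
                for b in BASES:
                    if b == cod[pos]:
                        continue
                    alt = cod[:pos] + b + cod[pos + 1:]
                    if alt in STOP_CODONS:
                        continue
                    if (CODON_TABLE[alt] == aa) == want_syn:
                        options.append(alt)
            if options:
                codons[ci] = options[rng.integers(0, len(options))]
                done += 1
    return "".join(codons)


def mutate_nt(seq: str, k: float, rng: np.random.Generator) -> str:
    """Neutral substitution of non-coding sequence at divergence ``k``."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < _jc_p(k)
    if hit.any():
        repl = rng.integers(0, 4, size=int(hit.sum()))
        alphabet = np.frombuffer(b"ACGT", dtype="S1")
        arr[hit] = alphabet[repl]
    return arr.tobytes().decode()


def _split_exons(total_nt: int, k: int, rng: np.random.Generator,
                 min_exon: int = 60) -> list[int]:
    """Partition ``total_nt`` into ``k`` exon lengths, each >= min_exon."""
    k = max(1, min(k, total_nt // min_exon))
    extra = total_nt - k * min_exon
    if k == 1:
        return [total_nt]
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1))
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [int(min_exon + p) for p in parts]


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

class _GeneDraft:
    """Mutable gene record while the simulated scaffolds are laid out."""

    __slots__ = ("gene_id", "cds", "exon_lengths", "introns")

    def __init__(self, gene_id, cds, exon_lengths, introns):
        self.gene_id = gene_id
        self.cds = cds
        self.exon_lengths = exon_lengths
        self.introns = introns


def _copy_gene(src: _GeneDraft, new_id: str, ks: float,
               rng: np.random.Generator) -> _GeneDraft:
    return _GeneDraft(new_id, mutate_cds(src.cds, ks, rng),
                      list(src.exon_lengths),
                      [mutate_nt(i, ks, rng) for i in src.introns])


def simulate_wgd_genome(params: GenomeSimParams
                        ) -> tuple[GeneCatalog, HomologyHitSet, TruthTable,
                                   dict[str, str]]:
    """Simulate a haploid genome after a recent WGD.

    Returns (catalog, filtered hit set, truth, scaffold sequences).  Each
    ancestral scaffold is duplicated wholesale; duplicated copies survive
    with probability ``wgd_retention`` and are deleted otherwise (rank
    compaction, no pseudogene remnants).  Surviving WGD pairs diverge to
    Ks ~ N(ks_peak_mean, ks_peak_sd); small-scale duplicates diverge at
    ``background_ks_mean``.  The hit table carries reciprocal hits within
    every homology family, with synthetic scores passing the standard
    coverage/evalue filter.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    per_scaffold = np.full(params.n_scaffolds,
                           params.n_ancestral_genes // params.n_scaffolds)
    per_scaffold[: params.n_ancestral_genes % params.n_scaffolds] += 1

    gene_no = 0
    scaffolds: dict[str, list[_GeneDraft]] = {}
    families: list[list[str]] = []          # homologous gene ids
    pair_rows: list[dict] = []
    class_truth: dict[str, str] = {}

    ancestral: list[tuple[str, _GeneDraft]] = []
    for si in range(params.n_scaffolds):
        scaf = f"scf{si:03d}"
        scaffolds[scaf] = []
        for _ in range(per_scaffold[si]):
            gid = f"g{gene_no:05d}"
            gene_no += 1
            n_cod = params.codons_per_gene
            cds = _random_cds(n_cod, rng)
            k_ex = int(rng.integers(params.exons_per_gene[0],
                                    params.exons_per_gene[1] + 1))
            lengths = _split_exons(3 * n_cod, k_ex, rng,
                                   min_exon=params.min_exon_bp)
            introns = [_random_nt(params.intron_bp, rng)
                       for _ in range(len(lengths) - 1)]
            draft = _GeneDraft(gid, cds, lengths, introns)
            scaffolds[scaf].append(draft)
            ancestral.append((scaf, draft))
            class_truth[gid] = "singleton"
            families.append([gid])
    fam_of = {d.gene_id: i for i, (s, d) in enumerate(ancestral)}

    # WGD: duplicate every scaffold; copies survive with wgd_retention
    for si in range(params.n_scaffolds):
        scaf = f"scf{si:03d}"
        dup = f"{scaf}_wgd"
        scaffolds[dup] = []
        for draft in list(scaffolds[scaf]):
            if rng.random() >= params.wgd_retention:
                continue
            ks = float(np.clip(rng.normal(params.ks_peak_mean,
                                          params.ks_peak_sd), 0.02, None))
            copy = _copy_gene(draft, draft.gene_id + "_w", ks, rng)
            scaffolds[dup].append(copy)
            families[fam_of[draft.gene_id]].append(copy.gene_id)
            class_truth[draft.gene_id] = "wgd_segmental"
            class_truth[copy.gene_id] = "wgd_segmental"
            pair_rows.append({"gene_a": draft.gene_id, "gene_b": copy.gene_id,
                              "kind": "wgd", "ks_true": ks})

    # small-scale duplications on the ancestral scaffolds
    small = (("tandem", params.tandem_rate), ("proximal", params.proximal_rate),
             ("dispersed", params.dispersed_rate))
    scaffold_names = [f"scf{si:03d}" for si in range(params.n_scaffolds)]
    for scaf, draft in ancestral:
        for kind, rate in small:
            if rng.random() >= rate:
                continue
            ks = float(np.clip(rng.normal(params.background_ks_mean,
                                          0.2 * params.background_ks_mean),
                               0.2, None))
            suffix = {"tandem": "_t", "proximal": "_p", "dispersed": "_d"}[kind]
            copy = _copy_gene(draft, draft.gene_id + suffix, ks, rng)
            src_list = scaffolds[scaf]
            pos = next(i for i, d in enumerate(src_list)
                       if d.gene_id == draft.gene_id)
            if kind == "tandem":
                src_list.insert(pos + 1, copy)
            elif kind == "proximal":
                offset = int(rng.integers(2, 15))
                src_list.insert(min(pos + offset, len(src_list)), copy)
            else:
                others = [s for s in scaffold_names if s != scaf]
                target = others[rng.integers(0, len(others))]
                scaffolds[target].insert(
                    int(rng.integers(0, len(scaffolds[target]) + 1)), copy)
            families[fam_of[draft.gene_id]].append(copy.gene_id)
            if class_truth[draft.gene_id] == "singleton":
                class_truth[draft.gene_id] = kind
            class_truth[copy.gene_id] = kind
            pair_rows.append({"gene_a": draft.gene_id, "gene_b": copy.gene_id,
                              "kind": kind, "ks_true": ks})

    # lay out scaffold sequences and gene models
    genes: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for scaf, drafts in scaffolds.items():
        parts: list[str] = []
        pos = 0          # 0-based running offset
        for draft in drafts:
            spacer = _random_nt(params.spacer_bp, rng)
            parts.append(spacer)
            pos += len(spacer)
            exon_seqs = []
            off = 0
            for ln in draft.exon_lengths:
                exon_seqs.append(draft.cds[off:off + ln])
                off += ln
            exons = []
            start_1 = pos + 1
            for i, es in enumerate(exon_seqs):
                exons.append((pos + 1, pos + len(es)))
                parts.append(es)
                pos += len(es)
                if i < len(draft.introns):
                    parts.append(draft.introns[i])
                    pos += len(draft.introns[i])
            genes.append(GeneModel(gene_id=draft.gene_id, scaffold_id=scaf,
                                   start=start_1, end=pos, strand="+",
                                   exons=exons))
            cds_map[draft.gene_id] = draft.cds
        seqs[scaf] = "".join(parts)

    proteins = {}
    from Bio.Seq import Seq
    for gid, cds in cds_map.items():
        proteins[gid] = str(Seq(cds).translate())
    catalog = GeneCatalog("sim", genes, cds=cds_map, proteins=proteins)

    hits = _family_hits(families, cds_map, rng)
    truth = TruthTable(
        gene_classes=pd.DataFrame(
            sorted(class_truth.items()), columns=["gene_id", "category"]),
        pairs=pd.DataFrame(pair_rows,
                           columns=["gene_a", "gene_b", "kind", "ks_true"]),
    )
    return catalog, hits, truth, seqs


def _family_hits(families: list[list[str]], cds_map: dict[str, str],
                 rng: np.random.Generator) -> HomologyHitSet:
    """Reciprocal all-vs-all hits within each homology family; scores are
    synthetic but pass the top-5/coverage/evalue filter."""
    rows = []
    for fam in families:
        for i, a in enumerate(fam):
            for b in fam[i + 1:]:
                ln = min(len(cds_map[a]), len(cds_map[b])) // 3
                ident = float(np.round(70 + 25 * rng.random(), 1))
                bits = float(np.round(2.0 * ln * (0.5 + 0.5 * rng.random()), 1))
                for q, s in ((a, b), (b, a)):
                    rows.append((q, s, ident, ln, 0, 0, 1, ln, 1, ln,
                                 1e-100, bits, 95.0, 95.0))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HomologyHitSet(df, filtered=True)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def make_sample_sheet(n_replicates: int) -> pd.DataFrame:
    rows = []
    for cell in CELLS:
        lifestyle, temp = cell.split(":")
        for r in range(1, n_replicates + 1):
            rows.append({"sample": f"{lifestyle[:2]}{temp}_r{r}",
                         "lifestyle": lifestyle, "temperature": int(temp),
                         "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def _plant_group_shifts(group: int, lfc: float, rng: np.random.Generator
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-cell log2 shifts for the two copies implementing a DE group.

    A shift in one condition cell induces DE in the two contrasts involving
    that cell.  Group 4 uses the two diagonal cell pairs, whose induced
    contrast sets are disjoint.
    """
    sign = 1.0 if rng.random() < 0.5 else -1.0
    cell = CELLS[rng.integers(0, len(CELLS))]
    a: dict[str, float] = {}
    b: dict[str, float] = {}
    if group == 1:
        pass
    elif group == 2:
        (a if rng.random() < 0.5 else b)[cell] = sign * lfc
    elif group == 3:
        a[cell] = sign * lfc
        b[cell] = sign * lfc
    elif group == 4:
        diag = (("free:28", "symbiotic:34"), ("free:34", "symbiotic:28"))
        ca, cb = diag[rng.integers(0, 2)]
        a[ca] = sign * lfc
        b[cb] = (1.0 if rng.random() < 0.5 else -1.0) * lfc
    elif group == 5:
        a[cell] = sign * lfc
        b[cell] = -sign * lfc
    else:
        raise ValueError(f"unknown group {group}")
    return a, b


def simulate_expression(catalog: GeneCatalog, truth: TruthTable,
                        params: ExprSimParams):
    """Simulate the lifestyle x temperature experiment over a simulated genome.

    Returns (counts, samples, bin_counts, junction_events, truth) where
    ``counts`` is genes x samples, ``bin_counts`` is (gene_id, bin_id) x
    samples for the duplicate-pair genes, and ``junction_events`` is a table
    of splice events with planted conservation.  ``truth`` is updated in
    place with pair groups, planted cell means, tau classes, DEU shifts and
    junction sharing.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    samples = make_sample_sheet(params.n_replicates)
    sample_cells = (samples["lifestyle"] + ":"
                    + samples["temperature"].astype(str)).to_numpy()
    gene_ids = sorted(catalog.genes)

    wgd_pairs = truth.wgd_pairs
    if len(wgd_pairs) == 0 and any(v > 0 for g, v in
                                   params.group_fractions.items() if g != 1):
        raise ValueError("no duplicate pairs to plant group behaviour on")
    pair_gene_ids = set(wgd_pairs["gene_a"]) | set(wgd_pairs["gene_b"])

    # group assignment per pair
    groups = sorted(params.group_fractions)
    probs = np.array([params.group_fractions[g] for g in groups])
    assigned = rng.choice(groups, size=len(wgd_pairs), p=probs)

    # planted per-cell log2 mean shifts
    base = rng.lognormal(np.log(params.base_mean), 0.4, size=len(gene_ids))
    base_of = dict(zip(gene_ids, base))
    shifts: dict[str, dict[str, float]] = {g: {} for g in gene_ids}
    group_rows = []
    for (row, grp) in zip(wgd_pairs.itertuples(index=False), assigned):
        sa, sb = _plant_group_shifts(int(grp), params.de_log2fc, rng)
        shifts[row.gene_a] = sa
        shifts[row.gene_b] = sb
        group_rows.append({"gene_a": row.gene_a, "gene_b": row.gene_b,
                           "group": int(grp)})
    truth.pair_groups = pd.DataFrame(
        group_rows, columns=["gene_a", "gene_b", "group"])

    # tau-specific background genes: expressed in exactly one condition
    background = [g for g in gene_ids if g not in pair_gene_ids]
    n_tau = int(round(params.tau_specific_fraction * len(background)))
    tau_genes = list(rng.choice(background, size=n_tau, replace=False)) \
        if n_tau else []
    tau_rows = []
    for g in tau_genes:
        cell = CELLS[rng.integers(0, len(CELLS))]
        for c in CELLS:
            shifts[g][c] = 0.0 if c == cell else -12.0
        tau_rows.append({"gene_id": g, "specific_cell": cell})
    truth.tau_truth = pd.DataFrame(tau_rows, columns=["gene_id", "specific_cell"])

    # per-gene per-cell means and NB counts
    mean_rows = []
    lib = params.mean_library_factor * rng.lognormal(
        0.0, params.library_sd, size=len(samples))
    mu = np.empty((len(gene_ids), len(samples)))
    for gi, g in enumerate(gene_ids):
        cell_mean = {c: base_of[g] * 2.0 ** shifts[g].get(c, 0.0) for c in CELLS}
        mean_rows.append({"gene_id": g, **cell_mean})
        mu[gi] = [cell_mean[c] for c in sample_cells]
    mu = mu * lib[None, :]
    truth.planted_means = pd.DataFrame(mean_rows).set_index("gene_id")

    r = 1.0 / params.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-8)))
    counts = pd.DataFrame(counts, index=gene_ids, columns=samples.index)

    bin_counts, deu_truth = _simulate_bins(catalog, truth, counts, params, rng)
    truth.deu_truth = deu_truth
    junctions, junction_truth = _simulate_junctions(catalog, truth, params, rng)
    truth.junction_truth = junction_truth
    return counts, samples, bin_counts, junctions, truth


def _simulate_bins(catalog, truth, counts, params, rng):
    """Multinomial exon-bin counts; a fraction of pairs gets a usage shift in
    copy A (two bins trade ``deu_shift`` of relative usage in the
    symbiotic:34 cell)."""
    wgd_pairs = truth.wgd_pairs
    pair_genes: list[str] = sorted(
        set(wgd_pairs["gene_a"]) | set(wgd_pairs["gene_b"]))
    shifted_pairs = {
        (r.gene_a, r.gene_b): bool(rng.random() < params.deu_fraction)
        for r in wgd_pairs.itertuples(index=False)}
    shifted_genes = {a for (a, b), s in shifted_pairs.items() if s}

    samples = counts.columns
    sample_is_target = np.array(
        [s.startswith("sy34") for s in samples])
    rows_idx = []
    data = []
    deu_rows = []
    for g in pair_genes:
        exons = catalog[g].exons
        k = len(exons)
        if k < 2:
            continue
        lengths = np.array([e - s + 1 for s, e in exons], dtype=float)
        usage = lengths / lengths.sum()
        shifted_usage = usage.copy()
        if g in shifted_genes and k >= 2:
            i, j = np.argsort(usage)[-2:]
            delta = min(params.deu_shift, shifted_usage[j] * 0.9)
            shifted_usage[j] -= delta
            shifted_usage[i] += delta
        deu_rows.append({"gene_id": g, "shifted": g in shifted_genes})
        gene_tot = counts.loc[g].to_numpy()
        mat = np.zeros((k, len(samples)), dtype=np.int64)
        for sj in range(len(samples)):
            p = shifted_usage if (g in shifted_genes and sample_is_target[sj]) \
                else usage
            mat[:, sj] = rng.multinomial(int(gene_tot[sj]), p)
        for bi in range(k):
            rows_idx.append((g, f"{g}:bin{bi:03d}"))
            data.append(mat[bi])
    if not data:
        empty = pd.DataFrame(
            columns=samples,
            index=pd.MultiIndex.from_tuples([], names=["gene_id", "bin_id"]))
        return empty, pd.DataFrame(deu_rows, columns=["gene_id", "shifted"])
    bin_counts = pd.DataFrame(
        np.vstack(data),
        index=pd.MultiIndex.from_tuples(rows_idx, names=["gene_id", "bin_id"]),
        columns=samples)
    return bin_counts, pd.DataFrame(deu_rows, columns=["gene_id", "shifted"])


def _simulate_junctions(catalog, truth, params, rng):
    """Splice-junction events at intron positions of each duplicate pair.

    Each ancestral intron yields a junction shared by both copies with
    probability ``junction_conservation_p``, otherwise present in exactly one
    (random) copy.  Event spans are the intron intervals, so 300-bp flank
    extraction from the simulated scaffolds sees homologous sequence for
    conserved junctions.
    """
    types = ("alternative_acceptor", "alternative_donor", "alternative_exon",
             "retained_exon", "skipped_exon")
    ev_rows = []
    truth_rows = []
    for row in truth.wgd_pairs.itertuples(index=False):
        ga, gb = catalog[row.gene_a], catalog[row.gene_b]
        n_introns = min(len(ga.exons), len(gb.exons)) - 1
        for k in range(n_introns):
            conserved = bool(rng.random() < params.junction_conservation_p)
            in_a = in_b = True
            if not conserved:
                if rng.random() < 0.5:
                    in_b = False
                else:
                    in_a = False
            jtype = types[rng.integers(0, len(types))]
            for present, gene in ((in_a, ga), (in_b, gb)):
                if not present:
                    continue
                start = gene.exons[k][1]          # 0-based intron start
                end = gene.exons[k + 1][0] - 1    # 0-based half-open end
                ev_rows.append({
                    "event_id": f"{gene.gene_id}:j{k}",
                    "gene_id": gene.gene_id,
                    "scaffold_id": gene.scaffold_id,
                    "start": start, "end": end, "type": jtype})
            truth_rows.append({"gene_a": row.gene_a, "gene_b": row.gene_b,
                               "intron": k, "conserved": conserved,
                               "in_a": in_a, "in_b": in_b})
    events = pd.DataFrame(ev_rows, columns=["event_id", "gene_id",
                                            "scaffold_id", "start", "end",
                                            "type"])
    jtruth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "intron",
                                               "conserved", "in_a", "in_b"])
    return events, jtruth
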