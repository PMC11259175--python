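"""Collinear gene-block detection and duplicate-gene classification.

Blocks are chains of homologous gene pairs (anchors) whose gene ranks are
strictly monotone on both scaffolds — increasing on both for same-orientation
blocks, increasing/decreasing for inverted blocks — with a bounded rank gap
between consecutive anchors.  A block needs at least five anchors, the
classical minimum for calling segmental duplication / WGD rather than chance
collinearity.  Every gene then receives exactly one duplication category:
WGD/segmental (block anchor), tandem (adjacent homolog), proximal (homolog
within a small number of intervening genes), dispersed, or singleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneCatalog, HomologyHitSet

CATEGORIES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass
class CollinearBlock:
    block_id: int
    genome_a: str
    genome_b: str
    scaffold_a: str
    scaffold_b: str
    orientation: str                       # "same" | "inverted"
    anchor_pairs: list[tuple[str, str]] = field(default_factory=list)
    score: float = 0.0

    def __len__(self) -> int:
        return len(self.anchor_pairs)


@dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    block_id: int = -1

    def __post_init__(self):
        if self.gene_b < self.gene_a:
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _link_ok(prev, nxt, orientation: str, max_gene_gap: int) -> bool:
    """Chain-extension rule between consecutive anchors (rank coordinates)."""
    da = nxt[0] - prev[0]
    db = nxt[1] - prev[1]
    if orientation == "inverted":
        db = -db
    return 1 <= da <= max_gene_gap + 1 and 1 <= db <= max_gene_gap + 1


def _link_penalty(prev, nxt, orientation: str) -> int:
    """Gap penalty: one per skipped gene beyond the first on the worse side."""
    da = nxt[0] - prev[0]
    db = abs(nxt[1] - prev[1])
    skip = max(da, db) - 1
    return max(0, skip - 1)


def _best_chain(anchors: list[tuple[int, int]], orientation: str,
                max_gene_gap: int):
    """Best-scoring monotone chain over the given anchors, by sparse DP.

    Returns (score, chain) where chain is a tuple of anchors; ties resolved
    toward the lexicographically smallest chain so results are deterministic
    and comparable with an exhaustive oracle.
    """
    order = sorted(range(len(anchors)), key=lambda i: anchors[i])
    best: list[tuple[float, tuple]] = [(0.0, ())] * len(anchors)
    for pos, i in enumerate(order):
        ai = anchors[i]
        sc, chain = 1.0, (ai,)
        for j in order[:pos]:
            aj = anchors[j]
            if aj[0] >= ai[0]:
                continue
            if not _link_ok(aj, ai, orientation, max_gene_gap):
                continue
            cand = best[j][0] + 1 - _link_penalty(aj, ai, orientation)
            if cand > sc or (cand == sc and best[j][1] + (ai,) < chain):
                sc, chain = cand, best[j][1] + (ai,)
        best[i] = (sc, chain)
    if not best:
        return 0.0, ()
    top_score = max(t[0] for t in best)
    return top_score, min(t[1] for t in best if t[0] == top_score)


def detect_collinear_blocks(catalog: GeneCatalog, hits: HomologyHitSet,
                            min_block_genes: int = 5, max_gene_gap: int = 25,
                            mode: str = "intra",
                            catalog_b: GeneCatalog | None = None,
                            ) -> list[CollinearBlock]:
    """Find collinear blocks by DP chaining of hit anchors over gene ranks.

    ``mode='intra'`` chains duplicate blocks within one genome; ``mode='inter'``
    chains syntenic blocks between ``catalog`` and ``catalog_b``.  The hit set
    must already carry the top-5/coverage/evalue filter.  Overlapping chains
    are resolved greedily by descending score, removing assigned anchors; a
    gene pair lands in at most one block.
    """
    if not hits.filtered:
        raise ValueError("hit set must be filtered (filter_hits) before chaining")
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "inter" and catalog_b is None:
        raise ValueError("inter mode requires catalog_b")
    cat_b = catalog if mode == "intra" else catalog_b

    # anchors per (scaffold_a, scaffold_b): rank pairs
    anchors_by_pair: dict[tuple[str, str], dict[tuple[int, int], tuple[str, str]]] = {}
    for q, s in hits.pairs():
        if mode == "intra":
            if q not in catalog or s not in catalog or q == s:
                continue
            ga, gb = catalog[q], catalog[s]
            # canonical orientation of the anchor so mirrors collapse
            if (ga.scaffold_id, ga.rank) > (gb.scaffold_id, gb.rank):
                ga, gb = gb, ga
        else:
            if q in catalog and s in cat_b:
                ga, gb = catalog[q], cat_b[s]
            elif s in catalog and q in cat_b:
                ga, gb = catalog[s], cat_b[q]
            else:
                continue
        key = (ga.scaffold_id, gb.scaffold_id)
        anchors_by_pair.setdefault(key, {})[(ga.rank, gb.rank)] = (
            ga.gene_id, gb.gene_id)

    blocks: list[CollinearBlock] = []
    genome_b_id = cat_b.genome_id
    for (sa, sb) in sorted(anchors_by_pair):
        pool = dict(anchors_by_pair[(sa, sb)])
        while pool:
            cands = []
            for orientation in ("same", "inverted"):
                sc, chain = _best_chain(list(pool), orientation, max_gene_gap)
                if chain:
                    cands.append((sc, orientation, chain))
            if not cands:
                break
            # greedy: best score, same orientation preferred, then smallest chain
            sc, orientation, chain = min(
                cands, key=lambda t: (-t[0], t[1] != "same", t[2]))
            if len(chain) >= min_block_genes:
                blocks.append(CollinearBlock(
                    block_id=len(blocks), genome_a=catalog.genome_id,
                    genome_b=genome_b_id, scaffold_a=sa, scaffold_b=sb,
                    orientation=orientation,
                    anchor_pairs=[pool[a] for a in chain], score=sc))
            for a in chain:
                del pool[a]
    return blocks


def classify_duplicates(catalog: GeneCatalog, hits: HomologyHitSet,
                        blocks: list[CollinearBlock],
                        proximal_max_gap: int = 20) -> pd.DataFrame:
    """Assign every gene one of the five duplication categories.

    Precedence (highest wins): WGD/segmental (block anchor) > tandem (a hit
    partner rank-adjacent on the same scaffold) > proximal (a partner with
    fewer than ``proximal_max_gap`` intervening genes) > dispersed (any other
    hit partner) > singleton (no partners).
    """
    if not hits.filtered:
        raise ValueError("hit set must be filtered before classification")
    in_block: set[str] = set()
    for b in blocks:
        for ga, gb in b.anchor_pairs:
            in_block.add(ga)
            in_block.add(gb)

    partners: dict[str, set[str]] = {gid: set() for gid in catalog.genes}
    for q, s in hits.pairs():
        if q in partners and s in partners and q != s:
            partners[q].add(s)
            partners[s].add(q)

    rows = []
    for gid, g in catalog.genes.items():
        if gid in in_block:
            cat = "wgd_segmental"
        elif not partners[gid]:
            cat = "singleton"
        else:
            gaps = [
                abs(catalog[p].rank - g.rank) - 1
                for p in partners[gid]
                if catalog[p].scaffold_id == g.scaffold_id
            ]
            if any(gap == 0 for gap in gaps):
                cat = "tandem"
            elif any(0 < gap < proximal_max_gap for gap in gaps):
                cat = "proximal"
            else:
                cat = "dispersed"
        rows.append((gid, cat))
    return pd.DataFrame(rows, columns=["gene_id", "category"])


def extract_ohnolog_pairs(blocks: list[CollinearBlock]) -> list[OhnologPair]:
    """One pair per block anchor, deduplicated as unordered pairs."""
    seen: dict[tuple[str, str], OhnologPair] = {}
    for b in blocks:
        for ga, gb in b.anchor_pairs:
            p = OhnologPair(ga, gb, block_id=b.block_id)
            seen.setdefault(p.key, p)
    return list(seen.values())


def block_summary(blocks: list[CollinearBlock], catalog: GeneCatalog,
                  catalog_b: GeneCatalog | None = None) -> dict:
    """Headline block statistics (distinct-gene counting).

    Percentages are 100 * distinct genes in blocks / genes in the catalog,
    reported to two decimals.
    """
    from .pipeline import report_percentages

    genes_a: set[str] = set()
    genes_b: set[str] = set()
    for b in blocks:
        for ga, gb in b.anchor_pairs:
            genes_a.add(ga)
            genes_b.add(gb)
    if catalog_b is None:
        in_blocks = genes_a | genes_b
        total = len(catalog)
        return {
            "n_blocks": len(blocks),
            "n_genes_in_blocks": len(in_blocks),
            "pct_genes_in_blocks": report_percentages(len(in_blocks), total)
            if total else 0.0,
        }
    return {
        "n_blocks": len(blocks),
        "n_syntenic_genes_a": len(genes_a),
        "n_syntenic_genes_b": len(genes_b),
        "pct_syntenic_a": report_percentages(len(genes_a), len(catalog)),
        "pct_syntenic_b": report_percentages(len(genes_b), len(catalog_b)),
    }
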