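"""Preferential retention of metabolic pathways in duplicate after WGD.

An enzyme (a distinct enzyme identifier within a pathway) is "uniquely
retained as ohnolog" when every gene encoding it is classed WGD/segmental,
and "uniquely singleton" when every encoding gene is a singleton; enzymes
with mixed gene classes count to neither.  Per pathway, the unique-ohnolog
versus unique-singleton split is tested one-sided (Fisher exact) against the
genome-wide ohnolog/singleton background, BH-corrected across pathways
within each isolate.  A pathway is reported as retained in duplicate only
when it has at least five uniquely retained enzymes and is significant in
BOTH isolates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PathwayRetentionResult:
    pathway_id: str
    n_unique_ohnolog: int
    n_unique_singleton: int
    background_ohnolog: int
    background_singleton: int
    pvalue: float
    fdr: float
    passes_min_enzymes: bool
    significant: bool


def unique_retention(classes: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway counts of enzymes uniquely retained as ohnologs/singletons.

    ``classes``: columns gene_id, category; ``annotation``: columns gene_id,
    enzyme_id, pathway_id.  Annotation rows naming unknown genes are skipped
    with a warning.  Also returns the genome background (ohnolog and
    singleton gene counts among annotated genes) as frame attrs.
    """
    for col in ("gene_id", "enzyme_id", "pathway_id"):
        if col not in annotation.columns:
            raise ValueError(f"annotation missing column {col!r}")
    cls = classes.set_index("gene_id")["category"]
    known = annotation["gene_id"].isin(cls.index)
    if (~known).any():
        logger.warning("%d annotation rows reference unknown genes - skipped",
                       (~known).sum())
        annotation = annotation.loc[known]
    ann = annotation.assign(category=cls.loc[annotation["gene_id"]].to_numpy())

    rows = []
    for pid, sub in ann.groupby("pathway_id"):
        uo = us = 0
        for _, genes in sub.groupby("enzyme_id"):
            cats = set(genes["category"])
            if cats == {"wgd_segmental"}:
                uo += 1
            elif cats == {"singleton"}:
                us += 1
        rows.append((pid, uo, us))
    out = pd.DataFrame(rows, columns=["pathway_id", "n_unique_ohnolog",
                                      "n_unique_singleton"])
    annotated_genes = ann.drop_duplicates("gene_id")
    out.attrs["background_ohnolog"] = int(
        (annotated_genes["category"] == "wgd_segmental").sum())
    out.attrs["background_singleton"] = int(
        (annotated_genes["category"] == "singleton").sum())
    return out


def test_retention(per_isolate_counts: dict[str, pd.DataFrame],
                   min_enzymes: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher tests of duplicate retention per pathway, per isolate, with the
    dual-isolate verdict.

    Each isolate's frame comes from :func:`unique_retention` (background in
    attrs).  Returns a long frame with per-isolate p/FDR plus a
    ``retained_in_duplicate`` column: True only when the pathway passes the
    minimum-enzyme rule and FDR < alpha in every isolate.  With a single
    isolate the per-isolate columns are emitted and the combined verdict is
    withheld (all False, with a warning).
    """
    results = []
    for isolate, counts in per_isolate_counts.items():
        bg_o = counts.attrs.get("background_ohnolog", 0)
        bg_s = counts.attrs.get("background_singleton", 0)
        pvals = []
        for row in counts.itertuples(index=False):
            table = [[row.n_unique_ohnolog, row.n_unique_singleton],
                     [bg_o, bg_s]]
            _, p = stats.fisher_exact(table, alternative="greater")
            pvals.append(p)
        fdr = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        for row, p, q in zip(counts.itertuples(index=False), pvals, fdr):
            results.append({
                "isolate": isolate, "pathway_id": row.pathway_id,
                "n_unique_ohnolog": row.n_unique_ohnolog,
                "n_unique_singleton": row.n_unique_singleton,
                "background_ohnolog": bg_o, "background_singleton": bg_s,
                "pvalue": p, "fdr": q,
                "passes_min_enzymes": max(row.n_unique_ohnolog,
                                          row.n_unique_singleton) >= min_enzymes,
            })
    df = pd.DataFrame(results)
    if df.empty:
        return df
    per_pathway_ok = (
        df.assign(ok=df["passes_min_enzymes"] & (df["fdr"] < alpha))
        .groupby("pathway_id")
        .agg(n_isolates=("isolate", "nunique"), all_ok=("ok", "all"))
    )
    if len(per_isolate_counts) < 2:
        logger.warning("only one isolate provided - combined verdict withheld")
        df["retained_in_duplicate"] = False
    else:
        verdict = per_pathway_ok["all_ok"] & (
            per_pathway_ok["n_isolates"] == len(per_isolate_counts))
        df["retained_in_duplicate"] = verdict.loc[df["pathway_id"]].to_numpy()
    return df
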