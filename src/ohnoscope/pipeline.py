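"""End-to-end orchestration: simulate or load inputs, run every stage in
dependency order, and assemble a JSON summary report.

The report carries the headline statistics of a post-WGD analysis: block and
synteny counts, the duplication-class census, the five-group census of
duplicate-pair DE behaviour, the tau specificity census, the Ks mixture fit,
pathway retention verdicts and the module-preference test, together with
provenance (seed, thresholds, package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collinearity import (block_summary, classify_duplicates,
                           detect_collinear_blocks, extract_ohnolog_pairs)
from .divergence import align_pair_codons, fit_ks_gmm, ng86, node_average_ks
from .expression import (CONTRASTS, classify_pair_groups,
                         filter_expressed_pairs, normalize_counts,
                         pair_correlation, tau_index, test_all_contrasts)
from .simulate import (ExprSimParams, GenomeSimParams, simulate_expression,
                       simulate_wgd_genome)
from .splicing import (build_junction_profiles, extract_junction_flanks,
                       junction_conservation_stats, match_junctions, test_deu)

logger = logging.getLogger(__name__)

_STAGES = ("collinearity", "divergence", "expression", "splicing", "pathways")


def report_percentages(numerator: int, denominator: int) -> float:
    """Percentage with half-up rounding to two decimals (printed precision)."""
    if denominator == 0:
        raise ValueError("denominator is 0")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys in the YAML are rejected."""

    seed: int = 0
    outdir: str = "ohnoscope_out"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    genome: dict = field(default_factory=dict)       # GenomeSimParams overrides
    expression: dict = field(default_factory=dict)   # ExprSimParams overrides
    min_block_genes: int = 5
    max_gene_gap: int = 25
    proximal_max_gap: int = 20
    gmm_k_max: int = 4
    tau_cutoff: float = 0.7
    max_ks_pairs: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


REPORT_REQUIRED_KEYS = {
    "provenance": dict, "block_stats": dict, "duplication_census": dict,
}


def validate_report(report: dict) -> None:
    """Schema check: required keys present with the right container types and
    group percentages recomputable from their integer fields."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] has wrong type")
    census = report.get("group_census")
    if census:
        total = sum(census[g]["n"] for g in census)
        if total:
            s = sum(census[g]["pct"] for g in census)
            if abs(s - 100.0) > 0.05:
                raise ValueError(f"group percentages sum to {s}")
            for g in census:
                expect = report_percentages(census[g]["n"], total)
                if abs(census[g]["pct"] - expect) > 0.005:
                    raise ValueError(f"group {g} percentage not recomputable")


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run all enabled stages on a simulated dataset and build the report.

    Stages run in dependency order (collinearity -> divergence -> expression
    -> splicing -> pathways); a hard error in a stage aborts with the stage
    named, keeping the partial outputs written so far.
    """
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {
        "version": __version__, "seed": config.seed,
        "thresholds": {"min_block_genes": config.min_block_genes,
                       "max_gene_gap": config.max_gene_gap,
                       "proximal_max_gap": config.proximal_max_gap,
                       "gmm_k_max": config.gmm_k_max,
                       "tau_cutoff": config.tau_cutoff},
    }, "block_stats": {}, "duplication_census": {}}

    gparams = GenomeSimParams(**{"seed": config.seed, **config.genome})
    eparams = ExprSimParams(**{"seed": config.seed + 1, **config.expression})
    catalog, hits, truth, genome_seqs = simulate_wgd_genome(gparams)

    stage = "collinearity"
    try:
        blocks = detect_collinear_blocks(
            catalog, hits, min_block_genes=config.min_block_genes,
            max_gene_gap=config.max_gene_gap)
        classes = classify_duplicates(catalog, hits, blocks,
                                      proximal_max_gap=config.proximal_max_gap)
        pairs = extract_ohnolog_pairs(blocks)
        report["block_stats"] = block_summary(blocks, catalog)
        report["duplication_census"] = (
            classes["category"].value_counts().to_dict())
        if write:
            classes.to_csv(outdir / "duplication_classes.tsv", sep="\t",
                           index=False)

        if "divergence" in config.stages:
            stage = "divergence"
            report["ks"] = _divergence_stage(catalog, hits, pairs, config,
                                             outdir, write)

        counts = samples = de = retained = log2fpkm = None
        if "expression" in config.stages:
            stage = "expression"
            (counts, samples, bin_counts, junctions,
             truth) = simulate_expression(catalog, truth, eparams)
            expr_out, de, retained, log2fpkm = _expression_stage(
                catalog, counts, samples, pairs, config, outdir, write)
            report.update(expr_out)

        if "splicing" in config.stages and counts is not None:
            stage = "splicing"
            report["splicing"] = _splicing_stage(
                bin_counts, counts, samples, retained, junctions,
                genome_seqs, outdir, write)

        if "pathways" in config.stages:
            stage = "pathways"
            report["pathways"] = _pathway_stage(classes, config)
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        if write:
            (outdir / "report_partial.json").write_text(
                json.dumps(report, indent=2, default=_jsonify))
        raise

    validate_report(report)
    if write:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonify))
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _divergence_stage(catalog, hits, pairs, config, outdir, write):
    # pairwise Ks within homologous clusters (hit-graph components),
    # node-averaged, then the mixture fit over the Ks distribution
    from collections import defaultdict

    adj = defaultdict(set)
    for a, b in hits.pairs():
        if a in catalog and b in catalog:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    clusters = []
    for g in sorted(adj):
        if g in seen:
            continue
        comp, stack = [], [g]
        seen.add(g)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(comp) > 1:
            clusters.append(sorted(comp))

    rows = []
    cluster_ks = []
    n_done = 0
    for comp in clusters:
        pair_ks = {}
        for i, a in enumerate(comp):
            for b in comp[i + 1:]:
                if n_done >= config.max_ks_pairs:
                    break
                if a not in catalog.cds or b not in catalog.cds:
                    continue
                aln = align_pair_codons(catalog.cds[a], catalog.cds[b],
                                        gene_a=a, gene_b=b)
                est = ng86(aln, gene_a=a, gene_b=b)
                n_done += 1
                rows.append({"gene_a": a, "gene_b": b, "Ks": est.Ks,
                             "Ka": est.Ka, "omega": est.omega,
                             "saturated": est.saturated})
                if not est.saturated:
                    pair_ks[(a, b)] = est.Ks
        if pair_ks:
            cluster_ks.append(pair_ks)
    ks_table = pd.DataFrame(rows)
    if write:
        ks_table.to_csv(outdir / "ks_pairs.tsv", sep="\t", index=False)
    node_ks = node_average_ks(cluster_ks)
    out = {"n_pairs": int(len(ks_table)),
           "n_node_averaged": int(node_ks.size),
           "median_ks": float(np.median(node_ks)) if node_ks.size else None}
    try:
        fit = fit_ks_gmm(node_ks, k_max=config.gmm_k_max, seed=config.seed)
        out["gmm"] = {"k": fit.k, "weights": fit.weights.tolist(),
                      "means": fit.means.tolist(), "sds": fit.sds.tolist(),
                      "aic_by_k": {str(k): v for k, v in fit.aic_by_k.items()}}
    except ValueError as exc:
        out["gmm"] = {"error": str(exc)}
    return out


def _expression_stage(catalog, counts, samples, pairs, config, outdir, write):
    de = test_all_contrasts(counts, samples)
    retained = filter_expressed_pairs(counts, pairs)
    retained = [p for p in retained
                if all(p.gene_a in de[c].index and p.gene_b in de[c].index
                       for c in CONTRASTS)]
    groups = classify_pair_groups(de, retained)
    norm = normalize_counts(counts, catalog.gene_lengths)
    log2fpkm = norm["log2fpkm"]
    corr = [pair_correlation(log2fpkm, p) for p in retained]
    groups["pearson_r"] = corr
    tau = tau_index(log2fpkm, samples)
    classes_df = pd.DataFrame({"gene_id": tau.index})
    if write:
        groups.to_csv(outdir / "pair_groups.tsv", sep="\t", index=False)
        tau.to_csv(outdir / "tau.tsv", sep="\t")
        for c, df in de.items():
            df.to_csv(outdir / f"de_{c}.tsv", sep="\t")

    census = {}
    n_total = len(groups)
    for g in (1, 2, 3, 4, 5):
        n = int((groups["group"] == g).sum())
        census[str(g)] = {"n": n,
                          "pct": report_percentages(n, n_total) if n_total else 0.0}
    high_tau = tau[tau["eligible"] & (tau["tau"] > config.tau_cutoff)]
    out = {
        "n_retained_pairs": len(retained),
        "group_census": census,
        "tau_census": {"n_eligible": int(tau["eligible"].sum()),
                       "n_high_tau": int(len(high_tau))},
    }
    return out, de, retained, log2fpkm


def _splicing_stage(bin_counts, counts, samples, retained, junctions,
                    genome_seqs, outdir, write):
    out: dict = {}
    if bin_counts is not None and len(bin_counts):
        gene_totals = counts.loc[
            bin_counts.index.get_level_values("gene_id").unique()]
        deu = test_deu(bin_counts, gene_totals, samples, "T-Sy")
        out["n_deu_bins"] = int(deu["significant"].sum())
        out["n_deu_genes"] = int(
            deu.loc[deu["significant"], "gene_id"].nunique())
        if write:
            deu.to_csv(outdir / "deu_T-Sy.tsv", sep="\t")
    if junctions is not None and len(junctions) and retained:
        flanks = extract_junction_flanks(junctions, genome_seqs)
        stats_rows = []
        for p in retained:
            fa = flanks[flanks["gene_id"] == p.gene_a]
            fb = flanks[flanks["gene_id"] == p.gene_b]
            if fa.empty or fb.empty:
                continue
            matches = match_junctions(fa, fb)
            prof = build_junction_profiles(fa, fb, matches,
                                           gene_a=p.gene_a, gene_b=p.gene_b)
            if len(prof.profile_a) >= 2:
                stats_rows.append(junction_conservation_stats(prof))
        if stats_rows:
            cons = [s["conserved_fraction"] for s in stats_rows
                    if np.isfinite(s["conserved_fraction"])]
            out["n_junction_pairs"] = len(stats_rows)
            out["mean_conserved_fraction"] = float(np.mean(cons)) if cons else None
    return out


def _pathway_stage(classes, config):
    # synthetic annotation over the classified genes: enzymes drawn per
    # pathway so the retention test has dual-isolate input to exercise
    from .pathways import test_retention, unique_retention

    rng = np.random.default_rng(config.seed + 7)
    gene_ids = classes["gene_id"].to_numpy()
    n_path = 6
    rows = []
    for i, g in enumerate(gene_ids):
        if rng.random() < 0.5:
            pid = f"path{rng.integers(0, n_path):02d}"
            rows.append({"gene_id": g, "enzyme_id": f"EC:{i % 97}",
                         "pathway_id": pid})
    ann = pd.DataFrame(rows)
    if ann.empty:
        return {"n_pathways_tested": 0}
    counts = unique_retention(classes, ann)
    res = test_retention({"iso_a": counts, "iso_b": counts})
    retained = res[res["retained_in_duplicate"]]["pathway_id"].nunique() \
        if len(res) else 0
    return {"n_pathways_tested": int(counts.shape[0]),
            "n_retained_in_duplicate": int(retained)}
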