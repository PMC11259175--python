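"""Readers/writers for the on-disk formats and homology-hit filtering.

Coordinates follow the GFF3 convention (1-based, inclusive) on disk; helper
functions convert to 0-based half-open intervals for internal arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Column order of the extended BLAST tabular (outfmt-6) dialect read by
#: :func:`parse_hits`: the 12 standard columns plus per-side percent coverage.
HIT_COLUMNS = [
    "query_id", "subject_id", "identity", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "query_coverage", "subject_coverage",
]


@dataclass
class GeneModel:
    """A gene on a scaffold with its exon structure.

    ``start``/``end`` are 1-based inclusive; ``exons`` is the sorted list of
    (start, end) intervals; ``rank`` is the 0-based order index of the gene
    along its scaffold (by ascending start, ties broken by gene id).
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    rank: int = -1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        """Summed exon length in bp (gene span if no exon rows were present)."""
        if not self.exons:
            return self.end - self.start + 1
        return sum(e - s + 1 for s, e in self.exons)


class GeneCatalog:
    """Ordered gene models of one genome, plus optional sequences.

    Ranks are (re)assigned on construction: genes are ordered per scaffold by
    ascending start with gene-id lexicographic tie-break, yielding a
    permutation of 0..n-1 within every scaffold.
    """

    def __init__(self, genome_id: str, genes: list[GeneModel],
                 cds: dict[str, str] | None = None,
                 proteins: dict[str, str] | None = None):
        self.genome_id = genome_id
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.cds = cds or {}
        self.proteins = proteins or {}
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        self.scaffolds: dict[str, list[str]] = {}
        by_scaffold: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_scaffold.setdefault(g.scaffold_id, []).append(g)
        for scaf in sorted(by_scaffold):
            ordered = sorted(by_scaffold[scaf], key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(ordered):
                g.rank = i
            self.scaffolds[scaf] = [g.gene_id for g in ordered]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {gid: g.exonic_length for gid, g in self.genes.items()}


@dataclass
class HomologyHitSet:
    """All-versus-all similarity hits, optionally filtered.

    When ``filtered`` is True every hit satisfies (query_coverage > 50 or
    subject_coverage > 50) and evalue <= 1e-5, and each query retains at most
    five subjects.
    """

    hits: pd.DataFrame
    filtered: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.hits.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.hits)

    def pairs(self) -> set[tuple[str, str]]:
        """Unordered (gene_a, gene_b) pairs present in the table."""
        q = self.hits["query_id"].to_numpy()
        s = self.hits["subject_id"].to_numpy()
        return {tuple(sorted(p)) for p in zip(q, s)}


# ---------------------------------------------------------------------------
# GFF3-like gene coordinates
# ---------------------------------------------------------------------------

def parse_gene_positions(path, genome_id: str = "genome") -> GeneCatalog:
    """Parse a GFF3-like file of ``gene`` and ``exon`` features.

    Exon rows attach to their gene via the ``Parent=`` attribute. Rows with
    end < start are rejected with a logged warning; duplicate gene ids are a
    hard error.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                logger.warning("%s:%d: expected 9 columns, got %d - skipped",
                               path, lineno, len(parts))
                continue
            scaf, _source, ftype, start, end, _score, strand, _frame, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                logger.warning("%s:%d: non-integer coordinates - skipped", path, lineno)
                continue
            if end_i < start_i:
                logger.warning("%s:%d: end < start - row rejected", path, lineno)
                continue
            attr = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    logger.warning("%s:%d: gene without ID - skipped", path, lineno)
                    continue
                if gid in genes:
                    raise ValueError(f"duplicate gene_id {gid} at {path}:{lineno}")
                genes[gid] = dict(scaffold_id=scaf, start=start_i, end=end_i,
                                  strand=strand)
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    logger.warning("%s:%d: exon without Parent - skipped", path, lineno)
                    continue
                exons.setdefault(parent, []).append((start_i, end_i))
    models = [GeneModel(gene_id=gid, exons=exons.get(gid, []), **info)
              for gid, info in genes.items()]
    return GeneCatalog(genome_id, models)


def write_gene_positions(catalog: GeneCatalog, path) -> None:
    """Write a catalog back to the GFF3-like dialect read by the parser."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf in catalog.scaffolds:
            for gid in catalog.scaffolds[scaf]:
                g = catalog[gid]
                fh.write(f"{scaf}\tohnoscope\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={gid}\n")
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(f"{scaf}\tohnoscope\texon\t{s}\t{e}\t.\t"
                             f"{g.strand}\t.\tID={gid}.exon{i};Parent={gid}\n")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Homology hits
# ---------------------------------------------------------------------------

def parse_hits(path) -> HomologyHitSet:
    """Read the extended outfmt-6 table (12 standard + 2 coverage columns)."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    return HomologyHitSet(df, filtered=False)


def write_hits(hitset: HomologyHitSet, path) -> None:
    hitset.hits.to_csv(path, sep="\t", header=False, index=False,
                       columns=HIT_COLUMNS)


def filter_hits(raw: HomologyHitSet, max_hits: int = 5,
                min_cov_pct: float = 50.0,
                max_evalue: float = 1e-5) -> HomologyHitSet:
    """Apply the top-5 / coverage / significance filter to a raw hit table.

    Self-hits are removed; hits with (query or subject coverage > min_cov_pct)
    and evalue <= max_evalue are kept; per query the top ``max_hits`` by
    ascending evalue (ties: descending bitscore, then subject id) survive.
    Idempotent.
    """
    df = raw.hits
    keep = (
        (df["query_id"] != df["subject_id"])
        & ((df["query_coverage"] > min_cov_pct) | (df["subject_coverage"] > min_cov_pct))
        & (df["evalue"] <= max_evalue)
    )
    df = df.loc[keep]
    df = df.sort_values(
        ["query_id", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    df = df.groupby("query_id", sort=False).head(max_hits).reset_index(drop=True)
    return HomologyHitSet(df, filtered=True)


# ---------------------------------------------------------------------------
# Count matrices and sample sheets
# ---------------------------------------------------------------------------

LIFESTYLES = ("free", "symbiotic")
TEMPERATURES = (28, 34)


def parse_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample, lifestyle, temperature, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "lifestyle", "temperature", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad_ls = set(sheet["lifestyle"]) - set(LIFESTYLES)
    if bad_ls:
        raise ValueError(f"unknown lifestyle values: {sorted(bad_ls)}")
    bad_t = set(sheet["temperature"].astype(int)) - set(TEMPERATURES)
    if bad_t:
        raise ValueError(f"unknown temperature values: {sorted(bad_t)}")
    sheet["temperature"] = sheet["temperature"].astype(int)
    return sheet.set_index("sample")


def parse_counts(path, samples: pd.DataFrame) -> pd.DataFrame:
    """Read a genes x samples TSV of non-negative integer counts.

    Every matrix column must appear in the sample sheet; non-integer or
    negative values are a hard error naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in samples.index]
    if unknown:
        raise ValueError(f"samples absent from sheet: {unknown}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric count at gene {row}, sample {col}")
        if (vals < 0).any():
            row = df.index[(vals < 0).to_numpy().nonzero()[0][0]]
            raise ValueError(f"negative count at gene {row}, sample {col}")
        if not np.allclose(vals, np.round(vals)):
            bad = ~np.isclose(vals.to_numpy(), np.round(vals.to_numpy()))
            row = df.index[bad.nonzero()[0][0]]
            raise ValueError(f"non-integer count at gene {row}, sample {col}")
    return df.astype(np.int64)


def condition_of(samples: pd.DataFrame) -> pd.Series:
    """Condition label (lifestyle:temperature) per sample."""
    return samples["lifestyle"] + ":" + samples["temperature"].astype(str)


def parse_two_column_table(path, key: str, value: str) -> pd.DataFrame:
    """Generic TSV reader for gene->pathway / gene->module style tables."""
    df = pd.read_csv(path, sep="\t")
    for col in (key, value):
        if col not in df.columns:
            raise ValueError(f"table {path} missing column {col!r}")
    return df
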