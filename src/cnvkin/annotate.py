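"""CNV annotation against pathogenic regions, gene models and cytobands.

Percentages follow the reporting conventions of clinical CNV tables:
overlap with a reference region is expressed as a percentage of the
reference length rounded half-up to two decimals; overlap with a gene is
a percentage of the gene span rounded half-up to the nearest integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cnvkin.calls import CNVCall
from cnvkin.filters import FilterAudit
from cnvkin.intervals import (
    intersection_length,
    interval_length,
    reciprocal_overlap,
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with optional exon structure (1-based inclusive)."""

    symbol: str
    chrom: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.symbol}: gene_start > gene_end")
        for s, e in self.exons:
            if not (self.gene_start <= s <= e <= self.gene_end):
                raise ValueError(f"{self.symbol}: exon [{s},{e}] outside gene span")

    @property
    def length(self) -> int:
        return interval_length(self.gene_start, self.gene_end)


@dataclass(frozen=True)
class PathogenicRegion:
    """A curated pathogenic CNV region, optionally with critical genes."""

    name: str
    chrom: str
    start: int
    end: int
    type_constraint: str = "either"  # "deletion" | "duplication" | "either"
    critical_genes: tuple[GeneModel, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.type_constraint not in ("deletion", "duplication", "either"):
            raise ValueError(f"{self.name}: bad type_constraint {self.type_constraint!r}")
        for g in self.critical_genes:
            if g.chrom != self.chrom:
                raise ValueError(
                    f"{self.name}: critical gene {g.symbol} on {g.chrom}, region on {self.chrom}"
                )


@dataclass(frozen=True)
class OverlapResult:
    hit: bool
    pct_of_reference: float
    pct_of_gene: float | None = None
    rule_used: str | None = None  # critical_gene | region_80pct | exon_any | full_gene

    def __post_init__(self) -> None:
        if not self.hit and self.rule_used is not None:
            raise ValueError("rule_used must be absent when hit is False")


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_overlap_of_reference(cnv: CNVCall, region: PathogenicRegion) -> float:
    """100 x (inclusive intersection length) / (inclusive reference length),
    rounded half-up to 2 decimals; 0 when disjoint or on another chromosome."""
    if cnv.chrom != region.chrom:
        return 0.0
    o = intersection_length(cnv.start, cnv.end, region.start, region.end)
    pct = 100.0 * o / interval_length(region.start, region.end)
    return _round_half_up(pct, 2)


def _hits_any_exon(cnv: CNVCall, gene: GeneModel) -> bool:
    if cnv.chrom != gene.chrom:
        return False
    if gene.exons:
        return any(
            intersection_length(cnv.start, cnv.end, s, e) > 0 for s, e in gene.exons
        )
    warnings.warn(
        f"gene {gene.symbol} has no exon structure; "
        "falling back to whole-gene-interval overlap",
        stacklevel=3,
    )
    return intersection_length(cnv.start, cnv.end, gene.gene_start, gene.gene_end) > 0


def match_pathogenic(
    cnv: CNVCall, region: PathogenicRegion, threshold: float = 0.8
) -> OverlapResult:
    """Match a CNV against one pathogenic region.

    Regions carrying critical genes hit on any (>= 1 bp) overlap with a
    critical-gene exon; regions without critical genes hit when the CNV
    covers >= ``threshold`` of the region. A type-incompatible CNV never
    hits. The reference-overlap percentage is reported either way.
    """
    pct = pct_overlap_of_reference(cnv, region)
    if region.type_constraint != "either" and cnv.type != region.type_constraint:
        return OverlapResult(hit=False, pct_of_reference=pct)
    if region.critical_genes:
        hit = any(_hits_any_exon(cnv, g) for g in region.critical_genes)
        return OverlapResult(
            hit=hit,
            pct_of_reference=pct,
            rule_used="critical_gene" if hit else None,
        )
    hit = pct > 0.0 and pct >= 100.0 * threshold
    return OverlapResult(
        hit=hit, pct_of_reference=pct, rule_used="region_80pct" if hit else None
    )


def match_gene(cnv: CNVCall, gene: GeneModel) -> OverlapResult:
    """Deletion: hit on any exonic overlap. Duplication: hit only when the
    gene span is fully contained in the CNV. pct_of_gene is the share of
    the gene span intersected, rounded half-up to an integer."""
    if cnv.chrom != gene.chrom:
        return OverlapResult(hit=False, pct_of_reference=0.0, pct_of_gene=0.0)
    inter = intersection_length(cnv.start, cnv.end, gene.gene_start, gene.gene_end)
    pct_gene = _round_half_up(100.0 * inter / gene.length, 0)
    if cnv.type == "deletion":
        hit = _hits_any_exon(cnv, gene)
        rule = "exon_any" if hit else None
    else:
        hit = cnv.start <= gene.gene_start and gene.gene_end <= cnv.end
        rule = "full_gene" if hit else None
    return OverlapResult(
        hit=hit, pct_of_reference=0.0, pct_of_gene=pct_gene, rule_used=rule
    )


def annotate_cytoband(cnv: CNVCall, cytobands: pd.DataFrame) -> list[str]:
    """Bands covering >= 50% of the CNV length (both reported on an exact
    50/50 straddle). ``cytobands`` needs chrom/start/end/band columns tiling
    each chromosome."""
    sub = cytobands[cytobands["chrom"] == cnv.chrom]
    if sub.empty:
        raise ValueError(f"chromosome {cnv.chrom} absent from cytoband tiling")
    hits = []
    for row in sub.itertuples(index=False):
        o = intersection_length(cnv.start, cnv.end, int(row.start), int(row.end))
        if 2 * o >= cnv.length:
            hits.append(str(row.band))
    return hits


def annotate_calls(
    calls: Sequence[CNVCall],
    regions: Sequence[PathogenicRegion],
    genes: Sequence[GeneModel] = (),
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Cross every call against every region and gene; one row per hit."""
    rows = []
    for cnv in calls:
        for region in regions:
            res = match_pathogenic(cnv, region, threshold=threshold)
            if res.hit:
                rows.append(
                    {
                        "sample": cnv.sample_id,
                        "chrom": cnv.chrom,
                        "start": cnv.start,
                        "end": cnv.end,
                        "type": cnv.type,
                        "target": region.name,
                        "target_kind": "region",
                        "rule": res.rule_used,
                        "pct": res.pct_of_reference,
                    }
                )
        for gene in genes:
            res = match_gene(cnv, gene)
            if res.hit:
                rows.append(
                    {
                        "sample": cnv.sample_id,
                        "chrom": cnv.chrom,
                        "start": cnv.start,
                        "end": cnv.end,
                        "type": cnv.type,
                        "target": gene.symbol,
                        "target_kind": "gene",
                        "rule": res.rule_used,
                        "pct": res.pct_of_gene,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start", "end", "type",
            "target", "target_kind", "rule", "pct",
        ],
    )


def report_large_and_familial(
    audits: Sequence[FilterAudit],
    pedigree: pd.DataFrame,
    pathogenic_hits: Iterable[CNVCall] = (),
    min_length_bp: int = 1_000_000,
    share_overlap: float = 0.5,
) -> pd.DataFrame:
    """Retained CNVs strictly longer than ``min_length_bp`` without a
    pathogenic hit, with an apparent-inheritance flag when a first-degree
    relative carries a same-type CNV at >= ``share_overlap`` reciprocal
    overlap.

    ``pedigree`` needs sample_id/father_id/mother_id columns; missing
    parents are empty strings or "0".
    """
    hit_keys = {c.key for c in pathogenic_hits}
    kept = [a.cnv for a in audits if a.status == "retained"]
    large = [
        c for c in kept if c.length > min_length_bp and c.key not in hit_keys
    ]

    parents: dict[str, set[str]] = {}
    for row in pedigree.itertuples(index=False):
        ps = {str(row.father_id), str(row.mother_id)} - {"", "0", "nan"}
        parents[str(row.sample_id)] = ps

    def first_degree(a: str, b: str) -> bool:
        if b in parents.get(a, set()) or a in parents.get(b, set()):
            return True  # parent-offspring
        pa, pb = parents.get(a, set()), parents.get(b, set())
        return bool(pa) and pa == pb  # full siblings

    by_sample: dict[str, list[CNVCall]] = {}
    for c in kept:
        by_sample.setdefault(c.sample_id, []).append(c)

    rows = []
    for c in large:
        shared_with = []
        for other_id, others in by_sample.items():
            if other_id == c.sample_id or not first_degree(c.sample_id, other_id):
                continue
            for o in others:
                if (
                    o.chrom == c.chrom
                    and o.type == c.type
                    and reciprocal_overlap(c.start, c.end, o.start, o.end)
                    >= share_overlap
                ):
                    shared_with.append(other_id)
                    break
        rows.append(
            {
                "sample": c.sample_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "type": c.type,
                "length": c.length,
                "familial": bool(shared_with),
                "shared_with": ",".join(sorted(set(shared_with))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "type", "length", "familial", "shared_with"],
    )


# ---------------------------------------------------------------------------
# file formats


def read_pathogenic_regions(path: str | Path) -> list[PathogenicRegion]:
    """Tab-separated columns: name, chrom, start, end, type_constraint,
    source, critical_genes (semicolon-separated gene:chrom:start:end
    tuples; empty for none)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    regions = []
    for row in df.itertuples(index=False):
        genes = []
        if row.critical_genes:
            for spec in str(row.critical_genes).split(";"):
                sym, chrom, s, e = spec.split(":")
                genes.append(
                    GeneModel(symbol=sym, chrom=chrom, gene_start=int(s), gene_end=int(e))
                )
        regions.append(
            PathogenicRegion(
                name=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                type_constraint=str(row.type_constraint) or "either",
                critical_genes=tuple(genes),
                source=str(getattr(row, "source", "")),
            )
        )
    return regions


def write_pathogenic_regions(
    regions: Sequence[PathogenicRegion], path: str | Path
) -> None:
    rows = []
    for r in regions:
        genes = ";".join(
            f"{g.symbol}:{g.chrom}:{g.gene_start}:{g.gene_end}" for g in r.critical_genes
        )
        rows.append(
            {
                "name": r.name,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "type_constraint": r.type_constraint,
                "source": r.source,
                "critical_genes": genes,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Tab-separated columns: symbol, chrom, start, end, exons
    (semicolon-separated start-end pairs; may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        if row.exons:
            for spec in str(row.exons).split(";"):
                s, e = spec.split("-")
                exons.append((int(s), int(e)))
        genes.append(
            GeneModel(
                symbol=str(row.symbol),
                chrom=str(row.chrom),
                gene_start=int(row.start),
                gene_end=int(row.end),
                exons=tuple(exons),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "symbol": g.symbol,
            "chrom": g.chrom,
            "start": g.gene_start,
            "end": g.gene_end,
            "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
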