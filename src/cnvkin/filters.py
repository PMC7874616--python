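"""Sample-level intensity QC and the CNV exclusion cascade.

The cascade applies rules in a fixed order and attributes each removed CNV
to the first failing rule, so attrition tables are reproducible. Overlap
fractions are measured against the CNV's own length unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cnvkin.calls import CNVCall, calls_to_frame
from cnvkin.intervals import (
    covered_fraction,
    coverage_regions,
    intersection_length,
    reciprocal_overlap,
)


class ConfigurationError(ValueError):
    """A rule was enabled without the resource it needs."""


@dataclass(frozen=True)
class SampleIntensityQC:
    """Per-sample array-intensity statistics plus per-chromosome CNV load."""

    sample_id: str
    LRRSD: float
    BAFSD: float
    GCWF: float
    chrom_cnv_fraction: Mapping[str, float] = field(default_factory=dict)
    n_cnvs: int | None = None

    def __post_init__(self) -> None:
        for chrom, frac in self.chrom_cnv_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"chrom_cnv_fraction[{chrom}] = {frac} outside [0, 1]"
                )


@dataclass(frozen=True)
class FilterAudit:
    """Outcome of the exclusion cascade for one CNV."""

    cnv: CNVCall
    status: str  # "retained" | "removed"
    failed_filter: str | None = None

    def __post_init__(self) -> None:
        if (self.status == "removed") != (self.failed_filter is not None):
            raise ValueError("status=removed iff failed_filter is present")


def sample_qc(
    stats: Sequence[SampleIntensityQC],
    sd_limit: float = 3.0,
    aneuploidy_fraction: float = 0.2,
    max_cnvs_per_sample: int | None = None,
) -> pd.DataFrame:
    """Flag samples with outlying intensity statistics or aneuploidy.

    A sample fails when any of LRRSD/BAFSD/GCWF lies more than ``sd_limit``
    sample standard deviations (n-1 denominator, batch = full input, single
    pass) from the batch mean; when its CNVs cover more than
    ``aneuploidy_fraction`` of any chromosome; or when it exceeds
    ``max_cnvs_per_sample`` (if set).

    Returns a frame with columns sample_id, passed, reasons.
    """
    if len(stats) < 2:
        raise ValueError("sample_qc needs >= 2 samples (SD undefined otherwise)")
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in stats],
            "LRRSD": [s.LRRSD for s in stats],
            "BAFSD": [s.BAFSD for s in stats],
            "GCWF": [s.GCWF for s in stats],
        }
    )
    reasons: list[list[str]] = [[] for _ in stats]
    for stat in ("LRRSD", "BAFSD", "GCWF"):
        mean = df[stat].mean()
        sd = df[stat].std(ddof=1)
        # sd == 0: only exact-mean values pass (identical batch all passes)
        bad = (df[stat] - mean).abs() > sd_limit * sd
        for i in bad[bad].index:
            reasons[i].append(stat)
    for i, s in enumerate(stats):
        if any(f > aneuploidy_fraction for f in s.chrom_cnv_fraction.values()):
            reasons[i].append("aneuploidy")
        if (
            max_cnvs_per_sample is not None
            and s.n_cnvs is not None
            and s.n_cnvs > max_cnvs_per_sample
        ):
            reasons[i].append("cnv_count")
    df["passed"] = [not r for r in reasons]
    df["reasons"] = [",".join(r) for r in reasons]
    return df[["sample_id", "passed", "reasons"]]


def build_common_mask(
    calls: Iterable[CNVCall], min_support: int = 25
) -> pd.DataFrame:
    """Maximal regions covered by >= ``min_support`` CNVs (any type/sample).

    Returns a frame with columns chrom, start, end (1-based inclusive).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    rows = []
    for chrom in sorted(by_chrom):
        for s, e in coverage_regions(by_chrom[chrom], min_support):
            rows.append({"chrom": chrom, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _region_tuples(df: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
    sub = df[df["chrom"] == chrom]
    return list(zip(sub["start"].astype(int), sub["end"].astype(int)))


def _any_overlap(cnv: CNVCall, regions: pd.DataFrame) -> bool:
    return any(
        intersection_length(cnv.start, cnv.end, s, e) > 0
        for s, e in _region_tuples(regions, cnv.chrom)
    )


def _cnv_covered_fraction(cnv: CNVCall, regions: pd.DataFrame) -> float:
    tuples = _region_tuples(regions, cnv.chrom)
    if not tuples:
        return 0.0
    return covered_fraction(cnv.start, cnv.end, tuples)


# Cascade order mirrors the published exclusion list; attribution is to the
# first failing rule only.
RULE_ORDER = (
    "confidence",
    "centromere",
    "mhc",
    "segdup",
    "common_internal",
    "size",
    "benign",
    "common_external",
    "gnomad",
    "noncoding",
)

_RESOURCE_FOR_RULE = {
    "centromere": "centromeres",
    "mhc": "mhc_region",
    "segdup": "segdups",
    "benign": "benign_catalog",
    "common_external": "common_external",
    "gnomad": "gnomad_freqs",
    "noncoding": "exons",
}


@dataclass(frozen=True)
class FilterThresholds:
    min_confidence: float = 10.0
    max_segdup_fraction: float = 0.5  # strict > removes
    common_mask_fraction: float = 0.5  # >= removes
    min_snps: int = 10  # strict < removes
    min_length_bp: int = 20_000  # strict < removes
    benign_fraction: float = 0.7  # >= removes (of CNV length)
    common_external_fraction: float = 0.7  # >= removes (of CNV length)
    gnomad_reciprocal: float = 0.5  # >= matches a catalog entry
    gnomad_max_freq: float = 0.01  # >= removes


def filter_cnvs(
    calls: Sequence[CNVCall],
    resources: Mapping[str, pd.DataFrame],
    mask: pd.DataFrame | None = None,
    rules: Sequence[str] | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterAudit]:
    """Run the exclusion cascade; one audit row per input CNV.

    ``resources`` maps resource names (centromeres, mhc_region, segdups,
    benign_catalog, common_external, gnomad_freqs, exons) to frames with
    1-based inclusive chrom/start/end columns (gnomad_freqs additionally
    needs a ``freq`` column). ``rules`` defaults to every rule whose
    resource is available plus the resource-free confidence/size rules;
    requesting a rule without its resource raises ConfigurationError.
    """
    if rules is None:
        rules = [
            r
            for r in RULE_ORDER
            if _RESOURCE_FOR_RULE.get(r) is None
            or _RESOURCE_FOR_RULE[r] in resources
        ]
        if "common_internal" in rules and mask is None:
            rules.remove("common_internal")
    else:
        for r in rules:
            res = _RESOURCE_FOR_RULE.get(r)
            if res is not None and res not in resources:
                raise ConfigurationError(f"rule {r!r} needs resource {res!r}")
            if r == "common_internal" and mask is None:
                raise ConfigurationError("rule 'common_internal' needs a mask")
    rules = [r for r in RULE_ORDER if r in rules]

    gnomad = resources.get("gnomad_freqs")

    def first_failure(cnv: CNVCall) -> str | None:
        for rule in rules:
            if rule == "confidence":
                if cnv.confidence is not None and cnv.confidence < thresholds.min_confidence:
                    return rule
            elif rule == "centromere":
                if _any_overlap(cnv, resources["centromeres"]):
                    return rule
            elif rule == "mhc":
                if _any_overlap(cnv, resources["mhc_region"]):
                    return rule
            elif rule == "segdup":
                if _cnv_covered_fraction(cnv, resources["segdups"]) > thresholds.max_segdup_fraction:
                    return rule
            elif rule == "common_internal":
                if _cnv_covered_fraction(cnv, mask) >= thresholds.common_mask_fraction:
                    return rule
            elif rule == "size":
                short_snps = cnv.n_snps is not None and cnv.n_snps < thresholds.min_snps
                short_bp = cnv.length < thresholds.min_length_bp
                if short_snps or short_bp:
                    return rule
            elif rule == "benign":
                if _cnv_covered_fraction(cnv, resources["benign_catalog"]) >= thresholds.benign_fraction:
                    return rule
            elif rule == "common_external":
                if _cnv_covered_fraction(cnv, resources["common_external"]) >= thresholds.common_external_fraction:
                    return rule
            elif rule == "gnomad":
                for row in gnomad[gnomad["chrom"] == cnv.chrom].itertuples(index=False):
                    if (
                        row.freq >= thresholds.gnomad_max_freq
                        and reciprocal_overlap(cnv.start, cnv.end, int(row.start), int(row.end))
                        >= thresholds.gnomad_reciprocal
                    ):
                        return rule
            elif rule == "noncoding":
                if not _any_overlap(cnv, resources["exons"]):
                    return rule
        return None

    audits = []
    for cnv in calls:
        failed = first_failure(cnv)
        audits.append(
            FilterAudit(
                cnv=cnv,
                status="removed" if failed else "retained",
                failed_filter=failed,
            )
        )
    return audits


def retained(audits: Iterable[FilterAudit]) -> list[CNVCall]:
    return [a.cnv for a in audits if a.status == "retained"]


def audits_to_frame(audits: Sequence[FilterAudit]) -> pd.DataFrame:
    df = calls_to_frame([a.cnv for a in audits])
    df["status"] = [a.status for a in audits]
    df["failed_filter"] = [a.failed_filter or "" for a in audits]
    return df
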