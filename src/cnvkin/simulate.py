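"""Synthetic cohort generation with planted ground truth.

Everything the pipeline consumes can be generated here on a miniature
genome (default 5 chromosomes of 50 Mb): family cohorts with
Mendelian-consistent genotypes, group-structured polygenic scores,
relationship-typical IBD statistics, PC coordinates around population
centroids, fragmented/jittered dual-caller views of planted CNVs, and all
reference tracks in the same coordinate space.

Randomness: a single seed is split with ``numpy.random.SeedSequence`` into
named substreams (one per sub-generator, fixed order), so each sub-generator
is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cnvkin.calls import (
    CNVCall,
    calls_to_frame,
    write_bed,
    write_call_table,
    write_rawcnv,
)
from cnvkin.annotate import GeneModel, PathogenicRegion, write_gene_models, write_pathogenic_regions

_STREAMS = ("cohort", "genotypes", "pgs", "ibd", "views_a", "views_b", "qc")

# population centroids on the first two ancestry PCs (well separated at 4 SD)
POPULATIONS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "EUR": ((0.00, 0.00), (0.01, 0.01)),
    "SAS": ((0.10, 0.00), (0.01, 0.01)),
    "EAS": ((0.20, 0.10), (0.01, 0.01)),
    "AFR": ((-0.10, 0.15), (0.01, 0.01)),
}

DEFAULT_CHROM_LENGTHS = {f"chr{i}": 50_000_000 for i in range(1, 6)}


class ConfigError(ValueError):
    """An invalid SimConfig field; the message names the field."""


@dataclass(frozen=True)
class CNVSpec:
    """A planted true CNV: coordinates, type, carriers, caller metadata."""

    chrom: str
    start: int
    end: int
    type: str
    carriers: tuple[str, ...]
    n_snps: int | None = None
    confidence: float = 50.0

    def resolved_n_snps(self) -> int:
        if self.n_snps is not None:
            return self.n_snps
        return max(10, (self.end - self.start + 1) // 5_000)


@dataclass(frozen=True)
class CommonRegionSpec:
    """A polymorphic common-CNV region with a population carrier frequency."""

    chrom: str
    start: int
    end: int
    freq: float
    type: str = "deletion"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_families: int = 10
    n_unrelated: int = 5
    n_controls: int = 0
    quad_fraction: float = 0.0
    group_pgs_shifts: Mapping[str, float] = field(default_factory=dict)
    ptdt_overtransmission: float = 0.0  # in midparent-SD units
    pgs_r2: float = 0.0
    n_variants: int = 100
    cnv_truth: tuple[CNVSpec, ...] = ()
    fragmentation_rate: float = 0.0
    boundary_jitter_bp: int = 0
    fp_rate: float = 0.0
    detection_rate: float = 1.0
    max_fragment_gap_bp: int = 50_000
    common_region_specs: tuple[CommonRegionSpec, ...] = ()
    mendelian_error_rate: float = 0.0
    n_qc_outliers: int = 0
    n_pcs: int = 5
    population_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"EUR": 1.0}
    )
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )

    def __post_init__(self) -> None:
        for name in ("n_families", "n_unrelated", "n_controls", "n_variants", "n_qc_outliers"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "quad_fraction", "pgs_r2", "fragmentation_rate", "fp_rate",
            "detection_rate", "mendelian_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_jitter_bp < 0:
            raise ConfigError("boundary_jitter_bp must be >= 0")
        if self.max_fragment_gap_bp < 0:
            raise ConfigError("max_fragment_gap_bp must be >= 0")
        if self.n_pcs < 2:
            raise ConfigError("n_pcs must be >= 2")
        for spec in self.common_region_specs:
            if not 0.0 <= spec.freq <= 1.0:
                raise ConfigError(
                    f"common_region_specs frequency must be in [0, 1], got {spec.freq}"
                )
        total = sum(self.population_fractions.values())
        if self.population_fractions and abs(total - 1.0) > 1e-9:
            raise ConfigError("population_fractions must sum to 1")
        for pop in self.population_fractions:
            if pop not in POPULATIONS:
                raise ConfigError(f"population_fractions has unknown label {pop!r}")


@dataclass
class TruthSet:
    true_cnvs: list[CNVCall]
    true_relationships: dict[tuple[str, str], str]
    true_group_means: dict[str, float]
    true_r2: float
    samples: list[str] = field(default_factory=list)
    common_carriers: dict[CommonRegionSpec, list[str]] = field(default_factory=dict)
    mendel_errors: dict[str, int] = field(default_factory=dict)


@dataclass
class CohortBundle:
    pedigree: pd.DataFrame  # family_id, sample_id, father_id, mother_id, sex, group, age, population
    pcs: pd.DataFrame  # sample_id, pc1..pcN
    dosages: pd.DataFrame  # samples x variants
    weights: pd.DataFrame  # variant, effect_allele, effect
    phenotypes: pd.DataFrame  # sample_id, group, pgs, phenotype
    ibd: pd.DataFrame  # id1, id2, PI_HAT, Z0, Z1, Z2
    population_reference: pd.DataFrame  # label, mean1, mean2, sd1, sd2


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _draw_ibd(rng: np.random.Generator, relationship: str) -> tuple[float, float, float, float]:
    """(PI_HAT, Z0, Z1, Z2) from a relationship-typical distribution,
    satisfying Z0+Z1+Z2 = 1 and PI_HAT = 0.5 Z1 + Z2 exactly."""
    if relationship == "parent_offspring":
        z0 = float(np.clip(abs(rng.normal(0.0, 0.004)), 0.0, 0.04))
        z2 = float(np.clip(abs(rng.normal(0.0, 0.004)), 0.0, 0.04))
    elif relationship == "full_sibling":
        z0 = float(np.clip(rng.normal(0.25, 0.02), 0.15, 0.35))
        z2 = float(np.clip(rng.normal(0.25, 0.02), 0.15, 0.35))
    elif relationship == "monozygotic":
        z0 = float(np.clip(abs(rng.normal(0.0, 0.002)), 0.0, 0.01))
        z2 = 1.0 - z0 - float(np.clip(abs(rng.normal(0.0, 0.002)), 0.0, 0.01))
        z1 = 1.0 - z0 - z2
        return 0.5 * z1 + z2, z0, z1, z2
    else:  # unrelated / spouse
        z1 = float(np.clip(abs(rng.normal(0.0, 0.01)), 0.0, 0.05))
        z0 = 1.0 - z1
        return 0.5 * z1, z0, z1, 0.0
    z1 = 1.0 - z0 - z2
    return 0.5 * z1 + z2, z0, z1, z2


def _transmit(rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    """One transmitted allele per variant given a parent's dosage vector."""
    return (rng.random(dosage.shape) < dosage / 2.0).astype(np.int8)


def generate_cohort(config: SimConfig) -> tuple[CohortBundle, TruthSet]:
    """Build the full cohort bundle plus its ground truth.

    Families are trios (or quads, per ``quad_fraction``) with
    Mendelian-consistent child genotypes; polygenic scores follow a
    family-structured Gaussian model in which group mean shifts (in
    control-SD units) and pTDT over-transmission (in midparent-SD units)
    hold in expectation; phenotypes carry ``pgs_r2`` of their variance from
    the PGS.
    """
    rngs = _rngs(config.seed)
    rc = rngs["cohort"]

    pop_labels = list(config.population_fractions)
    pop_probs = [config.population_fractions[p] for p in pop_labels]

    rows = []  # pedigree rows
    trio_children: list[tuple[str, str, str]] = []  # (child, father, mother)
    sib_pairs: list[tuple[str, str]] = []
    spouse_pairs: list[tuple[str, str]] = []

    def draw_pop() -> str:
        if not pop_labels:
            return "EUR"
        return str(rc.choice(pop_labels, p=pop_probs))

    for i in range(config.n_families):
        fam = f"FAM{i:03d}"
        pop = draw_pop()
        father, mother = f"{fam}_FA", f"{fam}_MO"
        rows.append((fam, father, "", "", "male", "FTR", int(rc.integers(30, 56)), pop))
        rows.append((fam, mother, "", "", "female", "MTR", int(rc.integers(30, 56)), pop))
        spouse_pairs.append((father, mother))
        n_children = 2 if rc.random() < config.quad_fraction else 1
        kids = []
        for j in range(n_children):
            child = f"{fam}_C{j + 1}"
            group = "ASD" if j == 0 else "SIB"
            sex = "male" if rc.random() < 0.5 else "female"
            rows.append((fam, child, father, mother, sex, group, int(rc.integers(2, 18)), pop))
            trio_children.append((child, father, mother))
            kids.append(child)
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                sib_pairs.append((kids[a], kids[b]))

    for i in range(config.n_unrelated):
        sid = f"UNR{i:03d}"
        sex = "male" if rc.random() < 0.5 else "female"
        rows.append((sid, sid, "", "", sex, "UNR", int(rc.integers(2, 18)), draw_pop()))
    for i in range(config.n_controls):
        sid = f"CTL{i:03d}"
        sex = "male" if rc.random() < 0.5 else "female"
        rows.append((sid, sid, "", "", sex, "CTL", int(rc.integers(30, 71)), draw_pop()))

    pedigree = pd.DataFrame(
        rows,
        columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "group", "age", "population"],
    )
    samples = list(pedigree["sample_id"])
    groups = dict(zip(pedigree["sample_id"], pedigree["group"]))

    # --- PC coordinates around population centroids -----------------------
    pc_rows = []
    for sid, pop in zip(pedigree["sample_id"], pedigree["population"]):
        mean, sd = POPULATIONS[pop]
        coords = [rc.normal(mean[0], sd[0]), rc.normal(mean[1], sd[1])]
        coords += [rc.normal(0.0, 1.0) for _ in range(config.n_pcs - 2)]
        pc_rows.append([sid] + coords)
    pcs = pd.DataFrame(
        pc_rows, columns=["sample_id"] + [f"pc{i + 1}" for i in range(config.n_pcs)]
    )
    population_reference = pd.DataFrame(
        [
            {"label": lab, "mean1": m[0], "mean2": m[1], "sd1": s[0], "sd2": s[1]}
            for lab, (m, s) in POPULATIONS.items()
        ]
    )

    # --- genotype panel (Mendelian-consistent) ----------------------------
    rg = rngs["genotypes"]
    variants = [f"v{i + 1:05d}" for i in range(config.n_variants)]
    af = rg.uniform(0.1, 0.9, size=config.n_variants)
    dosage_map: dict[str, np.ndarray] = {}
    father_of = dict(zip(pedigree["sample_id"], pedigree["father_id"]))
    founders = [sid for sid in samples if father_of[sid] == ""]
    for sid in founders:
        dosage_map[sid] = rg.binomial(2, af).astype(np.int8)
    mendel_errors: dict[str, int] = {}
    for child, father, mother in trio_children:
        d = _transmit(rg, dosage_map[father]) + _transmit(rg, dosage_map[mother])
        n_err = 0
        if config.mendelian_error_rate > 0:
            flip = rg.random(config.n_variants) < config.mendelian_error_rate
            for idx in np.nonzero(flip)[0]:
                fa, mo = int(dosage_map[father][idx]), int(dosage_map[mother][idx])
                # force an impossible child dosage where one exists
                if fa == 0 and mo == 0:
                    d[idx] = 1
                elif fa == 2 and mo == 2:
                    d[idx] = 1
                elif {fa, mo} == {0, 2}:
                    d[idx] = 0
                else:
                    continue
                n_err += 1
        dosage_map[child] = d
        mendel_errors[child] = n_err
    dosages = pd.DataFrame(
        {v: [int(dosage_map[sid][i]) for sid in samples] for i, v in enumerate(variants)},
        index=pd.Index(samples, name="sample_id"),
    )
    weights = pd.DataFrame(
        {
            "variant": variants,
            "effect_allele": ["A"] * config.n_variants,
            "effect": rg.normal(0.0, 1.0 / math.sqrt(max(config.n_variants, 1)), size=config.n_variants),
        }
    )

    # --- polygenic scores and phenotypes ----------------------------------
    rp = rngs["pgs"]
    shifts = dict(config.group_pgs_shifts)
    pgs: dict[str, float] = {}
    for sid in samples:
        if sid not in {c for c, _, _ in trio_children}:
            pgs[sid] = rp.normal(shifts.get(groups[sid], 0.0), 1.0)
    mid_sd_theory = 1.0 / math.sqrt(2.0)
    for child, father, mother in trio_children:
        mid = 0.5 * (pgs[father] + pgs[mother])
        pgs[child] = (
            mid
            + shifts.get(groups[child], 0.0)
            + config.ptdt_overtransmission * mid_sd_theory
            + rp.normal(0.0, mid_sd_theory)
        )
    r2 = config.pgs_r2
    phen_rows = []
    for sid in samples:
        noise = rp.normal(0.0, 1.0)
        phen = math.sqrt(r2) * pgs[sid] + math.sqrt(1.0 - r2) * noise
        phen_rows.append({"sample_id": sid, "group": groups[sid], "pgs": pgs[sid], "phenotype": phen})
    phenotypes = pd.DataFrame(
        phen_rows, columns=["sample_id", "group", "pgs", "phenotype"]
    )

    # --- pairwise IBD ------------------------------------------------------
    ri = rngs["ibd"]
    relationships: dict[tuple[str, str], str] = {}
    for child, father, mother in trio_children:
        relationships[_pair_key(child, father)] = "parent_offspring"
        relationships[_pair_key(child, mother)] = "parent_offspring"
    for a, b in sib_pairs:
        relationships[_pair_key(a, b)] = "full_sibling"
    for a, b in spouse_pairs:
        relationships[_pair_key(a, b)] = "unrelated_or_unclassified"
    ibd_rows = []
    for (a, b), rel in sorted(relationships.items()):
        label = rel if rel != "unrelated_or_unclassified" else "unrelated"
        pi, z0, z1, z2 = _draw_ibd(ri, label if label != "unrelated" else "unrelated")
        ibd_rows.append({"id1": a, "id2": b, "PI_HAT": pi, "Z0": z0, "Z1": z1, "Z2": z2})
    ibd = pd.DataFrame(ibd_rows, columns=["id1", "id2", "PI_HAT", "Z0", "Z1", "Z2"])

    # --- planted CNV truth and common-region carriers ----------------------
    true_cnvs = []
    sample_set = set(samples)
    for spec in config.cnv_truth:
        if spec.chrom not in config.chrom_lengths:
            raise ConfigError(f"cnv_truth chromosome {spec.chrom!r} not in chrom_lengths")
        for carrier in spec.carriers:
            if carrier not in sample_set:
                raise ConfigError(f"cnv_truth carrier {carrier!r} not in cohort")
            true_cnvs.append(
                CNVCall(
                    sample_id=carrier,
                    chrom=spec.chrom,
                    start=spec.start,
                    end=spec.end,
                    type=spec.type,
                    n_snps=spec.resolved_n_snps(),
                    confidence=spec.confidence,
                    caller="truth",
                )
            )
    common_carriers: dict[CommonRegionSpec, list[str]] = {}
    for region in config.common_region_specs:
        carriers = [sid for sid in samples if rc.random() < region.freq]
        common_carriers[region] = carriers

    expected_means = {g: shifts.get(g, 0.0) for g in set(groups.values())}
    truth = TruthSet(
        true_cnvs=true_cnvs,
        true_relationships=relationships,
        true_group_means=expected_means,
        true_r2=r2,
        samples=samples,
        common_carriers=common_carriers,
        mendel_errors=mendel_errors,
    )
    bundle = CohortBundle(
        pedigree=pedigree,
        pcs=pcs,
        dosages=dosages,
        weights=weights,
        phenotypes=phenotypes,
        ibd=ibd,
        population_reference=population_reference,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# caller views


def _fragment(
    rng: np.random.Generator, start: int, end: int, max_gap: int
) -> list[tuple[int, int]]:
    """Split [start, end] into >= 2 fragments with internal gaps <= max_gap;
    the outer boundaries are preserved so a gap-merge recovers the span."""
    length = end - start + 1
    if length < 4 or max_gap < 1:
        return [(start, end)]
    n_frags = int(rng.integers(2, 4))
    n_gaps = n_frags - 1
    max_total_gap = min(n_gaps * max_gap, length - n_frags - 1)
    if max_total_gap < n_gaps:
        return [(start, end)]
    gaps = [int(rng.integers(1, min(max_gap, max_total_gap // n_gaps) + 1)) for _ in range(n_gaps)]
    frag_space = length - sum(gaps)
    cuts = sorted(rng.choice(np.arange(1, frag_space), size=n_frags - 1, replace=False))
    sizes = np.diff([0, *cuts, frag_space])
    frags = []
    pos = start
    for i, size in enumerate(sizes):
        frags.append((pos, pos + int(size) - 1))
        pos += int(size)
        if i < n_gaps:
            pos += gaps[i]
    assert frags[0][0] == start and frags[-1][1] == end
    return frags


def _jitter(
    rng: np.random.Generator, start: int, end: int, jitter: int, chrom_len: int
) -> tuple[int, int]:
    if jitter == 0:
        return start, end
    s = start + int(rng.integers(-jitter, jitter + 1))
    e = end + int(rng.integers(-jitter, jitter + 1))
    s = max(1, min(s, chrom_len))
    e = max(1, min(e, chrom_len))
    if s > e:
        s, e = e, s
    return s, e


def generate_caller_views(
    truth: TruthSet, config: SimConfig
) -> tuple[list[CNVCall], list[CNVCall], pd.DataFrame]:
    """Noisy per-caller views of the truth plus a per-sample intensity QC
    table.

    Each true CNV appears in each caller with probability
    ``detection_rate``, fragmented with probability ``fragmentation_rate``
    (gaps <= ``max_fragment_gap_bp``, outer span preserved) and jittered by
    up to ``boundary_jitter_bp`` per boundary. Common-region carrier calls
    appear identically in both callers. False positives are caller-private
    by construction (Poisson(``fp_rate``) per sample per caller, placed to
    avoid all other calls), so consensus removes them.
    """
    views: dict[str, list[CNVCall]] = {"A": [], "B": []}
    occupied: dict[str, list[tuple[str, int, int]]] = {"A": [], "B": []}
    rngs = _rngs(config.seed)

    for caller in ("A", "B"):
        rng = rngs[f"views_{caller.lower()}"]
        for cnv in truth.true_cnvs:
            if rng.random() >= config.detection_rate:
                continue
            chrom_len = config.chrom_lengths[cnv.chrom]
            if rng.random() < config.fragmentation_rate:
                frags = _fragment(rng, cnv.start, cnv.end, config.max_fragment_gap_bp)
            else:
                frags = [(cnv.start, cnv.end)]
            total = sum(e - s + 1 for s, e in frags)
            for s, e in frags:
                js, je = _jitter(rng, s, e, config.boundary_jitter_bp, chrom_len)
                n_snps = max(1, round((cnv.n_snps or 0) * (e - s + 1) / total)) if cnv.n_snps else None
                views[caller].append(
                    CNVCall(
                        sample_id=cnv.sample_id,
                        chrom=cnv.chrom,
                        start=js,
                        end=je,
                        type=cnv.type,
                        n_snps=n_snps if caller == "A" else None,
                        confidence=cnv.confidence if caller == "A" else None,
                        caller=caller,
                    )
                )
                occupied[caller].append((f"{cnv.sample_id}:{cnv.chrom}", js, je))
        for region, carriers in truth.common_carriers.items():
            for sid in carriers:
                views[caller].append(
                    CNVCall(
                        sample_id=sid,
                        chrom=region.chrom,
                        start=region.start,
                        end=region.end,
                        type=region.type,
                        n_snps=max(10, (region.end - region.start + 1) // 5_000) if caller == "A" else None,
                        confidence=30.0 if caller == "A" else None,
                        caller=caller,
                    )
                )
                occupied[caller].append((f"{sid}:{region.chrom}", region.start, region.end))

    # false positives: placed to avoid any true call and the other caller's FPs
    chroms = list(config.chrom_lengths)
    for caller in ("A", "B"):
        rng = rngs[f"views_{caller.lower()}"]
        for sid in truth.samples:
            n_fp = rng.poisson(config.fp_rate)
            for _ in range(n_fp):
                for _attempt in range(100):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    length = int(rng.integers(25_000, 80_000))
                    start = int(rng.integers(1, config.chrom_lengths[chrom] - length))
                    end = start + length - 1
                    key = f"{sid}:{chrom}"
                    clash = any(
                        k == key and not (end < s or start > e)
                        for view in (occupied["A"], occupied["B"])
                        for k, s, e in view
                    )
                    if not clash:
                        break
                else:
                    continue
                views[caller].append(
                    CNVCall(
                        sample_id=sid,
                        chrom=chrom,
                        start=start,
                        end=end,
                        type="deletion" if rng.random() < 0.5 else "duplication",
                        n_snps=15 if caller == "A" else None,
                        confidence=25.0 if caller == "A" else None,
                        caller=caller,
                    )
                )
                occupied[caller].append((f"{sid}:{chrom}", start, end))

    # per-sample intensity QC stats, with optional planted outliers
    rq = rngs["qc"]
    n = len(truth.samples)
    qc = pd.DataFrame(
        {
            "sample_id": truth.samples,
            "LRRSD": rq.normal(0.12, 0.02, size=n),
            "BAFSD": rq.normal(0.04, 0.008, size=n),
            "GCWF": rq.normal(0.0, 0.01, size=n),
        }
    )
    for i in range(min(config.n_qc_outliers, n)):
        qc.loc[i, "LRRSD"] = 0.12 + 10 * 0.02

    order = lambda c: (c.sample_id, c.chrom, c.start, c.end, c.type)  # noqa: E731
    return sorted(views["A"], key=order), sorted(views["B"], key=order), qc


# ---------------------------------------------------------------------------
# reference tracks on the miniature genome


def generate_reference_tracks(config: SimConfig) -> dict[str, object]:
    """Deterministic reference tracks in the mini-genome coordinate space.

    Returns a dict with frames (cytobands, centromeres, mhc_region,
    segdups, benign_catalog, common_external, gnomad_freqs, exons) and
    object lists (genes: GeneModel, pathogenic: PathogenicRegion). All
    coordinates 1-based inclusive.
    """
    cyto_rows, cent_rows, segdup_rows, benign_rows, gnomad_rows = [], [], [], [], []
    genes: list[GeneModel] = []
    exon_rows = []
    band_names = ("p2", "p1", "q1", "q2")
    for chrom, length in config.chrom_lengths.items():
        q = length // 4
        bounds = [1, q + 1, 2 * q + 1, 3 * q + 1, length + 1]
        for i, band in enumerate(band_names):
            cyto_rows.append(
                {"chrom": chrom, "start": bounds[i], "end": bounds[i + 1] - 1, "band": f"{chrom.replace('chr', '')}{band}"}
            )
        mid = length // 2
        cent_rows.append({"chrom": chrom, "start": mid - 100_000 + 1, "end": mid + 100_000})
        segdup_rows.append({"chrom": chrom, "start": 30_000_001, "end": 30_500_000})
        benign_rows.append({"chrom": chrom, "start": 35_000_001, "end": 35_400_000})
        gnomad_rows.append(
            {"chrom": chrom, "start": 20_000_001, "end": 20_100_000, "freq": 0.05}
        )
        # genes every 50 kb: 20 kb span, four 1 kb exons
        for k in range(0, length // 50_000):
            gs = k * 50_000 + 1
            ge = gs + 20_000 - 1
            if ge > length:
                break
            exons = tuple((gs + off, gs + off + 999) for off in (0, 6_000, 12_000, 18_000))
            sym = f"G_{chrom}_{k:04d}"
            genes.append(GeneModel(symbol=sym, chrom=chrom, gene_start=gs, gene_end=ge, exons=exons))
            for es, ee in exons:
                exon_rows.append({"chrom": chrom, "start": es, "end": ee, "name": sym})

    chroms = list(config.chrom_lengths)
    mhc_chrom = chroms[-1]
    mhc = pd.DataFrame(
        [{"chrom": mhc_chrom, "start": 40_000_001, "end": 41_000_000}]
    )
    first = chroms[0]
    pathogenic = [
        PathogenicRegion(
            name="SYN_REGION_CG",
            chrom=first,
            start=10_000_001,
            end=11_000_000,
            type_constraint="either",
            critical_genes=(
                GeneModel(
                    symbol="SYNCG1",
                    chrom=first,
                    gene_start=10_400_001,
                    gene_end=10_450_000,
                    exons=((10_400_001, 10_401_000), (10_430_001, 10_431_000)),
                ),
            ),
            source="synthetic",
        ),
        PathogenicRegion(
            name="SYN_REGION_80",
            chrom=chroms[min(1, len(chroms) - 1)],
            start=5_000_001,
            end=6_000_000,
            type_constraint="deletion",
            source="synthetic",
        ),
    ]
    return {
        "cytobands": pd.DataFrame(cyto_rows),
        "centromeres": pd.DataFrame(cent_rows),
        "mhc_region": mhc,
        "segdups": pd.DataFrame(segdup_rows),
        "benign_catalog": pd.DataFrame(benign_rows),
        "common_external": pd.DataFrame(benign_rows),  # same default track
        "gnomad_freqs": pd.DataFrame(gnomad_rows),
        "exons": pd.DataFrame(exon_rows),
        "genes": genes,
        "pathogenic": pathogenic,
    }


# ---------------------------------------------------------------------------
# emission


def write_bundle(
    bundle: CohortBundle,
    views_a: Sequence[CNVCall],
    views_b: Sequence[CNVCall],
    qc: pd.DataFrame,
    tracks: Mapping[str, object],
    outdir: str | Path,
) -> None:
    """Write every emitted file: rawcnv text for caller A, TSV for caller
    B, BED for reference tracks, TSV for all tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_rawcnv(views_a, out / "caller_a.rawcnv")
    write_call_table(views_b, out / "caller_b.tsv")
    qc.to_csv(out / "intensity_qc.tsv", sep="\t", index=False)
    bundle.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    bundle.pcs.to_csv(out / "pcs.tsv", sep="\t", index=False)
    bundle.dosages.to_csv(out / "dosages.tsv", sep="\t")
    bundle.weights.to_csv(out / "weights.tsv", sep="\t", index=False)
    bundle.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    bundle.ibd.to_csv(out / "ibd.tsv", sep="\t", index=False)
    bundle.population_reference.to_csv(out / "population_reference.tsv", sep="\t", index=False)
    for name in ("cytobands", "centromeres", "mhc_region", "segdups",
                 "benign_catalog", "common_external", "exons"):
        write_bed(pd.DataFrame(tracks[name]), out / f"{name}.bed")
    pd.DataFrame(tracks["gnomad_freqs"]).to_csv(out / "gnomad_freqs.tsv", sep="\t", index=False)
    write_gene_models(list(tracks["genes"]), out / "genes.tsv")
    write_pathogenic_regions(list(tracks["pathogenic"]), out / "pathogenic_regions.tsv")


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> TruthSet:
    """End-to-end generation: cohort, caller views, tracks, files."""
    bundle, truth = generate_cohort(config)
    views_a, views_b, qc = generate_caller_views(truth, config)
    tracks = generate_reference_tracks(config)
    write_bundle(bundle, views_a, views_b, qc, tracks, outdir)
    truth_frame = calls_to_frame(truth.true_cnvs)
    truth_frame.to_csv(Path(outdir) / "truth_cnvs.tsv", sep="\t", index=False)
    return truth
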