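"""Relationship classification from IBD sharing, sex checks, Mendelian
error rates, PC-based ancestry assignment and nearest-neighbour control
matching."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MONOZYGOTIC = "monozygotic"
PARENT_OFFSPRING = "parent_offspring"
FULL_SIBLING = "full_sibling"
HALF_SIBLING = "half_sibling_or_2nd_degree"
UNRELATED = "unrelated_or_unclassified"

RELATIONSHIP_LABELS = (
    MONOZYGOTIC,
    PARENT_OFFSPRING,
    FULL_SIBLING,
    HALF_SIBLING,
    UNRELATED,
)


class ValidationError(ValueError):
    """IBD statistics violate their internal-consistency invariants."""


@dataclass(frozen=True)
class PairIBD:
    """Pairwise identity-by-descent summary."""

    id1: str
    id2: str
    PI_HAT: float
    Z0: float
    Z1: float
    Z2: float

    def validate(self, tol: float = 0.01) -> None:
        if abs(self.Z0 + self.Z1 + self.Z2 - 1.0) > tol:
            raise ValidationError(
                f"{self.id1}-{self.id2}: Z0+Z1+Z2 = "
                f"{self.Z0 + self.Z1 + self.Z2:.4f} != 1"
            )
        if abs(self.PI_HAT - (0.5 * self.Z1 + self.Z2)) > tol:
            raise ValidationError(
                f"{self.id1}-{self.id2}: PI_HAT {self.PI_HAT:.4f} != "
                f"0.5*Z1 + Z2 = {0.5 * self.Z1 + self.Z2:.4f}"
            )


@dataclass(frozen=True)
class SexCheckRecord:
    sample_id: str
    reported_sex: str  # "male" | "female" | "unknown"
    x_inbreeding_F: float
    genome_F: float = 0.0


@dataclass(frozen=True)
class AncestryAssignment:
    sample_id: str
    pc_coords: tuple[float, ...]
    label: str
    ambiguous: bool = False


def classify_relationship(pair: PairIBD) -> str:
    """Threshold-rule classification with fixed precedence
    MZ -> parent-offspring -> full-sibling -> half-sibling -> unrelated;
    the first matching rule wins."""
    pair.validate()
    p, z1, z2 = pair.PI_HAT, pair.Z1, pair.Z2
    if p > 0.8 and z2 > 0.8:
        return MONOZYGOTIC
    if p > 0.45 and z1 > 0.8 and z2 < 0.1:
        return PARENT_OFFSPRING
    if p > 0.35 and 0.3 < z1 < 0.8 and z2 > 0.1:
        return FULL_SIBLING
    if p > 0.1 and z1 > 0.45 and z2 < 0.1:
        return HALF_SIBLING
    return UNRELATED


def classify_pairs(ibd: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a pairwise-IBD table (columns id1, id2,
    PI_HAT, Z0, Z1, Z2; PLINK-style IID1/IID2 headers also accepted)."""
    cols = {c.upper(): c for c in ibd.columns}
    id1 = cols.get("ID1", cols.get("IID1"))
    id2 = cols.get("ID2", cols.get("IID2"))
    if id1 is None or id2 is None:
        raise ValueError("IBD table needs id1/id2 (or IID1/IID2) columns")
    out = []
    for row in ibd.itertuples(index=False):
        d = row._asdict()
        pair = PairIBD(
            id1=str(d[id1]),
            id2=str(d[id2]),
            PI_HAT=float(d[cols["PI_HAT"]]),
            Z0=float(d[cols["Z0"]]),
            Z1=float(d[cols["Z1"]]),
            Z2=float(d[cols["Z2"]]),
        )
        out.append(
            {"id1": pair.id1, "id2": pair.id2, "relationship": classify_relationship(pair)}
        )
    return pd.DataFrame(out, columns=["id1", "id2", "relationship"])


def sex_check(
    record: SexCheckRecord,
    female_max_F: float = 0.25,
    male_min_F: float = 0.75,
    rescue_genome_F: float = 0.05,
) -> str:
    """Compare X-chromosome inbreeding against reported sex.

    Genetic sex is female below ``female_max_F``, male above ``male_min_F``,
    inconclusive in between. Reported females in the inconclusive band are
    rescued when the genome-wide inbreeding coefficient is >=
    ``rescue_genome_F`` (consistent with consanguineous ancestry inflating
    X homozygosity); a clear genetic sex conflicting with the report is a
    mismatch; everything else is excluded as inconclusive.
    """
    x = record.x_inbreeding_F
    if x < female_max_F:
        genetic = "female"
    elif x > male_min_F:
        genetic = "male"
    else:
        genetic = None
    if genetic is not None:
        if record.reported_sex == genetic:
            return "consistent"
        if record.reported_sex in ("male", "female"):
            return "mismatch"
        return "inconclusive_excluded"
    if record.reported_sex == "female" and record.genome_F >= rescue_genome_F:
        return "rescued_female"
    return "inconclusive_excluded"


_HALF = {0: (0,), 1: (0, 1), 2: (1,)}


def _possible_children(father: int, mother: int) -> set[int]:
    return {a + b for a in _HALF[father] for b in _HALF[mother]}


def mendelian_error_rate(
    child: Sequence[float],
    father: Sequence[float],
    mother: Sequence[float],
) -> float:
    """Fraction of tested variants where the child dosage is impossible
    given parental dosages. Variants with any missing member (NaN or a
    value outside {0,1,2}) are not tested."""
    c = np.asarray(child, dtype=float)
    f = np.asarray(father, dtype=float)
    m = np.asarray(mother, dtype=float)
    if not (len(c) == len(f) == len(m)):
        raise ValueError("genotype vectors must have equal length")
    if len(c) == 0:
        raise ValueError("empty variant panel")
    valid = np.isin(c, (0, 1, 2)) & np.isin(f, (0, 1, 2)) & np.isin(m, (0, 1, 2))
    tested = int(valid.sum())
    if tested == 0:
        raise ValueError("no testable variants (all missing)")
    errors = sum(
        int(ci) not in _possible_children(int(fi), int(mi))
        for ci, fi, mi in zip(c[valid], f[valid], m[valid])
    )
    return errors / tested


def assign_ancestry(
    sample_id: str,
    coords: Sequence[float],
    populations: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    n_sd: float = 4.0,
) -> AncestryAssignment:
    """Assign a population label when every coordinate lies within ``n_sd``
    SDs of that population's mean; no candidate -> "other"; several
    candidates -> nearest by SD-scaled Euclidean distance, flagged."""
    if not populations:
        raise ValueError("populations must be non-empty")
    x = np.asarray(coords, dtype=float)
    candidates = []
    for label, (mean, sd) in populations.items():
        mu = np.asarray(mean, dtype=float)
        sigma = np.asarray(sd, dtype=float)
        if mu.shape != x.shape or sigma.shape != x.shape:
            raise ValueError(
                f"dimension mismatch for population {label}: "
                f"coords {x.shape}, mean {mu.shape}, sd {sigma.shape}"
            )
        if np.all(np.abs(x - mu) <= n_sd * sigma):
            dist = float(np.sqrt(np.sum(((x - mu) / sigma) ** 2)))
            candidates.append((dist, label))
    if not candidates:
        return AncestryAssignment(sample_id, tuple(x), "other")
    candidates.sort()
    return AncestryAssignment(
        sample_id, tuple(x), candidates[0][1], ambiguous=len(candidates) > 1
    )


def match_controls(
    cases: Mapping[str, Sequence[float]],
    pool: Mapping[str, Sequence[float]],
    k: int = 5,
    n_pcs: int = 3,
    replace: bool = False,
) -> dict[str, list[str]]:
    """For each case, the ``k`` nearest pool members by Euclidean distance
    on the first ``n_pcs`` coordinates.

    Default mode is greedy without replacement in ascending case-identifier
    order; ties are broken by pool identifier.
    """
    if not replace and len(pool) < k * len(cases):
        raise ValueError(
            f"pool of {len(pool)} cannot supply {k} controls each "
            f"for {len(cases)} cases without replacement"
        )
    pool_ids = sorted(pool)
    pool_mat = np.asarray([list(pool[i])[:n_pcs] for i in pool_ids], dtype=float)
    available = np.ones(len(pool_ids), dtype=bool)
    out: dict[str, list[str]] = {}
    for case_id in sorted(cases):
        x = np.asarray(list(cases[case_id])[:n_pcs], dtype=float)
        d = np.sqrt(((pool_mat - x) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(len(pool_ids)), d))
        chosen = []
        for j in order:
            if replace or available[j]:
                chosen.append(pool_ids[j])
                if not replace:
                    available[j] = False
                if len(chosen) == k:
                    break
        out[case_id] = chosen
    return out
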