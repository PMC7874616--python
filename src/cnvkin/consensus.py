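"""Greedy merging of fragmented CNV calls and dual-caller consensus.

Fragment merging repairs callers that artificially split one large event
into several adjacent calls: within a (chromosome, type) stratum that is
busy enough to look fragmented, adjacent calls are coalesced first under a
fixed gap ceiling and then under a gap ceiling proportional to the
neighbouring call length, iterated to a fixpoint.

Consensus keeps only events seen by both callers with sufficient
reciprocal overlap and matching copy-number direction; the consensus
segment is the intersection of the two supporting calls.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal, Sequence

from cnvkin.calls import CNVCall
from cnvkin.intervals import intersection_length, interval_length

NeighbourRule = Literal["longer", "shorter", "left", "right"]


class ContractViolationError(ValueError):
    """Raised when inputs break an operation precondition."""


def _merge_pair(a: CNVCall, b: CNVCall) -> CNVCall:
    """Coalesce two calls of one stratum: span hull, n_snps summed,
    confidence = max."""
    snps = None
    if a.n_snps is not None or b.n_snps is not None:
        snps = (a.n_snps or 0) + (b.n_snps or 0)
    confs = [c.confidence for c in (a, b) if c.confidence is not None]
    return replace(
        a,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        n_snps=snps,
        confidence=max(confs) if confs else None,
    )


def _neighbour_length(a: CNVCall, b: CNVCall, rule: NeighbourRule) -> int:
    if rule == "longer":
        return max(a.length, b.length)
    if rule == "shorter":
        return min(a.length, b.length)
    if rule == "left":
        return a.length
    if rule == "right":
        return b.length
    raise ValueError(f"unknown neighbour rule {rule!r}")


def _sweep(
    calls: list[CNVCall],
    mergeable,
) -> tuple[list[CNVCall], bool]:
    """One left-to-right pass merging adjacent calls where ``mergeable(a, b)``."""
    if not calls:
        return calls, False
    out = [calls[0]]
    changed = False
    for nxt in calls[1:]:
        cur = out[-1]
        if mergeable(cur, nxt):
            out[-1] = _merge_pair(cur, nxt)
            changed = True
        else:
            out.append(nxt)
    return out, changed


def _merge_stratum(
    calls: list[CNVCall],
    max_gap_bp: int,
    gap_fraction: float,
    neighbour_rule: NeighbourRule,
) -> list[CNVCall]:
    calls = sorted(calls, key=lambda c: (c.start, c.end))

    def gap(a: CNVCall, b: CNVCall) -> int:
        return b.start - a.end - 1

    def rule_fixed(a: CNVCall, b: CNVCall) -> bool:
        return gap(a, b) <= max_gap_bp

    def rule_fractional(a: CNVCall, b: CNVCall) -> bool:
        return gap(a, b) <= gap_fraction * _neighbour_length(a, b, neighbour_rule)

    changed = True
    while changed:
        changed = False
        for rule in (rule_fixed, rule_fractional):
            pass_changed = True
            while pass_changed:
                calls, pass_changed = _sweep(calls, rule)
                changed = changed or pass_changed
    return calls


def merge_fragments(
    calls: Sequence[CNVCall],
    max_gap_bp: int = 100_000,
    gap_fraction: float = 0.25,
    trigger_count: int = 5,
    neighbour_rule: NeighbourRule = "longer",
) -> list[CNVCall]:
    """Merge fragmented calls for one sample from one caller.

    Merging is applied only within (chromosome, type) strata holding
    strictly more than ``trigger_count`` calls. Within a triggered stratum,
    calls sorted by start are coalesced left-to-right whenever the gap
    between neighbours is <= ``max_gap_bp``, then whenever the gap is
    <= ``gap_fraction`` x the length of the neighbouring call (by default
    the longer of the two); both rules are iterated to a fixpoint.

    Output order is by (chromosome, type, start). Idempotent.
    """
    calls = list(calls)
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    callers = {c.caller for c in calls}
    if len(samples) > 1 or len(callers) > 1:
        raise ContractViolationError(
            f"merge_fragments expects one sample and one caller, "
            f"got samples={sorted(samples)} callers={sorted(callers)}"
        )
    strata: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        strata.setdefault((c.chrom, c.type), []).append(c)
    out: list[CNVCall] = []
    for key in sorted(strata):
        group = strata[key]
        if len(group) > trigger_count:
            group = _merge_stratum(group, max_gap_bp, gap_fraction, neighbour_rule)
        else:
            group = sorted(group, key=lambda c: (c.start, c.end))
        out.extend(group)
    return out


def intersect_callers(
    calls_a: Sequence[CNVCall],
    calls_b: Sequence[CNVCall],
    min_overlap: float = 0.5,
    reciprocal: bool = True,
) -> list[CNVCall]:
    """Intersect two callers' (post-merge) call sets into consensus calls.

    A pair of same-sample, same-chromosome, same-type calls (a, b) supports
    a consensus call iff the shared length is >= ``min_overlap`` of both
    call lengths (``reciprocal=True``, default) or of either length
    (``reciprocal=False``). Consensus coordinates are the intersection;
    n_snps and confidence come from the caller-A member. Each input call
    supports at most one consensus call: candidate pairs are ranked by the
    smaller of the two overlap fractions (ties by caller-A start, then
    caller-B start) and assigned greedily.
    """
    by_stratum_b: dict[tuple[str, str, str], list[CNVCall]] = {}
    for b in calls_b:
        by_stratum_b.setdefault((b.sample_id, b.chrom, b.type), []).append(b)

    candidates: list[tuple[float, int, int, CNVCall, CNVCall, int]] = []
    for ia, a in enumerate(calls_a):
        for b in by_stratum_b.get((a.sample_id, a.chrom, a.type), []):
            o = intersection_length(a.start, a.end, b.start, b.end)
            if o == 0:
                continue
            fa = o / a.length
            fb = o / b.length
            ok = (min(fa, fb) >= min_overlap) if reciprocal else (max(fa, fb) >= min_overlap)
            if ok:
                candidates.append((min(fa, fb), a.start, b.start, a, b, ia))

    # best reciprocal partner first; deterministic tie-breaking by start
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[5]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    consensus: list[CNVCall] = []
    for _frac, _sa, _sb, a, b, ia in candidates:
        ib = id(b)
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        consensus.append(
            CNVCall(
                sample_id=a.sample_id,
                chrom=a.chrom,
                start=max(a.start, b.start),
                end=min(a.end, b.end),
                type=a.type,
                n_snps=a.n_snps,
                confidence=a.confidence,
                caller="consensus",
            )
        )
    consensus.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.type))
    return consensus
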