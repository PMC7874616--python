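"""Independent brute-force oracles used to validate the fast paths.

Everything here works on explicit base-position sets or exhaustive
all-pairs scans, deliberately ignoring the implementations under test.
"""

from __future__ import annotations

import itertools

from cnvkin.calls import CNVCall


def positions(start: int, end: int) -> set[int]:
    return set(range(start, end + 1))


def overlap_len_sets(s1: int, e1: int, s2: int, e2: int) -> int:
    return len(positions(s1, e1) & positions(s2, e2))


def brute_merge(
    calls: list[CNVCall],
    max_gap_bp: int,
    gap_fraction: float,
    trigger_count: int,
    neighbour_rule: str = "longer",
) -> list[CNVCall]:
    """All-pairs repeated merging to a fixpoint, per (chrom, type) stratum."""
    strata: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        strata.setdefault((c.chrom, c.type), []).append(c)
    out = []
    for key in sorted(strata):
        group = list(strata[key])
        if len(group) <= trigger_count:
            out.extend(sorted(group, key=lambda c: (c.start, c.end)))
            continue
        changed = True
        while changed:
            changed = False
            for a, b in itertools.combinations(list(group), 2):
                if a not in group or b not in group:
                    continue
                lo, hi = (a, b) if a.start <= b.start else (b, a)
                gap = hi.start - lo.end - 1
                if neighbour_rule == "longer":
                    nb = max(a.length, b.length)
                elif neighbour_rule == "shorter":
                    nb = min(a.length, b.length)
                else:
                    raise NotImplementedError(neighbour_rule)
                if gap <= max_gap_bp or gap <= gap_fraction * nb:
                    snps = None
                    if a.n_snps is not None or b.n_snps is not None:
                        snps = (a.n_snps or 0) + (b.n_snps or 0)
                    confs = [x.confidence for x in (a, b) if x.confidence is not None]
                    merged = CNVCall(
                        sample_id=a.sample_id,
                        chrom=a.chrom,
                        start=min(a.start, b.start),
                        end=max(a.end, b.end),
                        type=a.type,
                        n_snps=snps,
                        confidence=max(confs) if confs else None,
                        caller=a.caller,
                    )
                    group.remove(a)
                    group.remove(b)
                    group.append(merged)
                    changed = True
                    break
        out.extend(sorted(group, key=lambda c: (c.start, c.end)))
    return out


def brute_consensus(
    calls_a: list[CNVCall],
    calls_b: list[CNVCall],
    min_overlap: float,
) -> list[tuple[str, str, int, int, str]]:
    """Naive all-pairs consensus using per-base position sets; returns
    sorted consensus keys. Tie-breaking mirrors the documented contract:
    candidates ranked by min overlap fraction desc, then caller-A start,
    caller-B start, caller-A input order."""
    cands = []
    for ia, a in enumerate(calls_a):
        for b in calls_b:
            if (a.sample_id, a.chrom, a.type) != (b.sample_id, b.chrom, b.type):
                continue
            shared = positions(a.start, a.end) & positions(b.start, b.end)
            if not shared:
                continue
            fa = len(shared) / len(positions(a.start, a.end))
            fb = len(shared) / len(positions(b.start, b.end))
            if min(fa, fb) >= min_overlap:
                cands.append((min(fa, fb), a.start, b.start, ia, a, b, shared))
    cands.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    used_a, used_b, out = set(), set(), []
    for _f, _sa, _sb, ia, a, b, shared in cands:
        if ia in used_a or id(b) in used_b:
            continue
        used_a.add(ia)
        used_b.add(id(b))
        out.append((a.sample_id, a.chrom, min(shared), max(shared), a.type))
    return sorted(out)


def brute_coverage_mask(
    intervals: list[tuple[int, int]], min_support: int
) -> list[tuple[int, int]]:
    """Per-base coverage counting on a single chromosome."""
    depth: dict[int, int] = {}
    for s, e in intervals:
        for p in range(s, e + 1):
            depth[p] = depth.get(p, 0) + 1
    hot = sorted(p for p, d in depth.items() if d >= min_support)
    regions = []
    for p in hot:
        if regions and p == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], p)
        else:
            regions.append((p, p))
    return regions


def mendel_error_table() -> dict[tuple[int, int, int], bool]:
    """Exhaustive truth table over all 27 (father, mother, child) dosage
    triples: True = Mendelian error."""
    table = {}
    half = {0: {0}, 1: {0, 1}, 2: {1}}
    for f in (0, 1, 2):
        for m in (0, 1, 2):
            possible = {a + b for a in half[f] for b in half[m]}
            for c in (0, 1, 2):
                table[(f, m, c)] = c not in possible
    return table
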