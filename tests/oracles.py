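"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: digestion is done by
enumerating cleavage boundaries, motif scanning by checking every window,
and site detection/classification by a direct transcription of the rules
(>75% best confidence and >=2 phospho-PSMs per replicate; detected =
passes in >=1 replicate; shared_all > mitotic_shared > unique_starred >
other).
"""

from __future__ import annotations


def brute_force_digest(sequence: str, max_missed: int) -> list[tuple[int, int, int]]:
    """All tryptic (start, end, missed) spans, 1-based inclusive, sorted."""
    n = len(sequence)
    cut_after = [
        i + 1
        for i in range(n)
        if sequence[i] in "KR" and (i + 1 == n or sequence[i + 1] != "P")
    ]
    boundaries = sorted({0, n, *[c for c in cut_after if c < n]})
    spans = []
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(boundaries))):
            spans.append((boundaries[a] + 1, boundaries[b], b - a - 1))
    return sorted(spans)


def brute_force_motif_scan(
    sequence: str, classes: list[frozenset], acceptor_offset: int
) -> list[tuple[int, int, int]]:
    """All (match_start, match_end, acceptor_position) windows matching."""
    k = len(classes)
    out = []
    for start in range(1, len(sequence) - k + 2):
        window = sequence[start - 1 : start - 1 + k]
        if all(aa in cls for aa, cls in zip(window, classes)):
            out.append((start, start + k - 1, start + acceptor_offset - 1))
    return out


def brute_force_site_analysis(
    evidence_rows: list[dict],
    conditions: list[str],
    reference: str,
    n_replicates: int,
    confidence: float = 75.0,
    min_psms: int = 2,
    min_star_reps: int = 2,
) -> dict:
    """Recount detection, means, and categories from raw evidence rows.

    ``evidence_rows``: dicts with position, residue, condition, replicate,
    count, best_prob. Returns per-site records plus summary counts.
    """
    mitotic = [c for c in conditions if c != reference]
    positions = sorted({(r["position"], r["residue"]) for r in evidence_rows})
    sites = {}
    for pos, residue in positions:
        per_cond = {}
        for cond in conditions:
            rows = [
                r for r in evidence_rows
                if r["position"] == pos and r["condition"] == cond
            ]
            passing = 0
            total = 0
            for r in rows:
                total += r["count"]
                if r["best_prob"] > confidence and r["count"] >= min_psms:
                    passing += 1
            per_cond[cond] = {
                "mean": total / n_replicates,
                "passing": passing,
                "detected": passing >= 1,
            }
        detected_conds = [c for c in conditions if per_cond[c]["detected"]]
        if not detected_conds:
            continue
        if len(detected_conds) == len(conditions):
            category = "shared_all"
        elif all(per_cond[c]["detected"] for c in mitotic) and not per_cond[reference]["detected"]:
            category = "mitotic_shared"
        elif (
            len(detected_conds) == 1
            and per_cond[detected_conds[0]]["passing"] >= min_star_reps
        ):
            category = "unique_starred"
        else:
            category = "other"
        sites[(pos, residue)] = {"per_cond": per_cond, "category": category}
    report = {
        "per_condition": {
            c: sum(1 for s in sites.values() if s["per_cond"][c]["detected"])
            for c in conditions
        },
        "union": len(sites),
    }
    for cat in ("shared_all", "mitotic_shared", "unique_starred", "other"):
        report[cat] = sum(1 for s in sites.values() if s["category"] == cat)
    return {"sites": sites, "report": report}
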