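"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and direct per-substring counting
rather than the vectorised/prefix-sum code paths of the package.
"""

from __future__ import annotations

import statistics


def brute_force_upregulated(values, gene_map, pairs, min_fold=2.0, min_lines=6):
    """Per-element loop over pairs; gene passes when any element passes."""
    genes = set()
    for element in values.index:
        n_up = 0
        for untreated, treated in pairs:
            if values.loc[element, treated] / values.loc[element, untreated] >= min_fold:
                n_up += 1
        if n_up >= min_lines:
            genes.add(gene_map.loc[element])
    return genes


def brute_force_downregulated(values, gene_map, tumor_cols, normal_cols):
    genes = set()
    for element in values.index:
        med_t = statistics.median(values.loc[element, c] for c in tumor_cols)
        med_n = statistics.median(values.loc[element, c] for c in normal_cols)
        if med_t < med_n:
            genes.add(gene_map.loc[element])
    return genes


def island_oracle(seq, gc_min=55.0, oe_min=0.65, min_length=500):
    """Exhaustive substring scan: every >= min_length substring is tested for
    the GC and CpG observed/expected criteria by incremental direct counting;
    maximal valid segments are kept, with greedy longest-first overlap
    resolution.  Returns a sorted list of (start, end) pairs."""
    seq = seq.upper()
    length = len(seq)
    best_end = [-1] * length
    for i in range(0, length - min_length + 1):
        c = g = cg = 0
        prev = ""
        best = -1
        for j in range(i, length):
            base = seq[j]
            if base == "C":
                c += 1
            elif base == "G":
                g += 1
                if prev == "C":
                    cg += 1
            elif base not in ("A", "T"):
                break  # ambiguous base invalidates every longer substring
            prev = base
            n = j - i + 1
            if n >= min_length and c > 0 and g > 0:
                if 100.0 * (c + g) >= gc_min * n and cg * n >= oe_min * c * g:
                    best = j + 1
        best_end[i] = best
    segments = []
    run_max = -1
    for i, j in enumerate(best_end):
        if j > run_max:
            segments.append((i, j))
            run_max = j
    kept = []
    for seg in sorted(segments, key=lambda s: (s[0] - s[1], s[0])):
        if all(seg[1] <= k[0] or seg[0] >= k[1] for k in kept):
            kept.append(seg)
    return sorted(kept)


def auc_pair_counting(case_scores, control_scores):
    """O(n^2) Mann-Whitney: mean over case/control pairs of win=1, tie=0.5."""
    total = 0.0
    for cs in case_scores:
        for ns in control_scores:
            if cs > ns:
                total += 1.0
            elif cs == ns:
                total += 0.5
    return total / (len(case_scores) * len(control_scores))
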