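"""Independent scoring/enumeration oracles shared by the test modules.

These re-derive the documented alignment scoring model from scratch and
enumerate chains recursively; they never call the package's DP internals.
"""

import math

import subtelomap as st


def oracle_transition(p: st.ScoringParams, dm, dr, n_extra, n_miss):
    sd = max(p.rel_sd * dr, p.abs_sd, 1e-9)
    half_z2 = 0.5 * ((dm - dr) / sd) ** 2
    reward = max(0.0, math.log(p.site_density_bp / (sd * math.sqrt(2 * math.pi))))
    if half_z2 >= p.outlier_penalty:
        return reward - p.outlier_penalty
    return reward - half_z2 - n_extra * p.extra_penalty - n_miss * p.miss_penalty


def oracle_best_score(labels, sites, p: st.ScoringParams, ref_length: float):
    """Best score over every monotone chain with >= 2 pairs.

    Chain ends are free except that unmatched labels beyond the chain which
    would project inside the reference are charged the extra-label penalty
    (semi-global in the molecule).
    """
    n, m = len(labels), len(sites)
    best = [None]

    def end_charges(i0, j0, i1, j1):
        start = sum(
            1 for k in range(i0) if labels[k] >= labels[i0] - sites[j0]
        )
        end = sum(
            1 for k in range(i1 + 1, n)
            if labels[k] <= labels[i1] + (ref_length - sites[j1])
        )
        return (start + end) * p.extra_penalty

    def extend(chain, score):
        i0, j0 = chain[0]
        i1, j1 = chain[-1]
        if len(chain) >= 2:
            total = score - end_charges(i0, j0, i1, j1)
            if best[0] is None or total > best[0]:
                best[0] = total
        for i in range(i1 + 1, min(i1 + 2 + p.max_skips, n)):
            for j in range(j1 + 1, min(j1 + 2 + p.max_skips, m)):
                t = oracle_transition(
                    p, labels[i] - labels[i1], sites[j] - sites[j1],
                    i - i1 - 1, j - j1 - 1,
                )
                extend(chain + [(i, j)], score + t + p.match_bonus)

    for i in range(n):
        for j in range(m):
            extend([(i, j)], p.match_bonus)
    return best[0]


def oracle_both_orientations(molecule, sites, p: st.ScoringParams, ref_length: float):
    scores = []
    for orientation in ("forward", "reverse"):
        labels = st.align.orient_labels(molecule, orientation)
        s = oracle_best_score(list(map(float, labels)), sites, p, ref_length)
        if s is not None:
            scores.append(s)
    return max(scores) if scores else None


def brute_force_nick(sequence: str, motif: str):
    """Sliding-window scan of both strands."""
    rc = st.revcomp(motif)
    hits = []
    for p in range(len(sequence) - len(motif) + 1):
        window = sequence[p : p + len(motif)]
        if window == motif:
            hits.append((p, "top"))
        if window == rc:
            hits.append((p, "bottom"))
    return sorted(hits)
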