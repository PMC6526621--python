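"""Independent brute-force oracles used by the tests.

These implementations are deliberately naive (plain-Python dynamic
programming, per-read counting) and share no code with the package.
"""

from __future__ import annotations

NEG = float("-inf")


def affine_local_score(a: str, b: str, match=1.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0) -> float:
    """Smith-Waterman score with affine gaps: open + (L-1)*extend."""
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def score_alignment_columns(aln, match=1.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0) -> float:
    """Re-score an Alignment's column list from scratch."""
    total = 0.0
    prev_gap = None  # 'q' or 's'
    for q, s in aln.columns:
        if q is not None and s is not None:
            good = aln.query[q] == aln.subject[s] and aln.query[q] != "N"
            total += match if good else mismatch
            prev_gap = None
        else:
            side = "q" if q is None else "s"
            total += gap_extend if prev_gap == side else gap_open
            prev_gap = side
    return total


def classify_reads_brute(read_mapqs: list[int], dark_depth_max=5, mapq_low_max=9, dark_mass_min_pct=90.0) -> str:
    """Classify a single-position pileup directly from per-read MAPQs."""
    depth = len(read_mapqs)
    if depth <= dark_depth_max:
        return "dark_by_depth"
    n_low = sum(1 for q in read_mapqs if q <= mapq_low_max)
    if 100.0 * n_low / depth >= dark_mass_min_pct:
        return "dark_by_mapq"
    return "none"


def best_genotype_brute(n_alt: int, n_ref: int, ploidy: int, eps: float) -> int:
    """Exhaustive maximum-likelihood alt copy number."""
    import math

    best_k, best_ll = 0, NEG
    for k in range(ploidy + 1):
        p = (k / ploidy) * (1 - eps) + (1 - k / ploidy) * eps
        ll = n_alt * math.log(p) + n_ref * math.log(1 - p)
        if ll > best_ll:
            best_k, best_ll = k, ll
    return best_k
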