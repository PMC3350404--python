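"""Independent brute-force reference implementations for cross-checking.

Everything here is written with explicit loops from the defining formulas
(pairwise difference counts, variance-component definitions, 2x2 haplotype
tables) and shares no code with the package.
"""

import math

MISSING = set("N?-")


def retained_columns(rows, max_missing):
    """Column indices passing the per-site missing-data filter."""
    n = len(rows)
    keep = []
    for j in range(len(rows[0])):
        miss = sum(1 for r in rows if r[j] in MISSING)
        if miss / n <= max_missing:
            keep.append(j)
    return keep


def brute_S(rows, max_missing=0.0):
    count = 0
    for j in retained_columns(rows, max_missing):
        alleles = {r[j] for r in rows if r[j] not in MISSING}
        if len(alleles) >= 2:
            count += 1
    return count


def brute_pi(rows, max_missing=0.0):
    """Per-locus pi: per retained site, mean pairwise difference among
    non-missing calls, summed over sites."""
    total = 0.0
    for j in retained_columns(rows, max_missing):
        calls = [r[j] for r in rows if r[j] not in MISSING]
        ne = len(calls)
        if ne < 2:
            continue
        diffs = 0
        for a in range(ne):
            for b in range(a + 1, ne):
                if calls[a] != calls[b]:
                    diffs += 1
        total += diffs / (ne * (ne - 1) / 2)
    return total


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


def brute_thetaW(rows, max_missing=0.0):
    return brute_S(rows, max_missing) / harmonic(len(rows))


def brute_tajima_d(rows, max_missing=0.0):
    n = len(rows)
    S = brute_S(rows, max_missing)
    if S == 0:
        return math.nan
    pi = brute_pi(rows, max_missing)
    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / a1) / math.sqrt(var)


def brute_K_He(rows, max_missing=0.0):
    cols = retained_columns(rows, max_missing)
    haps = []
    for r in rows:
        h = "".join(r[j] for j in cols)
        if not set(h) & MISSING:
            haps.append(h)
    n = len(haps)
    counts = {}
    for h in haps:
        counts[h] = counts.get(h, 0) + 1
    sumsq = sum((c / n) ** 2 for c in counts.values())
    return len(counts), n / (n - 1) * (1 - sumsq)


def brute_r2(rows, i, j):
    """r^2 from the exhaustive 2x2 haplotype table (complete pairs)."""
    pairs = [(r[i], r[j]) for r in rows
             if r[i] not in MISSING and r[j] not in MISSING]
    ai = sorted({a for a, _ in pairs})
    aj = sorted({b for _, b in pairs})
    assert len(ai) == 2 and len(aj) == 2
    A, B = ai[0], aj[0]
    nt = len(pairs)
    pA = sum(1 for a, _ in pairs if a == A) / nt
    pB = sum(1 for _, b in pairs if b == B) / nt
    pAB = sum(1 for a, b in pairs if a == A and b == B) / nt
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def brute_fst_wc(rows, groups, max_missing=0.0):
    """Multi-locus Weir-Cockerham theta for haploid data, from the
    mean-square definitions, per allele, summed over sites."""
    a_tot = b_tot = 0.0
    for col in retained_columns(rows, max_missing):
        per_pop = {}
        for r, g in zip(rows, groups):
            c = r[col]
            if c in MISSING:
                continue
            per_pop.setdefault(g, {}).setdefault(c, 0)
            per_pop[g][c] += 1
        pops = [cnt for cnt in per_pop.values() if sum(cnt.values()) >= 2]
        if len(pops) < 2:
            continue
        alleles = sorted(set().union(*pops))
        if len(alleles) < 2:
            continue
        ni = [sum(c.values()) for c in pops]
        N = sum(ni)
        r_ = len(pops)
        nc = (N - sum(x * x for x in ni) / N) / (r_ - 1)
        for al in alleles:
            p = [c.get(al, 0) / n for c, n in zip(pops, ni)]
            pbar = sum(n * x for n, x in zip(ni, p)) / N
            msp = sum(n * (x - pbar) ** 2 for n, x in zip(ni, p)) / (r_ - 1)
            msg = sum(n * x * (1 - x) for n, x in zip(ni, p)) / (N - r_)
            a_tot += (msp - msg) / nc
            b_tot += msg
    if a_tot + b_tot == 0:
        return math.nan
    return a_tot / (a_tot + b_tot)
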