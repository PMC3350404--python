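"""Nucleotide, haplotype and microsatellite diversity with missing-data tolerance.

The central idea is a per-site missing-data filter: a column is retained iff
its fraction of missing ingroup calls (``N``, ``?`` or ``-``) is at most
``max_missing``; every statistic is then computed on the retained columns
using each column's *effective* (non-missing) sample size.  With complete
data this reduces to the classical textbook estimators.

Statistics implemented
----------------------
* ``S`` segregating sites, ``eta`` minimum mutation count (multiallelic-aware)
* ``pi`` mean pairwise differences per locus, per-site n_e/(n_e-1)(1-sum p^2)
* ``thetaW`` Watterson's estimator S/a1, with a1 from the full ingroup size
* Tajima's ``D`` (undefined, NaN, when S = 0 or its variance is <= 0)
* Fay & Wu's ``thetaH`` and ``H = pi - thetaH`` (requires an outgroup)
* Haplotype count ``K`` and unbiased haplotype diversity ``He``
* Pairwise linkage disequilibrium ``D``, ``D'``, ``r^2`` (biallelic pairs)
* Weir & Cockerham's theta (F_ST) for haploid sequence data
* Per-locus microsatellite allele counts, gene diversity and theta

All estimators treat gaps as missing data, never as a fifth allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqdata import Alignment, MISSING

__all__ = [
    "SiteSurvey",
    "PolymorphismStats",
    "LdPair",
    "FstResult",
    "DiversityError",
    "survey_sites",
    "nucleotide_stats",
    "faywu",
    "haplotype_stats",
    "ld_pair",
    "fst",
    "microsat_stats",
    "tajima_constants",
]

logger = logging.getLogger(__name__)

MISSING_SET = frozenset(MISSING)


class DiversityError(ValueError):
    """Invalid input for a diversity computation."""


# ---------------------------------------------------------------------------
# Site survey (the missing-data filter)
# ---------------------------------------------------------------------------

@dataclass
class SiteSurvey:
    """Per-column census of ingroup alleles after the missing-data filter.

    ``allele_counts`` maps nucleotide -> count over non-missing ingroup calls;
    ``n_effective`` is the non-missing ingroup sample size at this column and
    ``outgroup_allele`` the consensus outgroup call (None when the outgroup is
    absent, missing or internally discordant).
    """

    position: int
    allele_counts: dict[str, int]
    n_missing: int
    n_effective: int
    outgroup_allele: str | None = None

    @property
    def n_alleles(self) -> int:
        return len(self.allele_counts)

    @property
    def is_polymorphic(self) -> bool:
        return self.n_alleles >= 2


def _split_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(ingroup matrix, outgroup matrix) as arrays of single characters."""
    ingroup = [e.sequence for e in aln.ingroup()]
    outgroup = [e.sequence for e in aln.outgroup()]
    to_mat = lambda seqs: (
        np.array([list(s) for s in seqs], dtype="U1")
        if seqs else np.empty((0, aln.length), dtype="U1")
    )
    return to_mat(ingroup), to_mat(outgroup)


def survey_sites(aln: Alignment, max_missing: float = 0.0) -> list[SiteSurvey]:
    """Census every column, keeping those passing the missing-data filter.

    A column is retained iff the fraction of missing ingroup calls is
    <= *max_missing*.  Allele counts are computed over non-missing ingroup
    calls only; an empty result is legal.
    """
    if len(aln) == 0:
        raise DiversityError("empty alignment")
    if not 0.0 <= max_missing <= 1.0:
        raise DiversityError(f"max_missing must be in [0, 1], got {max_missing}")
    ing, out = _split_matrix(aln)
    n_ing = ing.shape[0]
    if n_ing == 0:
        raise DiversityError("alignment has no ingroup sequences")
    surveys = []
    for j in range(aln.length):
        col = ing[:, j]
        missing_mask = np.isin(col, ("N", "?", "-"))
        n_missing = int(missing_mask.sum())
        if n_missing / n_ing > max_missing:
            continue
        values, counts = np.unique(col[~missing_mask], return_counts=True)
        allele_counts = dict(zip(values.tolist(), counts.tolist()))
        out_allele = None
        if out.shape[0]:
            ocol = out[:, j]
            ocalls = {c for c in ocol.tolist() if c not in MISSING_SET}
            if len(ocalls) == 1:
                out_allele = next(iter(ocalls))
        surveys.append(
            SiteSurvey(
                position=j,
                allele_counts=allele_counts,
                n_missing=n_missing,
                n_effective=n_ing - n_missing,
                outgroup_allele=out_allele,
            )
        )
    return surveys


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima's D for sample size *n* (a1 .. e2)."""
    if n < 2:
        raise DiversityError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _site_pi(sv: SiteSurvey) -> float:
    """Unbiased per-site heterozygosity n_e/(n_e-1) * (1 - sum p^2)."""
    ne = sv.n_effective
    if ne < 2:
        return 0.0
    counts = np.array(list(sv.allele_counts.values()), dtype=float)
    p = counts / ne
    return ne / (ne - 1.0) * (1.0 - float(np.sum(p**2)))


@dataclass
class PolymorphismStats:
    """Bundle of per-locus diversity statistics.

    ``D`` and ``H`` are NaN when undefined (S = 0, no outgroup, ...).
    ``lseff`` is the number of columns that passed the missing-data filter.
    """

    S: int
    eta: int
    pi: float
    thetaW: float
    D: float
    K: int
    He: float
    lseff: int
    n: int
    thetaH: float = math.nan
    H: float = math.nan

    def as_dict(self) -> dict[str, float]:
        """Flat statistic name -> value mapping."""
        return {
            "S": self.S, "eta": self.eta, "pi": self.pi,
            "thetaW": self.thetaW, "D": self.D, "thetaH": self.thetaH,
            "H": self.H, "K": self.K, "He": self.He,
            "lseff": self.lseff, "n": self.n,
        }


def tajima_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from S, pi and the sample size; NaN when undefined."""
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / c["a1"]) / math.sqrt(var)


def nucleotide_stats(
    aln: Alignment, max_missing: float = 0.0
) -> PolymorphismStats:
    """Standard per-locus diversity statistics under the missing-data filter.

    Watterson's theta uses ``a1`` computed from the full ingroup sample size;
    pi uses each retained site's effective sample size.  Statistics are per
    locus, not per site.  Fay & Wu's thetaH/H are filled in when an outgroup
    is present (see :func:`faywu`).
    """
    n = len(aln.ingroup())
    if n < 2:
        raise DiversityError("need at least 2 ingroup sequences")
    surveys = survey_sites(aln, max_missing)
    S = sum(1 for sv in surveys if sv.is_polymorphic)
    eta = sum(sv.n_alleles - 1 for sv in surveys)
    pi = float(sum(_site_pi(sv) for sv in surveys))
    a1 = tajima_constants(n)["a1"]
    thetaW = S / a1
    D = tajima_d(S, pi, n)
    try:
        K, He = haplotype_stats(aln, max_missing)
    except DiversityError:
        K, He = 0, math.nan
    stats = PolymorphismStats(
        S=S, eta=eta, pi=pi, thetaW=thetaW, D=D,
        K=K, He=He, lseff=len(surveys), n=n,
    )
    if aln.outgroup():
        stats.thetaH, stats.H = faywu(aln, max_missing)
    return stats


def faywu(aln: Alignment, max_missing: float = 0.0) -> tuple[float, float]:
    """Fay & Wu's (thetaH, H), polarising alleles with the outgroup.

    thetaH weights derived-allele counts quadratically,
    ``thetaH = sum_sites sum_derived 2 i^2 / (n_e (n_e - 1))``, and
    ``H = pi - thetaH`` with pi restricted to the polarisable sites.  Sites
    where the outgroup is missing, internally discordant, or carries an
    allele absent from a polymorphic ingroup column are skipped.
    """
    if not aln.outgroup():
        raise DiversityError("Fay & Wu's H requires an outgroup sequence")
    surveys = survey_sites(aln, max_missing)
    thetaH = 0.0
    pi = 0.0
    for sv in surveys:
        anc = sv.outgroup_allele
        if anc is None:
            continue
        if sv.is_polymorphic and anc not in sv.allele_counts:
            continue  # cannot polarise: outgroup allele not segregating
        ne = sv.n_effective
        if ne < 2:
            continue
        for allele, count in sv.allele_counts.items():
            # fixed differences (count == ne) are divergence, not polymorphism
            if allele != anc and count < ne:
                thetaH += 2.0 * count**2 / (ne * (ne - 1.0))
        pi += _site_pi(sv)
    return thetaH, pi - thetaH


def haplotype_stats(aln: Alignment, max_missing: float = 0.0) -> tuple[int, float]:
    """(K, He): distinct haplotypes and unbiased haplotype diversity.

    Haplotypes are built on the retained columns; ingroup sequences with any
    missing call at a retained column are excluded.
    """
    surveys = survey_sites(aln, max_missing)
    cols = [sv.position for sv in surveys]
    haps = []
    for e in aln.ingroup():
        h = "".join(e.sequence[c] for c in cols)
        if not set(h) & MISSING_SET:
            haps.append(h)
    n = len(haps)
    if n < 2:
        raise DiversityError(
            f"haplotype statistics need >= 2 usable sequences, got {n}"
        )
    _, counts = np.unique(haps, return_counts=True)
    p = counts / n
    He = n / (n - 1.0) * (1.0 - float(np.sum(p**2)))
    return len(counts), He


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LdPair:
    """Pairwise linkage disequilibrium between two biallelic columns."""

    i: int
    j: int
    D: float
    Dprime: float
    r2: float


def ld_pair(aln: Alignment, i: int, j: int) -> LdPair:
    """LD between columns *i* and *j* (ingroup, pairwise-complete).

    Alleles are labelled so that A is the alphabetically first allele at each
    column; ``D = p_AB - p_A p_B``, ``r^2 = D^2 / (p_A q_A p_B q_B)`` and
    ``D' = D / D_max``.  Columns must be biallelic after excluding sequences
    missing at either column.
    """
    pairs = []
    for e in aln.ingroup():
        a, b = e.sequence[i], e.sequence[j]
        if a in MISSING_SET or b in MISSING_SET:
            continue
        pairs.append((a, b))
    if len(pairs) < 2:
        raise DiversityError("fewer than 2 complete haplotypes at this pair")
    alleles_i = sorted({a for a, _ in pairs})
    alleles_j = sorted({b for _, b in pairs})
    if len(alleles_i) != 2 or len(alleles_j) != 2:
        raise DiversityError(
            f"columns ({i}, {j}) must both be biallelic "
            f"(got {len(alleles_i)} and {len(alleles_j)} alleles)"
        )
    A, B = alleles_i[0], alleles_j[0]
    ntot = len(pairs)
    pA = sum(1 for a, _ in pairs if a == A) / ntot
    pB = sum(1 for _, b in pairs if b == B) / ntot
    pAB = sum(1 for a, b in pairs if a == A and b == B) / ntot
    qA, qB = 1.0 - pA, 1.0 - pB
    D = pAB - pA * pB
    r2 = D**2 / (pA * qA * pB * qB)
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    elif D < 0:
        dmax = min(pA * pB, qA * qB)
    else:
        dmax = math.nan
    dprime = 0.0 if D == 0 else D / dmax
    return LdPair(i=i, j=j, D=D, Dprime=dprime, r2=r2)


# ---------------------------------------------------------------------------
# F-statistics (Weir & Cockerham, haploid data)
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Multi-locus Weir-Cockerham theta with its summed variance components.

    ``a`` is the among-population component and ``b`` the within-population
    component, summed over retained polymorphic sites and alleles;
    ``theta_wc = a / (a + b)``.
    """

    theta_wc: float
    a: float
    b: float
    n_sites: int


def _wc_site_components(
    counts: list[dict[str, int]]
) -> tuple[float, float]:
    """Weir-Cockerham (a, b) summed over alleles for one site.

    *counts* holds, per population, allele -> non-missing count.  Populations
    with fewer than 2 calls at the site are dropped; returns (0, 0) when
    fewer than 2 populations remain or the site is monomorphic.
    """
    counts = [c for c in counts if sum(c.values()) >= 2]
    r = len(counts)
    if r < 2:
        return 0.0, 0.0
    ni = np.array([sum(c.values()) for c in counts], dtype=float)
    N = ni.sum()
    alleles = sorted(set().union(*counts))
    if len(alleles) < 2:
        return 0.0, 0.0
    nc = (N - np.sum(ni**2) / N) / (r - 1)
    a_sum = b_sum = 0.0
    for allele in alleles:
        p = np.array([c.get(allele, 0) for c in counts], dtype=float) / ni
        pbar = float(np.sum(ni * p) / N)
        msp = float(np.sum(ni * (p - pbar) ** 2) / (r - 1))
        msg = float(np.sum(ni * p * (1.0 - p)) / (N - r))
        a_sum += (msp - msg) / nc
        b_sum += msg
    return a_sum, b_sum


def fst(aln: Alignment, max_missing: float = 0.0) -> FstResult:
    """Multi-locus Weir-Cockerham theta over the retained polymorphic sites.

    Requires >= 2 populations with >= 2 ingroup sequences each; variance
    components are summed over sites before taking the ratio.  NaN when no
    site is informative.
    """
    groups = sorted({e.group for e in aln.ingroup()})
    sizes = [sum(1 for e in aln.ingroup() if e.group == g) for g in groups]
    if len(groups) < 2 or any(s < 2 for s in sizes):
        raise DiversityError(
            "F-statistics need >= 2 populations with >= 2 sequences each"
        )
    ing = aln.ingroup()
    surveys = survey_sites(aln, max_missing)
    a_tot = b_tot = 0.0
    n_sites = 0
    for sv in surveys:
        if not sv.is_polymorphic:
            continue
        per_pop = []
        for g in groups:
            cnt: dict[str, int] = {}
            for e in ing:
                if e.group != g:
                    continue
                c = e.sequence[sv.position]
                if c not in MISSING_SET:
                    cnt[c] = cnt.get(c, 0) + 1
            per_pop.append(cnt)
        a, b = _wc_site_components(per_pop)
        if a or b:
            n_sites += 1
        a_tot += a
        b_tot += b
    denom = a_tot + b_tot
    theta = a_tot / denom if denom > 0 else math.nan
    return FstResult(theta_wc=theta, a=a_tot, b=b_tot, n_sites=n_sites)


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

MISSING_GENOTYPE = -1


def microsat_stats(
    genotypes: np.ndarray, groups: np.ndarray | list[int] | None = None
) -> list[dict[str, float] | None]:
    """Per-locus microsatellite diversity from an individuals x loci table.

    *genotypes* holds integer allele sizes with ``-1`` marking missing calls.
    Returns, per locus, the allele count, the unbiased gene diversity
    ``He = n/(n-1) (1 - sum p^2)`` and, when >= 2 groups are usable,
    Weir-Cockerham theta.  Loci with < 2 non-missing calls are skipped with
    a warning (reported as None in the output list).
    """
    geno = np.asarray(genotypes)
    if geno.ndim != 2:
        raise DiversityError("genotype table must be 2-dimensional")
    n_ind, n_loci = geno.shape
    if groups is None:
        groups = np.zeros(n_ind, dtype=int)
    groups = np.asarray(groups)
    results: list[dict[str, float] | None] = []
    for locus in range(n_loci):
        col = geno[:, locus]
        ok = col != MISSING_GENOTYPE
        calls = col[ok]
        if calls.size < 2:
            logger.warning(
                "locus %d skipped: only %d non-missing call(s)", locus, calls.size
            )
            results.append(None)
            continue
        values, counts = np.unique(calls, return_counts=True)
        n = calls.size
        p = counts / n
        He = n / (n - 1.0) * (1.0 - float(np.sum(p**2)))
        res = {"n_alleles": int(values.size), "He": He, "n": int(n)}
        pops = np.unique(groups[ok])
        if pops.size >= 2:
            per_pop = []
            for g in pops:
                sub = col[(groups == g) & ok]
                per_pop.append(
                    {str(v): int(c) for v, c in
                     zip(*np.unique(sub, return_counts=True))}
                )
            a, b = _wc_site_components(per_pop)
            res["theta_wc"] = a / (a + b) if (a + b) > 0 else math.nan
        results.append(res)
    return results
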