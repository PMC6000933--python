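"""SNP population genetics: allele frequencies, Hardy-Weinberg tests,
pairwise linkage disequilibrium (D, D', r²), and EM haplotype-frequency
estimation for two-locus pairs.

Genotypes are coded as minor-allele dosage 0/1/2 (NaN = missing).  Phase is
unobserved, so two-locus haplotype frequencies are estimated by
expectation-maximisation: every genotype pair except the double heterozygote
determines its two gametes; the double heterozygote is resolved in the E-step
with posterior weight h11*h22 / (h11*h22 + h12*h21) on the coupling phase, and
the M-step recounts expected haplotypes.  The EM likelihood is monotonically
non-decreasing and, when no double heterozygotes are present, the first M-step
already equals direct gamete counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HWEResult",
    "LDStats",
    "HaplotypeEMState",
    "allele_frequencies",
    "genotype_counts",
    "hwe_test",
    "hwe_table",
    "filter_hwe",
    "em_haplotype_frequencies",
    "ld_stats",
    "pairwise_ld",
    "classify_ld",
]

#: haplotype order used throughout: (minor,minor), (minor,major), (major,minor), (major,major)
HAPLOTYPES = ("11", "12", "21", "22")


@dataclass(frozen=True)
class HWEResult:
    locus: str
    n_hom_minor: int
    n_het: int
    n_hom_major: int
    p: float  # minor-allele frequency
    chi2: float
    p_value: float
    conforms: bool  # P > 0.05

    @property
    def n(self) -> int:
        return self.n_hom_minor + self.n_het + self.n_hom_major


@dataclass(frozen=True)
class LDStats:
    locus1: str
    locus2: str
    haplotype_frequencies: tuple  # (h11, h12, h21, h22)
    p1: float
    p2: float
    D: float
    d_prime: float
    r2: float
    defined: bool = True
    note: str = ""


@dataclass
class HaplotypeEMState:
    """Final EM state plus per-iteration history for diagnostics."""

    iterations: int
    frequencies: np.ndarray  # (h11, h12, h21, h22)
    expected_counts: np.ndarray
    loglik: float
    loglik_history: list[float] = field(default_factory=list)
    converged: bool = True
    n_birds: int = 0
    n_double_het: int = 0


# ---------------------------------------------------------------------------
# allele frequencies and HWE
# ---------------------------------------------------------------------------

def genotype_counts(genotypes: pd.DataFrame, locus: str) -> tuple[int, int, int]:
    """(n homozygous minor, n heterozygous, n homozygous major) at a locus."""
    g = genotypes[locus].dropna().to_numpy()
    if g.size == 0:
        raise ValueError(f"locus {locus}: all genotypes missing")
    return int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0))


def allele_frequencies(
    genotypes: pd.DataFrame, locus: str
) -> tuple[float, tuple[int, int, int]]:
    """Minor-allele frequency p = (2*n_hom + n_het) / 2n and genotype counts."""
    counts = genotype_counts(genotypes, locus)
    n_hom_minor, n_het, n_hom_major = counts
    n = sum(counts)
    p = (2 * n_hom_minor + n_het) / (2 * n)
    return float(p), counts


def hwe_test(counts: tuple[int, int, int], locus: str = "") -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` is (n homozygous minor, n heterozygous, n homozygous major).
    Expected counts are n*(p², 2pq, q²) from the sample allele frequency; no
    continuity correction is applied.  ``conforms`` is P > 0.05.
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotyped birds")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if p in (0.0, 1.0):
        chi2 = 0.0
    else:
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(
        locus=locus,
        n_hom_minor=n_aa,
        n_het=n_ab,
        n_hom_major=n_bb,
        p=float(p),
        chi2=chi2,
        p_value=p_value,
        conforms=p_value > 0.05,
    )


def hwe_table(genotypes: pd.DataFrame) -> pd.DataFrame:
    """HWE test for every locus; one row per locus."""
    rows = []
    for locus in genotypes.columns:
        res = hwe_test(genotype_counts(genotypes, locus), locus)
        rows.append(
            {
                "locus": locus,
                "n": res.n,
                "n_hom_minor": res.n_hom_minor,
                "n_het": res.n_het,
                "n_hom_major": res.n_hom_major,
                "maf": res.p,
                "chi2": res.chi2,
                "p_value": res.p_value,
                "conforms": res.conforms,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def filter_hwe(genotypes: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Drop loci whose HWE P-value is at or below ``threshold``.

    Mirrors the usual practice of excluding out-of-equilibrium sites before
    LD and haplotype analysis.
    """
    table = hwe_table(genotypes)
    keep = table.index[table["p_value"] > threshold]
    return genotypes[list(keep)]


# ---------------------------------------------------------------------------
# two-locus EM haplotype estimation
# ---------------------------------------------------------------------------

def _genotype_pair_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint dosage counts, indices = dosage at locus 1 / 2."""
    table = np.zeros((3, 3))
    for a, b in zip(g1.astype(int), g2.astype(int)):
        table[a, b] += 1
    return table


def _cell_probs(h: np.ndarray) -> np.ndarray:
    """P(joint genotype) for each 3x3 cell given haplotype frequencies.

    Haplotype a∈{0,1} copies of the minor allele at locus 1, b at locus 2;
    h indexed as (h11, h12, h21, h22) with '1' = minor.
    """
    hmap = {(1, 1): h[0], (1, 0): h[1], (0, 1): h[2], (0, 0): h[3]}
    probs = np.zeros((3, 3))
    for (a1, b1), (a2, b2) in itertools.product(hmap, repeat=2):
        probs[a1 + a2, b1 + b2] += hmap[(a1, b1)] * hmap[(a2, b2)]
    return probs


def _em_loglik(table: np.ndarray, h: np.ndarray) -> float:
    probs = _cell_probs(h)
    mask = table > 0
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    return float(np.sum(table[mask] * logp[mask]))


def _em_mstep(table: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Expected haplotype counts given current frequencies (one EM sweep).

    All cells except the double heterozygote (1,1) have unambiguous gametes;
    the double heterozygote contributes to 11/22 with posterior weight
    h11*h22 / (h11*h22 + h12*h21) and to 12/21 with the complement.
    """
    n11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    n12 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    n21 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    n22 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    nxx = table[1, 1]
    denom = h[0] * h[3] + h[1] * h[2]
    w = 0.5 if denom == 0 else h[0] * h[3] / denom
    counts = np.array(
        [n11 + w * nxx, n12 + (1 - w) * nxx, n21 + (1 - w) * nxx, n22 + w * nxx]
    )
    return counts


def em_haplotype_frequencies(
    genotypes: pd.DataFrame,
    locus_pair: tuple[str, str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[LDStats, HaplotypeEMState]:
    """Two-locus haplotype frequencies by EM, plus derived LD statistics.

    Birds missing either genotype are excluded pairwise.  The EM is run from
    the linkage-equilibrium product of allele frequencies and, to guard
    against the symmetric stationary point when many birds are doubly
    heterozygous, from ``n_restarts`` random starts; the run with the highest
    final log-likelihood wins (ties resolved toward the lexicographically
    smallest frequency vector).  A monomorphic locus yields a flagged,
    undefined LDStats rather than an exception.
    """
    l1, l2 = locus_pair
    sub = genotypes[[l1, l2]].dropna()
    g1 = sub[l1].to_numpy(float)
    g2 = sub[l2].to_numpy(float)
    if len(sub) == 0:
        raise ValueError(f"no birds genotyped at both {l1} and {l2}")
    p1 = g1.mean() / 2.0
    p2 = g2.mean() / 2.0
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        mono = l1 if p1 in (0.0, 1.0) else l2
        ld = LDStats(
            l1, l2, (np.nan,) * 4, p1, p2, np.nan, np.nan, np.nan,
            defined=False, note=f"locus {mono} is monomorphic; LD undefined",
        )
        state = HaplotypeEMState(
            0, np.full(4, np.nan), np.full(4, np.nan), np.nan,
            n_birds=len(sub),
        )
        return ld, state

    table = _genotype_pair_table(g1, g2)
    n_gametes = 2 * len(sub)
    rng = np.random.default_rng(seed)

    starts = [np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])]
    for _ in range(n_restarts):
        h0 = rng.dirichlet(np.ones(4))
        starts.append(h0)

    best = None
    for h0 in starts:
        h = h0.copy()
        ll = _em_loglik(table, h)
        history = [ll]
        converged = False
        for _ in range(max_iter):
            counts = _em_mstep(table, h)
            h_new = counts / n_gametes
            ll_new = _em_loglik(table, h_new)
            if ll_new < ll - 1e-9:
                raise RuntimeError(
                    f"EM log-likelihood decreased ({ll:.6f} -> {ll_new:.6f}) "
                    f"for pair ({l1}, {l2})"
                )
            h, delta = h_new, ll_new - ll
            ll = ll_new
            history.append(ll)
            if abs(delta) < tol:
                converged = True
                break
        cand = (ll, tuple(-np.round(h, 12)), h, history, converged)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand

    ll, _, h, history, converged = best
    state = HaplotypeEMState(
        iterations=len(history) - 1,
        frequencies=h,
        expected_counts=_em_mstep(table, h),
        loglik=ll,
        loglik_history=history,
        converged=converged,
        n_birds=len(sub),
        n_double_het=int(table[1, 1]),
    )
    return ld_stats(h, l1, l2), state


def ld_stats(haplotype_frequencies, locus1: str = "L1", locus2: str = "L2") -> LDStats:
    """D, Lewontin's D' and r² from (h11, h12, h21, h22).

    D = h11 − p1*p2; D' = |D| / Dmax with Dmax = min(p1*q2, q1*p2) for D > 0
    and min(p1*p2, q1*q2) for D < 0; r² = D² / (p1*q1*p2*q2).  A fixed allele
    at either locus yields a flagged, undefined result.
    """
    h = np.asarray(haplotype_frequencies, dtype=float)
    if h.min() < -1e-9 or abs(h.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid haplotype frequencies {h}")
    p1 = h[0] + h[1]
    p2 = h[0] + h[2]
    q1, q2 = 1.0 - p1, 1.0 - p2
    if min(p1, q1, p2, q2) <= 0:
        return LDStats(
            locus1, locus2, tuple(h), p1, p2, np.nan, np.nan, np.nan,
            defined=False, note="fixed allele; LD undefined",
        )
    D = h[0] - p1 * p2
    if D >= 0:
        d_max = min(p1 * q2, q1 * p2)
    else:
        d_max = min(p1 * p2, q1 * q2)
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (p1 * q1 * p2 * q2)
    return LDStats(locus1, locus2, tuple(h), p1, p2, float(D), float(d_prime), float(r2))


def pairwise_ld(
    genotypes: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, list[LDStats]]:
    """EM-based D' and r² for every locus pair.

    Returns (D' matrix, r² matrix, list of LDStats) over the loci in column
    order; undefined pairs (monomorphic loci) are NaN in the matrices.
    """
    loci = list(genotypes.columns)
    dp = pd.DataFrame(np.nan, index=loci, columns=loci)
    r2 = pd.DataFrame(np.nan, index=loci, columns=loci)
    all_stats = []
    for i, l1 in enumerate(loci):
        for l2 in loci[i + 1:]:
            ld, _ = em_haplotype_frequencies(genotypes, (l1, l2), seed=seed)
            all_stats.append(ld)
            dp.loc[l1, l2] = dp.loc[l2, l1] = ld.d_prime
            r2.loc[l1, l2] = r2.loc[l2, l1] = ld.r2
    return dp, r2, all_stats


def classify_ld(
    pairs: list[LDStats],
    d_prime_threshold: float = 0.75,
    r2_thresholds: tuple[float, float] = (0.6, 0.3),
) -> pd.DataFrame:
    """Flag strong-LD pairs: D' strictly above 0.75, cross-tabulated with r².

    ``r2_class`` reports which r² band a strong pair falls in
    (``>0.6``, ``>0.3`` or ``<=0.3``).
    """
    hi, lo = r2_thresholds
    rows = []
    for ld in pairs:
        if not ld.defined:
            strong, r2_class = False, "undefined"
        else:
            strong = ld.d_prime > d_prime_threshold
            if ld.r2 > hi:
                r2_class = f">{hi}"
            elif ld.r2 > lo:
                r2_class = f">{lo}"
            else:
                r2_class = f"<={lo}"
        rows.append(
            {
                "locus1": ld.locus1,
                "locus2": ld.locus2,
                "d_prime": ld.d_prime,
                "r2": ld.r2,
                "strong_ld": strong,
                "r2_class": r2_class,
            }
        )
    return pd.DataFrame(rows)
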