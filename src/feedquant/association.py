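"""Single-SNP association with derived traits via a fixed-effects GLM.

Model: Y = mu + G + F + S + e, with genotype G a categorical factor (up to
three classes), F the sire-family effect and S the sex effect, fit by OLS.
The genotype effect is tested with a type-III F-test (genotype classes are
unbalanced); genotype least-squares means are averaged over family and sex
levels.  Pairwise genotype comparisons use Fisher's least significant
difference (LSD) on the least-squares means at alpha = 0.05, summarised as a
compact letter display: two genotypes share a letter exactly when their LSD
comparison is non-significant.

No multiple-testing correction is applied across loci and traits (nominal
P-values, as is conventional for small candidate-gene panels); a Bonferroni
column is emitted in the summary table for transparency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "AliasedDesignError",
    "fit_association",
    "lsd_pairwise",
    "compact_letter_display",
    "association_table",
]

GENOTYPE_LABELS = {0: "maj/maj", 1: "het", 2: "min/min"}


class AliasedDesignError(ValueError):
    """Genotype classes are confounded with another factor."""


@dataclass
class AssociationResult:
    locus: str
    trait: str
    genotype_classes: list[int]  # dosage codes present after filtering
    n_per_class: dict
    ls_means: dict
    raw_means: dict
    raw_sds: dict
    f_statistic: float
    p_value: float
    df_num: int
    df_resid: int
    residual_ms: float
    letters: dict = field(default_factory=dict)
    dropped_classes: list = field(default_factory=list)
    # covariance of the LS means (for LSD comparisons)
    lsmean_cov: np.ndarray | None = None


def _design(df: pd.DataFrame, factors: dict[str, str]) -> tuple[np.ndarray, dict]:
    """Reference-coded design matrix; returns (X, column slices per factor)."""
    cols = [np.ones(len(df))]
    slices: dict[str, list[int]] = {"intercept": [0]}
    levels: dict[str, list] = {}
    k = 1
    for name, col in factors.items():
        levs = sorted(df[col].astype(str).unique())
        levels[name] = levs
        slices[name] = []
        for lev in levs[1:]:
            cols.append((df[col].astype(str) == lev).to_numpy(float))
            slices[name].append(k)
            k += 1
    return np.column_stack(cols), {"slices": slices, "levels": levels}


def fit_association(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    locus: str,
    trait: str,
    family: pd.Series | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Fit Y = mu + genotype + family + sex + e and test the genotype effect.

    ``family`` is a per-bird family code aligned with the phenotype index
    (typically the sire id); if None, no family effect is fitted.  Genotype
    classes with fewer than 2 birds are dropped (and logged on the result).
    The genotype F-test is the type-III (partial) test: full model vs the
    model with genotype columns removed.
    """
    data = phenotypes[[c for c in (trait, "sex") if c in phenotypes.columns]].copy()
    data["genotype"] = genotypes[locus].reindex(data.index)
    if family is not None:
        data["family"] = family.reindex(data.index).astype(str)
    data = data.dropna(subset=[trait, "genotype"])

    class_counts = data["genotype"].value_counts()
    dropped = sorted(int(g) for g in class_counts.index[class_counts < 2])
    if dropped:
        data = data[~data["genotype"].isin(dropped)]
    classes = sorted(int(g) for g in data["genotype"].unique())
    if len(classes) < 2:
        raise ValueError(
            f"locus {locus}: fewer than 2 genotype classes with >= 2 birds"
        )
    data["genotype"] = data["genotype"].astype(int)

    factors = {"genotype": "genotype"}
    if family is not None and data["family"].nunique() > 1:
        factors["family"] = "family"
    if "sex" in data.columns and data["sex"].nunique() > 1:
        factors["sex"] = "sex"

    X, meta = _design(data, factors)
    rank_full = np.linalg.matrix_rank(X)
    geno_cols = meta["slices"]["genotype"]
    other = [j for j in range(X.shape[1]) if j not in geno_cols]
    if rank_full < X.shape[1]:
        # find which genotype columns are in the span of the others
        aliased = [
            f"genotype[{meta['levels']['genotype'][i + 1]}]"
            for i, j in enumerate(geno_cols)
            if np.linalg.matrix_rank(X[:, other + [j]]) == np.linalg.matrix_rank(X[:, other])
        ]
        if aliased:
            raise AliasedDesignError(
                f"locus {locus}: genotype is confounded with other factors; "
                f"aliased columns: {aliased}"
            )
        raise AliasedDesignError(
            f"locus {locus}: rank-deficient design (non-genotype aliasing)"
        )

    y = data[trait].to_numpy(float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise ValueError(f"locus {locus}: no residual degrees of freedom")
    ss_full = float(resid @ resid)
    ms_resid = ss_full / df_resid

    X0 = X[:, other]
    beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    ss_red = float(np.sum((y - X0 @ beta0) ** 2))
    df_num = len(geno_cols)
    f_stat = ((ss_red - ss_full) / df_num) / ms_resid
    p_value = float(stats.f.sf(f_stat, df_num, df_resid))

    # LS means: average prediction over the cross of family x sex levels
    xtx_inv = np.linalg.inv(X.T @ X)
    cov_beta = xtx_inv * ms_resid
    contrast_rows = []
    other_factors = [f for f in factors if f != "genotype"]
    for g in classes:
        rows = []
        combos = itertools.product(
            *[meta["levels"][f] for f in other_factors]
        ) if other_factors else [()]
        for combo in combos:
            row = np.zeros(X.shape[1])
            row[0] = 1.0
            gi = meta["levels"]["genotype"].index(str(g))
            if gi > 0:
                row[meta["slices"]["genotype"][gi - 1]] = 1.0
            for f, lev in zip(other_factors, combo):
                li = meta["levels"][f].index(lev)
                if li > 0:
                    row[meta["slices"][f][li - 1]] = 1.0
            rows.append(row)
        contrast_rows.append(np.mean(rows, axis=0))
    L = np.vstack(contrast_rows)
    ls_means = {g: float(v) for g, v in zip(classes, L @ beta)}
    lsmean_cov = L @ cov_beta @ L.T

    raw_means = {g: float(data.loc[data["genotype"] == g, trait].mean()) for g in classes}
    raw_sds = {g: float(data.loc[data["genotype"] == g, trait].std(ddof=1)) for g in classes}
    n_per_class = {g: int((data["genotype"] == g).sum()) for g in classes}

    result = AssociationResult(
        locus=locus,
        trait=trait,
        genotype_classes=classes,
        n_per_class=n_per_class,
        ls_means=ls_means,
        raw_means=raw_means,
        raw_sds=raw_sds,
        f_statistic=float(f_stat),
        p_value=p_value,
        df_num=df_num,
        df_resid=df_resid,
        residual_ms=float(ms_resid),
        dropped_classes=dropped,
        lsmean_cov=lsmean_cov,
    )
    result.letters = lsd_pairwise(result, alpha=alpha)
    return result


def lsd_pairwise(result: AssociationResult, alpha: float = 0.05) -> dict:
    """LSD letters: genotype means compared pairwise at level ``alpha``.

    Each pair is declared different when |mean_i - mean_j| exceeds
    t(1-alpha/2, df_resid) * SE(diff), with the SE taken from the model's
    residual mean square through the LS-mean covariance.  Returns
    {genotype_code: letters}.
    """
    classes = result.genotype_classes
    if len(classes) == 1:
        return {classes[0]: "a"}
    tcrit = stats.t.ppf(1 - alpha / 2, result.df_resid)
    cov = result.lsmean_cov
    different = {}
    for i, j in itertools.combinations(range(len(classes)), 2):
        se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        diff = abs(result.ls_means[classes[i]] - result.ls_means[classes[j]])
        different[(i, j)] = bool(se > 0 and diff > tcrit * se)
    letters = compact_letter_display(
        [result.ls_means[g] for g in classes], different
    )
    return {g: letters[i] for i, g in enumerate(classes)}


def compact_letter_display(means: list[float], different: dict) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``different[(i, j)]`` (i < j) marks significantly different pairs.  The
    result guarantees: i and j share a letter iff (i, j) is not different.
    Letters are assigned in descending-mean order, 'a' first.
    """
    k = len(means)
    # letter groups as sets of item indices; start with one all-inclusive group
    groups: list[set[int]] = [set(range(k))]
    for (i, j), is_diff in sorted(different.items()):
        if not is_diff:
            continue
        for g in [g for g in groups if i in g and j in g]:
            groups.remove(g)
            gi, gj = g - {j}, g - {i}
            for cand in (gi, gj):
                if not any(cand <= other for other in groups):
                    groups.append(cand)
    # absorb redundant groups
    groups = [g for g in groups if not any(g < other for other in groups)]
    # order letters by descending mean of the top member
    order = sorted(range(len(groups)), key=lambda gi: -max(means[i] for i in groups[gi]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    rank = sorted(range(k), key=lambda i: -means[i])
    for letter_i, gi in enumerate(order):
        for i in rank:
            if i in groups[gi]:
                out[i] += alphabet[letter_i]
    return out


def association_table(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    loci: list[str],
    traits: list[str],
    family: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One block per locus x trait: genotype ns, means +/- sd, letters, F, P.

    Loci whose genotype effect is non-significant for every trait are listed
    with ``significant_any = False`` so they can be summarised as such.
    A Bonferroni-adjusted P (across all locus x trait fits) is included.
    """
    rows = []
    n_tests = max(len(loci) * len(traits), 1)
    for locus in loci:
        for trait in traits:
            res = fit_association(phenotypes, genotypes, locus, trait, family, alpha)
            for g in res.genotype_classes:
                rows.append(
                    {
                        "locus": locus,
                        "trait": trait,
                        "genotype": GENOTYPE_LABELS.get(g, str(g)),
                        "dosage": g,
                        "n": res.n_per_class[g],
                        "ls_mean": res.ls_means[g],
                        "raw_mean": res.raw_means[g],
                        "sd": res.raw_sds[g],
                        "letters": res.letters[g],
                        "F": res.f_statistic,
                        "p_value": res.p_value,
                        "p_bonferroni": min(res.p_value * n_tests, 1.0),
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        sig = table.groupby("locus")["p_value"].min() < alpha
        table["significant_any"] = table["locus"].map(sig)
    return table
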