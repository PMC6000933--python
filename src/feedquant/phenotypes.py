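"""Per-bird feed-efficiency phenotypes from daily records.

The derivation chain, run separately within each sex:

1. Fit a per-bird growth line BW = mu + a*DOT + e by ordinary least squares;
   the slope a is the bird's average daily gain (ADG).
2. Predict mid-test body weight MBW = mu + a*mid_dot and metabolic mid-test
   weight MMBW = MBW^0.75.
3. ADFI = total feed intake / number of test days.
4. Regress ADFI on MMBW and ADG (with intercept); the fitted value is the
   expected feed intake (EFI) and the residual is the residual feed intake
   (RFI).  By OLS construction, within-sex RFI has zero mean and zero sample
   correlation with MMBW and ADG.
5. FCR = total feed intake / body-weight gain over the test window.

BW8 and BW15 (body weight at the start and end of test, 56 and 105 d of age)
are the growth-line predictions at the first and last test day, which damps
weighing noise; pass ``use_fitted_endpoints=False`` for raw weighings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthFit",
    "EFIModel",
    "DegenerateGrowthData",
    "fit_growth_line",
    "midtest_weights",
    "compute_adfi",
    "fit_efi_model",
    "compute_rfi",
    "compute_fcr",
    "derive_phenotypes",
    "decile_contrast",
]

#: traits reported in the high/low-RFI decile contrast, in report order
CONTRAST_TRAITS = ["RFI", "FCR", "ADG", "ADFI", "EFI", "MMBW", "BW8", "BW15"]


class DegenerateGrowthData(ValueError):
    """Raised when a bird's records cannot support a growth-line fit."""


@dataclass(frozen=True)
class GrowthFit:
    """Per-bird linear growth fit (BW regressed on day of test)."""

    bird_id: object
    intercept: float  # g, predicted BW at DOT 0
    slope: float  # g/day = ADG estimate
    residual_sd: float
    n_days: int


@dataclass(frozen=True)
class EFIModel:
    """Within-sex expected-feed-intake regression ADFI ~ b0 + b1*MMBW + b2*ADG."""

    sex: str
    b0: float
    b1: float  # g feed per g^0.75 metabolic weight (maintenance)
    b2: float  # g feed per g/day gain (growth)
    r_squared: float
    n_birds: int

    def predict(self, mmbw, adg):
        return self.b0 + self.b1 * np.asarray(mmbw) + self.b2 * np.asarray(adg)


def fit_growth_line(records: pd.DataFrame, bird) -> GrowthFit:
    """OLS growth line for one bird; needs >= 3 distinct test days."""
    sub = records.loc[records["bird_id"] == bird]
    return _growth_fit_from_arrays(
        bird, sub["dot"].to_numpy(float), sub["bw_g"].to_numpy(float)
    )


def _growth_fit_from_arrays(bird, dot: np.ndarray, bw: np.ndarray) -> GrowthFit:
    if len(np.unique(dot)) < 3:
        raise DegenerateGrowthData(
            f"bird {bird}: need >= 3 distinct test days, got {len(np.unique(dot))}"
        )
    sxx = np.sum((dot - dot.mean()) ** 2)
    sxy = np.sum((dot - dot.mean()) * (bw - bw.mean()))
    slope = sxy / sxx
    intercept = bw.mean() - slope * dot.mean()
    resid = bw - intercept - slope * dot
    dof = max(len(dot) - 2, 1)
    return GrowthFit(
        bird_id=bird,
        intercept=float(intercept),
        slope=float(slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_days=len(dot),
    )


def midtest_weights(fit: GrowthFit, mid_dot: int = 25) -> tuple[float, float]:
    """Mid-test body weight and its metabolic (0.75-power) scaling."""
    mbw = fit.intercept + fit.slope * mid_dot
    if mbw <= 0:
        raise ValueError(
            f"bird {fit.bird_id}: nonphysical trajectory, predicted mid-test BW "
            f"{mbw:.1f} g <= 0"
        )
    return float(mbw), float(mbw**0.75)


def compute_adfi(records: pd.DataFrame, bird) -> float:
    """Average daily feed intake: total FI divided by number of test days."""
    sub = records.loc[records["bird_id"] == bird]
    n_days = sub["dot"].nunique()
    if n_days == 0:
        raise ValueError(f"bird {bird}: no test days recorded")
    return float(sub["fi_g"].sum() / n_days)


def compute_fcr(total_fi: float, bw_start: float, bw_end: float) -> float:
    """Feed conversion ratio: feed consumed per unit of weight gain.

    Non-positive gain yields NaN (flagged missing, excluded from FCR
    analyses) rather than an exception, since a handful of non-growing birds
    should not abort a batch derivation.
    """
    gain = bw_end - bw_start
    if gain <= 0:
        return float("nan")
    return float(total_fi / gain)


def fit_efi_model(phenotypes: pd.DataFrame, sex: str) -> EFIModel:
    """Within-sex OLS of ADFI on MMBW and ADG (the expected-intake model)."""
    sub = phenotypes.loc[phenotypes["sex"] == sex]
    if len(sub) < 4:
        raise ValueError(
            f"sex {sex!r}: need >= 4 birds to fit intercept + 2 slopes, got {len(sub)}"
        )
    X = np.column_stack(
        [np.ones(len(sub)), sub["MMBW"].to_numpy(float), sub["ADG"].to_numpy(float)]
    )
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(
            f"sex {sex!r}: MMBW and ADG are collinear "
            f"(design condition number {cond:.3g})"
        )
    y = sub["ADFI"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return EFIModel(
        sex=sex,
        b0=float(beta[0]),
        b1=float(beta[1]),
        b2=float(beta[2]),
        r_squared=r2,
        n_birds=len(sub),
    )


def compute_rfi(phenotypes: pd.DataFrame, model: EFIModel) -> pd.DataFrame:
    """Fill EFI and RFI for birds of the model's sex; returns a copy.

    RFI = ADFI - EFI, so ADFI == EFI + RFI holds exactly per bird, the
    within-sex RFI mean is zero, and RFI is uncorrelated with MMBW and ADG
    (OLS orthogonality) - the construction behind RFI's phenotypic
    independence from growth and metabolic weight.
    """
    out = phenotypes.copy()
    mask = out["sex"] == model.sex
    if not mask.any():
        raise ValueError(f"no birds of sex {model.sex!r} in phenotype table")
    efi = model.predict(out.loc[mask, "MMBW"], out.loc[mask, "ADG"])
    out.loc[mask, "EFI"] = efi
    out.loc[mask, "RFI"] = out.loc[mask, "ADFI"] - efi
    return out


def derive_phenotypes(
    records: pd.DataFrame,
    mid_dot: int = 25,
    use_fitted_endpoints: bool = True,
) -> tuple[pd.DataFrame, dict[str, EFIModel]]:
    """Full phenotype table from long-format daily records.

    Returns ``(phenotypes, efi_models)``.  The table is indexed by bird id
    with columns ``sex, pen, n_days, ADG, MBW, MMBW, ADFI, FI_total, BW8,
    BW15, FCR, EFI, RFI``.  Birds with fewer than 3 distinct test days are
    skipped with a warning; birds with non-positive weight gain keep their
    RFI but have missing FCR.
    """
    required = {"bird_id", "sex", "pen", "dot", "bw_g", "fi_g"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    rows = []
    for bird, sub in records.groupby("bird_id", sort=True):
        dot = sub["dot"].to_numpy(float)
        bw = sub["bw_g"].to_numpy(float)
        try:
            fit = _growth_fit_from_arrays(bird, dot, bw)
            mbw, mmbw = midtest_weights(fit, mid_dot)
        except (DegenerateGrowthData, ValueError) as exc:
            warnings.warn(f"skipping bird: {exc}", stacklevel=2)
            continue
        n_days = len(np.unique(dot))
        fi_total = float(sub["fi_g"].sum())
        first, last = dot.min(), dot.max()
        if use_fitted_endpoints:
            bw_start = fit.intercept + fit.slope * first
            bw_end = fit.intercept + fit.slope * last
        else:
            bw_start = float(bw[np.argmin(dot)])
            bw_end = float(bw[np.argmax(dot)])
        rows.append(
            {
                "bird_id": bird,
                "sex": sub["sex"].iloc[0],
                "pen": sub["pen"].iloc[0],
                "n_days": n_days,
                "ADG": fit.slope,
                "MBW": mbw,
                "MMBW": mmbw,
                "ADFI": fi_total / n_days,
                "FI_total": fi_total,
                "BW8": bw_start,
                "BW15": bw_end,
                "FCR": compute_fcr(fi_total, bw_start, bw_end),
            }
        )
    if not rows:
        raise ValueError("no birds with usable records")
    pheno = pd.DataFrame(rows).set_index("bird_id")
    pheno["EFI"] = np.nan
    pheno["RFI"] = np.nan

    models: dict[str, EFIModel] = {}
    for sex in sorted(pheno["sex"].unique()):
        model = fit_efi_model(pheno, sex)
        pheno = compute_rfi(pheno, model)
        models[sex] = model
    return pheno, models


def decile_contrast(
    phenotypes: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Contrast the highest-10%-RFI against the lowest-10%-RFI birds.

    Groups are the ``floor(0.10 * n)`` birds with the largest / smallest RFI;
    each trait is compared with Welch's two-sample t-test.  Returns one row
    per trait: group means and SDs, highest-minus-lowest difference, P-value.
    """
    pheno = phenotypes.dropna(subset=["RFI"])
    n = len(pheno)
    if n < 20:
        raise ValueError(f"decile contrast needs >= 20 birds, got {n}")
    k = n // 10
    order = pheno["RFI"].sort_values()
    low_ids = order.index[:k]
    high_ids = order.index[-k:]
    if traits is None:
        traits = [t for t in CONTRAST_TRAITS if t in pheno.columns]

    rows = []
    for trait in traits:
        hi = pheno.loc[high_ids, trait].dropna().to_numpy(float)
        lo = pheno.loc[low_ids, trait].dropna().to_numpy(float)
        if np.var(hi) == 0 and np.var(lo) == 0 and np.mean(hi) == np.mean(lo):
            pval = 1.0
        else:
            pval = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
        rows.append(
            {
                "trait": trait,
                "mean_high": float(np.mean(hi)),
                "sd_high": float(np.std(hi, ddof=1)),
                "mean_low": float(np.mean(lo)),
                "sd_low": float(np.std(lo, ddof=1)),
                "difference": float(np.mean(hi) - np.mean(lo)),
                "p_value": pval,
                "n_per_group": k,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
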