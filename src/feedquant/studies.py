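"""Replicated parameter-recovery studies.

These drive the simulator and the REML machinery end to end: populations with
a paternal half-sib pedigree (100 sires x 4 dams each x 5 offspring = 2,000
phenotyped birds by default), sex and pen fixed effects, and trait pairs
simulated with configured heritabilities and genetic/phenotypic correlations.
Each replicate re-estimates the generating parameters by single- and two-trait
animal-model REML; replicate means quantify estimator bias at study scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quantgen as qg
from . import simulate as sm

__all__ = ["RecoveryResult", "bivariate_trait_config", "recovery_study"]


@dataclass
class RecoveryResult:
    """Replicate-level and mean REML estimates for one simulated trait pair."""

    traits: tuple[str, str]
    true_h2: dict
    true_r_g: float
    h2_estimates: pd.DataFrame  # one row per replicate, one column per trait
    r_g_estimates: np.ndarray
    n_birds: int
    n_replicates: int

    @property
    def mean_h2(self) -> dict:
        return {t: float(self.h2_estimates[t].mean()) for t in self.traits}

    @property
    def mean_r_g(self) -> float:
        return float(np.mean(self.r_g_estimates))


def bivariate_trait_config(
    traits: tuple[str, str],
    h2: dict,
    sd_p: dict,
    r_g: float,
    r_p: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """G and R matrices for a trait pair from h², phenotypic SDs, r_g and r_p."""
    t1, t2 = traits
    sd_g = {t: sd_p[t] * np.sqrt(h2[t]) for t in traits}
    g12 = r_g * sd_g[t1] * sd_g[t2]
    G = pd.DataFrame(
        [[sd_g[t1] ** 2, g12], [g12, sd_g[t2] ** 2]], index=traits, columns=traits
    )
    p12 = r_p * sd_p[t1] * sd_p[t2]
    R = pd.DataFrame(
        [
            [sd_p[t1] ** 2 - G.iloc[0, 0], p12 - g12],
            [p12 - g12, sd_p[t2] ** 2 - G.iloc[1, 1]],
        ],
        index=traits,
        columns=traits,
    )
    eig = np.linalg.eigvalsh(R.to_numpy())
    if eig.min() <= 0:
        raise ValueError(
            f"residual covariance for {traits} not positive definite "
            f"(implied residual correlation out of range)"
        )
    return G, R


def recovery_study(
    traits: tuple[str, str],
    h2: dict,
    r_g: float,
    r_p: float,
    sd_p: dict,
    fixed_effects: dict,
    seed: int,
    n_replicates: int = 30,
    n_birds: int = 2000,
    n_sires: int = 100,
    fit_univariate: bool = True,
    fit_bivariate: bool = True,
) -> RecoveryResult:
    """Simulate ``n_replicates`` populations and re-estimate the parameters.

    Every replicate gets an independent seed spawned from ``seed``.  Returns
    per-replicate h² (if ``fit_univariate``) and r_g (if ``fit_bivariate``)
    estimates along with the generating values.
    """
    G, R = bivariate_trait_config(traits, h2, sd_p, r_g, r_p)
    dams_per_sire = max(n_birds // (5 * n_sires), 1)
    spec = qg.MixedModelSpec()

    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    h2_rows = []
    rg_list = []
    for rep_seed in child_seeds:
        cfg = sm.SimConfig(
            n_sires=n_sires,
            n_dams=n_sires * dams_per_sire,
            offspring_per_dam=max(n_birds // (n_sires * dams_per_sire), 1),
            n_birds_target=n_birds,
            genetic_covariance=G,
            residual_covariance=R,
            fixed_effects=fixed_effects,
            seed=int(rep_seed),
        )
        ped = sm.simulate_pedigree(cfg)
        pheno, _ = sm.simulate_trait_phenotypes(
            ped, G, R, fixed_effects, seed=int(rep_seed)
        )
        A = qg.build_relationship_matrix(ped)
        if fit_univariate:
            h2_rows.append(
                {
                    t: float(qg.reml_single_trait(pheno, t, spec, A).h2[t])
                    for t in traits
                }
            )
        if fit_bivariate:
            rg_list.append(qg.reml_two_trait(pheno, traits, spec, A).r_g)

    return RecoveryResult(
        traits=traits,
        true_h2=dict(h2),
        true_r_g=r_g,
        h2_estimates=pd.DataFrame(h2_rows, columns=list(traits)),
        r_g_estimates=np.array(rg_list),
        n_birds=n_birds,
        n_replicates=n_replicates,
    )


def rfi_fcr_fixed_effects() -> dict:
    """Sex and pen fixed effects used in the RFI/FCR recovery studies."""
    return {
        "RFI": {"mean": 0.0, "sex": {"M": 0.8, "F": -0.8},
                "pen": {f"{s}{k}": 0.2 * (k - 2) for s in "MF" for k in (1, 2, 3)}},
        "FCR": {"mean": 3.9, "sex": {"M": 0.1, "F": -0.1},
                "pen": {f"{s}{k}": 0.02 * (k - 2) for s in "MF" for k in (1, 2, 3)}},
        "ADG": {"mean": 21.0, "sex": {"M": 1.5, "F": -1.5},
                "pen": {f"{s}{k}": 0.3 * (k - 2) for s in "MF" for k in (1, 2, 3)}},
    }
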