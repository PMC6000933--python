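"""Synthetic feeding-trial populations with known genetic architecture.

Generates the four inputs the downstream analysis consumes — a two-generation
pedigree, correlated true breeding values, daily body-weight/feed-intake
records, and biallelic SNP genotypes with target allele frequencies and
pairwise linkage disequilibrium — so that every stage of the pipeline can be
exercised and validated offline against known truth.

The population emulated by the defaults is a two-sex meat-type chicken line:
roughly 900 birds per sex housed in three pens per sex, with daily feed intake
and body weight recorded over a 50-day test window starting at 56 d of age.
Latent traits are simulated jointly at the trait level (average daily gain,
start-of-test body weight, residual feed intake); average daily feed intake,
mid-test metabolic weight and end-of-test weight then emerge structurally from
the linear growth model, which keeps the generator consistent with the
phenotype-derivation stage it feeds.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LocusSpec",
    "SimConfig",
    "TrueValues",
    "SimulatedPopulation",
    "default_config",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_trait_phenotypes",
    "simulate_daily_records",
    "simulate_genotypes",
    "simulate_population",
    "max_attainable_r2",
    "load_config",
    "write_tsv",
]

UNKNOWN_PARENT = 0

# Trait keys understood by the daily-record generator.  Everything else the
# pipeline reports (ADFI, MMBW, BW15, FCR, EFI) is a deterministic function of
# these three under the linear growth model.
CORE_TRAITS = ("ADG", "BW8", "RFI")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class LocusSpec:
    """A biallelic SNP to simulate.

    Parameters
    ----------
    name
        Locus label (e.g. ``"C334A"``).
    minor_allele_frequency
        Founder frequency of the minor allele, in (0, 0.5].
    ld_partner
        Name of a second locus this one is in linkage disequilibrium with.
        Haplotypes for the pair are drawn jointly; each locus may appear in at
        most one pair.
    ld_r2
        Target pairwise r² with ``ld_partner`` (coupling phase: minor alleles
        co-occur).  Must be attainable given the two allele frequencies.
    additive_effect
        Per-copy-of-minor-allele additive effect on latent traits, keyed by
        trait name (``"ADFI"`` and/or ``"ADG"``), in trait units.
    """

    name: str
    minor_allele_frequency: float
    ld_partner: str | None = None
    ld_r2: float = 0.0
    additive_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.minor_allele_frequency <= 0.5:
            raise ConfigurationError(
                f"locus {self.name}: MAF must be in (0, 0.5], "
                f"got {self.minor_allele_frequency}"
            )
        if not 0.0 <= self.ld_r2 <= 1.0:
            raise ConfigurationError(
                f"locus {self.name}: ld_r2 must be in [0, 1], got {self.ld_r2}"
            )


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic feeding trial."""

    n_sires: int = 100
    n_dams: int = 200
    offspring_per_dam: int = 6
    n_birds_target: int | None = 1220
    sex_ratio: float = 0.5  # fraction male
    n_pens_per_sex: int = 3
    test_days: int = 50
    mid_dot: int = 25
    genetic_covariance: pd.DataFrame | None = None
    residual_covariance: pd.DataFrame | None = None
    fixed_effects: dict = field(default_factory=dict)
    # per-sex structural feed-intake coefficients (b0, b1, b2):
    # latent ADFI = b0 + b1*MMBW + b2*ADG + RFI
    efi_coefficients: dict = field(default_factory=dict)
    bw_noise_sd: float = 25.0
    fi_noise_sd: float = 8.0
    loci: Sequence[LocusSpec] = field(default_factory=list)
    n_genotyped: int | None = 527
    seed: int = 0

    def validate(self) -> None:
        if self.n_sires <= 0 or self.n_dams <= 0:
            raise ConfigurationError("n_sires and n_dams must be positive")
        if self.offspring_per_dam <= 0:
            raise ConfigurationError("offspring_per_dam must be positive")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ConfigurationError("sex_ratio must lie strictly in (0, 1)")
        if self.n_birds_target is not None and self.n_birds_target <= 0:
            raise ConfigurationError("n_birds_target must be positive")
        if self.test_days < 3:
            raise ConfigurationError("test_days must be at least 3")
        for mat, label in (
            (self.genetic_covariance, "genetic_covariance"),
            (self.residual_covariance, "residual_covariance"),
        ):
            if mat is not None:
                _check_psd(np.asarray(mat, dtype=float), label)


def _check_psd(mat: np.ndarray, label: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError(f"{label} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigurationError(f"{label} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals).max()):
        raise ConfigurationError(
            f"{label} is not positive semidefinite "
            f"(smallest eigenvalue {eigvals.min():.3e})"
        )
    return mat


def _cov_from_correlations(
    sds: Mapping[str, float], corr: Mapping[tuple[str, str], float]
) -> pd.DataFrame:
    traits = list(sds)
    mat = np.eye(len(traits))
    for (a, b), r in corr.items():
        i, j = traits.index(a), traits.index(b)
        mat[i, j] = mat[j, i] = r
    sd = np.array([sds[t] for t in traits])
    return pd.DataFrame(mat * np.outer(sd, sd), index=traits, columns=traits)


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale default configuration.

    Heritabilities: h²(ADG)=0.383, h²(BW8)=0.305, h²(RFI)=0.282.  Phenotypic
    scales follow the observed population (ADG sd ≈ 3.9 g/d, start-of-test BW
    sd ≈ 86 g, RFI sd ≈ 5.5 g/d).  Genetic correlations: RFI–ADG −0.198,
    RFI–BW8 0.0281; ADG–BW8 set to 0.30 (moderate, typical of growth traits).
    Residual covariances are chosen so the phenotypic correlations match the
    observed near-zero RFI–ADG and 0.111 RFI–BW8 values.
    """
    h2 = {"ADG": 0.383, "BW8": 0.305, "RFI": 0.282}
    sd_p = {"ADG": 3.9, "BW8": 86.0, "RFI": 5.5}
    rg = {("ADG", "BW8"): 0.30, ("ADG", "RFI"): -0.198, ("BW8", "RFI"): 0.0281}
    rp = {("ADG", "BW8"): 0.25, ("ADG", "RFI"): 0.0, ("BW8", "RFI"): 0.111}

    traits = list(h2)
    sd_g = {t: sd_p[t] * np.sqrt(h2[t]) for t in traits}
    G = _cov_from_correlations(sd_g, rg)
    P = _cov_from_correlations(sd_p, rp)
    R = P - G
    _check_psd(R.to_numpy(), "residual_covariance (derived)")

    fixed = {
        "ADG": {"mean": 0.0, "sex": {"M": 22.7, "F": 19.6}, "pen": {}},
        "BW8": {"mean": 0.0, "sex": {"M": 802.0, "F": 671.0}, "pen": {}},
        "RFI": {"mean": 0.0, "sex": {"M": 0.0, "F": 0.0}, "pen": {}},
    }
    # small pen effects on growth traits (g); pens labelled M1..M3 / F1..F3
    for trait, scale in (("ADG", 0.4), ("BW8", 8.0)):
        fixed[trait]["pen"] = {
            f"{s}{k}": scale * (k - 2) for s in "MF" for k in (1, 2, 3)
        }

    loci = [
        LocusSpec("G176A", 0.36, ld_partner="G219A", ld_r2=0.704),
        LocusSpec("G219A", 0.40),
        LocusSpec(
            "C334A", 0.32, ld_partner="G1290A", ld_r2=0.428,
            additive_effect={"ADFI": 1.7, "ADG": 0.45},
        ),
        LocusSpec("G1290A", 0.48, additive_effect={"ADFI": 1.3}),
        LocusSpec("C448T", 0.25),
        LocusSpec("T3325C", 0.15),
        LocusSpec("C5818T", 0.30),
        LocusSpec("G6058A", 0.35, ld_partner="A6163G", ld_r2=0.412),
        LocusSpec("A6163G", 0.38),
        LocusSpec("G6768A", 0.20),
    ]

    return SimConfig(
        genetic_covariance=G,
        residual_covariance=R,
        fixed_effects=fixed,
        efi_coefficients={"M": (0.0, 0.30, 0.80), "F": (-4.0, 0.30, 0.80)},
        loci=loci,
        seed=seed,
    )


@dataclass
class TrueValues:
    """Ground truth for a simulated population (for parameter-recovery tests)."""

    breeding_values: pd.DataFrame  # index bird id, columns traits
    environmental: pd.DataFrame  # residual trait deviations, same shape
    fixed: pd.DataFrame  # fixed-effect contribution per trait
    latent: pd.DataFrame  # fixed + bv + env (+ genotype effects)
    genotype_shift: pd.DataFrame | None = None


@dataclass
class SimulatedPopulation:
    config: SimConfig
    pedigree: pd.DataFrame
    true_values: TrueValues
    records: pd.DataFrame
    genotypes: pd.DataFrame | None


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Two-generation mating pedigree with sexed, penned offspring.

    Founders (sires then dams, unknown parents) are followed by offspring;
    dams are assigned to sires round-robin so paternal half-sib families of
    roughly ``n_dams / n_sires`` dams each arise.  Offspring sex counts are
    within one bird of ``n * sex_ratio``; pens are balanced within sex.

    Returns a DataFrame with columns ``id, sire, dam, sex, pen, is_founder``.
    ``0`` encodes an unknown parent.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    sires = np.arange(1, config.n_sires + 1)
    dams = np.arange(config.n_sires + 1, config.n_sires + config.n_dams + 1)
    dam_sire = sires[np.arange(config.n_dams) % config.n_sires]

    n_off = config.n_dams * config.offspring_per_dam
    if config.n_birds_target is not None:
        n_off = min(n_off, config.n_birds_target)

    off_ids = np.arange(dams[-1] + 1, dams[-1] + 1 + n_off)
    # cycle dams so truncation by n_birds_target stays balanced across families
    dam_idx = np.arange(n_off) % config.n_dams
    off_dam = dams[dam_idx]
    off_sire = dam_sire[dam_idx]

    n_male = int(round(n_off * config.sex_ratio))
    sexes = np.array(["M"] * n_male + ["F"] * (n_off - n_male))
    rng.shuffle(sexes)

    pens = np.empty(n_off, dtype=object)
    for s in ("M", "F"):
        idx = np.flatnonzero(sexes == s)
        pens[idx] = [f"{s}{1 + i % config.n_pens_per_sex}" for i in range(len(idx))]

    founders = pd.DataFrame(
        {
            "id": np.concatenate([sires, dams]),
            "sire": UNKNOWN_PARENT,
            "dam": UNKNOWN_PARENT,
            "sex": ["M"] * len(sires) + ["F"] * len(dams),
            "pen": "",
            "is_founder": True,
        }
    )
    offspring = pd.DataFrame(
        {
            "id": off_ids,
            "sire": off_sire,
            "dam": off_dam,
            "sex": sexes,
            "pen": pens,
            "is_founder": False,
        }
    )
    return pd.concat([founders, offspring], ignore_index=True)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def _psd_factor(mat: np.ndarray, label: str) -> np.ndarray:
    """Matrix square root via eigendecomposition; errors on negative eigenvalues."""
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh(mat)
    tol = -1e-8 * max(1.0, abs(w).max())
    if w.min() < tol:
        raise ConfigurationError(
            f"{label} is not positive semidefinite: eigenvalue {w.min():.6g} < 0"
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_breeding_values(
    pedigree: pd.DataFrame,
    genetic_covariance: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Draw true breeding values down a pedigree.

    Founders are sampled from N(0, G).  A non-founder receives the mean of its
    parents' values plus an independent Mendelian-sampling deviation with
    covariance G/2 (non-inbred base convention, appropriate for the shallow
    two-generation pedigrees simulated here).

    Returns a DataFrame indexed by bird id with one column per trait.
    """
    G = np.asarray(genetic_covariance, dtype=float)
    traits = list(genetic_covariance.columns)
    L = _psd_factor(G, "genetic_covariance")
    L_half = _psd_factor(G / 2.0, "genetic_covariance/2")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    ids = pedigree["id"].to_numpy()
    pos = {i: k for k, i in enumerate(ids)}
    bv = np.zeros((len(ids), len(traits)))

    founder_mask = (pedigree["sire"].to_numpy() == UNKNOWN_PARENT) & (
        pedigree["dam"].to_numpy() == UNKNOWN_PARENT
    )
    z = rng.standard_normal((int(founder_mask.sum()), len(traits)))
    bv[founder_mask] = z @ L.T

    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    for k in np.flatnonzero(~founder_mask):
        s, d = sires[k], dams[k]
        mid = np.zeros(len(traits))
        if s != UNKNOWN_PARENT:
            mid += 0.5 * bv[pos[s]]
        if d != UNKNOWN_PARENT:
            mid += 0.5 * bv[pos[d]]
        bv[k] = mid + L_half @ rng.standard_normal(len(traits))

    return pd.DataFrame(bv, index=pd.Index(ids, name="id"), columns=traits)


def simulate_trait_phenotypes(
    pedigree: pd.DataFrame,
    genetic_covariance: pd.DataFrame,
    residual_covariance: pd.DataFrame,
    fixed_effects: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    genotype_shift: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate trait records directly (no daily-record layer).

    Offspring phenotype = fixed effects + breeding value + residual deviation
    (+ optional per-bird genotype shift).  This is the generator used for
    variance-component recovery studies, where traits such as RFI and FCR are
    simulated as a correlated pair with configured heritabilities.

    Returns ``(phenotypes, true_values)`` where phenotypes has columns
    ``sex, pen`` plus one column per trait, indexed by bird id (offspring only).
    """
    traits = list(genetic_covariance.columns)
    bv = simulate_breeding_values(pedigree, genetic_covariance, seed)

    off = pedigree.loc[~pedigree["is_founder"]].set_index("id")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    L_r = _psd_factor(np.asarray(residual_covariance, dtype=float), "residual_covariance")
    env = pd.DataFrame(
        rng.standard_normal((len(off), len(traits))) @ L_r.T,
        index=off.index,
        columns=traits,
    )

    fixed = pd.DataFrame(0.0, index=off.index, columns=traits)
    fixed_effects = fixed_effects or {}
    for trait in traits:
        spec = fixed_effects.get(trait, {})
        fixed[trait] += spec.get("mean", 0.0)
        for effect, col in (("sex", "sex"), ("pen", "pen")):
            levels = spec.get(effect, {})
            if levels:
                missing = sorted(set(off[col]) - set(levels))
                if missing:
                    raise ConfigurationError(
                        f"missing {effect} level(s) {missing} in fixed effects "
                        f"for trait {trait}"
                    )
                fixed[trait] += off[col].map(levels).astype(float).to_numpy()

    latent = fixed + bv.loc[off.index] + env
    if genotype_shift is not None:
        latent = latent.add(genotype_shift.reindex(latent.index, fill_value=0.0)[
            [c for c in genotype_shift.columns if c in traits]
        ], fill_value=0.0)

    pheno = pd.concat([off[["sex", "pen"]], latent], axis=1)
    tv = TrueValues(
        breeding_values=bv,
        environmental=env,
        fixed=fixed,
        latent=latent,
        genotype_shift=genotype_shift,
    )
    return pheno, tv


# ---------------------------------------------------------------------------
# daily records
# ---------------------------------------------------------------------------

def simulate_daily_records(
    true_values: TrueValues, config: SimConfig, pedigree: pd.DataFrame
) -> pd.DataFrame:
    """Daily body-weight and feed-intake records from latent traits.

    Per bird: BW on test day ``d`` is ``(BW8 − ADG) + ADG·d`` plus iid
    weighing noise, so the latent growth line passes through BW8 at day 1.
    Daily feed intake is latent ADFI plus iid noise, where latent ADFI is the
    structural model ``b0 + b1·MMBW + b2·ADG + RFI`` with the bird's true
    mid-test metabolic weight and sex-specific coefficients.  With the noise
    SDs set to zero the derivation stage recovers every configured quantity
    exactly (closure property).
    """
    if config.test_days < 3:
        raise ConfigurationError("test_days must be at least 3")
    latent = true_values.latent
    off = pedigree.loc[~pedigree["is_founder"]].set_index("id")
    off = off.loc[latent.index]

    for sex in off["sex"].unique():
        if sex not in config.efi_coefficients:
            raise ConfigurationError(f"no EFI coefficients configured for sex {sex!r}")

    adg = latent["ADG"].to_numpy()
    bw8 = latent["BW8"].to_numpy()
    rfi = latent["RFI"].to_numpy()
    intercept = bw8 - adg  # BW at DOT 0 so that BW(1) = BW8

    mbw = intercept + adg * config.mid_dot
    if np.any(mbw <= 0):
        raise ConfigurationError("nonphysical trajectory: mid-test BW <= 0")
    mmbw = mbw ** 0.75

    coeffs = np.array(
        [config.efi_coefficients[s] for s in off["sex"]], dtype=float
    )
    adfi = coeffs[:, 0] + coeffs[:, 1] * mmbw + coeffs[:, 2] * adg + rfi

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    days = np.arange(1, config.test_days + 1)
    n = len(off)

    bw = intercept[:, None] + adg[:, None] * days[None, :]
    if config.bw_noise_sd > 0:
        bw = bw + rng.normal(0.0, config.bw_noise_sd, size=bw.shape)
    fi = np.broadcast_to(adfi[:, None], (n, len(days))).copy()
    if config.fi_noise_sd > 0:
        fi = fi + rng.normal(0.0, config.fi_noise_sd, size=fi.shape)

    rec = pd.DataFrame(
        {
            "bird_id": np.repeat(off.index.to_numpy(), len(days)),
            "sex": np.repeat(off["sex"].to_numpy(), len(days)),
            "pen": np.repeat(off["pen"].to_numpy(), len(days)),
            "dot": np.tile(days, n),
            "bw_g": bw.ravel(),
            "fi_g": fi.ravel(),
        }
    )
    return rec


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def max_attainable_r2(p1: float, p2: float) -> float:
    """Maximum r² between two loci with minor-allele frequencies p1, p2
    when the minor alleles are in coupling phase."""
    q1, q2 = 1.0 - p1, 1.0 - p2
    d_max = min(p1 * q2, p2 * q1)
    return d_max**2 / (p1 * q1 * p2 * q2)


def _pair_haplotype_freqs(p1: float, p2: float, r2: float, names: tuple[str, str]):
    """Coupling-phase haplotype frequencies achieving a target r²."""
    q1, q2 = 1.0 - p1, 1.0 - p2
    r2_max = max_attainable_r2(p1, p2)
    if r2 > r2_max + 1e-12:
        raise ConfigurationError(
            f"ld_r2={r2} unattainable for loci {names[0]} (MAF {p1}) and "
            f"{names[1]} (MAF {p2}); maximum attainable r² is {r2_max:.4f}"
        )
    d = np.sqrt(r2 * p1 * q1 * p2 * q2)
    # order: (minor,minor), (minor,major), (major,minor), (major,major)
    freqs = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def simulate_genotypes(
    pedigree: pd.DataFrame, loci: Sequence[LocusSpec], seed: int
) -> pd.DataFrame:
    """Founder haplotypes with target MAF/LD, dropped through the pedigree.

    Loci linked by ``ld_partner`` form two-locus haplotype blocks drawn
    jointly in founders; unlinked loci are independent Bernoulli haplotypes.
    Gametes are transmitted without recombination within a block (tight
    within-gene SNPs), which preserves LD down the pedigree; at large founder
    counts each locus is in Hardy-Weinberg proportions among founders.

    Returns a bird × locus DataFrame of minor-allele dosages (0/1/2).
    """
    by_name = {l.name: l for l in loci}
    pairs: list[tuple[LocusSpec, LocusSpec]] = []
    singles: list[LocusSpec] = []
    seen: set[str] = set()
    for l in loci:
        if l.name in seen:
            continue
        if l.ld_partner is not None:
            if l.ld_partner not in by_name:
                raise ConfigurationError(
                    f"locus {l.name}: unknown ld_partner {l.ld_partner!r}"
                )
            partner = by_name[l.ld_partner]
            pairs.append((l, partner))
            seen.update({l.name, partner.name})
        else:
            singles.append(l)
            seen.add(l.name)
    singles = [l for l in singles if l.name not in {p.name for pr in pairs for p in pr}]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    ids = pedigree["id"].to_numpy()
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    founder_mask = (pedigree["sire"].to_numpy() == UNKNOWN_PARENT) & (
        pedigree["dam"].to_numpy() == UNKNOWN_PARENT
    )
    n_founders = int(founder_mask.sum())

    locus_names = [l.name for l in loci]
    # haplotypes[b, h, j]: bird b, haplotype copy h in {0,1}, locus j
    haplo = np.zeros((n, 2, len(locus_names)), dtype=np.int8)
    col = {name: j for j, name in enumerate(locus_names)}

    for l1, l2 in pairs:
        freqs = _pair_haplotype_freqs(
            l1.minor_allele_frequency,
            l2.minor_allele_frequency,
            l1.ld_r2,
            (l1.name, l2.name),
        )
        draw = rng.choice(4, size=(n_founders, 2), p=freqs)
        a1 = (draw < 2).astype(np.int8)  # minor at locus 1 for categories 0,1
        a2 = ((draw == 0) | (draw == 2)).astype(np.int8)  # minor at locus 2
        haplo[founder_mask, :, col[l1.name]] = a1
        haplo[founder_mask, :, col[l2.name]] = a2
    for l in singles:
        haplo[founder_mask, :, col[l.name]] = rng.random(
            (n_founders, 2)
        ) < l.minor_allele_frequency

    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    block_cols = [[col[a.name], col[b.name]] for a, b in pairs] + [
        [col[l.name]] for l in singles
    ]
    for k in np.flatnonzero(~founder_mask):
        for parent_slot, parent in ((0, sires[k]), (1, dams[k])):
            if parent == UNKNOWN_PARENT:
                raise ConfigurationError(
                    f"non-founder {ids[k]} has an unknown parent; cannot transmit"
                )
            pk = pos[parent]
            for cols in block_cols:
                gamete = rng.integers(2)
                haplo[k, parent_slot, cols] = haplo[pk, gamete, cols]

    dosage = haplo.sum(axis=1)
    return pd.DataFrame(
        dosage, index=pd.Index(ids, name="bird_id"), columns=locus_names
    )


# ---------------------------------------------------------------------------
# full population
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Pedigree → breeding values → genotypes → daily records, one call."""
    config.validate()
    if config.genetic_covariance is None or config.residual_covariance is None:
        raise ConfigurationError(
            "genetic_covariance and residual_covariance are required; "
            "see default_config()"
        )
    ped = simulate_pedigree(config)

    genotypes = None
    shift = None
    if config.loci:
        genotypes = simulate_genotypes(ped, config.loci, config.seed)
        off_ids = ped.loc[~ped["is_founder"], "id"]
        shift_cols: dict[str, np.ndarray] = {}
        for l in config.loci:
            for trait, eff in l.additive_effect.items():
                key = "RFI" if trait == "ADFI" else trait
                shift_cols.setdefault(key, np.zeros(len(off_ids)))
                shift_cols[key] = shift_cols[key] + eff * genotypes.loc[
                    off_ids, l.name
                ].to_numpy().astype(float)
        if shift_cols:
            shift = pd.DataFrame(shift_cols, index=pd.Index(off_ids.to_numpy(), name="id"))

    # SNP effects on feed intake enter through the RFI slot of the structural
    # ADFI model (they shift intake at fixed MMBW/ADG); effects on ADG enter ADG.
    pheno, tv = simulate_trait_phenotypes(
        ped,
        config.genetic_covariance,
        config.residual_covariance,
        config.fixed_effects,
        seed=config.seed,
        genotype_shift=shift,
    )
    records = simulate_daily_records(tv, config, ped)

    if genotypes is not None and config.n_genotyped is not None:
        off_ids = ped.loc[~ped["is_founder"], "id"].to_numpy()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
        keep = rng.choice(
            off_ids, size=min(config.n_genotyped, len(off_ids)), replace=False
        )
        genotypes = genotypes.loc[np.sort(keep)]
    elif genotypes is not None:
        genotypes = genotypes.loc[ped.loc[~ped["is_founder"], "id"].to_numpy()]

    return SimulatedPopulation(config, ped, tv, records, genotypes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, seed: int | None = None, index: bool = False) -> None:
    """Write a TSV with an optional provenance header recording the seed."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_pedigree_tsv(pedigree: pd.DataFrame, path, seed: int | None = None) -> None:
    write_tsv(pedigree[["id", "sire", "dam"]], path, seed=seed)


def load_config(path) -> SimConfig:
    """Load a SimConfig from YAML; unspecified fields keep package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(seed=raw.pop("seed", 0))
    if "loci" in raw:
        cfg.loci = [LocusSpec(**l) for l in raw.pop("loci")]
    for key in ("genetic_covariance", "residual_covariance"):
        if key in raw:
            block = raw.pop(key)
            setattr(
                cfg,
                key,
                pd.DataFrame(block["matrix"], index=block["traits"], columns=block["traits"]),
            )
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown configuration key {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def config_to_yaml(config: SimConfig) -> str:
    """Serialise a SimConfig back to YAML (round-trips through load_config)."""
    d = dataclasses.asdict(config)
    d["efi_coefficients"] = {k: list(v) for k, v in config.efi_coefficients.items()}
    for key in ("genetic_covariance", "residual_covariance"):
        mat = getattr(config, key)
        d[key] = (
            None
            if mat is None
            else {"traits": list(mat.columns), "matrix": mat.to_numpy().tolist()}
        )
    d["loci"] = [
        {k: v for k, v in dataclasses.asdict(l).items() if v not in (None, {}, 0.0) or k in ("name", "minor_allele_frequency")}
        for l in config.loci
    ]
    buf = io.StringIO()
    yaml.safe_dump(d, buf, sort_keys=False)
    return buf.getvalue()
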