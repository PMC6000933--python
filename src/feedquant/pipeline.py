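"""End-to-end orchestration: simulate (or load) -> derive phenotypes ->
estimate genetic parameters -> SNP popgen -> association, with a consolidated
report (TSV table analogues + machine-readable JSON + log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import io as fio
from . import popgen as popgen_mod
from . import quantgen as qg
from . import simulate as sim_mod
from .phenotypes import decile_contrast, derive_phenotypes

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)

REML_TRAITS = ["RFI", "FCR", "BW8", "BW15", "ADG", "MMBW", "ADFI"]
ASSOC_TRAITS = ["RFI", "FCR", "FI_kg", "EFI", "ADFI", "ADG"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Either a simulation block or paths to real data, plus analysis knobs."""

    sim: sim_mod.SimConfig | None = None
    records_path: str | None = None
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    mid_dot: int = 25
    hwe_threshold: float = 0.05
    d_prime_threshold: float = 0.75
    alpha: float = 0.05
    reml_traits: list[str] = field(default_factory=lambda: list(REML_TRAITS))
    assoc_traits: list[str] = field(default_factory=lambda: list(ASSOC_TRAITS))
    family_effect: str = "sire"  # sire | dam | fullsib
    outdir: str = "feedquant_out"
    seed: int = 0
    write_vcf: bool = False

    def validate(self) -> None:
        if self.sim is None and self.records_path is None:
            raise ValueError(
                "configuration needs either a simulation block or a records path"
            )
        if self.sim is None and self.pedigree_path is None:
            raise ValueError("real-data runs need a pedigree path")


def _family_codes(pedigree: pd.DataFrame, kind: str) -> pd.Series:
    ped = pedigree.set_index("id")
    if kind == "sire":
        fam = ped["sire"].astype(str)
    elif kind == "dam":
        fam = ped["dam"].astype(str)
    elif kind == "fullsib":
        fam = ped["sire"].astype(str) + "x" + ped["dam"].astype(str)
    else:
        raise ValueError(f"unknown family effect {kind!r}")
    fam.name = "family"
    return fam


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the JSON-serialisable summary dictionary (also written to
    ``summary.json``).  Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_file = logging.FileHandler(outdir / "pipeline.log", mode="w")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("feedquant")
    root.addHandler(log_file)
    root.setLevel(logging.INFO)

    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(log_file)
        log_file.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    import feedquant

    summary: dict = {
        "seed": config.seed,
        "versions": {
            "feedquant": feedquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    @_stage("inputs")
    def stage_inputs():
        if config.sim is not None:
            config.sim.seed = config.seed
            pop = sim_mod.simulate_population(config.sim)
            sim_mod.write_tsv(pop.records, outdir / "records.tsv", seed=config.seed)
            sim_mod.write_pedigree_tsv(pop.pedigree, outdir / "pedigree.tsv", seed=config.seed)
            if pop.genotypes is not None:
                sim_mod.write_tsv(
                    pop.genotypes.reset_index(), outdir / "genotypes.tsv", seed=config.seed
                )
                if config.write_vcf:
                    fio.write_genotypes_vcf(pop.genotypes, outdir / "genotypes.vcf")
            return pop.records, pop.pedigree, pop.genotypes
        records = fio.read_records_tsv(config.records_path)
        pedigree = fio.read_pedigree_tsv(config.pedigree_path)
        genotypes = None
        if config.genotypes_path:
            path = str(config.genotypes_path)
            genotypes = (
                fio.read_genotypes_vcf(path)
                if path.endswith(".vcf")
                else fio.read_genotypes_tsv(path)
            )
        return records, pedigree, genotypes

    records, pedigree, genotypes = stage_inputs()

    @_stage("derive-phenotypes")
    def stage_pheno():
        pheno, models = derive_phenotypes(records, mid_dot=config.mid_dot)
        pheno["FI_kg"] = pheno["FI_total"] / 1000.0
        sim_mod.write_tsv(pheno.reset_index(), outdir / "phenotypes.tsv", seed=config.seed)
        contrast = decile_contrast(pheno)
        sim_mod.write_tsv(contrast.reset_index(), outdir / "table1_decile_contrast.tsv")
        return pheno, models, contrast

    pheno, efi_models, contrast = stage_pheno()
    summary["efi_models"] = {
        s: {"b0": m.b0, "b1": m.b1, "b2": m.b2, "r_squared": m.r_squared, "n": m.n_birds}
        for s, m in efi_models.items()
    }
    summary["table1_decile_contrast"] = contrast.reset_index().to_dict(orient="records")

    @_stage("estimate")
    def stage_estimate():
        A = qg.build_relationship_matrix(pedigree)
        spec = qg.MixedModelSpec()
        h2: dict[str, float] = {}
        h2_se: dict[str, float] = {}
        for trait in config.reml_traits:
            vc = qg.reml_single_trait(pheno, trait, spec, A)
            h2[trait] = float(vc.h2[trait])
            h2_se[trait] = float(vc.h2_se[trait])
        corr_rows = []
        rg: dict[tuple[str, str], float] = {}
        primaries = [t for t in ("RFI", "FCR") if t in config.reml_traits]
        seen = set()
        for p in primaries:
            for s in config.reml_traits:
                if s == p or frozenset((p, s)) in seen:
                    continue
                seen.add(frozenset((p, s)))
                vc = qg.reml_two_trait(pheno, (p, s), spec, A)
                rg[(p, s)] = vc.r_g
                corr_rows.append(
                    {
                        "trait1": p,
                        "trait2": s,
                        "r_g": vc.r_g,
                        "r_g_se": vc.r_g_se,
                        "r_p": vc.r_p,
                        "r_p_se": vc.r_p_se,
                        "n_birds": vc.n_birds,
                    }
                )
        table2 = pd.DataFrame(
            {"trait": list(h2), "h2": list(h2.values()), "se": [h2_se[t] for t in h2]}
        )
        table3 = pd.DataFrame(corr_rows)
        secondary = [t for t in config.reml_traits if t not in primaries]
        table4 = qg.efficiency_table(h2, rg, primaries, secondary)
        sim_mod.write_tsv(table2, outdir / "table2_heritability.tsv")
        sim_mod.write_tsv(table3, outdir / "table3_correlations.tsv")
        sim_mod.write_tsv(table4.reset_index(), outdir / "table4_selection_efficiency.tsv")
        return table2, table3, table4

    table2, table3, table4 = stage_estimate()
    summary["table2_heritability"] = table2.to_dict(orient="records")
    summary["table3_correlations"] = table3.to_dict(orient="records")
    summary["table4_selection_efficiency"] = json.loads(table4.to_json())

    if genotypes is not None:
        @_stage("popgen")
        def stage_popgen():
            geno = genotypes.loc[genotypes.index.intersection(pheno.index)]
            hwe = popgen_mod.hwe_table(geno)
            sim_mod.write_tsv(hwe.reset_index(), outdir / "hwe.tsv")
            kept = popgen_mod.filter_hwe(geno, config.hwe_threshold)
            dp, r2, stats_list = popgen_mod.pairwise_ld(kept, seed=config.seed)
            strong = popgen_mod.classify_ld(stats_list, config.d_prime_threshold)
            sim_mod.write_tsv(dp.reset_index(), outdir / "table5_d_prime.tsv")
            sim_mod.write_tsv(r2.reset_index(), outdir / "table5_r2.tsv")
            sim_mod.write_tsv(strong, outdir / "ld_classification.tsv")
            return geno, hwe, r2, strong

        geno, hwe, r2, strong = stage_popgen()
        summary["hwe"] = hwe.reset_index().to_dict(orient="records")
        summary["ld_strong_pairs"] = strong.loc[strong["strong_ld"]].to_dict(orient="records")

        @_stage("associate")
        def stage_assoc():
            family = _family_codes(pedigree, config.family_effect)
            traits = [t for t in config.assoc_traits if t in pheno.columns]
            table6 = assoc_mod.association_table(
                pheno, geno, list(geno.columns), traits, family, config.alpha
            )
            sim_mod.write_tsv(table6, outdir / "table6_association.tsv")
            return table6

        table6 = stage_assoc()
        summary["table6_association"] = table6.to_dict(orient="records")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    logger.info("report bundle written to %s", outdir)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
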