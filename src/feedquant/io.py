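"""Readers and writers for the pipeline's tabular formats.

Daily records, pedigrees, phenotypes and genotypes travel as TSV with an
optional ``# key=value`` provenance header.  Genotypes can also be written to
and read from VCF v4.2 (via pysam), with dosage taken over the ALT allele.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "read_tsv",
    "read_records_tsv",
    "read_pedigree_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
]

_LOCUS_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """TSV reader tolerating ``#`` provenance/comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_records_tsv(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"bird_id", "sex", "pen", "dot", "bw_g", "fi_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} missing columns {sorted(missing)}")
    return df


def read_pedigree_tsv(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"id", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file {path} missing columns {sorted(missing)}")
    if "is_founder" not in df.columns:
        df["is_founder"] = (df["sire"] == 0) & (df["dam"] == 0)
    return df


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = read_tsv(path).set_index("bird_id")
    bad = [
        c for c in df.columns
        if not df[c].dropna().isin([0, 1, 2]).all()
    ]
    if bad:
        raise ValueError(f"non-dosage genotype codes in columns {bad}")
    return df


def _locus_vcf_fields(name: str, fallback_pos: int) -> tuple[str, str, int]:
    """(ref, alt, position) from a ``C334A``-style locus name, else defaults."""
    m = _LOCUS_RE.match(name)
    if m:
        return m.group(1), m.group(3), int(m.group(2))
    return "A", "G", fallback_pos


def write_genotypes_vcf(genotypes: pd.DataFrame, path, contig: str = "chr4") -> None:
    """Write dosage genotypes as an uncompressed VCF v4.2 with GT fields.

    Locus names of the form ``<ref><pos><alt>`` supply REF/ALT and POS;
    other names get placeholder alleles and positions in column order.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig}>")
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [str(s) for s in genotypes.index]
    for s in samples:
        header.add_sample(s)

    fields = []
    used = set()
    for j, name in enumerate(genotypes.columns):
        ref, alt, pos = _locus_vcf_fields(name, 10_000 + j)
        while pos in used:  # keep positions unique for well-formed output
            pos += 1
        used.add(pos)
        fields.append((name, ref, alt, pos))
    fields.sort(key=lambda t: t[3])

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for name, ref, alt, pos in fields:
            rec = vf.new_record(
                contig=contig, start=pos - 1, alleles=(ref, alt), id=name
            )
            col = genotypes[name]
            for s, sample in zip(genotypes.index, samples):
                dose = col.loc[s]
                if pd.isna(dose):
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    dose = int(dose)
                    rec.samples[sample]["GT"] = (
                        (0, 0) if dose == 0 else (0, 1) if dose == 1 else (1, 1)
                    )
            vf.write(rec)


def read_genotypes_vcf(path) -> pd.DataFrame:
    """ALT-allele dosage matrix (birds x loci) from a VCF."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        data: dict[str, list] = {}
        for rec in vf:
            name = rec.id or f"{rec.contig}:{rec.pos}"
            doses = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    doses.append(np.nan)
                else:
                    doses.append(float(sum(gt)))
            data[name] = doses
    return pd.DataFrame(data, index=pd.Index(samples, name="bird_id"))
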