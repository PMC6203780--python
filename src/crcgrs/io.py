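"""File formats: tab-separated tables, minimal VCF dosage round-trip, configs.

All tables are UTF-8 tab-separated with a header row:

* cohort table — ``participant_id`` plus covariate columns, ``time``,
  ``event``;
* dosage matrix — ``participant_id`` then one column per SNP id;
* weight table — ``snp_id``, ``effect_allele``, ``log_or``;
* GRS output — ``participant_id``, ``grs``.

Dosages can also be read from a VCF using the ``DS`` FORMAT field when
present, else hard-calls from ``GT``; multi-allelic records are rejected.
Configs are YAML or JSON, by file extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_dosages",
    "write_dosages",
    "read_weights",
    "write_weights",
    "write_grs",
    "write_dosages_vcf",
    "read_dosages_vcf",
    "load_config",
]


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: cohort table must have a participant_id column")
    return df.set_index("participant_id", drop=False)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: dosage matrix must have a participant_id column")
    return df.set_index("participant_id")


def write_dosages(dosages: pd.DataFrame, path) -> None:
    dosages.rename_axis("participant_id").to_csv(path, sep="\t")


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_weights(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def write_grs(scores: pd.Series, path) -> None:
    scores.rename("grs").rename_axis("participant_id").to_csv(path, sep="\t")


def write_dosages_vcf(
    dosages: pd.DataFrame,
    path,
    effect_alleles: dict[str, str] | None = None,
) -> None:
    """Export a dosage matrix as a minimal single-chromosome VCF.

    Each SNP becomes one biallelic record with the effect allele as ALT, so
    the DS field is the effect-allele dosage; GT carries the rounded
    hard-call.  Intended for round-trip testing of the VCF reader, not as
    a general-purpose exporter.
    """
    ids = list(dosages.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, snp in enumerate(dosages.columns, start=1):
        alt = (effect_alleles or {}).get(snp, "A")
        ref = "G" if alt != "G" else "C"
        vals = dosages[snp].to_numpy(dtype=float)
        cells = []
        for v in vals:
            if np.isnan(v):
                cells.append("./.:.")
            else:
                cells.append(f"{gt_codes[int(round(v))]}:{v:g}")
        lines.append(
            f"1\t{pos}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT:DS\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosages_vcf(path, snp_ids=None):
    """Read effect-allele (ALT) dosages from a VCF.

    Uses the DS FORMAT field when present, falling back to counting ALT
    alleles in GT.  Returns ``(dosages, alleles)`` where ``alleles`` maps
    snp_id -> (counted_allele, other_allele) for allele alignment.
    Multi-allelic records are rejected; requesting absent SNPs is an
    error.
    """
    import pysam

    wanted = set(snp_ids) if snp_ids is not None else None
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        data: dict[str, np.ndarray] = {}
        alleles: dict[str, tuple[str, str]] = {}
        for rec in vcf:
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            if wanted is not None and rid not in wanted:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos} ({rid})"
                )
            vals = np.full(len(samples), np.nan)
            for k, s in enumerate(samples):
                sample = rec.samples[s]
                ds = sample.get("DS")
                if ds is not None:
                    vals[k] = float(ds)
                else:
                    gt = sample.get("GT")
                    if gt is not None and None not in gt:
                        vals[k] = float(sum(gt))
            data[rid] = vals
            alleles[rid] = (rec.alts[0], rec.ref)
    if wanted is not None:
        missing = sorted(wanted - set(data))
        if missing:
            raise ValueError(f"SNPs absent from VCF: {missing}")
    dosages = pd.DataFrame(data, index=pd.Index(samples, name="participant_id"))
    return dosages, alleles


def load_config(path) -> dict:
    """Load a YAML or JSON configuration by extension."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    text = p.read_text()
    if p.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    if p.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {p.suffix}")
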