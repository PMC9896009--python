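"""File I/O: long-format phenotype CSV, genotype matrices (TSV / VCF),
trait metadata and simulation-truth JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import cross_id
from .simdata import GenotypeMatrix, SimTruth
from .tables import PHENO_COLUMNS, PhenotypeTable, TraitMeta

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# phenotypes

def write_phenotypes(pheno: PhenotypeTable, path: PathLike) -> None:
    pheno.data.to_csv(path, index=False)


def write_trait_meta(trait_meta: dict[str, TraitMeta], path: PathLike) -> None:
    rows = []
    for trait, meta in trait_meta.items():
        lo, hi = meta.bounds if meta.bounds else (np.nan, np.nan)
        rows.append((trait, meta.scale, meta.direction, lo, hi))
    pd.DataFrame(rows, columns=["trait", "scale", "direction",
                                "bound_low", "bound_high"]).to_csv(path, index=False)


def read_trait_meta(path: PathLike) -> dict[str, TraitMeta]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        bounds = None
        if not (pd.isna(row["bound_low"]) or pd.isna(row["bound_high"])):
            bounds = (float(row["bound_low"]), float(row["bound_high"]))
        out[row["trait"]] = TraitMeta(scale=row["scale"],
                                      direction=row["direction"], bounds=bounds)
    return out


def read_phenotypes(path: PathLike,
                    meta_path: Optional[PathLike] = None) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={c: str for c in PHENO_COLUMNS[:-1]})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"phenotype file {path} lacks required columns {missing}; "
            f"expected header {','.join(PHENO_COLUMNS)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    meta = read_trait_meta(meta_path) if meta_path else {}
    return PhenotypeTable(data=df, trait_meta=meta)


# ---------------------------------------------------------------------------
# genotypes

def write_genotypes_tsv(geno: GenotypeMatrix, path: PathLike) -> None:
    """HapMap-style tab matrix: rows = parents, columns = marker IDs."""
    geno.to_frame().to_csv(path, sep="\t", index_label="parent", na_rep="NA")


def read_genotypes_tsv(path: PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "./."])
    return GenotypeMatrix(parents=[str(i) for i in df.index],
                          markers=[str(c) for c in df.columns],
                          calls=df.to_numpy(dtype=float))


def write_genotypes_vcf(geno: GenotypeMatrix, path: PathLike) -> None:
    """Minimal VCF 4.2 with GT-only biallelic records (REF=A, ALT=T)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.parents) + "\n")
        for m, marker in enumerate(geno.markers):
            gts = []
            for i in range(geno.n_parents):
                v = geno.calls[i, m]
                gts.append("./." if np.isnan(v) else code[v])
            fh.write(f"1\t{m + 1}\t{marker}\tA\tT\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_genotypes_vcf(path: PathLike) -> GenotypeMatrix:
    """Read biallelic SNP dosages from a VCF (GT field) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    parents = list(vcf.samples)
    markers, cols = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    mapping = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(mapping[var.gt_types])
    vcf.close()
    if not markers:
        raise ValueError(f"no biallelic SNPs found in {path}")
    calls = np.column_stack(cols)
    return GenotypeMatrix(parents=parents, markers=markers, calls=calls)


def read_genotypes(path: PathLike) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_genotypes_vcf(path)
    return read_genotypes_tsv(path)


# ---------------------------------------------------------------------------
# simulation truth

def write_truth(truths: dict[str, SimTruth], path: PathLike) -> None:
    payload = {}
    for trait, t in truths.items():
        payload[trait] = {
            "parent_ids": list(t.parent_ids),
            "grand_mean": t.grand_mean,
            "env_effects": t.env_effects,
            "true_gca": t.true_gca,
            "true_sca": {f"{a}/{b}": v for (a, b), v in t.true_sca.items()},
            "var_gca": t.var_gca, "var_sca": t.var_sca,
            "var_gca_e": t.var_gca_e, "var_sca_e": t.var_sca_e,
            "var_error": t.var_error,
            "marker_effects": t.marker_effects,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: PathLike) -> dict[str, SimTruth]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for trait, d in payload.items():
        out[trait] = SimTruth(
            parent_ids=tuple(d["parent_ids"]),
            grand_mean=d["grand_mean"],
            env_effects=d["env_effects"],
            true_gca=d["true_gca"],
            true_sca={cross_id(*k.split("/")): v
                      for k, v in d["true_sca"].items()},
            var_gca=d["var_gca"], var_sca=d["var_sca"],
            var_gca_e=d["var_gca_e"], var_sca_e=d["var_sca_e"],
            var_error=d["var_error"], marker_effects=d["marker_effects"])
    return out
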