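"""File-format adapters: VCF dosages, scoring files, ancestry labels, panels.

Conventions: VCF coordinates are 1-based; the effect allele counted in a
dosage matrix is the ALT allele; dosage is taken from the DS FORMAT field
when present, else from the GT allele sum. Only biallelic records are
accepted. Scoring files are tab-separated PGS-Catalog-style tables.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    DosageMatrix,
    HaplotypePanel,
    ReplicateSet,
    SCORING_COLUMNS,
)
from .scoring import validate_model


def read_dosage_vcf(path) -> DosageMatrix:
    """Read a dosage matrix from VCF, preferring DS over GT per record."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); only biallelic sites are supported"
            )
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            # DS is carried as float32 in the htslib record; round to the
            # 5th decimal so written text values survive the round trip
            dose = np.round(np.asarray(ds, dtype=float).reshape(len(samples)), 5)
        else:
            gts = rec.genotypes
            if gts is None:
                raise ValueError(f"record at {rec.CHROM}:{rec.POS} has neither DS nor GT")
            alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
            if (alleles < 0).any():
                raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
            dose = alleles.sum(axis=1)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dose)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": pos, "ref": refs, "alt": alts}
    )
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return DosageMatrix(samples, variants, dosages)


def write_dosage_vcf(matrix: DosageMatrix, path) -> None:
    """Write a VCF 4.2 with GT (rounded best-guess) and DS (3 decimals)."""
    from .accuracy import calls_from_dosage

    order = np.lexsort(
        (matrix.variants["pos"].to_numpy(), matrix.variants["chrom"].to_numpy())
    )
    calls = calls_from_dosage(matrix.dosages)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(matrix.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
            '"Estimated ALT allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in order:
            row = matrix.variants.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["id"]),
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            fields += [
                f"{gt_strings[int(calls[i, j])]}:{matrix.dosages[i, j]:.3f}"
                for i in range(matrix.n_samples)
            ]
            fh.write("\t".join(fields) + "\n")


def read_scoring_file(path) -> pd.DataFrame:
    """Read a tab-separated PGS-Catalog-style scoring table."""
    model = pd.read_csv(path, sep="\t", comment="#", dtype={"chr_name": str})
    missing = [c for c in SCORING_COLUMNS if c not in model.columns]
    if missing:
        raise ValueError(f"scoring file {path} missing columns: {missing}")
    try:
        model["effect_weight"] = model["effect_weight"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable effect_weight in {path}: {exc}") from exc
    return validate_model(model[SCORING_COLUMNS])


def write_scoring_file(model: pd.DataFrame, path) -> None:
    validate_model(model).to_csv(path, sep="\t", index=False)


def read_ancestry(path) -> pd.Series:
    """Two-column TSV (sample, population) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"ancestry file {path} needs (sample, population) columns")
    df.columns = ["sample", "population"] + list(df.columns[2:])
    return df.set_index("sample")["population"]


def write_ancestry(samples, populations, path) -> None:
    pd.DataFrame({"sample": samples, "population": populations}).to_csv(
        path, sep="\t", index=False
    )


def write_panel(panel: HaplotypePanel, path) -> None:
    """Serialize a haplotype panel as TSV: one row per haplotype."""
    with Path(path).open("w") as fh:
        fh.write("population\t" + "\t".join(panel.variants["id"]) + "\n")
        for i in range(panel.n_haplotypes):
            fh.write(
                str(panel.populations[i])
                + "\t"
                + "\t".join(map(str, panel.alleles[i]))
                + "\n"
            )


def read_panel(path, variants: pd.DataFrame) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    ids = list(df.columns[1:])
    if ids != list(variants["id"]):
        raise ValueError(f"panel file {path} variants do not match the variant table")
    return HaplotypePanel(
        df.iloc[:, 1:].to_numpy(dtype=np.uint8),
        variants,
        df.iloc[:, 0].to_numpy(dtype=object),
    )


def write_replicate_set(replicates: ReplicateSet, outdir) -> None:
    """One VCF per replicate plus a JSON manifest (process, seeds, mask)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(replicates.k):
        write_dosage_vcf(replicates.replicate(i), outdir / f"replicate_{i + 1}.vcf")
    manifest = {
        "process": replicates.process,
        "k": replicates.k,
        "seeds": list(map(int, replicates.seeds)),
        "typed_mask": replicates.typed_mask.astype(int).tolist(),
        "metadata": {
            k: v for k, v in replicates.metadata.items() if not isinstance(v, np.ndarray)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_replicate_set(outdir) -> ReplicateSet:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    matrices = [
        read_dosage_vcf(outdir / f"replicate_{i + 1}.vcf")
        for i in range(manifest["k"])
    ]
    first = matrices[0]
    return ReplicateSet(
        process=manifest["process"],
        samples=first.samples,
        variants=first.variants,
        dosages=np.stack([m.dosages for m in matrices]),
        typed_mask=np.asarray(manifest["typed_mask"], dtype=bool),
        seeds=manifest["seeds"],
        metadata=manifest.get("metadata", {}),
    )
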