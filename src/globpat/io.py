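"""Plain-text readers and writers for all pipeline artifacts.

Counts and binary calls travel as TSV with "individual_mark" column
headers; annotations as BED4 (0-based half-open, adjacent same-state
bins merged); models as an emissions/transitions/initial TSV triple
with a JSON sidecar; genotypes as a dosage TSV or a minimal GT-only
VCF.  Binary calls can also be written per chromosome with the
two-line header convention used by segmentation tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BinaryCallMatrix,
    BinnedTrackMatrix,
    GenomeAnnotation,
    GenotypeMatrix,
    GlobalPatternModel,
)

__all__ = [
    "write_counts",
    "read_counts",
    "write_calls",
    "read_calls",
    "write_calls_per_chrom",
    "write_annotation_bed",
    "read_bed",
    "write_model",
    "read_model",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "read_vcf",
]


def _split_track_ids(ids: list[str]) -> pd.DataFrame:
    rows = []
    for t in ids:
        ind, _, mark = t.rpartition("_")
        rows.append((ind, mark))
    return pd.DataFrame(rows, columns=["individual", "mark"])


def write_counts(mat: BinnedTrackMatrix, path) -> None:
    frame = pd.DataFrame(mat.values, columns=mat.track_ids)
    out = pd.concat([mat.bins[["chrom", "start", "end"]], frame], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> BinnedTrackMatrix:
    df = pd.read_csv(path, sep="\t")
    bins = df[["chrom", "start", "end"]]
    track_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return BinnedTrackMatrix(df[track_cols].to_numpy(float), bins, _split_track_ids(track_cols))


def write_calls(calls: BinaryCallMatrix, path) -> None:
    frame = pd.DataFrame(calls.calls, columns=calls.track_ids)
    out = pd.concat([calls.bins[["chrom", "start", "end"]], frame], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> BinaryCallMatrix:
    df = pd.read_csv(path, sep="\t")
    bins = df[["chrom", "start", "end"]]
    track_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return BinaryCallMatrix(df[track_cols].to_numpy(), bins, _split_track_ids(track_cols))


def write_calls_per_chrom(calls: BinaryCallMatrix, outdir, cell: str = "stacked") -> list[Path]:
    """One file per chromosome with a two-line header (cell/chrom line,
    then the track-id line), matching segmentation-tool conventions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    ids = calls.track_ids
    for chrom, sl in calls.bin_table.chrom_slices().items():
        path = outdir / f"{cell}_{chrom}_binary.txt"
        with open(path, "w") as fh:
            fh.write(f"{cell}\t{chrom}\n")
            fh.write("\t".join(ids) + "\n")
            np.savetxt(fh, calls.calls[sl], fmt="%d", delimiter="\t")
        paths.append(path)
    return paths


def write_annotation_bed(annotation: GenomeAnnotation, path) -> None:
    annotation.to_bed().to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, labeled: bool = False) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["label"] if labeled else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_model(model: GlobalPatternModel, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    em = pd.DataFrame(model.emission, columns=model.track_ids)
    em.insert(0, "state", np.arange(1, model.k + 1))
    em.to_csv(f"{prefix}_emissions.tsv", sep="\t", index=False)
    pd.DataFrame(model.transition).to_csv(
        f"{prefix}_transitions.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame({"initial": model.initial}).to_csv(
        f"{prefix}_initial.tsv", sep="\t", index=False, header=False
    )
    meta = {"k": model.k, "tracks": model.track_ids, **model.meta}
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def read_model(prefix) -> GlobalPatternModel:
    em = pd.read_csv(f"{prefix}_emissions.tsv", sep="\t")
    track_cols = [c for c in em.columns if c != "state"]
    emission = em[track_cols].to_numpy(float)
    transition = pd.read_csv(f"{prefix}_transitions.tsv", sep="\t", header=None).to_numpy(float)
    initial = pd.read_csv(f"{prefix}_initial.tsv", sep="\t", header=None).to_numpy(float).ravel()
    meta_path = Path(f"{prefix}_meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    meta.pop("tracks", None)
    return GlobalPatternModel(initial, transition, emission, _split_track_ids(track_cols), meta)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(genotypes.dosages, columns=genotypes.individuals)
    out = pd.concat([genotypes.snps[["chrom", "pos", "id", "ref", "alt"]], frame], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    individuals = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(df[individuals].to_numpy(), df[meta_cols], individuals)


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT genotypes only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.individuals))
            + "\n"
        )
        for row, dose in zip(genotypes.snps.itertuples(), genotypes.dosages):
            gts = "\t".join(_GT[int(d)] for d in dose)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a dosage matrix (alt-allele count)."""
    rows, dosages, individuals = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                individuals = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            dose = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_i].replace("|", "/")
                dose.append(sum(int(a) for a in gt.split("/")))
            rows.append((chrom, pos, vid, ref, alt))
            dosages.append(dose)
    if individuals is None:
        raise ValueError("missing #CHROM header line")
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(np.array(dosages), snps, individuals)
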