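"""Reading and writing genotypes, images and result tables.

Genotypes travel either as a clone x marker dosage CSV (first column
``clone_id``, then one column per marker; a companion map CSV carries
``marker_id, chrom, pos``) or as a VCF.  VCF reading goes through cyvcf2
(GT -> alternate-allele dosage, missing -> NaN); the writer emits a minimal
sites+GT VCF whose genotypes are dosage-consistent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "write_dosage_csv",
    "read_dosage_csv",
    "write_vcf",
    "read_vcf",
    "save_image_png",
    "load_image",
]


def write_dosage_csv(geno: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.markers["marker_id"])
    df.insert(0, "clone_id", geno.clone_ids)
    df.to_csv(path, index=False)
    geno.markers.to_csv(map_path, index=False)


def read_dosage_csv(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    markers = pd.read_csv(map_path)
    clone_ids = df["clone_id"].astype(str).to_numpy()
    dos = df.drop(columns="clone_id").to_numpy(float)
    if list(df.columns[1:]) != list(markers["marker_id"].astype(str)):
        raise ValueError("dosage columns do not match the marker map")
    return GenotypeMatrix(dosages=dos, clone_ids=clone_ids, markers=markers)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT calls consistent with the dosage matrix."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(geno.markers["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(geno.clone_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, row in geno.markers.iterrows():
            calls = []
            for d in geno.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_of[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['marker_id']}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT fields into an alternate-allele dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    clone_ids = np.array(vcf.samples)
    rows, recs = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        recs.append(
            dict(marker_id=var.ID or f"{var.CHROM}_{var.POS}",
                 chrom=int(var.CHROM), pos=var.POS)
        )
    vcf.close()
    return GenotypeMatrix(
        dosages=np.array(rows).T,
        clone_ids=clone_ids,
        markers=pd.DataFrame(recs),
    )


def save_image_png(rgb: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), rgb)


def load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    rgb = iio.imread(str(path))
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[:, :, :3]
    return rgb
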