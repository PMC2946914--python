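"""Genotype container and plain-text PLINK PED/MAP (and VCF) I/O.

Genotypes are held as a dense samples x markers matrix of minor-allele
dosage (0/1/2; -1 = missing) with marker metadata alongside — the
layout every downstream QC and association step consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """samples x markers minor-allele dosage matrix.

    dosage
        int8 array, shape (n_samples, n_markers); 0/1/2 counts of the
        ``a1`` (minor/counted) allele, -1 for missing.
    samples
        sample ids, row order of ``dosage``.
    markers
        DataFrame with ``marker_id, chrom, bp, a1, a2`` (+ optional
        extra columns), column order of ``dosage``.
    """

    dosage: np.ndarray
    samples: list
    markers: pd.DataFrame

    def __post_init__(self):
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        valid = np.isin(self.dosage, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeMatrix":
        d = self.dosage
        samples = list(self.samples)
        markers = self.markers
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask, dtype=bool)
            d = d[sample_mask]
            samples = [s for s, k in zip(samples, sample_mask) if k]
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask, dtype=bool)
            d = d[:, marker_mask]
            markers = markers.loc[marker_mask]
        return GenotypeMatrix(
            dosage=d.copy(), samples=samples, markers=markers.reset_index(drop=True)
        )


def write_ped_map(g: GenotypeMatrix, prefix) -> None:
    """Write whitespace-delimited PED + MAP (alleles ACGT, missing 0)."""
    prefix = Path(prefix)
    with open(f"{prefix}.map", "w") as fh:
        for row in g.markers.itertuples(index=False):
            fh.write(f"{row.chrom} {row.marker_id} 0 {row.bp}\n")
    a1 = g.markers["a1"].to_numpy()
    a2 = g.markers["a2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            d = g.dosage[i]
            for j in range(g.n_markers):
                if d[j] < 0:
                    fields.extend(("0", "0"))
                elif d[j] == 0:
                    fields.extend((a2[j], a2[j]))
                elif d[j] == 1:
                    fields.extend((a1[j], a2[j]))
                else:
                    fields.extend((a1[j], a1[j]))
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read PED/MAP; dosage counts the rarer observed allele per marker.

    For monomorphic or allele-balanced markers the lexicographically
    smaller allele is counted, so a write/read roundtrip is stable.
    """
    prefix = Path(prefix)
    markers = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "bp"],
        dtype={"chrom": str, "marker_id": str},
    )
    m = len(markers)
    samples, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'}: expected "
                    f"{6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype="U1").reshape(len(samples), m, 2)

    dosage = np.full((len(samples), m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        called = col[:, 0] != "0"
        obs, counts = np.unique(col[called], return_counts=True)
        if len(obs) == 0:
            a1, a2 = "0", "0"
        elif len(obs) == 1:
            a1, a2 = obs[0], obs[0]
        elif len(obs) == 2:
            order = np.lexsort((obs, counts))  # rarer first, ties lexical
            a1, a2 = obs[order[0]], obs[order[1]]
        else:
            raise ValueError(f"marker {markers['marker_id'][j]}: >2 alleles observed")
        a1_list.append(a1)
        a2_list.append(a2)
        dosage[called, j] = (col[called] == a1).sum(axis=1).astype(np.int8)
    markers = markers.drop(columns=["cm"]).assign(a1=a1_list, a2=a2_list)
    return GenotypeMatrix(dosage=dosage, samples=samples, markers=markers)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text VCF 4.2 (GT only); a2 is REF."""
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.samples)
            + "\n"
        )
        for j, row in enumerate(g.markers.itertuples(index=False)):
            gts = "\t".join(gt_str[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{row.chrom}\t{row.bp}\t{row.marker_id}\t{row.a2}\t{row.a1}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (ALT-allele dosage); needs cyvcf2."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append(dosage.astype(np.int8))
        meta.append(
            {
                "marker_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "bp": var.POS,
                "a1": var.ALT[0] if var.ALT else "0",
                "a2": var.REF,
            }
        )
    dosage = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(dosage=dosage, samples=samples, markers=pd.DataFrame(meta))
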