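"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices travel as a 10x-style MatrixMarket trio (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``); everything else is tab-separated text
with a header row.  Genotypes can additionally be read from a minimal VCF
(CHROM POS ID REF ALT ... plus one GT column per line).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Genes x droplets sparse integer count matrix with identifiers."""

    matrix: sp.csr_matrix  # genes x cells
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and self.shape == other.shape
            and (self.matrix != other.matrix).nnz == 0
        )


def write_10x(counts: CountMatrix, directory: str | os.PathLike) -> None:
    """Write a CountMatrix as a 10x-style MTX trio under ``directory``."""
    os.makedirs(directory, exist_ok=True)
    mat = sp.coo_matrix(counts.matrix)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), mat, field="integer")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.writelines(b + "\n" for b in counts.barcodes)
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        fh.writelines(g + "\n" for g in counts.genes)


def read_10x(directory: str | os.PathLike) -> CountMatrix:
    """Read a 10x-style MTX trio written by :func:`write_10x`."""
    try:
        mat = scipy.io.mmread(os.path.join(directory, "matrix.mtx"))
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file in {directory}: {exc}") from exc
    with open(os.path.join(directory, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n") for line in fh if line.strip() or line == "\n"]
    with open(os.path.join(directory, "features.tsv")) as fh:
        genes = [line.rstrip("\n") for line in fh if line.strip() or line == "\n"]
    # mmread on a 0-column matrix returns a coo with the declared shape
    return CountMatrix(sp.csr_matrix(mat), genes=genes, barcodes=barcodes)


def write_table(df: pd.DataFrame, path: str | os.PathLike, comment: str | None = None) -> None:
    """Write a DataFrame as TSV; optional '#'-prefixed provenance header line."""
    with open(path, "w") as fh:
        if comment:
            fh.write("# " + comment.replace("\n", " ") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_genotypes_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Genotype table: rows = lines, columns = SNP ids, values = dosage 0/1/2."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    _check_dosages(df)
    return df


def read_genotypes_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a minimal uncompressed VCF into a lines x SNPs dosage table.

    Dosage counts ALT alleles in the GT field (0/0 -> 0, 0/1 -> 1, 1/1 -> 2).
    """
    rows: list[tuple[str, list[int]]] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"VCF record with <10 fields: {line!r}")
            snp_id = fields[2]
            dosages = []
            for gt_field in fields[9:]:
                gt = gt_field.split(":")[0]
                alleles = gt.replace("|", "/").split("/")
                dosages.append(sum(a not in ("0", ".") for a in alleles))
            rows.append((snp_id, dosages))
    if not samples:
        raise ValueError(f"no #CHROM header line in {path}")
    df = pd.DataFrame(
        {snp: dict(zip(samples, dos)) for snp, dos in rows}
    ).loc[samples]
    _check_dosages(df)
    return df


def write_genotypes_tsv(genotypes: pd.DataFrame, path: str | os.PathLike) -> None:
    genotypes.to_csv(path, sep="\t", index_label="line")


def _check_dosages(df: pd.DataFrame) -> None:
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1, 2]).all():
        raise ValueError("genotype dosages must be integers in {0, 1, 2}")
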