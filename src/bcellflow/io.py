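"""Readers and writers for the plain-text formats the pipeline exchanges.

10x-style triplets (matrix.mtx + features.tsv + barcodes.tsv, optionally
gzipped) hold the count matrices; GMT files hold gene sets; two-column TSVs
hold homolog maps and sample→subtype maps.
"""
from __future__ import annotations

import gzip
import os
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_10x(
    outdir: str,
    matrix: sp.spmatrix,
    feature_names: Sequence[str],
    barcodes: Sequence[str],
    feature_types: Sequence[str] | None = None,
    gzipped: bool = False,
) -> None:
    """Write a features×cells matrix as a 10x-style MTX triplet.

    The features file carries three columns (id, name, type); the type column
    distinguishes "Gene Expression" from "Antibody Capture" rows.
    """
    if matrix.shape != (len(feature_names), len(barcodes)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(feature_names)} features x {len(barcodes)} barcodes"
        )
    if feature_types is None:
        feature_types = [GENE_EXPRESSION] * len(feature_names)
    os.makedirs(outdir, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    mtx_path = os.path.join(outdir, "matrix.mtx")
    scipy.io.mmwrite(mtx_path, sp.coo_matrix(matrix))
    if gzipped:
        with open(mtx_path, "rb") as fin, gzip.open(mtx_path + ".gz", "wb") as fout:
            fout.write(fin.read())
        os.remove(mtx_path)
    with _open_text(os.path.join(outdir, "features.tsv" + suffix), "wt") as fh:
        for name, ftype in zip(feature_names, feature_types):
            fh.write(f"{name}\t{name}\t{ftype}\n")
    with _open_text(os.path.join(outdir, "barcodes.tsv" + suffix), "wt") as fh:
        for bc in barcodes:
            fh.write(f"{bc}\n")


def read_10x(indir: str) -> Tuple[sp.csr_matrix, pd.DataFrame, List[str]]:
    """Read a 10x-style triplet; returns (matrix, features frame, barcodes).

    The features frame has columns id, name, type.
    """

    def _find(base: str) -> str:
        for cand in (base, base + ".gz"):
            p = os.path.join(indir, cand)
            if os.path.exists(p):
                return p
        raise FileNotFoundError(f"{base}[.gz] not found in {indir}")

    mtx_path = _find("matrix.mtx")
    if mtx_path.endswith(".gz"):
        with gzip.open(mtx_path, "rb") as fh:
            matrix = scipy.io.mmread(fh)
    else:
        matrix = scipy.io.mmread(mtx_path)
    features = pd.read_csv(
        _find("features.tsv"), sep="\t", header=None, names=["id", "name", "type"]
    )
    barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)[0].tolist()
    return sp.csr_matrix(matrix), features, barcodes


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT file into an ordered name → gene-list mapping."""
    sets: Dict[str, List[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line[:80]}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"empty GMT file: {path}")
    return sets


def write_gmt(path: str, sets: Mapping[str, Sequence[str]], descriptions: Mapping[str, str] | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, name)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_two_column_tsv(path: str) -> List[Tuple[str, str]]:
    """Read a headered two-column TSV (e.g. a homolog map) into pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, found {df.shape[1]}")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))
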