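"""Readers and writers for every on-disk artifact the pipeline touches.

Formats
-------
counts        MatrixMarket coordinate integer (``x.mtx`` with sidecar
              ``x.genes.txt`` / ``x.cells.txt``, one id per line, file
              order preserved) or dense TSV (gene rows, cell columns).
metadata      TSV with the CellMetadata columns.
gene sets     GMT: ``set_id<TAB>description<TAB>gene...``.
gene lists    one gene per line; the housekeeping list is ``gene<TAB>category``.
interactions  TSV with columns ``protein_a``, ``protein_b``, ``experimental``.
results       TSV tables and JSON reports (written by the CLI layer).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from nichescore.containers import (
    AnnotationLists,
    CountMatrix,
    GeneSetCollection,
    InteractionLibrary,
    ValidationError,
    validate_metadata,
)

log = logging.getLogger(__name__)


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def _read_id_file(path: Path, kind: str) -> np.ndarray:
    if not path.exists():
        raise ValidationError(f"missing {kind} id sidecar file: {path}")
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise ValidationError(f"no records in {kind} id file {path}")
    return np.asarray(ids, dtype=object)


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a UMI count matrix from MTX (+ id sidecars) or dense TSV.

    ``format`` is ``"mtx"`` or ``"tsv"``; inferred from the extension when
    omitted. Gene and cell order follow the files.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "tsv"
    if format not in ("mtx", "tsv"):
        raise ValueError(f"unknown counts format: {format}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"no records in counts file {path}")

    if format == "mtx":
        genes_path, cells_path = _sidecar_paths(path)
        gene_ids = _read_id_file(genes_path, "gene")
        cell_ids = _read_id_file(cells_path, "cell")
        mat = scipy.io.mmread(path)
        coo = sp.coo_matrix(mat)
        bad = np.flatnonzero((coo.data < 0) | (coo.data != np.floor(coo.data)))
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"negative or non-integer entry {coo.data[i]} at "
                f"(row {coo.row[i] + 1}, col {coo.col[i] + 1}) in {path}"
            )
        counts = sp.csr_matrix(coo, dtype=np.int64)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise ValidationError(
                f"matrix shape {counts.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)")
        return CountMatrix(gene_ids, cell_ids, counts)

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValidationError(f"no records in counts file {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in counts file {path}")
    neg = np.argwhere((values < 0) | (values != np.floor(values)))
    if len(neg):
        r, c = neg[0]
        raise ValidationError(
            f"negative or non-integer entry {values[r, c]} at "
            f"(row {r + 1}, col {c + 1}) [gene {df.index[r]}, cell {df.columns[c]}]")
    return CountMatrix(df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object),
                       sp.csr_matrix(values.astype(np.int64)))


def write_counts(cm: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix.lower() == ".mtx" else "tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(str(path), cm.counts.tocoo(), field="integer")
        genes_path, cells_path = _sidecar_paths(path)
        genes_path.write_text("\n".join(map(str, cm.gene_ids)) + "\n")
        cells_path.write_text("\n".join(map(str, cm.cell_ids)) + "\n")
    elif format == "tsv":
        cm.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown counts format: {format}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file. Duplicate members within one line are dropped with
    a logged warning; a repeated set id or a line with fewer than three
    fields is an error."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected set_id, description and at least one gene")
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                log.warning("%s:%d: duplicate members in set %s deduplicated",
                            path, lineno, set_id)
            collection.add(set_id, desc, genes)
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sid in collection.set_ids:
            fh.write("\t".join([sid, collection.description(sid),
                                *collection.members(sid)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    genes = {line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()}
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(sorted(map(str, genes))) + "\n")


def read_housekeeping(path: str | Path) -> dict[str, str]:
    """Housekeeping list: ``gene<TAB>category`` per line."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 'gene<TAB>category', got {raw!r}")
        gene, category = fields[0].strip(), fields[1].strip()
        if gene in out:
            raise ValidationError(f"{path}:{lineno}: duplicate housekeeping gene {gene}")
        out[gene] = category
    return out


def write_housekeeping(housekeeping: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gene in sorted(housekeeping):
            fh.write(f"{gene}\t{housekeeping[gene]}\n")


def read_annotations(secreted: str | Path, membrane: str | Path,
                     mitochondrial: str | Path,
                     housekeeping: str | Path | None = None) -> AnnotationLists:
    return AnnotationLists(
        secreted=read_gene_list(secreted),
        membrane=read_gene_list(membrane),
        mitochondrial=read_gene_list(mitochondrial),
        housekeeping=read_housekeeping(housekeeping) if housekeeping else {},
    )


INTERACTION_COLUMNS = ("protein_a", "protein_b", "experimental")


def read_interactions(path: str | Path, min_evidence: float = 0.0) -> InteractionLibrary:
    """Read a STRING-like interaction table, keeping pairs whose
    experimental evidence score is strictly greater than ``min_evidence``
    (default 0: any experimental evidence at all)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"interaction table {path} missing column(s): {', '.join(missing)}")
    kept = df[df["experimental"].astype(float) > min_evidence]
    lib = InteractionLibrary()
    for a, b, score in kept[list(INTERACTION_COLUMNS)].itertuples(index=False):
        lib.add(str(a), str(b), float(score))
    if len(lib) == 0:
        log.warning("interaction table %s yielded no pairs above evidence %s",
                    path, min_evidence)
    return lib


def write_interactions(lib: InteractionLibrary, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [(a, b, lib.score(a, b)) for a, b in lib.pairs()]
    pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def write_normalized(norm, path: str | Path) -> None:
    """Normalized matrix as MatrixMarket real with the same id sidecars as
    counts."""
    from nichescore.containers import NormalizedMatrix  # local to avoid cycle

    assert isinstance(norm, NormalizedMatrix)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path), norm.values.tocoo(), field="real", precision=12)
    genes_path, cells_path = _sidecar_paths(path)
    genes_path.write_text("\n".join(map(str, norm.gene_ids)) + "\n")
    cells_path.write_text("\n".join(map(str, norm.cell_ids)) + "\n")


def read_normalized(path: str | Path, size_factor: float = 10_000.0):
    from nichescore.containers import NormalizedMatrix

    path = Path(path)
    genes_path, cells_path = _sidecar_paths(path)
    gene_ids = _read_id_file(genes_path, "gene")
    cell_ids = _read_id_file(cells_path, "cell")
    mat = sp.csr_matrix(scipy.io.mmread(path))
    return NormalizedMatrix(gene_ids, cell_ids, mat, size_factor=size_factor)


def write_table(df: pd.DataFrame, path: str | Path, header_lines=()) -> None:
    """Write a result table as TSV with optional '#'-prefixed header lines
    (parameter echo)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
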