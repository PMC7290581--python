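"""Plain-text I/O for the pipeline's tabular formats.

Wide Ct tables are TSV with samples as rows, miRNAs as columns and empty
cells for non-detects; metadata, survival, ΔCt, expression and score tables
are ordinary TSV; gene sets use the GMT format (name, description, genes,
tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ct import CtMatrix, DeltaCtMatrix

__all__ = [
    "write_ct", "read_ct", "write_table", "read_table",
    "write_delta", "read_delta", "write_gmt", "read_gmt",
    "read_gene_list", "write_gene_list",
]


def write_ct(ct: CtMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    ct.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")
    if meta_path is not None:
        ct.plate.rename("plate").to_frame().to_csv(
            meta_path, sep="\t", index_label="sample_id"
        )


def read_ct(path: str | Path, meta: pd.DataFrame | str | Path) -> CtMatrix:
    """Read a wide Ct TSV plus metadata carrying the plate column."""
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    if not isinstance(meta, pd.DataFrame):
        meta = read_table(meta)
    plate = meta.loc[values.index, "plate"].astype(str)
    return CtMatrix(values=values, plate=plate)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: str | int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_delta(delta: DeltaCtMatrix, path: str | Path) -> None:
    out = delta.values.copy()
    out.insert(0, "_reference", delta.per_sample_reference)
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_delta(path: str | Path) -> DeltaCtMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    ref = df.pop("_reference")
    return DeltaCtMatrix(values=df, per_sample_reference=ref)


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
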