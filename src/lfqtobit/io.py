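"""Tab-separated readers and writers for every pipeline table.

All tables are plain TSV with a header row.  Matrices are written with
proteins as rows (first column ``protein_id``) and samples as columns;
the detect mask of a normalized matrix travels as a parallel table with
the suffix ``.mask.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import AbundanceMatrix, NormalizedMatrix


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    write_table(design, path)


def read_design(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t")


def read_abundance(path: str | Path, design: pd.DataFrame) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    return AbundanceMatrix(
        values=df,
        sample_fractions=pd.Series(
            design["fraction"].to_numpy(), index=design["sample_id"].to_numpy()
        ),
    )


def _mask_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".mask.tsv")


def write_normalized(matrix: NormalizedMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t")
    mask = matrix.detected.astype(int).copy()
    mask.index.name = "protein_id"
    mask.to_csv(_mask_path(path), sep="\t")


def read_normalized(path: str | Path, design: pd.DataFrame) -> NormalizedMatrix:
    values = pd.read_csv(path, sep="\t", index_col="protein_id")
    mask = pd.read_csv(_mask_path(path), sep="\t", index_col="protein_id").astype(bool)
    return NormalizedMatrix(
        values=values,
        detected=mask,
        sample_fractions=pd.Series(
            design["fraction"].to_numpy(), index=design["sample_id"].to_numpy()
        ),
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation table: protein_id, localization, cazyme, cellulosomal, go_terms."""
    df = read_table(path)
    for flag in ("cazyme", "cellulosomal"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


def read_diffractogram(path: str | Path) -> pd.DataFrame:
    """Two-column (2-theta, intensity) text file."""
    return pd.read_csv(
        path, sep=r"\s+", comment="#", names=["two_theta", "intensity"], header=None
    )
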