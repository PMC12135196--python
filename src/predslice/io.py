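"""Reading and writing the package's tabular formats.

Genotypes travel as TSV (first column = individual id, remaining columns =
marker dosages 0/1/2, header row = marker ids) or in PLINK ``.raw`` column
layout (FID IID PAT MAT SEX PHENOTYPE then one column per marker).  Phenotypes
are TSV with columns id, generation, sex, then one column per trait.  A GRM can
be persisted as a raw float64 square matrix with a plain-text id sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gblup import GRM, GenotypeMatrix

__all__ = ["read_genotypes_tsv", "write_genotypes_tsv", "read_plink_raw",
           "read_phenotypes_tsv", "write_phenotypes_tsv", "read_grm", "write_grm",
           "write_provenance"]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(df.to_numpy(dtype=np.int8),
                          [str(i) for i in df.index], [str(c) for c in df.columns])


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.individual_ids,
                      columns=genotypes.marker_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_plink_raw(path) -> GenotypeMatrix:
    """PLINK --recode A output: whitespace-separated, IID used as individual id."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _PLINK_META if c not in df.columns]
    if missing:
        raise InvalidInputError(f".raw file lacks column(s) {missing!r}")
    markers = [c for c in df.columns if c not in _PLINK_META]
    dosages = df[markers].to_numpy()
    if np.isnan(dosages).any():
        raise InvalidInputError("missing genotypes are not supported; impute first")
    return GenotypeMatrix(dosages.astype(np.int8),
                          [str(i) for i in df["IID"]], markers)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "generation"):
        if col not in df.columns:
            raise InvalidInputError(f"phenotype table lacks required column {col!r}")
    df["id"] = df["id"].astype(str)
    return df


def write_phenotypes_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_grm(grm: GRM, path) -> None:
    """Raw float64 square matrix at ``path`` plus ids at ``path + '.ids'``."""
    path = Path(path)
    np.asarray(grm.values, dtype=np.float64).tofile(path)
    sidecar = path.with_suffix(path.suffix + ".ids")
    sidecar.write_text("\n".join(map(str, grm.individual_ids)) + "\n")


def read_grm(path, blend_alpha: float = 0.0) -> GRM:
    path = Path(path)
    ids = path.with_suffix(path.suffix + ".ids").read_text().split()
    values = np.fromfile(path, dtype=np.float64)
    n = len(ids)
    if values.size != n * n:
        raise InvalidInputError(f"GRM file holds {values.size} values, expected {n}x{n}")
    return GRM(values=values.reshape(n, n), individual_ids=ids,
               blend_alpha=blend_alpha)


def write_provenance(path, config: dict, seed) -> None:
    """Machine-readable record of what produced a result directory."""
    from . import __version__
    rec = {"package": "predslice", "version": __version__, "seed": seed,
           "numpy": np.__version__, "config": config}
    Path(path).write_text(json.dumps(rec, indent=2, default=str) + "\n")
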