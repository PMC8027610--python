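"""Readers and writers for the package's plain-text interchange formats.

Genotypes travel as PLINK ``.raw``-dialect TSV (header ``FID IID PAT MAT SEX
PHENOTYPE`` followed by ``variantid_effectallele`` dosage columns); panels as
long-format TSV; weight tables as ``ID A1 A2 BETA P CHR BP`` TSV (optional
columns may be absent, extra columns are ignored); truth records as JSON.
Readers validate strictly and report the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InputValidationError
from .scores import WeightTable
from .simulate import GenotypeMatrix, TruthRecord

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_panel",
    "read_panel",
    "write_weights",
    "read_weights",
    "write_truth",
    "read_truth",
]

PANEL_REQUIRED = ("person_id", "wave", "bmi", "age", "sex", "treated")


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as a PLINK ``.raw``-dialect TSV (effect-allele counts)."""
    cols = [f"{v}_{a}" for v, a in zip(genotypes.variant_ids, genotypes.effect_allele)]
    df = pd.DataFrame(genotypes.dosages, columns=cols)
    meta = pd.DataFrame(
        {
            "FID": genotypes.person_id,
            "IID": genotypes.person_id,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Read a ``.raw``-dialect TSV, validating dosages lie in [0, 2].

    The ``.raw`` format does not carry the non-counted allele, so
    ``other_allele`` is set to ``"0"`` (unknown); allele flipping during
    scoring then only happens when a weight table names the counted allele's
    complement explicitly.
    """
    df = pd.read_csv(path, sep="\t")
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing .raw header columns {missing}")
    variant_cols = [c for c in df.columns if c not in fixed]
    if not variant_cols:
        raise InputValidationError(f"{path}: no variant columns found")
    ids, alleles = [], []
    for c in variant_cols:
        if "_" not in c:
            raise InputValidationError(f"{path}: variant column {c!r} lacks the _allele suffix")
        vid, allele = c.rsplit("_", 1)
        ids.append(vid)
        alleles.append(allele)
    dos = df[variant_cols].to_numpy()
    try:
        dos = dos.astype(float)
    except ValueError as err:
        raise InputValidationError(f"{path}: non-numeric dosage: {err}") from err
    bad = np.argwhere(~((dos >= 0) & (dos <= 2)))
    if bad.size:
        r, c = bad[0]
        raise InputValidationError(
            f"{path}: dosage {dos[r, c]} out of [0,2] at data row {r + 1}, column {variant_cols[c]!r}"
        )
    freq = dos.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dos,
        variant_ids=np.array(ids),
        effect_allele=np.array(alleles),
        other_allele=np.array(["0"] * len(ids)),
        maf=np.minimum(freq, 1 - freq),
        person_id=df["IID"].to_numpy(),
    )


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a long-format panel TSV with schema validation."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: panel missing required columns {missing}")
    dup = df.duplicated(subset=["person_id", "wave"])
    if dup.any():
        first = df.loc[dup, ["person_id", "wave"]].iloc[0]
        raise InputValidationError(
            f"{path}: duplicate (person_id, wave) record: ({first['person_id']}, {first['wave']})"
        )
    if (df["bmi"] <= 0).any():
        row = int(np.flatnonzero(df["bmi"].to_numpy() <= 0)[0])
        raise InputValidationError(f"{path}: non-positive BMI at data row {row + 1}")
    return df


_WEIGHT_COLMAP = {
    "ID": "variant_id",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "weight",
    "P": "p_value",
    "CHR": "chrom",
    "BP": "pos",
}


def write_weights(weights: WeightTable, path) -> None:
    inv = {v: k for k, v in _WEIGHT_COLMAP.items()}
    out = weights.table.rename(columns=inv)
    cols = [c for c in ("ID", "A1", "A2", "BETA", "P", "CHR", "BP") if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_weights(path) -> WeightTable:
    """Read an ``ID A1 A2 BETA P CHR BP`` weight TSV (extra columns tolerated)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("ID", "A1", "BETA") if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: weight table missing columns {missing}")
    if df["ID"].duplicated().any():
        dups = df.loc[df["ID"].duplicated(), "ID"].tolist()
        raise InputValidationError(f"{path}: duplicate variant ids: {dups}")
    keep = {k: v for k, v in _WEIGHT_COLMAP.items() if k in df.columns}
    return WeightTable(df[list(keep)].rename(columns=keep))


def write_truth(truth: TruthRecord, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))
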