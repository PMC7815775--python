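"""Readers and writers for the plain-text interchange formats used by the
pipeline: TSV tables (quant, Ct, dosimetry, edges) and GMT term sets.

All files are UTF-8, tab-separated with headers (except GMT, which follows
the standard term/description/members layout), '.' decimal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .enrichment import AnnotationTerm


def write_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_quant(path: str | Path) -> pd.DataFrame:
    quant = read_tsv(path)
    required = {"protein_id", "group", "replicate", "ratio"}
    if not required <= set(quant.columns):
        raise ValueError(f"quant table must have columns {sorted(required)}")
    return quant


def read_ct(path: str | Path) -> pd.DataFrame:
    ct = read_tsv(path)
    required = {"sample", "group", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return ct


def read_dose(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


def write_gmt(
    terms: Iterable[tuple[str, str, Sequence[str]]], path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, description, members in terms:
            fh.write("\t".join([term_id, description, *members]) + "\n")
    return path


def read_gmt(path: str | Path) -> list[AnnotationTerm]:
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms.append(
                AnnotationTerm(
                    term_id=fields[0], name=fields[1], members=frozenset(fields[2:])
                )
            )
    if not terms:
        raise ValueError(f"no terms parsed from {path}")
    return terms
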