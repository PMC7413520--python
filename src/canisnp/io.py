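"""Reading, writing and numeric encoding of genotype tables.

Two plain-text formats are supported:

* **CSV** — one row per individual: ``individual_id, population`` followed by
  one two-character genotype string per locus (``GG``, ``GT``, ``--`` for
  missing).  Heterozygotes are unordered: ``GT`` and ``TG`` parse identically.
* **Genepop** — title line, one locus id per line, then one ``POP`` block per
  population.  Allele codes are two digits: ``01`` = allele_a, ``02`` =
  allele_b, ``00`` = missing, so a call is a four-digit string (``0101``,
  ``0102``, ``0000``).  The free-text name field before the comma is written
  as ``<population> <individual_id>`` so population labels survive a
  round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import Genotype, GenotypeMatrix, PanelDefinition

__all__ = ["read_genotype_table", "write_genotype_table", "encode_matrix", "GenotypeParseError"]

FORMATS = ("csv", "genepop")
ENCODINGS = ("dosage", "genotype_onehot", "allele_fraction")


class GenotypeParseError(ValueError):
    """A genotype file violates the panel's declared alleles or schema."""


def read_genotype_table(path, panel: PanelDefinition, format: str = "csv") -> GenotypeMatrix:
    """Parse a genotype table into a :class:`GenotypeMatrix`.

    The file must declare exactly the panel's loci (CSV header row or the
    Genepop locus list); alleles are interpreted relative to ``panel``.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "csv":
        return _read_csv(path, panel)
    return _read_genepop(path, panel)


def write_genotype_table(
    matrix: GenotypeMatrix, path, format: str = "csv"
) -> Path:
    """Write ``matrix`` to ``path``; inverse of :func:`read_genotype_table`."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "csv":
        _write_csv(matrix, path)
    else:
        _write_genepop(matrix, path)
    return path


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv(path: Path, panel: PanelDefinition) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["individual_id", "population"] + panel.locus_ids
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        raise GenotypeParseError(
            f"{path}: CSV schema mismatch; missing columns {missing}"
            if missing
            else f"{path}: CSV columns must be exactly {expected}"
        )
    dosages = np.full((len(df), len(panel)), -1, dtype=np.int8)
    for j, locus in enumerate(panel):
        for i, cell in enumerate(df[locus.locus_id]):
            try:
                dosages[i, j] = locus.parse_genotype(cell)
            except ValueError as exc:
                raise GenotypeParseError(f"{path}: row {i + 1}: {exc}") from exc
    dosage = pd.DataFrame(dosages, index=df["individual_id"].tolist(), columns=panel.locus_ids)
    pops = pd.Series(df["population"].tolist(), index=dosage.index)
    return GenotypeMatrix(panel=panel, dosage=dosage, populations=pops)


def _write_csv(matrix: GenotypeMatrix, path: Path) -> None:
    rows = []
    for ind in matrix.individual_ids:
        row = {"individual_id": ind, "population": matrix.populations.loc[ind]}
        for locus in matrix.panel:
            row[locus.locus_id] = locus.genotype_string(
                int(matrix.dosage.loc[ind, locus.locus_id])
            )
        rows.append(row)
    cols = ["individual_id", "population"] + matrix.panel.locus_ids
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genepop dialect
# ---------------------------------------------------------------------------

_CODE_FROM_DOSAGE = {2: "0101", 1: "0102", 0: "0202", -1: "0000"}


def _dosage_from_code(code: str, locus_id: str, line_no: int) -> int:
    if len(code) != 4 or not code.isdigit():
        raise GenotypeParseError(f"line {line_no}: malformed Genepop call {code!r}")
    a1, a2 = code[:2], code[2:]
    if "00" in (a1, a2):
        if a1 != a2:
            raise GenotypeParseError(f"line {line_no}: half-missing call {code!r}")
        return int(Genotype.MISSING)
    dosage = 0
    for a in (a1, a2):
        if a == "01":
            dosage += 1
        elif a != "02":
            raise GenotypeParseError(
                f"line {line_no}: allele code {a!r} at {locus_id} not in {{01, 02}}"
            )
    return dosage


def _read_genepop(path: Path, panel: PanelDefinition) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty Genepop file")
    locus_ids: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # locus names may be one per line or comma-separated
        locus_ids.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    if locus_ids != panel.locus_ids:
        raise GenotypeParseError(
            f"{path}: Genepop locus list {locus_ids} does not match panel {panel.locus_ids}"
        )
    ids: list[str] = []
    pops: list[str] = []
    calls: list[list[int]] = []
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}: line {i + 1}: missing comma separator")
        name, geno = line.split(",", 1)
        tokens = name.split()
        if len(tokens) < 2:
            raise GenotypeParseError(
                f"{path}: line {i + 1}: name field must be '<population> <individual_id>'"
            )
        pops.append(tokens[0])
        ids.append(" ".join(tokens[1:]))
        codes = geno.split()
        if len(codes) != len(panel):
            raise GenotypeParseError(
                f"{path}: line {i + 1}: expected {len(panel)} calls, found {len(codes)}"
            )
        calls.append(
            [_dosage_from_code(c, l, i + 1) for c, l in zip(codes, panel.locus_ids)]
        )
        i += 1
    dosage = pd.DataFrame(
        np.array(calls, dtype=np.int8).reshape(len(ids), len(panel)),
        index=ids,
        columns=panel.locus_ids,
    )
    return GenotypeMatrix(panel=panel, dosage=dosage, populations=pd.Series(pops, index=ids))


def _write_genepop(matrix: GenotypeMatrix, path: Path) -> None:
    pops_in_order: list[str] = []
    for p in matrix.populations:
        if p not in pops_in_order:
            pops_in_order.append(p)
    out = ["canisnp genotype export"]
    out.extend(matrix.panel.locus_ids)
    for pop in pops_in_order:
        out.append("POP")
        for ind in matrix.individual_ids:
            if matrix.populations.loc[ind] != pop:
                continue
            codes = " ".join(
                _CODE_FROM_DOSAGE[int(matrix.dosage.loc[ind, l])]
                for l in matrix.panel.locus_ids
            )
            out.append(f"{pop} {ind} ,  {codes}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# numeric encodings
# ---------------------------------------------------------------------------

def encode_matrix(
    matrix: GenotypeMatrix, scheme: str = "genotype_onehot", allow_missing: bool = False
) -> pd.DataFrame:
    """Encode genotype calls as a numeric feature grid.

    * ``dosage`` — one column per locus, count of allele_a in {0, 1, 2};
    * ``genotype_onehot`` — three 0/1 columns per locus in (HOM_A, HET,
      HOM_B) order, exactly one set per locus;
    * ``allele_fraction`` — dosage / 2, in {0, 0.5, 1}.

    Missing calls raise unless ``allow_missing``, in which case they become
    NaN (a whole NaN triple under one-hot).
    """
    if scheme not in ENCODINGS:
        raise ValueError(f"unknown encoding scheme {scheme!r}; expected one of {ENCODINGS}")
    d = matrix.dosage.to_numpy(np.int8)
    miss = d < 0
    if miss.any() and not allow_missing:
        raise ValueError("matrix contains MISSING calls; pass allow_missing=True to mask")
    if scheme == "dosage":
        out = d.astype(float)
        out[miss] = np.nan
        return pd.DataFrame(out, index=matrix.individual_ids, columns=matrix.locus_ids)
    if scheme == "allele_fraction":
        out = d.astype(float) / 2.0
        out[miss] = np.nan
        return pd.DataFrame(out, index=matrix.individual_ids, columns=matrix.locus_ids)
    # genotype one-hot
    cols = []
    blocks = []
    for j, locus in enumerate(matrix.locus_ids):
        block = np.zeros((len(d), 3))
        block[:, 0] = d[:, j] == 2
        block[:, 1] = d[:, j] == 1
        block[:, 2] = d[:, j] == 0
        block[miss[:, j], :] = np.nan
        blocks.append(block)
        cols.extend([f"{locus}:hom_a", f"{locus}:het", f"{locus}:hom_b"])
    return pd.DataFrame(np.hstack(blocks), index=matrix.individual_ids, columns=cols)
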