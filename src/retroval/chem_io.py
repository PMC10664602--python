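"""Reading, writing and standardization of compound tables and SMILES sets.

All downstream identity comparisons (uniqueness, novelty, rediscovery) are
made on canonical *non-isomeric* SMILES of the largest fragment, so this
module is the single place where SMILES normalization happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

# RDKit is chatty about every unparseable SMILES; failures are reported
# through LoadReport instead.
RDLogger.DisableLog("rdApp.*")

DEFAULT_COLUMN_MAP = {"smiles": "SMILES", "pxc50": "pXC50", "date": "date"}

#: fixed column order of the normalized project table
TABLE_COLUMNS = ("id", "smiles_canonical", "pxc50", "date", "source_row")


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound of a project dataset."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    pxc50: float
    date: object = None  # pandas Timestamp / date / int day offset
    source_row: int = 0


@dataclass
class LoadReport:
    """Accounting of a project-table load."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_smiles: int = 0
    n_dropped_pxc50: int = 0
    dropped_rows: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_smiles + self.n_dropped_pxc50


def standardize(smiles_raw: str) -> str:
    """Return canonical, non-isomeric SMILES of the largest fragment.

    De-salting keeps the fragment with the most heavy atoms; ties are broken
    by the lexicographically smallest canonical SMILES. Stereochemistry is
    stripped before canonicalization.

    Raises
    ------
    InvalidMoleculeError
        If the input does not parse/sanitize.
    """
    if not smiles_raw or not isinstance(smiles_raw, str):
        raise InvalidMoleculeError(f"not a SMILES string: {smiles_raw!r}")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles_raw!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        keyed = []
        for frag in frags:
            can = Chem.MolToSmiles(frag, isomericSmiles=False)
            keyed.append((-frag.GetNumHeavyAtoms(), can, frag))
        keyed.sort(key=lambda t: (t[0], t[1]))
        mol = keyed[0][2]
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def is_valid_smiles(smiles: str) -> bool:
    """True iff the string parses and sanitizes in RDKit."""
    if not smiles or not isinstance(smiles, str):
        return False
    return Chem.MolFromSmiles(smiles) is not None


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def load_project_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    id_prefix: str = "cpd",
    aggregate_duplicates: bool = False,
) -> tuple[list[MoleculeRecord], LoadReport]:
    """Load a CSV/XLSX compound table into :class:`MoleculeRecord` rows.

    Parameters
    ----------
    path:
        CSV or XLSX file with at least a SMILES and a pXC50 column.
    column_map:
        Maps the logical names ``smiles``, ``pxc50`` and (optionally)
        ``date`` to the file's column headers. Defaults to
        ``{"smiles": "SMILES", "pxc50": "pXC50", "date": "date"}``; the date
        column is used only when present in the file.
    aggregate_duplicates:
        If True, rows sharing a canonical structure are collapsed to a
        single record carrying the maximum pXC50 (earliest source_row/date
        kept). Off by default: a project table legitimately re-measures
        compounds.

    Returns
    -------
    (records, report)
        Records preserve input order via ``source_row``; rows with
        unparseable SMILES or non-finite pXC50 are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    for key in ("smiles", "pxc50"):
        if cmap[key] not in df.columns:
            raise KeyError(
                f"column {cmap[key]!r} (mapped from {key!r}) not in {path}: "
                f"available {list(df.columns)}"
            )
    has_date = cmap.get("date") in df.columns
    id_col = cmap.get("id")
    has_id = id_col is not None and id_col in df.columns

    report = LoadReport(n_rows=len(df))
    records: list[MoleculeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "_asdict", None)
        rowd = row._asdict() if raw else dict(zip(df.columns, row))
        smi = rowd[cmap["smiles"]]
        pxc = pd.to_numeric(rowd[cmap["pxc50"]], errors="coerce")
        if pd.isna(pxc):
            report.n_dropped_pxc50 += 1
            report.dropped_rows.append(i)
            continue
        try:
            canonical = standardize(str(smi))
        except InvalidMoleculeError:
            report.n_dropped_smiles += 1
            report.dropped_rows.append(i)
            continue
        records.append(
            MoleculeRecord(
                id=str(rowd[id_col]) if has_id else f"{id_prefix}{i}",
                smiles_raw=str(smi),
                smiles_canonical=canonical,
                pxc50=float(pxc),
                date=rowd[cmap["date"]] if has_date else None,
                source_row=i,
            )
        )
    if not records:
        raise ValueError(f"zero parseable rows in {path}")
    if report.n_dropped:
        warnings.warn(
            f"{path.name}: dropped {report.n_dropped} of {report.n_rows} rows "
            f"({report.n_dropped_smiles} bad SMILES, "
            f"{report.n_dropped_pxc50} missing pXC50)",
            stacklevel=2,
        )
    if aggregate_duplicates:
        best: dict[str, MoleculeRecord] = {}
        for rec in records:
            cur = best.get(rec.smiles_canonical)
            if cur is None or rec.pxc50 > cur.pxc50:
                keep_date = cur.date if cur is not None else rec.date
                keep_row = cur.source_row if cur is not None else rec.source_row
                keep_id = cur.id if cur is not None else rec.id
                best[rec.smiles_canonical] = MoleculeRecord(
                    id=keep_id,
                    smiles_raw=rec.smiles_raw,
                    smiles_canonical=rec.smiles_canonical,
                    pxc50=rec.pxc50,
                    date=keep_date,
                    source_row=keep_row,
                )
        records = sorted(best.values(), key=lambda r: r.source_row)
    report.n_loaded = len(records)
    return records, report


def write_records(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as the normalized project CSV (fixed column order)."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles_canonical": [r.smiles_canonical for r in records],
            "pxc50": [r.pxc50 for r in records],
            "date": [r.date for r in records],
            "source_row": [r.source_row for r in records],
        },
        columns=list(TABLE_COLUMNS),
    )
    df.to_csv(path, index=False)


def load_records(path: str | Path) -> list[MoleculeRecord]:
    """Reload a normalized project CSV written by :func:`write_records`."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        date = row["date"]
        if pd.isna(date):
            date = None
        records.append(
            MoleculeRecord(
                id=str(row["id"]),
                smiles_raw=row["smiles_canonical"],
                smiles_canonical=row["smiles_canonical"],
                pxc50=float(row["pxc50"]),
                date=date,
                source_row=int(row["source_row"]),
            )
        )
    return records


def load_generated_set(
    path: str | Path,
) -> tuple[list[str], list[float] | None]:
    """Load a plain-text generated SMILES set.

    One SMILES per line, optionally followed by a whitespace-separated
    numeric score. Blank lines are skipped. Raw strings are preserved
    verbatim; validity is judged later by the metrics module.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    smiles: list[str] = []
    scores: list[float] = []
    any_score = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        smiles.append(parts[0])
        if len(parts) > 1:
            scores.append(float(parts[1]))
            any_score = True
        else:
            scores.append(float("nan"))
    if not any_score:
        return smiles, None
    return smiles, scores


def write_generated_set(
    smiles: Sequence[str],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write a SMILES list (optionally with scores) as plain text."""
    with open(path, "w") as fh:
        for i, smi in enumerate(smiles):
            if scores is not None:
                fh.write(f"{smi}\t{scores[i]}\n")
            else:
                fh.write(f"{smi}\n")
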