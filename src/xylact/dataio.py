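"""Reading and writing the study's data artifacts.

The packaged fixture is the screening table of the 41 Bacillus subtilis
strains: GenBank protein accession, strain code, halo-zone diameter on xylan
agar (mm), the printed L/M/H halo class, and — for the 28 assayed strains —
xylanase specific activities (IU ml^-1) in three pH/temperature conditions.

Formats: multi-record FASTA for sequences (via Biopython), a flat CSV/TSV
strain table, a feature-matrix CSV (``id,e1..e34``), and an importer for the
published supplementary feature spreadsheet layout.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, MissingReferenceDataError, SchemaError
from .pseaac import EnzymeSequence, feature_names

#: Canonical condition labels, in the fixture's column order.
CONDITIONS = ("pH4_T60", "pH4_T26", "pH6_T26")

#: Aliases: the assay protocol states pH 4.6 / 6.9 where the results table
#: prints pH 4 / 6; the canonical labels follow the table.
CONDITION_ALIASES = {"pH4.6_T60": "pH4_T60", "pH4.6_T26": "pH4_T26",
                     "pH6.9_T26": "pH6_T26"}

_ACTIVITY_COLUMNS = tuple(f"act_{c}" for c in CONDITIONS)
_REQUIRED_COLUMNS = ("accession", "strain", "halo_mm", "class") + _ACTIVITY_COLUMNS
_VALID_CLASSES = ("L", "M", "H")


@dataclass(frozen=True)
class ConditionLabel:
    """One assay condition: pH and temperature, with its canonical label."""

    ph: float
    temperature_c: float
    label: str


#: The three assay conditions of the study.
CONDITION_DETAILS = (
    ConditionLabel(4.0, 60.0, "pH4_T60"),
    ConditionLabel(4.0, 26.0, "pH4_T26"),
    ConditionLabel(6.0, 26.0, "pH6_T26"),
)


@dataclass(frozen=True)
class StrainRecord:
    """One screening-table row.

    ``activity`` maps condition label -> IU ml^-1 and is None for strains
    that were not assayed.
    """

    accession: str
    strain: str
    halo_mm: float
    real_class: str
    activity: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.halo_mm <= 0:
            raise SchemaError(
                f"{self.accession}: halo diameter must be > 0 mm, got {self.halo_mm}"
            )
        if self.real_class not in _VALID_CLASSES:
            raise SchemaError(
                f"{self.accession}: unknown halo class {self.real_class!r}"
            )
        if self.activity is not None:
            if set(self.activity) != set(CONDITIONS):
                raise SchemaError(
                    f"{self.accession}: activity must cover exactly {CONDITIONS}"
                )
            if any(v < 0 for v in self.activity.values()):
                raise SchemaError(f"{self.accession}: negative activity")

    @property
    def assayed(self) -> bool:
        return self.activity is not None


@dataclass
class StudyDataset:
    """The strain table plus (optionally) a feature matrix keyed by accession."""

    records: list[StrainRecord]
    features: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    @property
    def assayed(self) -> list[StrainRecord]:
        return [r for r in self.records if r.assayed]

    def classes(self) -> np.ndarray:
        """The printed halo classes, in record order."""
        return np.array([r.real_class for r in self.records])

    def halos(self) -> np.ndarray:
        return np.array([r.halo_mm for r in self.records])

    def activities(self, condition: str) -> pd.Series:
        """Activities of the assayed strains for one condition, by accession."""
        condition = CONDITION_ALIASES.get(condition, condition)
        if condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {condition!r}; expected {CONDITIONS}")
        return pd.Series(
            {r.accession: float(r.activity[condition]) for r in self.assayed},
            name=condition,
        )

    def aligned_features(self, subset: Iterable[StrainRecord] | None = None) -> pd.DataFrame:
        """Feature rows aligned to (a subset of) the records, in record order."""
        if self.features is None:
            raise AlignmentError("dataset carries no feature matrix")
        recs = list(subset) if subset is not None else self.records
        missing = [r.accession for r in recs if r.accession not in self.features.index]
        if missing:
            raise AlignmentError(f"no feature row for accession(s) {missing}")
        return self.features.loc[[r.accession for r in recs]]


def _parse_record(row: Mapping[str, str], lineno: int) -> StrainRecord:
    try:
        halo = float(row["halo_mm"])
    except ValueError as exc:
        raise SchemaError(f"row {lineno}: non-numeric halo_mm {row['halo_mm']!r}") from exc
    acts = {c: row.get(f"act_{c}", "") for c in CONDITIONS}
    blank = [v is None or str(v).strip() == "" for v in acts.values()]
    if all(blank):
        activity = None
    elif any(blank):
        raise SchemaError(f"row {lineno}: partial activity columns")
    else:
        try:
            activity = {c: float(v) for c, v in acts.items()}
        except ValueError as exc:
            raise SchemaError(f"row {lineno}: non-numeric activity") from exc
    try:
        return StrainRecord(
            accession=row["accession"].strip(),
            strain=row["strain"].strip(),
            halo_mm=halo,
            real_class=row["class"].strip(),
            activity=activity,
        )
    except SchemaError as exc:
        raise SchemaError(f"row {lineno}: {exc}") from exc


def read_strain_table(path, dialect: str = "excel") -> StudyDataset:
    """Parse a strain-table CSV/TSV into a :class:`StudyDataset`.

    ``dialect`` is a csv module dialect name; "excel" reads comma-separated,
    "excel-tab" tab-separated. Schema errors name the offending row/column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        cols = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        records = [_parse_record(row, i) for i, row in enumerate(reader, start=2)]
    if not records:
        warnings.warn(f"{path}: empty strain table", stacklevel=2)
    seen: set[str] = set()
    for r in records:
        if r.accession in seen:
            raise SchemaError(f"duplicate accession {r.accession}")
        seen.add(r.accession)
    return StudyDataset(records=records)


def write_strain_table(dataset: StudyDataset, path, dialect: str = "excel") -> None:
    """Write a dataset back to the strain-table CSV/TSV contract."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, dialect=dialect)
        writer.writerow(_REQUIRED_COLUMNS)
        for r in dataset.records:
            acts = (
                [_fmt_num(r.activity[c]) for c in CONDITIONS]
                if r.assayed else ["", "", ""]
            )
            writer.writerow([r.accession, r.strain, _fmt_num(r.halo_mm),
                             r.real_class, *acts])


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def load_fixture() -> StudyDataset:
    """The packaged screening table: 41 strains, 28 of them assayed."""
    ref = resources.files("xylact").joinpath("data/strain_table.csv")
    with resources.as_file(ref) as f:
        return read_strain_table(f)


def read_fasta(path, on_nonstandard: str = "error") -> list[EnzymeSequence]:
    """Read a multi-record FASTA into validated sequences.

    Ids are the first whitespace-delimited header token; residues are
    uppercased. Empty records and duplicate ids are format errors.
    """
    seqs: list[EnzymeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(EnzymeSequence(rec.id, str(rec.seq), on_nonstandard=on_nonstandard))
    return seqs


def write_fasta(sequences: Iterable[EnzymeSequence], path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def write_feature_csv(features: pd.DataFrame, path) -> None:
    """Write a feature matrix with header ``id,e1..eN``."""
    features.to_csv(path, index_label="id")


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="id")
    return df.astype(float)


def read_s1_features(path, lambda_: int = 7) -> pd.DataFrame:
    """Import a feature matrix in the published supplementary layout.

    Accepts ``.xlsx`` (first worksheet) or CSV. The first column must hold
    sequence identifiers; the remaining ``20 + 2*lambda`` columns the feature
    values, in element order. Returns a DataFrame indexed by id with columns
    renamed to the canonical ``e1..eN``.
    """
    path = Path(path)
    if not path.exists():
        raise MissingReferenceDataError(
            f"reference feature matrix not found at {path}; the published "
            "supplementary spreadsheet must be supplied by the user"
        )
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, engine="openpyxl")
    else:
        df = pd.read_csv(path)
    n = 20 + 2 * lambda_
    if df.shape[1] < n + 1:
        raise SchemaError(
            f"{path}: expected id column + {n} feature columns, got {df.shape[1]}"
        )
    out = df.iloc[:, 1:n + 1].astype(float)
    out.index = pd.Index(df.iloc[:, 0].astype(str), name="id")
    out.columns = feature_names(lambda_)
    return out
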