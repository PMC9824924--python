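"""Domain records, tabular readers/writers, subset queries and reporting.

The pipeline's unit of input is the :class:`Measurement` — one raw activity
observation tying a molecule to a protein target through an assay.  Raw
tables from different sources use different column names; a *dialect*
mapping translates them to the canonical schema at read time so that the
column-name mapping lives in per-source configuration, not in code.

Proteins are carried as :class:`ProteinRecord` with the tiered functional
classification (enzyme -> kinase -> ... ) used for subset extraction, read
from a FASTA file plus a TSV sidecar.  The organism of a record is always
taken from the protein record, never from the measurement row.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("bioforge")

__all__ = [
    "Measurement",
    "ProteinRecord",
    "OrganismReport",
    "Rejection",
    "TARGET_MAPPINGS",
    "CURATED_COLUMNS",
    "read_measurements",
    "read_proteins",
    "write_curated",
    "read_curated",
    "query_by_classification",
    "organism_report",
    "organism_report_from_counts",
]

#: Admissible values of the target-mapping annotation, from unambiguous
#: ("single": the assay target is one known protein) to ambiguous
#: ("multi_homolog": possibly several proteins, identified by homology).
TARGET_MAPPINGS = (
    "single",
    "single_homolog",
    "multi_homolog",
    "multi",
    "complex_subunit",
    "homolog_complex_subunit",
)

RELATIONS = ("=", "<", ">", "<=", ">=")


@dataclass(frozen=True)
class Measurement:
    """One raw activity observation from one source table.

    ``value``/``unit`` are present exactly when the record is not a binary
    activity class; exact values carry relation ``"="``, censored values a
    bound relation.  ``target_mapping`` captures how confidently the assay
    target maps to ``target_accession``.
    """

    source_id: str
    molecule_ref: str
    target_accession: str
    assay_id: str
    activity_type: str
    relation: str = "="
    value: float | None = None
    unit: str | None = None
    is_binary: bool = False
    active_label: bool | None = None
    year: int | None = None
    target_mapping: str = "single"

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.target_mapping not in TARGET_MAPPINGS:
            raise ValueError(f"unknown target mapping {self.target_mapping!r}")
        if self.is_binary:
            if self.value is not None or self.unit is not None:
                raise ValueError("binary record cannot carry a value/unit")
        else:
            if self.value is None:
                raise ValueError("non-binary record requires a value")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein target: accession, sequence, organism and its tiered
    functional classification (level 1 = broadest)."""

    accession: str
    sequence: str
    organism: str
    classification: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(not lvl for lvl in self.classification):
            raise ValueError(
                "classification levels must be prefix-consistent "
                "(no empty intermediate level)"
            )

    def classification_at(self, level: int) -> str | None:
        """1-based classification label, ``None`` beyond this protein's depth."""
        if 1 <= level <= len(self.classification):
            return self.classification[level - 1]
        return None


@dataclass(frozen=True)
class Rejection:
    """A row that could not be turned into a Measurement, with the reason."""

    row_number: int
    reason: str
    row: Mapping[str, str]


@dataclass(frozen=True)
class OrganismReport:
    organism: str
    n_high: int
    n_medium: int
    n_low: int
    n_total: int
    pct_of_total: float


# ---------------------------------------------------------------------------
# Reading raw measurement tables


#: canonical field -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "source_id": "source_id",
    "molecule_ref": "molecule_ref",
    "target_accession": "target_accession",
    "assay_id": "assay_id",
    "activity_type": "activity_type",
    "relation": "relation",
    "value": "value",
    "unit": "unit",
    "is_binary": "is_binary",
    "active_label": "active_label",
    "year": "year",
    "target_mapping": "target_mapping",
}

_MANDATORY = ("molecule_ref", "target_accession", "assay_id", "activity_type")
_TRUE = {"1", "true", "yes", "active"}


def read_measurements(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    source_id: str | None = None,
    delimiter: str = "\t",
) -> tuple[list[Measurement], list[Rejection]]:
    """Read a delimited per-source activity table.

    ``dialect`` maps canonical field names to this source's column headers;
    unmapped optional fields fall back to defaults.  A missing mandatory
    column is a hard error; an unparseable row becomes a logged
    :class:`Rejection` rather than a crash, so one bad record never takes
    down an ingest.
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for fld in _MANDATORY:
            if cols[fld] not in header:
                raise ValueError(
                    f"{path.name}: mandatory column {cols[fld]!r} "
                    f"(field {fld!r}) missing from header"
                )
        measurements: list[Measurement] = []
        rejections: list[Rejection] = []
        for i, row in enumerate(reader, start=2):
            try:
                measurements.append(_parse_row(row, cols, source_id, path.stem))
            except (ValueError, KeyError) as exc:
                rej = Rejection(row_number=i, reason=str(exc), row=dict(row))
                logger.warning("%s:%d rejected: %s", path.name, i, exc)
                rejections.append(rej)
    return measurements, rejections


def _get(row: Mapping[str, str], cols: Mapping[str, str], fld: str) -> str:
    raw = row.get(cols[fld], "") or ""
    return raw.strip()


def _parse_row(
    row: Mapping[str, str],
    cols: Mapping[str, str],
    source_id: str | None,
    default_source: str,
) -> Measurement:
    is_binary = _get(row, cols, "is_binary").lower() in _TRUE
    value_s = _get(row, cols, "value")
    unit = _get(row, cols, "unit") or None
    relation = _get(row, cols, "relation") or "="

    value: float | None = None
    if is_binary:
        unit = None
    else:
        if not value_s:
            raise ValueError("missing value on non-binary record")
        try:
            value = float(value_s)
        except ValueError:
            raise ValueError(f"unparseable value {value_s!r}") from None
        if unit is None:
            raise ValueError("missing unit")

    year_s = _get(row, cols, "year")
    year = int(year_s) if year_s else None
    active_s = _get(row, cols, "active_label")
    active = active_s.lower() in _TRUE if active_s else None

    return Measurement(
        source_id=_get(row, cols, "source_id") or source_id or default_source,
        molecule_ref=_get(row, cols, "molecule_ref"),
        target_accession=_get(row, cols, "target_accession"),
        assay_id=_get(row, cols, "assay_id"),
        activity_type=_get(row, cols, "activity_type"),
        relation=relation,
        value=value,
        unit=unit,
        is_binary=is_binary,
        active_label=active,
        year=year,
        target_mapping=_get(row, cols, "target_mapping") or "single",
    )


# ---------------------------------------------------------------------------
# Proteins: FASTA + classification sidecar


def read_proteins(
    fasta_path: str | Path, table_path: str | Path, *, delimiter: str = "\t"
) -> dict[str, ProteinRecord]:
    """Read protein sequences (FASTA, id = accession) and the accession ->
    organism/classification sidecar TSV (columns ``accession``, ``organism``,
    then one column per classification level, left to right)."""
    seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    proteins: dict[str, ProteinRecord] = {}
    with Path(table_path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        fields = reader.fieldnames or []
        level_cols = [c for c in fields if c not in ("accession", "organism")]
        for row in reader:
            acc = row["accession"].strip()
            levels = []
            for c in level_cols:
                lbl = (row.get(c) or "").strip()
                if not lbl:
                    break
                levels.append(lbl)
            proteins[acc] = ProteinRecord(
                accession=acc,
                sequence=seqs.get(acc, ""),
                organism=row["organism"].strip(),
                classification=tuple(levels),
            )
    return proteins


# ---------------------------------------------------------------------------
# Curated output table

#: Fixed column order of the curated TSV.
CURATED_COLUMNS = (
    "connectivity_key",
    "InChIKey",
    "InChI",
    "SMILES",
    "target_accession",
    "organism",
    "activity_type",
    "relation",
    "pchembl_mean",
    "pchembl_std",
    "pchembl_median",
    "n_exact",
    "n_censored",
    "quality",
    "year_first",
    "year_last",
    "sources",
    "assays",
)


def write_curated(records: Sequence, path: str | Path) -> None:
    """Write aggregated activities as a TSV with the fixed column order.

    The writer is the inverse of :func:`read_curated`: a round trip is the
    identity on all fields.  Floats are written with full ``repr`` precision;
    the 2-decimal presentation convention applies to reports, not storage.
    """
    from .aggregate import AggregatedActivity  # local import, avoids cycle

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CURATED_COLUMNS)
        for r in records:
            if not isinstance(r, AggregatedActivity):
                raise TypeError(f"expected AggregatedActivity, got {type(r)!r}")
            writer.writerow(
                [
                    r.connectivity_key,
                    r.inchikey,
                    r.inchi,
                    r.smiles,
                    r.target_accession,
                    r.organism,
                    r.activity_type,
                    r.relation,
                    _fmt_float(r.pchembl_mean),
                    _fmt_float(r.pchembl_std),
                    _fmt_float(r.pchembl_median),
                    r.n_exact,
                    r.n_censored,
                    r.quality,
                    r.year_first if r.year_first is not None else "",
                    r.year_last if r.year_last is not None else "",
                    ";".join(r.sources),
                    ";".join(r.assays),
                ]
            )


def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(x)


def read_curated(path: str | Path) -> list:
    """Read back a curated TSV written by :func:`write_curated`."""
    from .aggregate import AggregatedActivity

    records = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if tuple(reader.fieldnames or ()) != CURATED_COLUMNS:
            raise ValueError(f"{path}: not a curated table (header mismatch)")
        for row in reader:
            records.append(
                AggregatedActivity(
                    connectivity_key=row["connectivity_key"],
                    inchikey=row["InChIKey"],
                    inchi=row["InChI"],
                    smiles=row["SMILES"],
                    target_accession=row["target_accession"],
                    organism=row["organism"],
                    activity_type=row["activity_type"],
                    relation=row["relation"],
                    pchembl_mean=_opt_float(row["pchembl_mean"]),
                    pchembl_std=_opt_float(row["pchembl_std"]),
                    pchembl_median=_opt_float(row["pchembl_median"]),
                    n_exact=int(row["n_exact"]),
                    n_censored=int(row["n_censored"]),
                    quality=row["quality"],
                    year_first=int(row["year_first"]) if row["year_first"] else None,
                    year_last=int(row["year_last"]) if row["year_last"] else None,
                    sources=tuple(filter(None, row["sources"].split(";"))),
                    assays=tuple(filter(None, row["assays"].split(";"))),
                )
            )
    return records


def _opt_float(s: str) -> float | None:
    return float(s) if s else None


# ---------------------------------------------------------------------------
# Subset queries


def query_by_classification(
    records: Iterable,
    proteins: Mapping[str, ProteinRecord],
    level: int,
    label: str,
) -> list:
    """Records whose target is classified ``label`` at 1-based ``level``.

    Case-sensitive exact label match, mirroring subset extraction such as
    "all targets whose level-2 class is 'Kinase'".  A protein whose
    classification is shallower than ``level`` simply never matches.
    """
    out = []
    for r in records:
        prot = proteins.get(r.target_accession)
        if prot is not None and prot.classification_at(level) == label:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Organism report


def _round2_half_up(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def organism_report(
    records: Iterable,
    proteins: Mapping[str, ProteinRecord],
    *,
    top: int | None = None,
) -> list[OrganismReport]:
    """Per-organism counts of high/medium/low-quality data points.

    ``records`` are quality-annotated measurement-level records (anything
    with ``target_accession`` and a ``quality`` attribute of
    high/medium/low).  Organisms are taken from the protein table; the
    percentage is of the grand total of input records, rounded half-up to
    two decimals.  Sorted by total descending, ties alphabetically.
    """
    counts: dict[str, list[int]] = {}
    tier_idx = {"high": 0, "medium": 1, "low": 2}
    for r in records:
        prot = proteins.get(r.target_accession)
        organism = prot.organism if prot is not None else "unknown"
        row = counts.setdefault(organism, [0, 0, 0])
        row[tier_idx[r.quality]] += 1
    rows = [(org, c[0], c[1], c[2]) for org, c in counts.items()]
    return organism_report_from_counts(rows, top=top)


def organism_report_from_counts(
    rows: Iterable[tuple[str, int, int, int]],
    *,
    grand_total: int | None = None,
    top: int | None = None,
) -> list[OrganismReport]:
    """Build the organism report from pre-tabulated per-organism tier counts.

    ``rows`` are ``(organism, n_high, n_medium, n_low)``.  ``grand_total``
    defaults to the sum over the given rows; pass it explicitly when the
    rows are a top-N excerpt of a larger dataset so percentages stay
    relative to the full set.
    """
    reports = []
    rows = list(rows)
    totals = [h + m + lo for _, h, m, lo in rows]
    denom = grand_total if grand_total is not None else sum(totals)
    for (org, h, m, lo), tot in zip(rows, totals):
        pct = (
            _round2_half_up(Decimal(100) * Decimal(tot) / Decimal(denom))
            if denom
            else 0.0
        )
        reports.append(
            OrganismReport(
                organism=org,
                n_high=h,
                n_medium=m,
                n_low=lo,
                n_total=tot,
                pct_of_total=pct,
            )
        )
    reports.sort(key=lambda r: (-r.n_total, r.organism))
    return reports[:top] if top is not None else reports
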