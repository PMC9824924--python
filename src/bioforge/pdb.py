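"""Offline matching of curated pairs to experimental protein-ligand complexes.

Links each curated compound-target pair to the experimentally determined 3D
complexes that contain it, working entirely from a local ligand table
(columns: PDB id, ligand InChI, chain UniProt accession) so no network
access is ever required.

Both sides are pushed through the same standardisation pipeline before
comparison, so identity is at connectivity level: a deposited ligand whose
InChI differs from a curated molecule only in its stereo layer still
matches, which is the correct behaviour for a stereo-free curated set.
Mutations in the deposited structure are not modelled — a complex maps to
the affinity data of the wild-type accession it is annotated with.  All
complexes of one matched pair are returned, not just one representative.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .standardize import StandardisedCompound, standardize_molecule

logger = logging.getLogger("bioforge")

__all__ = ["PDBLigandRow", "PDBMatch", "read_pdb_ligand_table", "match_complexes"]

_PDB_ID = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


@dataclass(frozen=True)
class PDBLigandRow:
    pdb_id: str
    ligand_inchi: str
    accession: str

    def __post_init__(self) -> None:
        if not _PDB_ID.match(self.pdb_id):
            raise ValueError(f"malformed PDB id {self.pdb_id!r}")


@dataclass(frozen=True)
class PDBMatch:
    """One curated pair linked to every deposited complex containing it."""

    connectivity_key: str
    accession: str
    pdb_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pdb_ids:
            raise ValueError("a match needs at least one PDB id")
        if list(self.pdb_ids) != sorted(set(self.pdb_ids)):
            raise ValueError("pdb_ids must be unique and sorted")


def read_pdb_ligand_table(
    path: str | Path, *, delimiter: str = "\t"
) -> tuple[list[PDBLigandRow], list[dict]]:
    """Read the offline ligand table; malformed rows are logged and
    returned separately, never fatal."""
    rows: list[PDBLigandRow] = []
    rejected: list[dict] = []
    with Path(path).open(newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter=delimiter), start=2):
            try:
                rows.append(
                    PDBLigandRow(
                        pdb_id=row["pdb_id"].strip(),
                        ligand_inchi=row["ligand_inchi"].strip(),
                        accession=row["accession"].strip(),
                    )
                )
            except (ValueError, KeyError, AttributeError) as exc:
                logger.warning("%s:%d rejected PDB row: %s", path, i, exc)
                rejected.append(dict(row))
    return rows, rejected


def _standardise_inchi(inchi_str: str, *, strict: bool) -> str | None:
    mol = Chem.MolFromInchi(inchi_str, treatWarningAsError=False)
    if mol is None:
        return None
    comp = standardize_molecule(Chem.MolToSmiles(mol), keep_stereo=strict)
    if comp.rejected:
        return None
    return comp.inchikey if strict else comp.connectivity_key


def match_complexes(
    curated: Iterable,
    pdb_table: Sequence[PDBLigandRow],
    *,
    strict_inchi: bool = False,
) -> list[PDBMatch]:
    """Match curated pairs to deposited complexes.

    A match requires structural identity of the ligand after both sides ran
    the same standardisation (connectivity level by default;
    ``strict_inchi=True`` compares full standardised InChIKeys for the
    stereo-preserving variant) *and* equality of the UniProt accession.
    Deterministic and symmetric in table order; every reported id comes
    from the input table.
    """
    ligand_index: dict[tuple[str, str], set[str]] = {}
    for row in pdb_table:
        key = _standardise_inchi(row.ligand_inchi, strict=strict_inchi)
        if key is None:
            logger.warning("unparseable ligand InChI in %s", row.pdb_id)
            continue
        ligand_index.setdefault((key, row.accession), set()).add(row.pdb_id)

    matches = []
    seen: set[tuple[str, str]] = set()
    for rec in curated:
        ckey = rec.inchikey if strict_inchi else rec.connectivity_key
        pair = (ckey, rec.target_accession)
        if pair in seen:
            continue
        seen.add(pair)
        ids = ligand_index.get(pair)
        if ids:
            matches.append(
                PDBMatch(
                    connectivity_key=rec.connectivity_key,
                    accession=rec.target_accession,
                    pdb_ids=tuple(sorted(ids)),
                )
            )
    matches.sort(key=lambda m: (m.connectivity_key, m.accession))
    return matches


def write_matches(matches: Sequence[PDBMatch], path: str | Path) -> None:
    """TSV export: connectivity_key, accession, semicolon-joined PDB ids."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["connectivity_key", "accession", "pdb_ids"])
        for m in matches:
            writer.writerow([m.connectivity_key, m.accession, ";".join(m.pdb_ids)])
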