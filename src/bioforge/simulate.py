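"""Seeded generator of raw multi-source bioactivity data with known truth.

Curation pipelines are hard to validate on real aggregated databases
because no ground truth exists there.  This generator builds a miniature
multi-source world in which every artefact the pipeline must handle is
*planted* and recorded in a manifest:

* a true pChEMBL per (molecule, target) pair, drawn N(6.5, 1.5) by default
  so an activity threshold of 6.5 splits classes roughly evenly;
* per-assay systematic bias (drawn N(0, ``assay_bias_sd``) or planted
  explicitly) plus i.i.d. measurement noise N(0, ``noise_sd``);
* observed values re-expressed as concentrations with varied unit
  spellings ("nM", "uM", "µM", ...);
* censoring at the detection window and at random, binary activity
  classes, homologous/multi-protein target mappings;
* structure variants (counter-ion salts, non-canonical atom orderings,
  kekulised SMILES) injected into the reported structures;
* an overlapping source that repackages part of another, with its lineage
  declared.

All randomness flows from one seed through named substreams, so each
artefact family can be regenerated independently and every run is exactly
reproducible.  The scale knobs default to a desk-sized world (tens of
molecules and targets); nothing here attempts real-database scale or
realistic medicinal chemistry beyond valid structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
from rdkit import Chem

from .io import Measurement, ProteinRecord
from .standardize import standardize_molecule

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedData",
    "molecule_library",
    "simulate_truth",
    "simulate_sources",
    "simulate",
    "write_sources",
]


@dataclass(frozen=True)
class SimConfig:
    n_targets: int = 8
    n_molecules: int = 40
    n_assays: int = 10
    n_sources: int = 3
    pair_fraction: float = 0.6
    measurements_per_pair: int = 2
    truth_mean: float = 6.5
    truth_sd: float = 1.5
    assay_bias_sd: float = 0.3
    planted_biases: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    censored_fraction: float = 0.05
    binary_fraction: float = 0.05
    variant_fraction: float = 0.1
    homolog_fraction: float = 0.1
    source_overlap: float = 0.2
    detection_window: tuple[float, float] = (3.0, 11.0)
    year_range: tuple[int, int] = (2005, 2020)
    activity_types: tuple[str, ...] = ("IC50", "EC50", "Ki", "KD")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pair_fraction",
            "censored_fraction",
            "binary_fraction",
            "variant_fraction",
            "homolog_fraction",
            "source_overlap",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth: the molecule library, the protein panel and the true
    pChEMBL of every simulated pair."""

    molecules: dict[str, str]  # molecule id -> canonical SMILES
    proteins: dict[str, ProteinRecord]
    truth: dict[tuple[str, str], float]  # (molecule id, accession) -> pChEMBL


@dataclass
class SimulatedData:
    sources: dict[str, list[Measurement]]
    lineage: dict[str, list[str]]
    manifest: dict
    truth: SimTruth


# named substreams: one root seed, an independent stream per artefact family,
# so e.g. the variant pattern is stable when only the noise model changes
_STREAM_NAMES = {
    "truth": 0,
    "assays": 1,
    "measurements": 2,
    "variants": 3,
    "overlap": 4,
    "proteins": 5,
}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM_NAMES[name]]))


# ---------------------------------------------------------------------------
# Molecule and protein libraries

_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccoc1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
)

_TAILS = (
    "",
    "C",
    "CC",
    "CCC",
    "CCCC",
    "O",
    "OC",
    "OCC",
    "N",
    "NC",
    "CN",
    "CO",
    "CCO",
    "CCN",
    "Cl",
    "F",
    "Br",
    "C(C)C",
    "C(=O)C",
    "CC(C)C",
    "OC(C)C",
    "NCC",
    "CCCl",
    "OCCC",
)


def molecule_library(n: int) -> list[str]:
    """Deterministic list of ``n`` small-molecule SMILES with pairwise
    distinct heavy-atom connectivity (substituted rings and chains)."""
    return list(_molecule_library_cached(n))


@lru_cache(maxsize=None)
def _molecule_library_cached(n: int) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    length = 0
    while len(out) < n:
        made_progress = False
        for scaffold in _SCAFFOLDS:
            for tail in _TAILS:
                smi = tail + "C" * length + scaffold
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                comp = standardize_molecule(smi)
                if comp.rejected or comp.connectivity_key in seen:
                    continue
                seen.add(comp.connectivity_key)
                out.append(comp.smiles)
                made_progress = True
                if len(out) == n:
                    return tuple(out)
        if not made_progress:
            raise ValueError(f"molecule library exhausted at {len(out)} < {n}")
        length += 1
    return tuple(out)


_CLASSIFICATIONS = (
    ("Enzyme", "Kinase", "Protein Kinase", "TK", "Tyrosine kinase"),
    ("Enzyme", "Kinase", "Protein Kinase", "CMGC", "CDK"),
    ("Enzyme", "Protease", "Serine protease"),
    ("Membrane receptor", "Family A GPCR", "Small molecule receptor",
     "Monoamine receptor", "Adrenergic receptor"),
    ("Membrane receptor", "Family A GPCR", "Small molecule receptor",
     "Nucleotide-like receptor", "Adenosine receptor"),
    ("Transporter", "Electrochemical transporter",
     "SLC superfamily", "SLC06 neurotransmitter transporter family"),
)

_ORGANISMS = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Draw the molecule library, protein panel and true pair affinities.

    True pChEMBL values are i.i.d. N(``truth_mean``, ``truth_sd``) over the
    selected (molecule, target) pairs; ``pair_fraction`` of all possible
    pairs exist, sampled uniformly.  Deterministic for a fixed seed.
    """
    rng_truth = _rng(cfg.seed, "truth")
    rng_prot = _rng(cfg.seed, "proteins")

    smiles = molecule_library(cfg.n_molecules)
    molecules = {f"MOL{i + 1:04d}": s for i, s in enumerate(smiles)}

    proteins: dict[str, ProteinRecord] = {}
    for i in range(cfg.n_targets):
        acc = f"P{i + 1:05d}"
        seq = "".join(rng_prot.choice(list(_AA), size=50))
        proteins[acc] = ProteinRecord(
            accession=acc,
            sequence=seq,
            organism=_ORGANISMS[i % len(_ORGANISMS)],
            classification=_CLASSIFICATIONS[i % len(_CLASSIFICATIONS)],
        )

    all_pairs = [(m, p) for m in molecules for p in proteins]
    n_pairs = max(1, int(round(cfg.pair_fraction * len(all_pairs))))
    idx = rng_truth.choice(len(all_pairs), size=n_pairs, replace=False)
    truth = {
        all_pairs[i]: float(rng_truth.normal(cfg.truth_mean, cfg.truth_sd))
        for i in sorted(idx)
    }
    return SimTruth(molecules=molecules, proteins=proteins, truth=truth)


# ---------------------------------------------------------------------------
# Observation model

_UNIT_SPELLINGS = (
    ("nM", 1e-9),
    ("nm", 1e-9),
    ("uM", 1e-6),
    ("µM", 1e-6),
    ("um", 1e-6),
    ("pM", 1e-12),
    ("mM", 1e-3),
)

_DEGRADED_MAPPINGS = (
    "single_homolog",
    "multi",
    "multi_homolog",
    "complex_subunit",
    "homolog_complex_subunit",
)


def _variant_smiles(smiles: str, kind: str, rng: np.random.Generator) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if kind == "salt":
        return smiles + ".Cl"
    if kind == "random_order":
        variants = Chem.MolToRandomSmilesVect(mol, 1, int(rng.integers(2**31)))
        return variants[0]
    if kind == "kekule":
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    raise ValueError(f"unknown variant kind {kind!r}")


def simulate_sources(truth: SimTruth, cfg: SimConfig) -> SimulatedData:
    """Turn true affinities into raw per-source measurement tables.

    Each selected pair is measured by ``measurements_per_pair`` distinct
    assays; each observation is truth + assay bias + N(0, noise_sd),
    re-expressed in a concentration unit with varied spelling.  Values
    outside the detection window become censored bounds at the window edge;
    further records are censored at random, turned into binary classes, or
    reported with structure variants, all per the configured fractions.
    One extra source repackages a ``source_overlap`` fraction of the first
    source's rows with its lineage declared; the manifest records every
    planted artefact by (source, row index).
    """
    rng_a = _rng(cfg.seed, "assays")
    rng_m = _rng(cfg.seed, "measurements")
    rng_v = _rng(cfg.seed, "variants")
    rng_o = _rng(cfg.seed, "overlap")

    assay_ids = [f"A{i + 1:03d}" for i in range(cfg.n_assays)]
    biases = {
        a: float(cfg.planted_biases.get(a, rng_a.normal(0.0, cfg.assay_bias_sd)))
        for a in assay_ids
    }
    type_cycle = [
        cfg.activity_types[i % len(cfg.activity_types)]
        for i in range(cfg.n_assays)
    ]
    assay_types = dict(zip(assay_ids, type_cycle))
    y0, y1 = cfg.year_range
    assay_years = {a: int(rng_a.integers(y0, y1 + 1)) for a in assay_ids}

    source_ids = [f"S{i + 1}" for i in range(cfg.n_sources)]
    sources: dict[str, list[Measurement]] = {s: [] for s in source_ids}
    manifest: dict = {
        "seed": cfg.seed,
        "assay_biases": biases,
        "assay_types": assay_types,
        "assay_years": assay_years,
        "censored": [],
        "binary": [],
        "homolog": [],
        "variants": [],
        "repackaged": [],
        "truth": {f"{m}|{p}": v for (m, p), v in truth.truth.items()},
    }

    lo, hi = cfg.detection_window
    k = min(cfg.measurements_per_pair, cfg.n_assays)
    for (mol_id, acc), true_p in truth.truth.items():
        chosen = rng_m.choice(cfg.n_assays, size=k, replace=False)
        for ai in sorted(chosen):
            assay = assay_ids[ai]
            source = source_ids[ai % cfg.n_sources]
            obs = true_p + biases[assay] + float(rng_m.normal(0.0, cfg.noise_sd))

            smiles = truth.molecules[mol_id]
            molecule_ref = smiles
            variant_kind = None
            if rng_v.random() < cfg.variant_fraction:
                variant_kind = ("salt", "random_order", "kekule")[
                    int(rng_v.integers(3))
                ]
                molecule_ref = _variant_smiles(smiles, variant_kind, rng_v)

            mapping = "single"
            if rng_m.random() < cfg.homolog_fraction:
                mapping = _DEGRADED_MAPPINGS[int(rng_m.integers(len(_DEGRADED_MAPPINGS)))]

            idx = len(sources[source])
            if rng_m.random() < cfg.binary_fraction:
                m = Measurement(
                    source_id=source,
                    molecule_ref=molecule_ref,
                    target_accession=acc,
                    assay_id=assay,
                    activity_type=assay_types[assay],
                    is_binary=True,
                    active_label=bool(true_p >= cfg.truth_mean),
                    year=assay_years[assay],
                    target_mapping=mapping,
                )
                manifest["binary"].append([source, idx])
            else:
                relation = "="
                reported_p = obs
                if obs > hi:
                    reported_p, relation = hi, "<"  # below detection: conc < bound
                elif obs < lo:
                    reported_p, relation = lo, ">"
                elif rng_m.random() < cfg.censored_fraction:
                    relation = "<" if rng_m.random() < 0.5 else ">"
                unit, factor = _UNIT_SPELLINGS[
                    int(rng_m.integers(len(_UNIT_SPELLINGS)))
                ]
                value = 10.0 ** (-reported_p) / factor
                m = Measurement(
                    source_id=source,
                    molecule_ref=molecule_ref,
                    target_accession=acc,
                    assay_id=assay,
                    activity_type=assay_types[assay],
                    relation=relation,
                    value=value,
                    unit=unit,
                    year=assay_years[assay],
                    target_mapping=mapping,
                )
                if relation != "=":
                    manifest["censored"].append([source, idx])
            if variant_kind is not None:
                manifest["variants"].append([source, idx, variant_kind])
            if mapping != "single":
                manifest["homolog"].append([source, idx, mapping])
            sources[source].append(m)

    lineage: dict[str, list[str]] = {}
    if cfg.source_overlap > 0 and sources[source_ids[0]]:
        repack_id = f"{source_ids[0]}_repack"
        donor = sources[source_ids[0]]
        n_copy = max(1, int(round(cfg.source_overlap * len(donor))))
        picked = sorted(rng_o.choice(len(donor), size=n_copy, replace=False))
        copies = []
        for j, di in enumerate(picked):
            orig = donor[di]
            copies.append(
                Measurement(
                    source_id=repack_id,
                    molecule_ref=orig.molecule_ref,
                    target_accession=orig.target_accession,
                    assay_id=orig.assay_id,
                    activity_type=orig.activity_type,
                    relation=orig.relation,
                    value=orig.value,
                    unit=orig.unit,
                    is_binary=orig.is_binary,
                    active_label=orig.active_label,
                    year=orig.year,
                    target_mapping=orig.target_mapping,
                )
            )
            manifest["repackaged"].append([repack_id, j, source_ids[0], int(di)])
            # the copies inherit their original's planted artefacts
            if orig.is_binary:
                manifest["binary"].append([repack_id, j])
            elif orig.relation != "=":
                manifest["censored"].append([repack_id, j])
        sources[repack_id] = copies
        lineage[repack_id] = [source_ids[0]]

    manifest["lineage"] = lineage
    return SimulatedData(
        sources=sources, lineage=lineage, manifest=manifest, truth=truth
    )


def simulate(cfg: SimConfig) -> SimulatedData:
    """Convenience: ``simulate_sources(simulate_truth(cfg), cfg)``."""
    return simulate_sources(simulate_truth(cfg), cfg)


# ---------------------------------------------------------------------------
# File emission (the raw-table side of the core readers)


def write_sources(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Emit the simulated world as files: one TSV per source, the molecule
    library as SDF, proteins as FASTA + classification TSV, and the
    manifest as JSON.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for source_id, records in data.sources.items():
        p = outdir / f"{source_id}.tsv"
        with p.open("w") as fh:
            cols = [
                "source_id", "molecule_ref", "target_accession", "assay_id",
                "activity_type", "relation", "value", "unit", "is_binary",
                "active_label", "year", "target_mapping",
            ]
            fh.write("\t".join(cols) + "\n")
            for m in records:
                fh.write(
                    "\t".join(
                        [
                            m.source_id,
                            m.molecule_ref,
                            m.target_accession,
                            m.assay_id,
                            m.activity_type,
                            m.relation,
                            "" if m.value is None else repr(m.value),
                            m.unit or "",
                            "true" if m.is_binary else "false",
                            ""
                            if m.active_label is None
                            else ("true" if m.active_label else "false"),
                            "" if m.year is None else str(m.year),
                            m.target_mapping,
                        ]
                    )
                    + "\n"
                )
        paths[source_id] = p

    sdf_path = outdir / "molecules.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    for mol_id, smi in data.truth.molecules.items():
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", mol_id)
        writer.write(mol)
    writer.close()
    paths["molecules"] = sdf_path

    fasta_path = outdir / "proteins.fasta"
    with fasta_path.open("w") as fh:
        for prot in data.truth.proteins.values():
            fh.write(f">{prot.accession}\n{prot.sequence}\n")
    paths["fasta"] = fasta_path

    table_path = outdir / "proteins.tsv"
    max_depth = max(
        (len(p.classification) for p in data.truth.proteins.values()), default=0
    )
    with table_path.open("w") as fh:
        cols = ["accession", "organism"] + [f"l{i + 1}" for i in range(max_depth)]
        fh.write("\t".join(cols) + "\n")
        for prot in data.truth.proteins.values():
            levels = list(prot.classification) + [""] * (
                max_depth - len(prot.classification)
            )
            fh.write("\t".join([prot.accession, prot.organism] + levels) + "\n")
    paths["proteins"] = table_path

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(data.manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
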