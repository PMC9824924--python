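"""Molecule standardisation and connectivity-level identity.

Bioactivity sources disagree on salt forms, protonation states, tautomers
and (often erroneous) stereo annotations for the same parent compound.  To
pool their measurements, every structure is reduced to a canonical
connectivity-level representative:

1. keep the largest organic fragment (salt / counter-ion stripping),
2. neutralise charges where chemically valid,
3. remove stereochemistry,
4. pick the canonical tautomer.

Two inputs that differ only in any of those aspects map to the same
``connectivity_key`` (the 14-character connectivity block of the InChIKey of
the standardised structure) and are therefore aggregated together.

A stereo-preserving mode exists behind ``keep_stereo=True`` but is excluded
from the deduplication guarantees: cross-source stereo annotations are too
unreliable to key on, so the connectivity-level set is the primary product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardisedCompound",
    "standardize_molecule",
    "connectivity_key",
]

_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


@dataclass(frozen=True)
class StandardisedCompound:
    """A structure reduced to its canonical connectivity-level parent.

    ``flags`` records every transformation that actually changed the
    structure; an already-standard input therefore carries an empty set.
    ``rejected`` compounds (unparseable or inorganic-only) carry a
    non-empty ``reject_reason`` and no identifiers.
    """

    connectivity_key: str
    inchikey: str
    inchi: str
    smiles: str
    flags: frozenset[str] = field(default_factory=frozenset)
    reject_reason: str = ""

    @property
    def rejected(self) -> bool:
        return "rejected" in self.flags

    def __post_init__(self) -> None:
        if self.rejected and not self.reject_reason:
            raise ValueError("rejected compound requires a reject_reason")


def _reject(reason: str) -> StandardisedCompound:
    return StandardisedCompound(
        connectivity_key="",
        inchikey="",
        inchi="",
        smiles="",
        flags=frozenset({"rejected"}),
        reject_reason=reason,
    )


def _parse(structure: str) -> Chem.Mol | None:
    """Parse a SMILES string or an SDF/Molfile block."""
    if not structure.strip():
        return None
    if "M  END" in structure or "\n" in structure.strip():
        # Molfile header starts with the (possibly blank) title line:
        # pass the block through unstripped
        return Chem.MolFromMolBlock(structure, sanitize=True)
    return Chem.MolFromSmiles(structure.strip())


def _has_stereo(mol: Chem.Mol) -> bool:
    if any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()):
        return True
    return any(
        a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
    )


def standardize_molecule(
    structure: str, *, keep_stereo: bool = False
) -> StandardisedCompound:
    """Standardise a SMILES string or SDF block to its connectivity parent.

    Pipeline order: salt strip -> neutralise -> strip stereo -> canonical
    tautomer (stereo first, because tautomer canonicalisation does not
    preserve stereocentres anyway).
    Each step sets its flag only when it changed the molecule, so
    ``standardize_molecule`` is idempotent: feeding the output SMILES back in
    returns the same structure with an empty flag set.

    Unparseable input and species without a carbon skeleton are returned as
    rejected records rather than raising; rejection is data, not failure.
    """
    mol = _parse(structure)
    if mol is None:
        return _reject("unparseable structure")

    flags: set[str] = set()

    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags > 1:
        mol = _largest_organic_fragment(mol)
        flags.add("salt_stripped")
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        return _reject("no organic fragment")

    before = Chem.MolToSmiles(mol)
    mol = _UNCHARGER.uncharge(mol)
    if Chem.MolToSmiles(mol) != before:
        flags.add("neutralised")

    if keep_stereo:
        # the stereo-preserving variant is deliberately lightly
        # standardised: tautomer canonicalisation can rewrite stereocentres,
        # so it is skipped here
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    else:
        if _has_stereo(mol):
            Chem.RemoveStereochemistry(mol)
            flags.add("stereo_removed")
        before = Chem.MolToSmiles(mol)
        mol = _TAUTOMER.Canonicalize(mol)
        if Chem.MolToSmiles(mol) != before:
            flags.add("tautomer_canonicalised")

    smiles = Chem.MolToSmiles(mol)
    std_inchi = inchi.MolToInchi(mol)
    if not std_inchi:
        return _reject("InChI generation failed")
    ikey = inchi.InchiToInchiKey(std_inchi)
    return StandardisedCompound(
        connectivity_key=ikey.split("-")[0],
        inchikey=ikey,
        inchi=std_inchi,
        smiles=smiles,
        flags=frozenset(flags),
    )


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    # LargestFragmentChooser prefers organic fragments and breaks size ties
    # deterministically; ties on canonical-SMILES order are resolved here so
    # the choice does not depend on atom input order.
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic or list(frags)
    return max(
        pool,
        key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )


def connectivity_key(compound: StandardisedCompound) -> str:
    """Return the connectivity-level identity key of a standardised compound.

    Equal keys identify equal heavy-atom connectivity after standardisation;
    stereoisomers, salt forms and protonation states of one parent share a
    key, constitutional isomers never do.
    """
    if compound.rejected:
        raise ValueError(
            f"rejected compound has no connectivity key: {compound.reject_reason}"
        )
    return compound.connectivity_key
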