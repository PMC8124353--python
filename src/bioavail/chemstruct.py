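"""Structure handling: parsing, signature descriptors, structural alerts and the
applicability-domain gate.

Molecules are represented by *signature descriptors*: for every heavy atom and
every height ``h`` up to a maximum, a canonical serialization of the atom's
depth-``h`` neighborhood tree.  Counting these strings over all atoms gives a
sparse, permutation-invariant feature vector — the QSAR feature space used by
the endpoint models.

Three structural alerts (phenol, quinolone, beta-lactam) select special
handling in the gut PBPK stage, and an applicability-domain check accumulates
the reasons a compound falls outside the model's reliable region (metals,
quaternary amines, molecular weight outside 100–700 Da, user-declared
hydrolysis sensitivity or blood-flow modulation, advisory descriptor ranges).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

#: Elements considered "organic" for the metal rule; anything else flags the
#: compound as a metal/organometallic and puts it outside the domain.
ORGANIC_ELEMENTS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})

#: Caller-supplied applicability flags (no structural rule exists for these).
USER_FLAGS = frozenset({"hydrolysis_sensitive", "blood_flow_modulator"})

_QUAT_AMINE = Chem.MolFromSmarts("[N+;X4;H0]")

DOMAIN_REASONS = (
    "metal",
    "quaternary_amine",
    "mw_low",
    "mw_high",
    "hydrolysis_sensitive",
    "blood_flow_modulator",
    "descriptor_range",
    "unparseable",
)


class CompoundParseError(ValueError):
    """Raised when a SMILES cannot be turned into a structure."""

    def __init__(self, compound_id: str, message: str):
        self.compound_id = compound_id
        super().__init__(f"{compound_id}: {message}")


class AlertConfigError(RuntimeError):
    """Raised when the alert pattern file is missing or ill-formed."""


@dataclass(frozen=True)
class Compound:
    """A parsed structure: the unit of all per-molecule computation.

    ``smiles`` is the canonical SMILES of the kept (largest) fragment;
    ``elements`` records the atomic numbers of the *full* input, including
    stripped counterions, so the metal domain rule sees the whole salt/complex.
    """

    compound_id: str
    smiles: str
    mol_weight: float
    user_flags: frozenset = frozenset()
    elements: frozenset = frozenset()
    warnings: tuple = ()

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always re-parse
            raise CompoundParseError(self.compound_id, "stored SMILES failed to re-parse")
        return mol


@dataclass(frozen=True)
class DescriptorVector:
    """Sparse signature counts; keys are ``"h{height}|{fragment}"`` strings."""

    entries: Mapping[str, int]
    max_height: int

    def heavy_atom_count(self) -> int:
        return sum(v for k, v in self.entries.items() if k.startswith("h0|"))


@dataclass(frozen=True)
class AlertFlags:
    phenol: bool = False
    quinolone: bool = False
    beta_lactam: bool = False

    def as_dict(self) -> dict:
        return {"phenol": self.phenol, "quinolone": self.quinolone, "beta_lactam": self.beta_lactam}


@dataclass(frozen=True)
class DescriptorRangeConfig:
    """Advisory training-domain property ranges (log P, H-bond donors/acceptors).

    ``warn_only=True`` records violations as advisories without taking the
    compound out of domain.
    """

    logp_min: float = -6.4
    logp_max: float = 7.6
    hbd_max: int = 19
    hba_max: int = 19
    warn_only: bool = True


@dataclass(frozen=True)
class DomainStatus:
    in_domain: bool
    reasons: tuple = ()
    advisories: tuple = ()

    def __post_init__(self):
        if self.in_domain != (len(self.reasons) == 0):
            raise ValueError("in_domain must be true iff reasons is empty")

    @property
    def predictable(self) -> bool:
        """Metals, quaternary amines and parse failures yield no estimate at all;
        every other out-of-domain compound still gets an (uncertain) estimate."""
        return not ({"metal", "quaternary_amine", "unparseable"} & set(self.reasons))


def parse_compound(compound_id: str, smiles: str, user_flags: Iterable[str] = ()) -> Compound:
    """Parse a SMILES into a :class:`Compound`.

    Multi-fragment inputs (salts) keep the largest fragment by heavy-atom count
    (ties broken by molecular weight) and record a ``salt_stripped`` warning.
    """
    if not smiles or not smiles.strip():
        raise CompoundParseError(compound_id, "empty SMILES")
    flags = frozenset(user_flags)
    unknown = flags - USER_FLAGS
    if unknown:
        raise ValueError(f"unknown user flags: {sorted(unknown)}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundParseError(compound_id, f"unparseable SMILES {smiles!r}")
    elements = frozenset(a.GetAtomicNum() for a in mol.GetAtoms())
    warnings: list = []
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        frags = sorted(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
        mol = frags[-1]
        warnings.append("salt_stripped")
    return Compound(
        compound_id=compound_id,
        smiles=Chem.MolToSmiles(mol),
        mol_weight=Descriptors.MolWt(mol),
        user_flags=flags,
        elements=elements,
        warnings=tuple(warnings),
    )


_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    q = atom.GetFormalCharge()
    if q:
        sym += f"{q:+d}"
    return sym


def _atom_signature(mol: Chem.Mol, idx: int, height: int, parent: int = -1) -> str:
    """Canonical string of the atom's depth-``height`` neighborhood tree.

    The rooted environment is unfolded into a tree (never stepping back over
    the bond just traversed) and serialized with children sorted
    lexicographically, which makes the string canonical by construction:
    invariant under atom renumbering, and prefix-consistent across heights
    (equal height-(h+1) signatures imply equal height-h signatures).
    """
    atom = mol.GetAtomWithIdx(idx)
    label = _atom_label(atom)
    if height == 0:
        return label
    branches = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtomIdx(idx)
        if nbr == parent:
            continue
        sym = _BOND_SYMBOL.get(bond.GetBondType(), "~")
        branches.append(sym + _atom_signature(mol, nbr, height - 1, idx))
    if not branches:
        return label
    return label + "(" + "".join(sorted(branches)) + ")"


def compute_signatures(compound: Compound, max_height: int = 3) -> DescriptorVector:
    """Count canonical atom signatures at every height up to ``max_height``."""
    if not 0 <= max_height <= 3:
        raise ValueError("max_height must be in [0, 3]")
    mol = compound.to_mol()
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        for h in range(max_height + 1):
            counts[f"h{h}|{_atom_signature(mol, atom.GetIdx(), h)}"] += 1
    return DescriptorVector(entries=dict(counts), max_height=max_height)


def load_alert_patterns(path=None) -> dict:
    """Read the SMARTS pattern file (``name<TAB>SMARTS`` per line, # comments)."""
    if path is None:
        text = resources.files("bioavail.data").joinpath("alerts.smarts").read_text()
    else:
        try:
            with open(path) as fh:
                text = fh.read()
        except OSError as exc:
            raise AlertConfigError(f"cannot read alert pattern file: {exc}") from exc
    patterns = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise AlertConfigError(f"line {lineno}: expected '<name> <SMARTS>'")
        name, smarts = parts
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise AlertConfigError(f"line {lineno}: invalid SMARTS for {name!r}")
        patterns[name] = query
    missing = {"phenol", "quinolone", "beta_lactam"} - patterns.keys()
    if missing:
        raise AlertConfigError(f"pattern file lacks required alerts: {sorted(missing)}")
    return patterns


_DEFAULT_PATTERNS: dict | None = None


def detect_alerts(compound: Compound, patterns: dict | None = None) -> AlertFlags:
    """Match the three structural alerts against the compound."""
    global _DEFAULT_PATTERNS
    if patterns is None:
        if _DEFAULT_PATTERNS is None:
            _DEFAULT_PATTERNS = load_alert_patterns()
        patterns = _DEFAULT_PATTERNS
    mol = compound.to_mol()
    return AlertFlags(
        phenol=mol.HasSubstructMatch(patterns["phenol"]),
        quinolone=mol.HasSubstructMatch(patterns["quinolone"]),
        beta_lactam=mol.HasSubstructMatch(patterns["beta_lactam"]),
    )


def check_domain(
    compound: Compound,
    ranges: DescriptorRangeConfig | None = None,
    mw_min: float = 100.0,
    mw_max: float = 700.0,
) -> DomainStatus:
    """Accumulate every violated applicability rule.

    MW bounds are inclusive: compounds with 100 <= MW <= 700 Da pass. The
    descriptor-range check (log P and H-bond counts of the training domain) is
    advisory by default and only runs when ``ranges`` is given.
    """
    reasons: list = []
    advisories: list = []
    if compound.elements - ORGANIC_ELEMENTS:
        reasons.append("metal")
    if compound.to_mol().HasSubstructMatch(_QUAT_AMINE):
        reasons.append("quaternary_amine")
    if compound.mol_weight < mw_min:
        reasons.append("mw_low")
    elif compound.mol_weight > mw_max:
        reasons.append("mw_high")
    for flag in sorted(compound.user_flags):
        reasons.append(flag)
    if ranges is not None:
        mol = compound.to_mol()
        logp = Crippen.MolLogP(mol)
        hbd = Lipinski.NumHDonors(mol)
        hba = Lipinski.NumHAcceptors(mol)
        violated = (
            not ranges.logp_min <= logp <= ranges.logp_max
            or hbd > ranges.hbd_max
            or hba > ranges.hba_max
        )
        if violated:
            (advisories if ranges.warn_only else reasons).append("descriptor_range")
    return DomainStatus(
        in_domain=not reasons, reasons=tuple(reasons), advisories=tuple(advisories)
    )
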