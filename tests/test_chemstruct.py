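"""Structure parsing, signature descriptors, alerts and the domain gate."""
import numpy as np
import pytest
from rdkit import Chem

from bioavail import chemstruct as cs
from bioavail.synthetic import fixture_panel

# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_ethanol_mass_and_determinism():
    c1 = cs.parse_compound("d1", "CCO")
    c2 = cs.parse_compound("d1", "OCC")
    assert c1.mol_weight == pytest.approx(46.069, abs=0.01)
    assert c1.smiles == c2.smiles


@pytest.mark.parametrize("smiles", ["", "   ", "C1CC", "not_a_smiles"])
def test_parse_rejects_bad_smiles(smiles):
    with pytest.raises(cs.CompoundParseError) as err:
        cs.parse_compound("d2", smiles)
    assert "d2" in str(err.value)


def test_parse_rejects_unknown_user_flags():
    with pytest.raises(ValueError, match="unknown user flags"):
        cs.parse_compound("d", "CCO", ["volatile"])


def test_salt_stripping_keeps_largest_fragment_but_remembers_elements():
    c = cs.parse_compound("na_acetate", "[Na+].CC(=O)[O-]")
    assert "salt_stripped" in c.warnings
    assert "Na" not in c.smiles
    assert 11 in c.elements  # sodium still visible to the metal rule


# ---------------------------------------------------------------------------
# signature descriptors
# ---------------------------------------------------------------------------

def _distinct_at_height(vec, h):
    return {k for k in vec.entries if k.startswith(f"h{h}|")}


def test_ethanol_height0_counts_atom_types():
    d = cs.compute_signatures(cs.parse_compound("e", "CCO"), 0)
    assert d.entries == {"h0|C": 2, "h0|O": 1}


def test_methane_single_signature_any_height():
    for h in range(4):
        d = cs.compute_signatures(cs.parse_compound("m", "C"), h)
        assert len(_distinct_at_height(d, h)) == 1
        assert sum(v for k, v in d.entries.items() if k.startswith(f"h{h}|")) == 1


def test_benzene_symmetry_one_signature_count_six():
    d = cs.compute_signatures(cs.parse_compound("b", "c1ccccc1"), 1)
    h1 = {k: v for k, v in d.entries.items() if k.startswith("h1|")}
    assert len(h1) == 1 and set(h1.values()) == {6}


def test_max_height_bounds():
    c = cs.parse_compound("e", "CCO")
    with pytest.raises(ValueError):
        cs.compute_signatures(c, 4)
    with pytest.raises(ValueError):
        cs.compute_signatures(c, -1)


@pytest.mark.parametrize("entry", fixture_panel()[:12], ids=lambda e: e.name)
def test_signature_permutation_invariance_and_monotonicity(entry):
    """Atom renumbering must not change the descriptor; richer heights can only
    split signature classes, never merge them."""
    c = cs.parse_compound(entry.name, entry.smiles)
    mol = c.to_mol()
    base = cs.compute_signatures(c, 3)
    rng = np.random.default_rng(hash(entry.name) % 2**31)
    for _ in range(3):
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        again = cs.compute_signatures(cs.Compound(entry.name, shuffled, c.mol_weight), 3)
        assert again.entries == base.entries
    counts = [len(_distinct_at_height(base, h)) for h in range(4)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))
    assert base.heavy_atom_count() == mol.GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# structural alerts: implementation vs an independent brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_phenol(mol):
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 8 and atom.GetTotalNumHs() >= 1 and atom.GetDegree() == 1:
            if any(n.GetIsAromatic() and n.GetAtomicNum() == 6 for n in atom.GetNeighbors()):
                return True
    return False


def _oracle_beta_lactam(mol):
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if len(ring) != 4:
            continue
        symbols = [mol.GetAtomWithIdx(i).GetAtomicNum() for i in ring]
        if symbols.count(7) < 1:
            continue
        for i in ring:
            a = mol.GetAtomWithIdx(i)
            if a.GetAtomicNum() != 6:
                continue
            has_exo_oxo = any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(a).GetAtomicNum() == 8
                for b in a.GetBonds()
            )
            bonded_ring_n = any(
                n.GetAtomicNum() == 7 and n.GetIdx() in ring for n in a.GetNeighbors()
            )
            if has_exo_oxo and bonded_ring_n:
                return True
    return False


def _oracle_quinolone(mol):
    """4-oxo-pyridinone ring carrying a 3-carboxyl, fused to a 6-ring."""
    ri = mol.GetRingInfo()
    rings6 = [set(r) for r in ri.AtomRings() if len(r) == 6]
    for ring in rings6:
        n_in_ring = [i for i in ring if mol.GetAtomWithIdx(i).GetAtomicNum() == 7]
        if not n_in_ring:
            continue
        carbonyl = None
        for i in ring:
            a = mol.GetAtomWithIdx(i)
            if a.GetAtomicNum() == 6 and any(
                b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(a).GetAtomicNum() == 8
                for b in a.GetBonds()
            ):
                carbonyl = i
        if carbonyl is None:
            continue
        has_carboxyl_neighbor = False
        for i in ring:
            a = mol.GetAtomWithIdx(i)
            if carbonyl not in [n.GetIdx() for n in a.GetNeighbors()]:
                continue
            for n in a.GetNeighbors():
                if n.GetIdx() in ring or n.GetAtomicNum() != 6:
                    continue
                oxy = [b for b in n.GetBonds() if b.GetOtherAtom(n).GetAtomicNum() == 8]
                if len(oxy) == 2:
                    has_carboxyl_neighbor = True
        fused = any(len(ring & other) == 2 for other in rings6 if other is not ring)
        if has_carboxyl_neighbor and fused:
            return True
    return False


@pytest.mark.parametrize("entry", fixture_panel(), ids=lambda e: e.name)
def test_alerts_match_hand_labels_and_oracle(entry):
    c = cs.parse_compound(entry.name, entry.smiles)
    flags = cs.detect_alerts(c)
    assert flags.phenol == entry.phenol
    assert flags.quinolone == entry.quinolone
    assert flags.beta_lactam == entry.beta_lactam
    mol = c.to_mol()
    assert flags.phenol == _oracle_phenol(mol)
    assert flags.beta_lactam == _oracle_beta_lactam(mol)
    assert flags.quinolone == _oracle_quinolone(mol)


def test_alert_pattern_file_errors(tmp_path):
    with pytest.raises(cs.AlertConfigError, match="cannot read"):
        cs.load_alert_patterns(tmp_path / "missing.smarts")
    bad = tmp_path / "bad.smarts"
    bad.write_text("phenol\t[OX2H][c]\nquinolone\t(((\n")
    with pytest.raises(cs.AlertConfigError, match="invalid SMARTS"):
        cs.load_alert_patterns(bad)
    partial = tmp_path / "partial.smarts"
    partial.write_text("phenol\t[OX2H][c]\n")
    with pytest.raises(cs.AlertConfigError, match="lacks required"):
        cs.load_alert_patterns(partial)


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("entry", fixture_panel(), ids=lambda e: e.name)
def test_domain_rules_match_hand_labels(entry):
    c = cs.parse_compound(entry.name, entry.smiles)
    status = cs.check_domain(c)
    reasons = set(status.reasons)
    assert ("quaternary_amine" in reasons) == entry.quaternary_amine
    assert ("metal" in reasons) == entry.metal
    assert ("mw_low" in reasons) == entry.mw_low
    assert ("mw_high" in reasons) == entry.mw_high


def test_domain_in_domain_iff_no_reasons(paracetamol):
    status = cs.check_domain(paracetamol)
    assert status.in_domain and status.reasons == ()
    with pytest.raises(ValueError):
        cs.DomainStatus(in_domain=True, reasons=("mw_low",))


def test_user_flags_become_domain_reasons():
    c = cs.parse_compound("x", "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1",
                          ["hydrolysis_sensitive"])
    status = cs.check_domain(c)
    assert "hydrolysis_sensitive" in status.reasons
    assert status.predictable  # flagged, but still gets an estimate


def test_metal_and_quaternary_block_estimation():
    for smi in ("C[N+](C)(C)C", "N.N.Cl[Pt]Cl"):
        status = cs.check_domain(cs.parse_compound("x", smi))
        assert not status.in_domain and not status.predictable


def test_descriptor_range_advisory_vs_strict():
    # triacontane: Crippen log P far above the 7.6 training ceiling
    c = cs.parse_compound("c30", "C" * 30)
    advisory = cs.check_domain(c, ranges=cs.DescriptorRangeConfig(warn_only=True))
    assert "descriptor_range" in advisory.advisories
    assert "descriptor_range" not in advisory.reasons
    strict = cs.check_domain(c, ranges=cs.DescriptorRangeConfig(warn_only=False))
    assert "descriptor_range" in strict.reasons
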