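"""Potential pharmacophore point (PPP) typing for CATS-style descriptors.

Each heavy atom receives a (possibly empty) subset of five labels:

* ``A`` — hydrogen-bond acceptor: N or O with an available lone pair,
  excluding amide / pyrrole-type nitrogens, protonatable nitrogens
  (protonated at pH 7.4, hence no lone pair) and oxygens of acidic groups
  already typed negative.
* ``D`` — hydrogen-bond donor: N or O carrying at least one hydrogen
  (acidic-group oxygens are treated in their deprotonated form and
  excluded).
* ``P`` — positively ionizable at pH 7.4: aliphatic amines and
  amidine/guanidine nitrogens, plus explicit cationic N.
* ``N`` — negatively ionizable: oxygens of carboxylic / sulfonic /
  phosphonic or phosphoric acid groups (neutral or anionic form) and
  tetrazole ring nitrogens.
* ``L`` — lipophilic: carbon or halogen whose heavy neighbors are all
  carbon or halogen.

The assignment is a deterministic, pure function of the molecular graph.
"""

from __future__ import annotations

from .graph import MolecularGraph

__all__ = ["PPP_TYPES", "assign_ppp"]

PPP_TYPES = ("A", "D", "P", "N", "L")
_HALOGENS = {"F", "Cl", "Br", "I"}


def _double_bonded_neighbors(atom, symbol: str) -> int:
    """Count neighbors of given element attached by a double bond."""
    count = 0
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() == symbol and bond.GetBondTypeAsDouble() == 2.0:
            count += 1
    return count


def _is_acid_heteroatom_oxygen(atom) -> bool:
    """O belonging to a C/S/P acid group: -C(=O)O[H/-], -S(=O)(=O)O, -P(=O)O."""
    if atom.GetSymbol() != "O":
        return False
    for bond in atom.GetBonds():
        center = bond.GetOtherAtom(atom)
        sym = center.GetSymbol()
        if sym not in ("C", "S", "P"):
            continue
        # the center must carry at least one O double bond, and at least one
        # of its oxygens must be acidic (O with H, or anionic O)
        n_dbl_o = _double_bonded_neighbors(center, "O")
        if n_dbl_o == 0:
            continue
        has_acidic_o = any(
            nb.GetSymbol() == "O"
            and (nb.GetTotalNumHs() > 0 or nb.GetFormalCharge() < 0)
            for nb in center.GetNeighbors()
        )
        if has_acidic_o:
            return True
    return False


def _is_tetrazole_nitrogen(atom) -> bool:
    if atom.GetSymbol() != "N" or not atom.GetIsAromatic():
        return False
    ri = atom.GetOwningMol().GetRingInfo()
    for ring in ri.AtomRings():
        if atom.GetIdx() not in ring or len(ring) != 5:
            continue
        symbols = [atom.GetOwningMol().GetAtomWithIdx(i).GetSymbol() for i in ring]
        if symbols.count("N") == 4 and symbols.count("C") == 1:
            return True
    return False


def _is_amide_like_nitrogen(atom) -> bool:
    """N single-bonded to a C or S that is double-bonded to O/S (amide, sulfonamide)."""
    for bond in atom.GetBonds():
        if bond.GetBondTypeAsDouble() != 1.0:
            continue
        center = bond.GetOtherAtom(atom)
        if center.GetSymbol() in ("C", "S") and (
            _double_bonded_neighbors(center, "O") or _double_bonded_neighbors(center, "S")
        ):
            return True
    return False


def _is_amidine_nitrogen(atom) -> bool:
    """N of an amidine/guanidine fragment N-C=N (either nitrogen)."""
    for bond in atom.GetBonds():
        center = bond.GetOtherAtom(atom)
        if center.GetSymbol() != "C" or center.GetIsAromatic():
            continue
        order = bond.GetBondTypeAsDouble()
        if order == 2.0:
            # atom is =N; amidine if center also has a single-bonded N
            for b2 in center.GetBonds():
                other = b2.GetOtherAtom(center)
                if other.GetIdx() != atom.GetIdx() and other.GetSymbol() == "N" \
                        and b2.GetBondTypeAsDouble() == 1.0:
                    return True
        elif order == 1.0 and not _is_amide_like_nitrogen(atom):
            if _double_bonded_neighbors(center, "N"):
                return True
    return False


def _is_basic_amine(atom) -> bool:
    """Aliphatic amine N expected protonated at pH 7.4."""
    if atom.GetSymbol() != "N" or atom.GetIsAromatic():
        return False
    if atom.GetFormalCharge() > 0:
        return True
    if atom.GetFormalCharge() < 0:
        return False
    # sp3 N with only single bonds, no adjacent carbonyl/sulfonyl/aromatic
    # ring or heteroatom neighbor
    for bond in atom.GetBonds():
        if bond.GetBondTypeAsDouble() != 1.0:
            return False
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() != "C" or other.GetIsAromatic():
            return False
    if _is_amide_like_nitrogen(atom):
        return False
    # exclude N adjacent to sp2 carbon bearing =N (guanidine handled separately)
    return True


def assign_ppp(graph: MolecularGraph) -> list[frozenset]:
    """Per-atom PPP label sets for a molecular graph (see module docstring)."""
    mol = graph.to_rdkit()
    labels: list[set] = [set() for _ in range(graph.n_atoms)]

    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()

        # negative ionizable
        negative = False
        if _is_acid_heteroatom_oxygen(atom) or _is_tetrazole_nitrogen(atom):
            negative = True
        elif sym == "O" and atom.GetFormalCharge() < 0:
            negative = True
        if negative:
            labels[idx].add("N")

        # positive ionizable
        positive = False
        if sym == "N" and not negative:
            if _is_basic_amine(atom) or _is_amidine_nitrogen(atom):
                positive = True
        if positive:
            labels[idx].add("P")

        # acceptor
        if sym in ("N", "O") and not negative and not positive:
            acceptor = True
            if sym == "N":
                if atom.GetFormalCharge() > 0:
                    acceptor = False
                elif atom.GetIsAromatic() and (atom.GetDegree() == 3 or atom.GetTotalNumHs() > 0):
                    acceptor = False  # pyrrole-type: lone pair in the π system
                elif _is_amide_like_nitrogen(atom):
                    acceptor = False
                elif _double_bonded_neighbors(atom, "O") >= 1:
                    acceptor = False  # nitro-like
            if acceptor:
                labels[idx].add("A")

        # donor
        if sym in ("N", "O") and atom.GetTotalNumHs() >= 1 and not negative:
            labels[idx].add("D")

        # lipophilic
        if sym == "C" or sym in _HALOGENS:
            neighbors_ok = all(
                nb.GetSymbol() == "C" or nb.GetSymbol() in _HALOGENS
                for nb in atom.GetNeighbors()
            )
            if neighbors_ok:
                labels[idx].add("L")

    return [frozenset(s) for s in labels]
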