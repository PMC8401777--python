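"""Matched-molecular-pair generation by single-cut fragmentation.

Every acyclic single bond between two heavy atoms is a candidate cut.  A
cut splits a compound into a *core* and a *substituent*, each carrying one
attachment point written as the mapped dummy atom ``[*:1]`` in canonical
SMILES.  Two compounds sharing a core with different substituents form an
MMP, subject to the size constraints: each substituent has at most 13
heavy atoms and the two substituents differ by at most 8 heavy atoms.
MMPs sharing a core form a matched molecular series (MMS); series that
contain only one class are discarded because they cannot contribute to
both sides of the classification problem.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field

from rdkit import Chem

from .data_model import Compound, PairLabel, label_pair

logger = logging.getLogger(__name__)

MAX_SUB_ATOMS = 13
MAX_SUB_DIFF = 8

_ATTACHMENT_MAP_NUM = 1


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut split of a parent compound into core + substituent."""

    core: str  # canonical SMILES with [*:1] attachment dummy
    substituent: str
    parent: Compound


@dataclass(frozen=True)
class MMP:
    """An ordered matched molecular pair (low-potency compound first)."""

    cpd_low: Compound
    cpd_high: Compound
    core: str
    sub_low: str
    sub_high: str
    delta_p: float
    label: PairLabel

    @property
    def mmp_id(self) -> str:
        return f"{self.cpd_low.cid}|{self.cpd_high.cid}"


@dataclass
class MMS:
    """A matched molecular series: all MMPs sharing one core."""

    core_key: str
    mmps: list[MMP] = field(default_factory=list)


def heavy_atom_count(fragment_smiles: str) -> int:
    """Heavy atoms in a fragment SMILES, excluding the attachment dummy."""
    mol = Chem.MolFromSmiles(fragment_smiles)
    if mol is None:
        raise ValueError(f"unparseable fragment: {fragment_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _canonical_fragment(mol: Chem.Mol) -> str:
    """Canonical SMILES of a fragment, attachment dummy mapped as [*:1]."""
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(_ATTACHMENT_MAP_NUM)
            atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def enumerate_single_cuts(
    compound: Compound, max_sub_atoms: int = MAX_SUB_ATOMS
) -> list[Fragmentation]:
    """Enumerate all single cuts of acyclic single bonds of a compound.

    Each qualifying cut is returned in the orientation(s) whose
    substituent has between 1 and ``max_sub_atoms`` heavy atoms; a cut may
    therefore yield two fragmentations (either side can play the
    substituent role).  Hydrogens are never a substituent.
    """
    mol = compound.mol()
    if mol.GetNumHeavyAtoms() < 2:
        return []

    results: list[Fragmentation] = []
    seen: set[tuple[str, str]] = set()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        fragmented = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True)
        pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:  # pragma: no cover - acyclic bond always splits in two
            continue
        frags = [_canonical_fragment(p) for p in pieces]
        counts = [heavy_atom_count(f) for f in frags]
        for (sub, n_sub), (core, _) in itertools.permutations(zip(frags, counts), 2):
            if 1 <= n_sub <= max_sub_atoms and (core, sub) not in seen:
                seen.add((core, sub))
                results.append(Fragmentation(core=core, substituent=sub, parent=compound))
    return results


def reassemble(core: str, substituent: str) -> str:
    """Rejoin a core and substituent at their attachment dummies.

    Returns the canonical SMILES of the reconstructed parent; used to
    verify that fragmentation is information-preserving.
    """
    combined = Chem.CombineMols(
        Chem.MolFromSmiles(core), Chem.MolFromSmiles(substituent)
    )
    return Chem.MolToSmiles(Chem.molzip(combined))


def generate_mmps(
    compounds: list[Compound],
    max_sub_atoms: int = MAX_SUB_ATOMS,
    max_sub_diff: int = MAX_SUB_DIFF,
) -> list[MMP]:
    """Generate MMPs from a compound set via a shared-core index.

    Every unordered compound pair that shares a core with differing
    substituents yields candidate fragmentations; exactly one MMP per
    pair is retained — the candidate with the maximum-heavy-atom core,
    ties broken by the lexicographically smallest canonical core string.
    Pairs whose potency difference falls in the ambiguous band are
    dropped.
    """
    index: dict[str, list[tuple[str, Compound]]] = defaultdict(list)
    for compound in compounds:
        for frag in enumerate_single_cuts(compound, max_sub_atoms=max_sub_atoms):
            index[frag.core].append((frag.substituent, compound))

    # unordered compound pair -> best (core_heavy_atoms, core, sub_a, sub_b)
    candidates: dict[tuple[str, str], tuple[int, str, str, str]] = {}
    cpd_by_id = {c.cid: c for c in compounds}
    for core, entries in index.items():
        n_core = heavy_atom_count(core)
        for (sub_a, cpd_a), (sub_b, cpd_b) in itertools.combinations(entries, 2):
            if cpd_a.cid == cpd_b.cid or sub_a == sub_b:
                continue
            if abs(heavy_atom_count(sub_a) - heavy_atom_count(sub_b)) > max_sub_diff:
                continue
            if cpd_a.cid > cpd_b.cid:
                cpd_a, cpd_b, sub_a, sub_b = cpd_b, cpd_a, sub_b, sub_a
            key = (cpd_a.cid, cpd_b.cid)
            # prefer the largest core; tie-break on the smaller core string
            cand = (n_core, core, sub_a, sub_b)
            best = candidates.get(key)
            if best is None or (cand[0], _neg_lex(cand[1])) > (best[0], _neg_lex(best[1])):
                candidates[key] = cand

    mmps: list[MMP] = []
    for (cid_a, cid_b), (_, core, sub_a, sub_b) in sorted(candidates.items()):
        cpd_a, cpd_b = cpd_by_id[cid_a], cpd_by_id[cid_b]
        delta = abs(cpd_a.potency - cpd_b.potency)
        label = label_pair(delta)
        if label is PairLabel.AMBIGUOUS:
            continue
        if (cpd_a.potency, cpd_a.cid) <= (cpd_b.potency, cpd_b.cid):
            low, high, sub_low, sub_high = cpd_a, cpd_b, sub_a, sub_b
        else:
            low, high, sub_low, sub_high = cpd_b, cpd_a, sub_b, sub_a
        mmps.append(
            MMP(
                cpd_low=low,
                cpd_high=high,
                core=core,
                sub_low=sub_low,
                sub_high=sub_high,
                delta_p=delta,
                label=label,
            )
        )
    return mmps


class _neg_lex(str):
    """String wrapper whose ordering is reversed (for max() tie-breaks)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def group_into_mms(mmps: list[MMP]) -> list[MMS]:
    """Partition MMPs by core and drop single-class series."""
    by_core: dict[str, MMS] = {}
    for mmp in mmps:
        by_core.setdefault(mmp.core, MMS(core_key=mmp.core)).mmps.append(mmp)
    kept = []
    for mms in by_core.values():
        labels = {m.label for m in mms.mmps}
        if PairLabel.AC in labels and PairLabel.NON_AC in labels:
            kept.append(mms)
        else:
            logger.debug("discarding single-class MMS %s (%d MMPs)", mms.core_key, len(mms.mmps))
    return sorted(kept, key=lambda m: m.core_key)


def mmps_to_frame(mmps: list[MMP]):
    """MMP table for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cid_low": [m.cpd_low.cid for m in mmps],
            "cid_high": [m.cpd_high.cid for m in mmps],
            "core": [m.core for m in mmps],
            "sub_low": [m.sub_low for m in mmps],
            "sub_high": [m.sub_high for m in mmps],
            "delta_p": [m.delta_p for m in mmps],
            "label": [m.label.value for m in mmps],
        }
    )
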