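"""Interpretable MMP fingerprints.

An MMP is represented by three binary segments built from ECFP-style
circular substructure features of the core and the two substituents:

* **core segment** — features of the shared core fragment;
* **substituent XOR segment** — features present in exactly one of the
  two substituents (the transformation);
* **substituent AND segment** — features common to both substituents.

Features are unfolded 32-bit environment identifiers restricted to bond
diameters 2 and 4 (atom-type and diameter-0 features are excluded so
that every feature describes a multi-atom environment).  Identifiers are
sorted in ascending order and assigned consecutive bits, so distinct
identifiers never collide on a bit.  Every on-bit keeps a back-map to
the atom/bond environments that produced it, which is what allows
feature contributions to be painted back onto the structures.

The attachment dummy atom takes part in environments, so substituent
features are aware of their surroundings relative to the attachment
point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Hashable, Iterable, Mapping, NamedTuple

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .fragmentation import MMP

logger = logging.getLogger(__name__)

#: bond radii kept (radius 1 and 2 = bond diameters 2 and 4)
KEPT_RADII = (1, 2)

#: substituent-feature channel tags
XOR = "X"
AND = "A"

#: a substituent-segment token: (channel, identifier)
SubToken = tuple[str, int]


class Environment(NamedTuple):
    """One occurrence of a circular substructure in a fragment."""

    atoms: tuple[int, ...]
    bonds: tuple[int, ...]


@dataclass(frozen=True)
class FeatureSet:
    """Substructure identifiers of one fragment with their occurrences."""

    identifiers: frozenset[int]
    environments: Mapping[int, tuple[Environment, ...]]


_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=max(KEPT_RADII))


def extract_features(fragment_smiles: str, radii: Iterable[int] = KEPT_RADII) -> FeatureSet:
    """Circular substructure features of a fragment.

    Only environments with bond radius in ``radii`` are kept; the
    radius-0 (single atom type) layer is excluded.  Duplicate
    occurrences of an identifier are recorded as separate environments
    but contribute a single set membership.  Results are cached: the
    computation is pure in the canonical fragment string.
    """
    return _extract_features_cached(fragment_smiles, tuple(sorted(set(radii))))


@lru_cache(maxsize=100_000)
def _extract_features_cached(fragment_smiles: str, radii: tuple[int, ...]) -> FeatureSet:
    if 0 in radii:
        raise ValueError("radius-0 features are excluded by design")
    mol = Chem.MolFromSmiles(fragment_smiles)
    if mol is None:
        raise ValueError(f"unparseable fragment: {fragment_smiles!r}")
    radii = set(radii)

    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    _GENERATOR.GetSparseCountFingerprint(mol, additionalOutput=out)
    bit_info = out.GetBitInfoMap()

    environments: dict[int, list[Environment]] = {}
    for identifier, occurrences in bit_info.items():
        for atom_idx, radius in occurrences:
            if radius not in radii:
                continue
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
            atoms = {atom_idx}
            for bid in bond_ids:
                bond = mol.GetBondWithIdx(bid)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            environments.setdefault(int(identifier), []).append(
                Environment(atoms=tuple(sorted(atoms)), bonds=tuple(sorted(bond_ids)))
            )

    return FeatureSet(
        identifiers=frozenset(environments),
        environments={k: tuple(v) for k, v in environments.items()},
    )


@dataclass(frozen=True)
class FeatureUniverse:
    """Sorted identifier -> bit tables for the core and substituent segments.

    The substituent XOR and AND channels share one identifier table with
    distinct offsets: token ``(X, id)`` maps to bit ``pos(id)`` and
    ``(A, id)`` to ``len(sub_bits) + pos(id)`` inside the substituent
    segment, so the segment length is twice the identifier count.
    """

    core_bits: Mapping[int, int]
    sub_bits: Mapping[int, int]

    @property
    def n_core_bits(self) -> int:
        return len(self.core_bits)

    @property
    def n_sub_bits(self) -> int:
        return 2 * len(self.sub_bits)

    def core_bit(self, identifier: int) -> int | None:
        return self.core_bits.get(identifier)

    def sub_bit(self, token: SubToken) -> int | None:
        channel, identifier = token
        pos = self.sub_bits.get(identifier)
        if pos is None:
            return None
        return pos if channel == XOR else len(self.sub_bits) + pos


def _sorted_bits(identifiers: Iterable[int]) -> dict[int, int]:
    return {ident: i for i, ident in enumerate(sorted(set(identifiers)))}


def build_universe(training_mmps: Iterable[MMP]) -> FeatureUniverse:
    """Feature universe from the union of training core/substituent features."""
    core_ids: set[int] = set()
    sub_ids: set[int] = set()
    n = 0
    for mmp in training_mmps:
        n += 1
        core_ids |= extract_features(mmp.core).identifiers
        sub_ids |= extract_features(mmp.sub_low).identifiers
        sub_ids |= extract_features(mmp.sub_high).identifiers
    if n == 0:
        raise ValueError("cannot build a universe from zero MMPs")
    if not core_ids or not sub_ids:
        logger.warning(
            "empty feature segment (|core|=%d, |sub|=%d)", len(core_ids), len(sub_ids)
        )
    return FeatureUniverse(core_bits=_sorted_bits(core_ids), sub_bits=_sorted_bits(sub_ids))


#: back-map roles
CORE_ROLE = "core"
SUB_LOW_ROLE = "sub_low"
SUB_HIGH_ROLE = "sub_high"

#: contribution/back-map key: ("core", identifier) or ("sub", (channel, identifier))
FeatureKey = tuple[str, Hashable]


@dataclass(frozen=True)
class MMPFingerprint:
    """Sparse MMP fingerprint over identifier sets.

    ``core_ids`` holds core-segment identifiers; ``sub_ids`` holds
    substituent-segment tokens tagged with the XOR/AND channel.  Kernels
    operate directly on these sets, which is equivalent to the binary
    vector formulation over the union universe: features unseen during
    training enlarge a test instance's self-similarity but can never
    overlap a training vector.
    """

    core_ids: frozenset[Hashable]
    sub_ids: frozenset[Hashable]
    universe: FeatureUniverse | None = None
    backmap: Mapping[FeatureKey, tuple[tuple[str, Environment], ...]] = field(
        default_factory=dict
    )
    mmp_id: str | None = None

    def unmapped(self) -> tuple[set, set]:
        """Identifiers absent from the universe (test-only features)."""
        if self.universe is None:
            return set(), set()
        core = {i for i in self.core_ids if self.universe.core_bit(i) is None}
        sub = {t for t in self.sub_ids if self.universe.sub_bit(t) is None}
        return core, sub

    def core_on_bits(self) -> set[int]:
        if self.universe is None:
            raise ValueError("fingerprint has no universe")
        return {
            b for b in (self.universe.core_bit(i) for i in self.core_ids) if b is not None
        }

    def sub_on_bits(self) -> set[int]:
        if self.universe is None:
            raise ValueError("fingerprint has no universe")
        return {
            b for b in (self.universe.sub_bit(t) for t in self.sub_ids) if b is not None
        }


def fingerprint_mmp(mmp: MMP, universe: FeatureUniverse) -> MMPFingerprint:
    """Build the MMP fingerprint of one pair against a universe.

    Swapping the two substituents leaves the result unchanged: XOR and
    AND channels are symmetric, and the back-map records occurrences in
    both fragments for AND features.
    """
    core_fs = extract_features(mmp.core)
    low_fs = extract_features(mmp.sub_low)
    high_fs = extract_features(mmp.sub_high)

    backmap: dict[FeatureKey, tuple[tuple[str, Environment], ...]] = {}
    for ident in core_fs.identifiers:
        backmap[("core", ident)] = tuple(
            (CORE_ROLE, env) for env in core_fs.environments[ident]
        )

    and_ids = low_fs.identifiers & high_fs.identifiers
    xor_ids = low_fs.identifiers ^ high_fs.identifiers
    sub_tokens: set[SubToken] = set()
    for ident in xor_ids:
        token = (XOR, ident)
        sub_tokens.add(token)
        if ident in low_fs.identifiers:
            occ = [(SUB_LOW_ROLE, env) for env in low_fs.environments[ident]]
        else:
            occ = [(SUB_HIGH_ROLE, env) for env in high_fs.environments[ident]]
        backmap[("sub", token)] = tuple(occ)
    for ident in and_ids:
        token = (AND, ident)
        sub_tokens.add(token)
        backmap[("sub", token)] = tuple(
            [(SUB_LOW_ROLE, env) for env in low_fs.environments[ident]]
            + [(SUB_HIGH_ROLE, env) for env in high_fs.environments[ident]]
        )

    fp = MMPFingerprint(
        core_ids=frozenset(core_fs.identifiers),
        sub_ids=frozenset(sub_tokens),
        universe=universe,
        backmap=backmap,
        mmp_id=mmp.mmp_id,
    )
    um_core, um_sub = fp.unmapped()
    if um_core or um_sub:
        logger.debug(
            "%s: %d core / %d sub features unseen in training",
            mmp.mmp_id,
            len(um_core),
            len(um_sub),
        )
    return fp


def abstract_fingerprint(
    core: Iterable[Hashable],
    sub: Iterable[Hashable],
    universe: FeatureUniverse | None = None,
) -> MMPFingerprint:
    """Chemistry-free fingerprint over raw feature tokens (for fixtures/tests)."""
    return MMPFingerprint(core_ids=frozenset(core), sub_ids=frozenset(sub), universe=universe)


def serialize_universe(universe: FeatureUniverse) -> str:
    """Universe as TSV text: identifier, bit, segment."""
    lines = ["identifier\tbit\tsegment"]
    for ident, bit in sorted(universe.core_bits.items(), key=lambda kv: kv[1]):
        lines.append(f"{ident}\t{bit}\tcore")
    for ident, bit in sorted(universe.sub_bits.items(), key=lambda kv: kv[1]):
        lines.append(f"{ident}\t{bit}\tsub")
    return "\n".join(lines) + "\n"
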