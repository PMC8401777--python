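"""Exact per-feature contributions for Tanimoto- and MMP-kernel SVMs.

For the plain Tanimoto kernel the decision value decomposes exactly:
each support vector ``sv_i`` with dual coefficient ``a_i`` contributes
``a_i / (|sv_i| + |x| - |sv_i & x|)`` to every feature shared with the
test instance ``x``, and these fragment contributions sum to
``a_i * K(sv_i, x)``.

The MMP kernel is a product of a core and a substituent Tanimoto kernel,
so the analogous expansion produces *cross-terms*, one per shared
(core feature, substituent feature) pair.  Each cross-term is split in
half: one half is assigned to the core feature and the other to the
substituent feature.  After the split, summing the per-feature values
returns the kernel part of the decision value exactly — no sampling, no
approximation.  The split is applied per support vector before
aggregation.

Feature contributions are finally redistributed evenly over the atoms
and bonds of the substructure occurrences that produced each feature,
which yields a chemistry-level heat map of the prediction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable

from .exceptions import ConfigurationError
from .fingerprints import AND, FeatureKey, MMPFingerprint
from .kernel_svm import MMPKernelSVC, TanimotoKernelSVC


@dataclass
class ContributionVector:
    """Additive per-feature explanation of one decision value.

    ``per_feature`` maps every contributing feature key to its value;
    the values sum to ``kernel_sum`` (the dual-weighted kernel total) and
    ``decision = kernel_sum - bias``.  ``remainder`` carries mass from
    features without a structural back-map (always 0 for the exact
    method; kept so conservation checks stay exact downstream).
    """

    per_feature: dict[Hashable, float]
    bias: float
    kernel_sum: float
    remainder: float = 0.0

    @property
    def decision(self) -> float:
        return self.kernel_sum - self.bias

    def total(self) -> float:
        return sum(self.per_feature.values())


@dataclass
class AtomBondWeightMap:
    """Feature contributions accumulated on atoms and bonds.

    Keys are ``(fragment role, index)`` with roles ``core``, ``sub_low``
    and ``sub_high``.  ``remainder`` holds contribution mass of features
    without a back-map entry (test-only features), reported rather than
    silently dropped.
    """

    atom_weights: dict[tuple[str, int], float] = field(default_factory=dict)
    bond_weights: dict[tuple[str, int], float] = field(default_factory=dict)
    remainder: float = 0.0

    def total(self) -> float:
        return sum(self.atom_weights.values()) + sum(self.bond_weights.values())


def frag_fc_tanimoto(
    sv: frozenset | set, dual_coef: float, x: frozenset | set, d: Hashable
) -> float:
    """Fragment feature contribution of one support vector to feature ``d``."""
    if d not in sv or d not in x:
        return 0.0
    denom = len(sv) + len(x) - len(sv & x)
    return dual_coef / denom


def fc_tanimoto(model: TanimotoKernelSVC, x: frozenset | set) -> ContributionVector:
    """Exact per-feature contributions for a plain Tanimoto-kernel SVM."""
    if not isinstance(model, TanimotoKernelSVC):
        raise ConfigurationError(
            f"fc_tanimoto requires a Tanimoto-kernel model, got {type(model).__name__}"
        )
    per_feature: dict[Hashable, float] = defaultdict(float)
    kernel_sum = 0.0
    for sv, coef in zip(model.support_fingerprints_, model.dual_coefs_):
        shared = sv & x
        if not shared:
            continue
        denom = len(sv) + len(x) - len(shared)
        term = coef / denom
        for d in shared:
            per_feature[d] += term
        kernel_sum += coef * len(shared) / denom
    return ContributionVector(
        per_feature=dict(per_feature), bias=model.bias_, kernel_sum=kernel_sum
    )


def frag_fc_mmp(
    sv: MMPFingerprint,
    dual_coef: float,
    x: MMPFingerprint,
    d_c: Hashable,
    d_s: Hashable,
) -> float:
    """Cross-term of one (core feature, substituent feature) pair."""
    if d_c not in sv.core_ids or d_c not in x.core_ids:
        return 0.0
    if d_s not in sv.sub_ids or d_s not in x.sub_ids:
        return 0.0
    denom_c = len(sv.core_ids) + len(x.core_ids) - len(sv.core_ids & x.core_ids)
    denom_s = len(sv.sub_ids) + len(x.sub_ids) - len(sv.sub_ids & x.sub_ids)
    return dual_coef / (denom_c * denom_s)


def decompose_mmp(model: MMPKernelSVC, x: MMPFingerprint) -> ContributionVector:
    """Exact per-feature contributions for an MMP-kernel SVM.

    For every support vector, each shared (core, substituent) feature
    pair contributes one cross-term; half of it is credited to the core
    feature and half to the substituent feature.  A support vector with
    zero core overlap or zero substituent overlap contributes nothing
    (its kernel value is zero).

    Returned keys are ``("core", identifier)`` and
    ``("sub", token)`` matching the fingerprint back-map.
    """
    if not isinstance(model, MMPKernelSVC):
        raise ConfigurationError(
            f"decompose_mmp requires an MMP-kernel model, got {type(model).__name__}"
        )
    per_feature: dict[FeatureKey, float] = defaultdict(float)
    kernel_sum = 0.0
    for sv, coef in zip(model.support_fingerprints_, model.dual_coefs_):
        shared_c = sv.core_ids & x.core_ids
        shared_s = sv.sub_ids & x.sub_ids
        if not shared_c or not shared_s:
            continue
        denom_c = len(sv.core_ids) + len(x.core_ids) - len(shared_c)
        denom_s = len(sv.sub_ids) + len(x.sub_ids) - len(shared_s)
        cross = coef / (denom_c * denom_s)
        # half of every cross-term to the core feature, half to the sub feature
        core_share = 0.5 * cross * len(shared_s)
        sub_share = 0.5 * cross * len(shared_c)
        for d_c in shared_c:
            per_feature[("core", d_c)] += core_share
        for d_s in shared_s:
            per_feature[("sub", d_s)] += sub_share
        kernel_sum += cross * len(shared_c) * len(shared_s)
    return ContributionVector(
        per_feature=dict(per_feature), bias=model.bias_, kernel_sum=kernel_sum
    )


def _environment_slots(occurrences) -> list[tuple[str, str, int]]:
    """Flatten environments into (role, kind, index) slots, duplicates kept."""
    slots = []
    for role, env in occurrences:
        for a in env.atoms:
            slots.append((role, "atom", a))
        for b in env.bonds:
            slots.append((role, "bond", b))
    return slots


def map_to_structure(cv: ContributionVector, fp: MMPFingerprint) -> AtomBondWeightMap:
    """Distribute feature contributions evenly onto atoms and bonds.

    Each feature's contribution is divided evenly over the atom/bond
    slots of all its recorded environments (duplicate occurrences count
    separately) and accumulated; overlapping features therefore add up
    on shared atoms.  AND-channel substituent features occur in both
    substituent fragments: their contribution is first split evenly
    between the two fragments, then spread within each.  Features with
    no back-map entry are collected into ``remainder``.
    """
    out = AtomBondWeightMap()

    for key, value in cv.per_feature.items():
        occurrences = fp.backmap.get(key)
        if not occurrences:
            out.remainder += value
            continue
        segment, token = key
        is_and = segment == "sub" and isinstance(token, tuple) and token[0] == AND
        if is_and:
            by_role: dict[str, list] = defaultdict(list)
            for role, env in occurrences:
                by_role[role].append((role, env))
            shares = [(occ, value / len(by_role)) for occ in by_role.values()]
        else:
            shares = [(list(occurrences), value)]
        for occ, share in shares:
            slots = _environment_slots(occ)
            w = share / len(slots)
            for role, kind, idx in slots:
                target = out.atom_weights if kind == "atom" else out.bond_weights
                target[(role, idx)] = target.get((role, idx), 0.0) + w
    out.remainder += cv.remainder
    return out


def contributions_frame(cv: ContributionVector, fp: MMPFingerprint | None = None):
    """Per-feature contribution table (segment, feature, bit, contribution)."""
    import pandas as pd

    rows = []
    for key, value in sorted(cv.per_feature.items(), key=lambda kv: -abs(kv[1])):
        segment, token = key if isinstance(key, tuple) and key[0] in ("core", "sub") else ("", key)
        bit = None
        if fp is not None and fp.universe is not None and segment:
            bit = (
                fp.universe.core_bit(token)
                if segment == "core"
                else fp.universe.sub_bit(token)
            )
        rows.append(
            {"segment": segment, "feature": repr(token), "bit": bit, "contribution": value}
        )
    return pd.DataFrame(rows, columns=["segment", "feature", "bit", "contribution"])
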