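"""Comparison reports and structure depictions.

The side-by-side report puts the exact kernel decomposition and the
Kernel SHAP control on one table per feature and summarizes how much of
each method's attribution mass lands on features *absent* from the
explained MMP — zero by construction for the exact method, typically
large for SHAP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fingerprints import SUB_HIGH_ROLE, SUB_LOW_ROLE, CORE_ROLE, MMPFingerprint
from .fragmentation import MMP
from .interpretation import AtomBondWeightMap, ContributionVector
from .shap_baseline import ShapExplanation


@dataclass
class CompareReport:
    """Feature-level comparison of the two attribution methods."""

    table: pd.DataFrame
    decision: float
    exact_absent_mass_fraction: float
    shap_absent_mass_fraction: float | None


def absent_mass_fraction(values, present) -> float:
    """Fraction of total |attribution| assigned to absent features (0/0 -> 0)."""
    values = np.asarray(values, dtype=float)
    present = np.asarray(present, dtype=bool)
    total = np.abs(values).sum()
    if total == 0:
        return 0.0
    return float(np.abs(values[~present]).sum() / total)


def compare_report(
    exact: ContributionVector,
    fp: MMPFingerprint,
    shap: ShapExplanation | None = None,
) -> CompareReport:
    """Tabulate exact contributions against Shapley values per feature."""
    rows: dict = {}
    for key, value in exact.per_feature.items():
        rows[key] = {"exact_contribution": value, "present": 1, "shapley_value": np.nan}

    if shap is not None:
        if shap.feature_names is None:
            raise ConfigurationError("SHAP explanation lacks feature names")
        if len(shap.feature_names) != len(shap.phis):
            raise ConfigurationError("SHAP explanation is inconsistent")
        for name, phi, present in zip(
            shap.feature_names, shap.phis, shap.features_present
        ):
            row = rows.setdefault(
                name,
                {"exact_contribution": 0.0, "present": int(present), "shapley_value": np.nan},
            )
            row["shapley_value"] = float(phi)
            row["present"] = int(present)

    table = pd.DataFrame(
        [
            {"feature": repr(k), **v}
            for k, v in sorted(
                rows.items(), key=lambda kv: -abs(kv[1]["exact_contribution"])
            )
        ],
        columns=["feature", "present", "exact_contribution", "shapley_value"],
    )

    # exact contributions exist only for features present in the instance
    exact_fraction = absent_mass_fraction(
        table["exact_contribution"], table["present"].astype(bool)
    )
    shap_fraction = None
    if shap is not None:
        shap_fraction = absent_mass_fraction(shap.phis, shap.features_present)
    return CompareReport(
        table=table,
        decision=exact.decision,
        exact_absent_mass_fraction=exact_fraction,
        shap_absent_mass_fraction=shap_fraction,
    )


# ---------------------------------------------------------------------------
# depiction

_WARM = (1.0, 0.55, 0.2)   # positive (orange-red)
_COOL = (0.3, 0.5, 1.0)    # negative (blue)


def _weight_color(weight: float, max_abs: float):
    if max_abs <= 0 or weight == 0:
        return (1.0, 1.0, 1.0)
    frac = min(abs(weight) / max_abs, 1.0)
    base = _WARM if weight > 0 else _COOL
    return tuple(1.0 - frac * (1.0 - c) for c in base)


def render_mmp_svg(mmp: MMP, weights: AtomBondWeightMap, path_low, path_high) -> None:
    """Write colored depictions of the two compounds of an MMP.

    Atom/bond weights are normalized by the maximum absolute weight of
    the pair; warm colors mark positive contributions, cool negative.
    Core weights appear identically in both depictions.
    """
    from rdkit import Chem
    from rdkit.Chem import rdDepictor
    from rdkit.Chem.Draw import rdMolDraw2D

    all_vals = list(weights.atom_weights.values()) + list(weights.bond_weights.values())
    max_abs = max((abs(v) for v in all_vals), default=0.0)

    for sub_role, path in ((SUB_LOW_ROLE, path_low), (SUB_HIGH_ROLE, path_high)):
        sub = mmp.sub_low if sub_role == SUB_LOW_ROLE else mmp.sub_high
        core_mol = Chem.MolFromSmiles(mmp.core)
        sub_mol = Chem.MolFromSmiles(sub)
        # tag fragment origin so indices survive the molzip reindexing
        for mol_, role in ((core_mol, CORE_ROLE), (sub_mol, sub_role)):
            for atom in mol_.GetAtoms():
                atom.SetProp("_frag_role", role)
                atom.SetIntProp("_frag_idx", atom.GetIdx())
        combined = Chem.CombineMols(core_mol, sub_mol)
        mol = Chem.molzip(combined)
        rdDepictor.Compute2DCoords(mol)

        atom_colors = {}
        for atom in mol.GetAtoms():
            if not atom.HasProp("_frag_role"):
                continue
            key = (atom.GetProp("_frag_role"), atom.GetIntProp("_frag_idx"))
            w = weights.atom_weights.get(key)
            if w:
                atom_colors[atom.GetIdx()] = _weight_color(w, max_abs)

        drawer = rdMolDraw2D.MolDraw2DSVG(400, 350)
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer,
            mol,
            highlightAtoms=list(atom_colors),
            highlightAtomColors=atom_colors,
        )
        drawer.FinishDrawing()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(drawer.GetDrawingText())
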