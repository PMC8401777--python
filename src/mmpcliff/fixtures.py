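"""Deterministic synthetic data for every pipeline stage.

Two generators live here:

* :func:`fig5_fixture` — a chemistry-free pair of MMP fingerprints over
  a six-feature abstract universe (three core features, three
  substituent features) whose kernel and cross-term values are known in
  closed form.  It exercises the MMP-kernel decomposition on paper-sized
  numbers.

* :func:`generate_cliff_dataset` — SMILES-level analog series with a
  *planted* activity cliff: each series is one scaffold decorated with
  substituents from a neutral pool plus one potency-boosting
  substituent.  The potency model is ``pKi = base + delta_strong *
  [has cliff substituent] + Normal(0, sigma)``, so pairs that exchange
  the cliff substituent against a neutral one are activity cliffs with
  near-certainty, while neutral-neutral pairs are non-cliffs.  This
  emulates the label structure of a real SAR data set without its
  potency distribution or chemical diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .data_model import Compound
from .fingerprints import XOR, MMPFingerprint, abstract_fingerprint

#: drug-like scaffolds, one marked attachment point each
SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1ccc2ccccc2c1",            # naphthalene
    "[*:1]c1ccc2[nH]ccc2c1",          # indole
    "[*:1]c1ccc2occc2c1",             # benzofuran
    "[*:1]c1ccc2sccc2c1",             # benzothiophene
    "[*:1]c1ccc(S(N)(=O)=O)cc1",      # benzenesulfonamide
    "[*:1]c1ccc(C(=O)N2CCCC2)cc1",    # phenyl pyrrolidinyl ketone
    "[*:1]C1CCN(c2ccccc2)CC1",        # 1-phenylpiperidine
    "[*:1]c1ccc2ncccc2c1",            # quinoline
    "[*:1]c1ccc(-c2ccncc2)cc1",       # phenylpyridine
    "[*:1]c1ccc2c(c1)OCO2",           # benzodioxole
)

#: neutral substituent pool ([*:1]-marked fragments)
NEUTRAL_SUBS: tuple[str, ...] = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]C(C)C",
    "[*:1]OC",
    "[*:1]Cl",
    "[*:1]F",
    "[*:1]C#N",
    "[*:1]CO",
    "[*:1]N(C)C",
)

DEFAULT_CLIFF_SUB = "[*:1]C(C)(C)C"  # tert-butyl


@dataclass(frozen=True)
class PlantedCliffSpec:
    """Parameters of the planted-cliff generator.

    ``delta_strong`` must exceed ``2 + 3 * sigma`` so that planted pairs
    clear the 2-log-unit cliff threshold with near-certainty.
    """

    n_series: int = 8
    series_size: int = 6
    cliff_sub: str = DEFAULT_CLIFF_SUB
    neutral_subs: tuple[str, ...] = NEUTRAL_SUBS
    delta_strong: float = 2.5
    sigma: float = 0.15
    base_potency: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not self.delta_strong > 2.0 + 3.0 * self.sigma:
            raise ValueError(
                f"delta_strong={self.delta_strong} must exceed 2 + 3*sigma="
                f"{2.0 + 3.0 * self.sigma:.3f} for reliable cliff labels"
            )
        if self.series_size - 1 > len(self.neutral_subs):
            raise ValueError("series_size exceeds the neutral substituent pool")
        for sub in (self.cliff_sub, *self.neutral_subs):
            if Chem.MolFromSmiles(sub) is None:
                raise ValueError(f"invalid substituent SMILES: {sub!r}")


def fig5_fixture() -> tuple[MMPFingerprint, MMPFingerprint]:
    """(support vector, test instance) over the abstract 3+3 feature universe.

    The test instance has core features {1, 3} and all three substituent
    features; the support vector has all three core features and
    substituent features {2, 3}.  Hence both Tanimoto factors are 2/3
    and the MMP kernel is 4/9, split over four cross-terms of 1/9 each.
    """
    support = abstract_fingerprint(core=[1, 2, 3], sub=[(XOR, 2), (XOR, 3)])
    test = abstract_fingerprint(core=[1, 3], sub=[(XOR, 1), (XOR, 2), (XOR, 3)])
    return support, test


def _attach(scaffold: str, substituent: str) -> str:
    combined = Chem.CombineMols(
        Chem.MolFromSmiles(scaffold), Chem.MolFromSmiles(substituent)
    )
    return Chem.MolToSmiles(Chem.molzip(combined))


def generate_cliff_dataset(spec: PlantedCliffSpec) -> list[Compound]:
    """Generate analog series with one planted cliff substituent per series.

    Deterministic under ``spec.seed``: the same spec yields a
    byte-identical compound table.
    """
    rng = np.random.default_rng(spec.seed)
    compounds: list[Compound] = []
    for s in range(spec.n_series):
        scaffold = SCAFFOLDS[s % len(SCAFFOLDS)]
        neutral = list(
            rng.choice(spec.neutral_subs, size=spec.series_size - 1, replace=False)
        )
        subs = [spec.cliff_sub] + neutral
        for j, sub in enumerate(subs):
            smiles = _attach(scaffold, sub)
            potency = (
                spec.base_potency
                + (spec.delta_strong if sub == spec.cliff_sub else 0.0)
                + float(rng.normal(0.0, spec.sigma))
            )
            compounds.append(
                Compound(cid=f"S{s:02d}C{j:02d}", smiles=smiles, potency=round(potency, 4))
            )
    return compounds
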