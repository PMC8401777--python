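"""Compound ingestion, potency handling and activity-cliff pair labeling.

A compound is a single connected structure with a pKi potency
(``-log10`` of the inhibition constant in molar units).  Candidate pairs
are labeled from the absolute potency difference ``delta_p``:

* ``AC``       — activity cliff, ``delta_p > 2`` log units,
* ``NON_AC``   — ``delta_p < 1`` log unit,
* ``AMBIGUOUS``— everything in between (discarded downstream).

The thresholds are strict inequalities, so deltas of exactly 1.0 or 2.0
fall in the ambiguous band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

AC_THRESHOLD = 2.0
NON_AC_THRESHOLD = 1.0

#: default column roles for :func:`read_compound_table`
DEFAULT_COLUMNS: Mapping[str, str] = {
    "cid": "cid",
    "smiles": "smiles",
    "potency": "pKi",
}


class PairLabel(Enum):
    """Class label of a compound pair by potency difference."""

    AC = "AC"
    NON_AC = "NON_AC"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class Compound:
    """A curated compound: identifier, canonical SMILES and pKi potency."""

    cid: str
    smiles: str
    potency: float

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - construction guarantees parseability
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return m


def label_pair(delta_p: float) -> PairLabel:
    """Label a pair from its absolute potency difference in log units.

    Parameters
    ----------
    delta_p : float
        Absolute pKi difference, must be non-negative and finite.
    """
    if not math.isfinite(delta_p) or delta_p < 0:
        raise ValueError(f"delta_p must be finite and >= 0, got {delta_p!r}")
    if delta_p > AC_THRESHOLD:
        return PairLabel.AC
    if delta_p < NON_AC_THRESHOLD:
        return PairLabel.NON_AC
    return PairLabel.AMBIGUOUS


def largest_organic_fragment(smiles: str) -> Chem.Mol | None:
    """Parse SMILES and keep the largest fragment (salt/solvent stripping).

    Ties are broken by preferring carbon-containing fragments, then by
    canonical SMILES order.  Returns ``None`` when nothing parses.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol

    def key(m: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
        return (m.GetNumHeavyAtoms(), has_c, Chem.MolToSmiles(m))

    return max(frags, key=key)


def _aggregate_replicates(
    rows: pd.DataFrame, max_range: float = 1.0
) -> tuple[float | None, str]:
    """Median-pKi curation rule for replicate measurements.

    Returns ``(median, "ok")`` or ``(None, reason)`` when the measurement
    range exceeds ``max_range`` log units and the compound is discarded.
    """
    values = rows.astype(float)
    if values.max() - values.min() > max_range:
        return None, f"potency range {values.max() - values.min():.2f} > {max_range}"
    return float(values.median()), "ok"


def read_compound_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    aggregate_replicates: bool = False,
    max_replicate_range: float = 1.0,
) -> list[Compound]:
    """Read a compound table from CSV.

    Parameters
    ----------
    path : path-like
        UTF-8 CSV file with a header row.
    columns : mapping, optional
        Role -> column-name mapping with roles ``cid``, ``smiles`` and
        ``potency``; defaults to :data:`DEFAULT_COLUMNS`.
    aggregate_replicates : bool
        When True, rows sharing an identifier are treated as replicate
        measurements: the median pKi is taken and the compound is dropped
        if the measurement range exceeds ``max_replicate_range`` log
        units.  When False (default) duplicate identifiers are an error.

    Returns
    -------
    list of :class:`Compound`
        Rows with unparseable SMILES or non-finite potency are logged and
        dropped.  SMILES are canonicalized after keeping the largest
        organic fragment.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty compound table: {path}") from exc
    if table.empty:
        raise InputError(f"compound table has no rows: {path}")

    missing = [c for c in cols.values() if c not in table.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing}; available: {list(table.columns)}"
        )

    cid_col, smi_col, pot_col = cols["cid"], cols["smiles"], cols["potency"]
    table[cid_col] = table[cid_col].astype(str)

    dup = table[cid_col][table[cid_col].duplicated()].unique()
    if len(dup) and not aggregate_replicates:
        raise InputError(f"duplicate compound identifier(s): {sorted(dup)}")

    compounds: list[Compound] = []
    for cid, rows in table.groupby(cid_col, sort=False):
        if aggregate_replicates and len(rows) > 1:
            potency, reason = _aggregate_replicates(
                rows[pot_col], max_range=max_replicate_range
            )
            if potency is None:
                logger.warning("dropping %s: %s", cid, reason)
                continue
        else:
            potency = rows[pot_col].iloc[0]
        try:
            potency = float(potency)
        except (TypeError, ValueError):
            potency = float("nan")
        if not math.isfinite(potency):
            logger.warning("dropping %s: non-finite potency %r", cid, potency)
            continue

        mol = largest_organic_fragment(str(rows[smi_col].iloc[0]))
        if mol is None:
            logger.warning(
                "dropping %s: unparseable SMILES %r", cid, rows[smi_col].iloc[0]
            )
            continue
        compounds.append(Compound(cid=str(cid), smiles=Chem.MolToSmiles(mol), potency=potency))

    return compounds


def compounds_to_frame(compounds: Sequence[Compound]) -> pd.DataFrame:
    """Serialize compounds to the canonical internal table."""
    return pd.DataFrame(
        {
            "cid": [c.cid for c in compounds],
            "smiles": [c.smiles for c in compounds],
            "pKi": [c.potency for c in compounds],
        }
    )
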