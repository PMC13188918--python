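"""Metabolic completion index (MCI) and per-sample metabolic capacity.

A MAG's MCI is its mean KEGG-module completeness, normalized by the
genome's estimated completion so that an incomplete assembly is
credited toward its full metabolic potential (values above 1 are
therefore possible).  Summing (or averaging) the MCI of the MAGs
present in a sample gives that sample's metabolic capacity.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import MagRecord, ModuleCompletenessMatrix


def mag_mci(module_completeness: np.ndarray | pd.Series, completion: float,
            nonzero_only: bool = False) -> float:
    """MCI for one MAG.

    Mean completeness over all catalog modules (zeros included by
    default; ``nonzero_only`` averages over detected modules instead),
    divided by the genome completion fraction.
    """
    if completion <= 0:
        raise ValueError("genome completion must be > 0")
    vals = np.asarray(module_completeness, dtype=float)
    if nonzero_only:
        vals = vals[vals > 0]
        mean = float(vals.mean()) if vals.size else 0.0
    else:
        mean = float(vals.mean()) if vals.size else 0.0
    return mean / (completion / 100.0)


def mci_table(modules: ModuleCompletenessMatrix, catalog: list[MagRecord],
              nonzero_only: bool = False) -> pd.Series:
    """Per-MAG MCI over the whole module completeness matrix."""
    completion = {m.mag_id: m.completion for m in catalog}
    missing = set(modules.values.index) - set(completion)
    if missing:
        raise ValueError(f"catalog lacks mag_id(s): {sorted(missing)[:5]}")
    out = {
        mag_id: mag_mci(row.to_numpy(), completion[mag_id], nonzero_only)
        for mag_id, row in modules.values.iterrows()
    }
    s = pd.Series(out, name="mci")
    s.index.name = "mag_id"
    return s


def sample_metabolic_capacity(
    mci: pd.Series,
    presence: pd.DataFrame,
    mag_subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Summed and mean MCI over the MAGs present in each sample.

    ``mag_subset`` restricts the computation (e.g. to gut-related
    MAGs); None means all MAGs with an MCI.  A sample with no present
    MAG gets summed capacity 0, mean 0 and ``empty`` = True.
    """
    if mag_subset is None:
        mags = [m for m in presence.index if m in mci.index]
    else:
        mags = [m for m in mag_subset if m in presence.index and m in mci.index]
    rows = {}
    for sample in presence.columns:
        present = [m for m in mags if presence.at[m, sample]]
        total = float(mci.loc[present].sum()) if present else 0.0
        rows[sample] = {
            "summed_capacity": total,
            "mean_capacity": total / len(present) if present else 0.0,
            "n_present": len(present),
            "empty": len(present) == 0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
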