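"""Provider identification and producer-to-dependent sufficiency estimation.

A "provider" is a producer whose culture supernatant contains detectable
corrinoid.  For each provider x dependent pair, the fold-sufficiency is the
provided corrinoid concentration divided by the dependent's EC50 for that
corrinoid (at equal culture volumes; a volume ratio generalizes this).  A
fold >= 1 means the provider's supernatant alone meets the dependent's
half-maximal requirement; published provider collections reach folds of
1 to 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .doseresponse import FourPLFit, PreferenceTable

__all__ = [
    "ProviderProfile",
    "SufficiencyResult",
    "sufficiency_ratio",
    "build_sufficiency_matrix",
]


@dataclass
class ProviderProfile:
    """A producer's extracellular release, as quantified by the bioassay."""

    isolate_id: str
    corrinoid: str
    extracellular_concentration: float  # molar in supernatant; NaN if n.d.
    percent_provided: float = math.nan

    @property
    def provider_flag(self) -> bool:
        return (math.isfinite(self.extracellular_concentration)
                and self.extracellular_concentration > 0)


@dataclass
class SufficiencyResult:
    matrix: pd.DataFrame           # providers x dependents, fold-sufficiency
    summary: pd.DataFrame          # per-provider min/median/max and support count
    definition: str                # metadata: the implemented ratio definition


def sufficiency_ratio(provided_conc: float, ec50: float,
                      volume_ratio: float = 1.0) -> float:
    """Fold-sufficiency of a provided concentration against a dependent EC50.

    ``volume_ratio`` scales provider culture volume relative to the
    dependent's (default 1: equal volumes).
    """
    if provided_conc <= 0 or ec50 <= 0:
        raise ValueError("provided concentration and ec50 must be positive")
    if volume_ratio <= 0:
        raise ValueError("volume_ratio must be positive")
    return volume_ratio * provided_conc / ec50


def build_sufficiency_matrix(
    providers: Iterable[ProviderProfile],
    dependents: Mapping[str, PreferenceTable] | Mapping[str, Dict[str, FourPLFit]],
    volume_ratio: float = 1.0,
) -> SufficiencyResult:
    """Cross every provider with every dependent on the released corrinoid.

    Each matrix entry is the fold-sufficiency computed on the corrinoid the
    provider releases (B12 for every provider in practice) against the
    dependent's fitted EC50 for that same corrinoid.  Entries are NaN when
    the provider released nothing detectable, the dependent has no
    successful fit for the corrinoid (NG/ND), or the pair shares no
    corrinoid.  The per-provider summary reports min/median/max fold and the
    count of dependents with fold >= 1 (supportable at half-maximal growth).
    """
    providers = list(providers)
    dep_fits: Dict[str, Dict[str, FourPLFit]] = {}
    for dep_id, table in dependents.items():
        if isinstance(table, PreferenceTable):
            dep_fits[dep_id] = table.fits
        else:
            dep_fits[dep_id] = dict(table)
    dep_ids = sorted(dep_fits)
    rows = {}
    for prov in providers:
        row = {}
        for dep_id in dep_ids:
            fit = dep_fits[dep_id].get(prov.corrinoid)
            if (not prov.provider_flag or fit is None or fit.status != "fit"):
                row[dep_id] = math.nan
            else:
                row[dep_id] = sufficiency_ratio(
                    prov.extracellular_concentration, fit.ec50, volume_ratio
                )
        rows[prov.isolate_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=dep_ids)
    matrix.index.name = "provider"

    summary_rows = []
    for prov in providers:
        vals = matrix.loc[prov.isolate_id].to_numpy(dtype=float)
        defined = vals[np.isfinite(vals)]
        summary_rows.append({
            "provider": prov.isolate_id,
            "corrinoid": prov.corrinoid,
            "extracellular_concentration": prov.extracellular_concentration,
            "n_dependents_evaluated": int(defined.size),
            "fold_min": float(defined.min()) if defined.size else math.nan,
            "fold_median": float(np.median(defined)) if defined.size else math.nan,
            "fold_max": float(defined.max()) if defined.size else math.nan,
            "n_supportable": int((defined >= 1.0).sum()),
        })
    summary = pd.DataFrame(summary_rows)
    definition = (
        "fold = volume_ratio * provided_concentration / dependent_EC50; "
        f"volume_ratio = {volume_ratio}; fold >= 1 means the provider "
        "supernatant meets the dependent's half-maximal requirement"
    )
    return SufficiencyResult(matrix=matrix, summary=summary, definition=definition)
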