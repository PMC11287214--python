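"""Genus-level prediction of corrinoid metabolism from species classifications.

Species-level genomic predictions (producer likelihood plus the count of
corrinoid-dependent functions encoded) are collapsed to the three corrinoid
metabolism categories and aggregated by genus.  A genus receives a genomic
call only when it has at least 20 classified species and at least 95% of
them fall in one category — both boundaries inclusive, compared with exact
integer arithmetic so the 95% cutoff has no floating-point edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "PRODUCER_CLASSES",
    "NONPRODUCER_CLASSES",
    "CATEGORIES",
    "SpeciesPrediction",
    "GenusCall",
    "classify_species",
    "classify_species_table",
    "classify_genus",
    "summarize_conservation",
    "compare_calls",
    "DEFAULT_MIN_SPECIES",
    "DEFAULT_CONCORDANCE",
]

logger = logging.getLogger(__name__)

PRODUCER_CLASSES = frozenset(
    {"very_likely_producer", "likely_producer", "possible_producer"}
)
NONPRODUCER_CLASSES = frozenset(
    {"likely_nonproducer", "very_likely_nonproducer"}
)
CATEGORIES = ("producer_G", "dependent_G", "independent_G")

DEFAULT_MIN_SPECIES = 20
DEFAULT_CONCORDANCE = Fraction(19, 20)  # 95%, exact


@dataclass
class SpeciesPrediction:
    """One species' genomically predicted corrinoid-metabolism attributes."""

    species_id: str
    genus: str
    producer_class: str
    n_dependent_functions: int
    phylum: str = ""


@dataclass
class GenusCall:
    """Genus-level trait-conservation call."""

    genus: str
    n_species: int
    fraction_producer: float
    fraction_dependent: float
    fraction_independent: float
    call: str  # producer_G | dependent_G | independent_G | unclassified | below_cutoff
    phylum: str = ""


def classify_species(producer_class: str, n_dependent_functions: int) -> str:
    """Map one species' predicted attributes to a corrinoid metabolism category.

    Any predicted producer likelihood (very likely, likely or possible) makes
    the species a producer; predicted non-producers are dependents when they
    encode at least one corrinoid-dependent function (regardless of
    corrinoid-independent alternative enzymes) and independents when they
    encode none.
    """
    if n_dependent_functions < 0:
        raise ValueError("n_dependent_functions must be >= 0")
    if producer_class in PRODUCER_CLASSES:
        return "producer_G"
    if producer_class in NONPRODUCER_CLASSES:
        return "dependent_G" if n_dependent_functions >= 1 else "independent_G"
    raise ValueError(f"unknown producer-likelihood label: {producer_class!r}")


def classify_species_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify a species TSV table; rows with unknown labels are dropped.

    Expects columns ``species_id, genus, producer_class,
    n_dependent_functions`` (``phylum`` optional); returns the table with a
    ``category`` column.  Rejected rows are logged with their reason.
    """
    out = table.copy()
    categories = []
    keep = []
    for idx, row in out.iterrows():
        try:
            categories.append(
                classify_species(row["producer_class"],
                                 int(row["n_dependent_functions"]))
            )
            keep.append(idx)
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting species %s: %s", row.get("species_id", idx), exc)
    out = out.loc[keep].copy()
    out["category"] = categories
    return out


def _as_fraction(concordance: Union[float, Fraction]) -> Fraction:
    if isinstance(concordance, Fraction):
        return concordance
    # route through the decimal string so 0.95 means exactly 19/20
    return Fraction(str(concordance))


def classify_genus(
    categories: Sequence[str],
    genus: str = "",
    min_n: int = DEFAULT_MIN_SPECIES,
    concordance: Union[float, Fraction] = DEFAULT_CONCORDANCE,
    phylum: str = "",
) -> GenusCall:
    """Call one genus from its species' categories.

    ``below_cutoff`` when fewer than ``min_n`` species; otherwise the
    category whose species fraction reaches ``concordance`` (inclusive,
    integer arithmetic: count * den >= num * total), or ``unclassified``
    when none does.
    """
    cats = list(categories)
    n = len(cats)
    if n == 0:
        raise ValueError(f"genus {genus!r} has no species records")
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = {c: cats.count(c) for c in CATEGORIES}
    fracs = {c: counts[c] / n for c in CATEGORIES}
    conc = _as_fraction(concordance)
    if n < min_n:
        call = "below_cutoff"
    else:
        call = "unclassified"
        for c in CATEGORIES:
            if counts[c] * conc.denominator >= conc.numerator * n:
                call = c
                break
    return GenusCall(
        genus=genus, n_species=n,
        fraction_producer=fracs["producer_G"],
        fraction_dependent=fracs["dependent_G"],
        fraction_independent=fracs["independent_G"],
        call=call, phylum=phylum,
    )


def classify_genera(
    species_table: pd.DataFrame,
    min_n: int = DEFAULT_MIN_SPECIES,
    concordance: Union[float, Fraction] = DEFAULT_CONCORDANCE,
) -> list:
    """Classify every genus in a categorized species table."""
    if "category" not in species_table.columns:
        species_table = classify_species_table(species_table)
    calls = []
    for genus, grp in species_table.groupby("genus", sort=True):
        phylum = str(grp["phylum"].iloc[0]) if "phylum" in grp.columns else ""
        calls.append(classify_genus(list(grp["category"]), genus=str(genus),
                                    min_n=min_n, concordance=concordance,
                                    phylum=phylum))
    return calls


@dataclass
class ConservationSummary:
    n_eligible: int          # genera meeting the species-count cutoff
    n_classified: int        # of those, genera with a concordant category
    n_unclassified: int
    per_category: Dict[str, int] = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def summarize_conservation(calls: Iterable[GenusCall]) -> ConservationSummary:
    """Tally genus calls and build the long-format tree-annotation table.

    The table has one row per genus (genus, phylum, n_species, the three
    category percentages, call) and is suitable as a trait annotation table
    next to a user-supplied newick tree.
    """
    calls = list(calls)
    eligible = [c for c in calls if c.call != "below_cutoff"]
    classified = [c for c in eligible if c.call in CATEGORIES]
    per_cat = {c: 0 for c in CATEGORIES}
    for g in classified:
        per_cat[g.call] += 1
    rows = [
        {
            "genus": c.genus,
            "phylum": c.phylum,
            "n_species": c.n_species,
            "pct_producer": 100.0 * c.fraction_producer,
            "pct_dependent": 100.0 * c.fraction_dependent,
            "pct_independent": 100.0 * c.fraction_independent,
            "call": c.call,
        }
        for c in calls
    ]
    return ConservationSummary(
        n_eligible=len(eligible),
        n_classified=len(classified),
        n_unclassified=len(eligible) - len(classified),
        per_category=per_cat,
        table=pd.DataFrame(rows),
    )


_EXPERIMENTAL_TO_GENOMIC = {
    "producer_E": "producer_G",
    "dependent_E": "dependent_G",
    "independent_E": "independent_G",
}


def compare_calls(
    genus_calls: Iterable[GenusCall],
    isolate_calls: Mapping[str, tuple] | pd.DataFrame,
) -> pd.DataFrame:
    """Compare genomic genus calls with experimental isolate categories.

    ``isolate_calls`` maps isolate_id -> (genus, experimental category) or is
    a DataFrame with columns ``isolate_id, genus, category``.  Each isolate is
    scored ``match`` / ``mismatch`` against its genus's genomic call;
    isolates whose genus is unclassified, below cutoff or absent are
    ``uncomparable``.
    """
    by_genus = {c.genus: c for c in genus_calls}
    if isinstance(isolate_calls, pd.DataFrame):
        items = [(str(r.isolate_id), str(r.genus), str(r.category))
                 for r in isolate_calls.itertuples()]
    else:
        items = [(i, g, cat) for i, (g, cat) in isolate_calls.items()]
    rows = []
    for isolate_id, genus, category in items:
        gcall = by_genus.get(genus)
        expected = _EXPERIMENTAL_TO_GENOMIC.get(category)
        if gcall is None or gcall.call not in CATEGORIES or expected is None:
            outcome = "uncomparable"
            genomic = gcall.call if gcall is not None else "absent"
        else:
            genomic = gcall.call
            outcome = "match" if genomic == expected else "mismatch"
        rows.append({
            "isolate_id": isolate_id, "genus": genus,
            "experimental": category, "genomic": genomic, "outcome": outcome,
        })
    return pd.DataFrame(rows)
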