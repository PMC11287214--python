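"""Seeded generators for every input the classification pipeline consumes.

The generators emulate the study conditions of a limiting-dilution soil
isolation and its downstream phenotyping: Poisson founder deposition in
microplate wells, four serial passages with ~3 ul -> 200 ul transfers (so
carried-over corrinoid decays ~67-fold per passage), 4PL-governed
dose-response and bioassay plates, and a species-level genomic prediction
table with genera of controlled size and category concordance.  Every
generator is deterministic under a fixed seed and emits ground-truth sidecar
tables so downstream stages can be scored against labeled truth.

Default study conditions: 10 nM corrinoid in isolation/passage media, four
passages at carryover fold 200/3, three passage replicates, a 12-point
4-fold dose-response series from 10 nM (two replicates), and additive
Gaussian OD noise (sd 0.02) truncated at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dilution import serial_dilution_series
from .doseresponse import CORRINOID_CODES

__all__ = [
    "IsolationDesign",
    "FourPLTruth",
    "IsolateSpec",
    "CommunitySpec",
    "StandardCurveTruth",
    "simulate_wells",
    "make_community",
    "default_genus_specs",
    "simulate_passages",
    "simulate_dose_response",
    "simulate_bioassay",
    "simulate_species_table",
    "DEFAULT_NOISE_SD",
    "DEFAULT_CARRYOVER_FOLD",
    "DEFAULT_MEDIA_CONC",
]

DEFAULT_NOISE_SD = 0.02
#: per-passage dilution of carried-over corrinoid: ~3 ul into 200 ul
DEFAULT_CARRYOVER_FOLD = 200.0 / 3.0
#: corrinoid concentration in isolation and passage media, molar
DEFAULT_MEDIA_CONC = 10e-9
NOC = "NOC"


def _noisy(rng: np.random.Generator, mean, sd: float):
    """Additive Gaussian OD noise, truncated at 0 and capped at OD 2."""
    mean = np.asarray(mean, dtype=float)
    return np.clip(mean + rng.normal(0.0, sd, size=mean.shape), 0.0, 2.0)


# ---------------------------------------------------------------------------
# limiting-dilution wells


@dataclass
class IsolationDesign:
    """One limiting-dilution plating condition."""

    n_wells: int
    lambda_: float
    corrinoid: str = "B12"  # media corrinoid code, or NOC
    media_conc: float = DEFAULT_MEDIA_CONC

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.n_wells < 0:
            raise ValueError("n_wells must be >= 0")


def simulate_wells(design: IsolationDesign, seed: int) -> pd.DataFrame:
    """Poisson founder deposition: one row per well with ground truth.

    Columns: well, founders, positive (founders >= 1), clonal (founders == 1).
    """
    rng = np.random.default_rng(seed)
    founders = rng.poisson(design.lambda_, size=design.n_wells)
    return pd.DataFrame({
        "well": np.arange(design.n_wells),
        "condition": design.corrinoid,
        "founders": founders,
        "positive": founders >= 1,
        "clonal": founders == 1,
    })


# ---------------------------------------------------------------------------
# community ground truth


@dataclass
class FourPLTruth:
    bottom: float
    top: float
    hill: float
    ec50: float

    def predict(self, x: float) -> float:
        if x <= 0:
            return self.bottom
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / x) ** self.hill)


@dataclass
class IsolateSpec:
    """Ground truth for one synthetic isolate."""

    isolate_id: str
    category: str  # producer | dependent | independent
    genus: str
    isolation_corrinoid: str  # corrinoid code, or NOC
    top: float                # plateau OD when growing
    baseline: float           # OD with no growth
    dose_response: Dict[str, Optional[FourPLTruth]] = field(default_factory=dict)
    production_total: float = 0.0    # molar-equivalent in the bioassay
    provided_fraction: float = 0.0   # of total production released
    noise_sd: float = DEFAULT_NOISE_SD


@dataclass
class CommunitySpec:
    isolates: List[IsolateSpec]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "isolate_id": s.isolate_id,
                "category": s.category,
                "genus": s.genus,
                "isolation_corrinoid": s.isolation_corrinoid,
                "top": s.top,
                "baseline": s.baseline,
                "production_total": s.production_total,
                "provided_fraction": s.provided_fraction,
                "b12_ec50": (s.dose_response.get("B12").ec50
                             if s.dose_response.get("B12") else math.nan),
            }
            for s in self.isolates
        ])

    def by_id(self) -> Dict[str, IsolateSpec]:
        return {s.isolate_id: s for s in self.isolates}


_GENUS_POOL = {
    "producer": ("Prodomonas", "Prodobacter"),
    "dependent": ("Dependimonas", "Dependibacter"),
    "independent": ("Indepimonas", "Indepibacter"),
}


def make_community(
    n_producers: int = 20,
    n_dependents: int = 20,
    n_independents: int = 20,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    provider_fraction: float = 7.0 / 11.0,
) -> CommunitySpec:
    """Draw ground truth for a synthetic isolate community.

    Dependents receive a B12 4PL truth with log10 EC50 uniform on
    [-13, -10.5] (picomolar-scale preferences) and higher, sometimes absent
    (NG), EC50s on the other corrinoids.  Producers receive a total corrinoid
    production spanning ~10-80x the bioassay standard-curve EC50, and a
    provided (extracellular) fraction between 1.3% and 21% for the provider
    subset.  Non-dependents cycle through the six corrinoid media plus NOC
    for their isolation condition, guaranteeing NOC control isolates for the
    dependence threshold.
    """
    rng = np.random.default_rng(seed)
    isolates: List[IsolateSpec] = []
    # NOC first so even small communities include the control isolates the
    # dependence threshold is derived from
    non_dep_conditions = [NOC] + list(CORRINOID_CODES)

    def base(category: str, i: int) -> tuple:
        genus_pool = _GENUS_POOL[category]
        return (
            f"{category[:4].upper()}_{i:03d}",
            genus_pool[i % len(genus_pool)],
            float(rng.uniform(0.5, 1.0)),     # plateau OD
            float(rng.uniform(0.03, 0.08)),   # baseline OD
        )

    for i in range(n_producers):
        iid, genus, top, baseline = base("producer", i)
        provider = rng.random() < provider_fraction
        isolates.append(IsolateSpec(
            isolate_id=iid, category="producer", genus=genus,
            isolation_corrinoid=non_dep_conditions[i % len(non_dep_conditions)],
            top=top, baseline=baseline,
            production_total=float(10.0 ** rng.uniform(-10.0, -9.1)),
            provided_fraction=float(rng.uniform(0.013, 0.21)) if provider else 0.0,
            noise_sd=noise_sd,
        ))

    for i in range(n_dependents):
        iid, genus, top, baseline = base("dependent", i)
        dr: Dict[str, Optional[FourPLTruth]] = {}
        b12_ec50 = float(10.0 ** rng.uniform(-13.0, -10.5))
        for code in CORRINOID_CODES:
            if code == "B12":
                dr[code] = FourPLTruth(baseline, top, float(rng.uniform(0.8, 2.0)),
                                       b12_ec50)
            elif code in ("ADE", "CRE", "CBI") and rng.random() < 0.4:
                dr[code] = None  # cannot use this corrinoid: NG
            else:
                dr[code] = FourPLTruth(baseline, top, float(rng.uniform(0.8, 2.0)),
                                       b12_ec50 * float(10.0 ** rng.uniform(0.0, 2.0)))
        usable = [c for c, t in dr.items() if t is not None]
        isolates.append(IsolateSpec(
            isolate_id=iid, category="dependent", genus=genus,
            isolation_corrinoid=usable[int(rng.integers(len(usable)))],
            top=top, baseline=baseline, dose_response=dr, noise_sd=noise_sd,
        ))

    for i in range(n_independents):
        iid, genus, top, baseline = base("independent", i)
        isolates.append(IsolateSpec(
            isolate_id=iid, category="independent", genus=genus,
            isolation_corrinoid=non_dep_conditions[i % len(non_dep_conditions)],
            top=top, baseline=baseline, noise_sd=noise_sd,
        ))
    return CommunitySpec(isolates=isolates)


# ---------------------------------------------------------------------------
# serial passages


def simulate_passages(
    community: CommunitySpec,
    seed: int,
    n_passages: int = 4,
    n_replicates: int = 3,
    carryover_fold: float = DEFAULT_CARRYOVER_FOLD,
    media_conc: float = DEFAULT_MEDIA_CONC,
) -> pd.DataFrame:
    """Paired with-corrinoid / NOC end-point ODs across serial passages.

    The with-corrinoid arm grows to the isolate's plateau every passage.  In
    the NOC arm, the corrinoid available to a dependent after passage k is
    ``media_conc / carryover_fold**k`` and its plateau is its true 4PL for
    the isolation corrinoid evaluated there; producers and independents keep
    their plateau.  Isolates whose isolation condition was NOC (the
    dependence-threshold controls) get B12 in their with-corrinoid arm.
    Returns long format: isolate_id, replicate, passage, arm ("corrinoid" or
    "NOC"), condition (the arm's corrinoid code, or NOC), isolation_condition,
    od600.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in community.isolates:
        with_code = spec.isolation_corrinoid if spec.isolation_corrinoid != NOC else "B12"
        truth = spec.dose_response.get(with_code)
        for rep in range(1, n_replicates + 1):
            for passage in range(1, n_passages + 1):
                if spec.category == "dependent":
                    if truth is None:
                        raise ValueError(
                            f"{spec.isolate_id}: dependent lacks 4PL truth for "
                            f"its isolation corrinoid"
                        )
                    carried = media_conc / carryover_fold ** passage
                    noc_plateau = truth.predict(carried)
                else:
                    noc_plateau = spec.top
                od_with = float(_noisy(rng, spec.top, spec.noise_sd))
                od_noc = float(_noisy(rng, noc_plateau, spec.noise_sd))
                rows.append((spec.isolate_id, rep, passage, "corrinoid",
                             with_code, spec.isolation_corrinoid, od_with))
                rows.append((spec.isolate_id, rep, passage, NOC, NOC,
                             spec.isolation_corrinoid, od_noc))
    return pd.DataFrame(rows, columns=[
        "isolate_id", "replicate", "passage", "arm", "condition",
        "isolation_condition", "od600",
    ])


# ---------------------------------------------------------------------------
# dose-response plates


def simulate_dose_response(
    community: CommunitySpec,
    seed: int,
    isolate_ids: Optional[Sequence[str]] = None,
    top_conc: float = DEFAULT_MEDIA_CONC,
    n_points: int = 12,
    fold: float = 4.0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Final ODs over a 12-point 4-fold concentration series per corrinoid.

    Only isolates with a dose-response ground truth (dependents) produce
    signal; corrinoids they cannot use yield baseline readings at every
    concentration.  Long format: isolate_id, corrinoid, concentration_molar,
    replicate, od600.
    """
    rng = np.random.default_rng(seed)
    series = serial_dilution_series(top_conc, n_points, fold)
    specs = community.isolates
    if isolate_ids is not None:
        wanted = set(isolate_ids)
        specs = [s for s in specs if s.isolate_id in wanted]
    rows = []
    for spec in specs:
        for code in CORRINOID_CODES:
            truth = spec.dose_response.get(code)
            for conc in series.concentrations:
                if truth is None:
                    mean = spec.baseline
                else:
                    mean = truth.predict(float(conc))
                for rep in range(1, n_replicates + 1):
                    od = float(_noisy(rng, mean, spec.noise_sd))
                    rows.append((spec.isolate_id, code, float(conc), rep, od))
    return pd.DataFrame(rows, columns=[
        "isolate_id", "corrinoid", "concentration_molar", "replicate", "od600",
    ])


# ---------------------------------------------------------------------------
# bioassay


@dataclass
class StandardCurveTruth:
    """True 4PL of the ΔmetE indicator response to corrinoid concentration."""

    bottom: float = 0.03
    top: float = 0.8
    hill: float = 1.0
    ec50: float = 1e-10
    basal_double: float = 0.03  # ΔmetEΔmetH growth on sample methionine
    wt_plateau: float = 0.85

    def response(self, conc: float) -> float:
        if conc <= 0:
            return self.bottom
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / conc) ** self.hill)


def simulate_bioassay(
    community: CommunitySpec,
    seed: int,
    truth: Optional[StandardCurveTruth] = None,
    n_replicates: int = 3,
    standard_top: float = 1e-8,
    standard_points: int = 12,
    standard_fold: float = 4.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the three-strain bioassay for every isolate's NOC lysate.

    Returns ``(readings, standard_curve, fraction_samples)``:

    - readings: sample_id (isolate), strain in {dmetE, dmetE_dmetH, wt},
      replicate, od600 — the lysate of a producer carries its true total
      production, all other isolates carry none;
    - standard_curve: concentration_molar, replicate, od600 over a geometric
      standard series;
    - fraction_samples: producers' supernatant/pellet samples, the total
      production split by the true provided fraction.
    """
    rng = np.random.default_rng(seed)
    truth = truth or StandardCurveTruth()

    reading_rows = []
    for spec in community.isolates:
        conc = spec.production_total if spec.category == "producer" else 0.0
        for rep in range(1, n_replicates + 1):
            od_ind = float(_noisy(rng, truth.response(conc), spec.noise_sd))
            od_dbl = float(_noisy(rng, truth.basal_double, spec.noise_sd))
            od_wt = float(_noisy(rng, truth.wt_plateau, spec.noise_sd))
            reading_rows += [
                (spec.isolate_id, "dmetE", rep, od_ind),
                (spec.isolate_id, "dmetE_dmetH", rep, od_dbl),
                (spec.isolate_id, "wt", rep, od_wt),
            ]
    readings = pd.DataFrame(reading_rows, columns=[
        "sample_id", "strain", "replicate", "od600",
    ])

    series = serial_dilution_series(standard_top, standard_points, standard_fold)
    std_rows = []
    for conc in series.concentrations:
        for rep in (1, 2):
            od = float(_noisy(rng, truth.response(float(conc)), DEFAULT_NOISE_SD))
            std_rows.append((float(conc), rep, od))
    standard = pd.DataFrame(std_rows, columns=[
        "concentration_molar", "replicate", "od600",
    ])

    frac_rows = []
    for spec in community.isolates:
        if spec.category != "producer":
            continue
        extra = spec.production_total * spec.provided_fraction
        intra = spec.production_total * (1.0 - spec.provided_fraction)
        for name, conc in (("supernatant", extra), ("pellet", intra)):
            for rep in range(1, n_replicates + 1):
                od = float(_noisy(rng, truth.response(conc), spec.noise_sd))
                frac_rows.append((spec.isolate_id, name, rep, od))
    fractions = pd.DataFrame(frac_rows, columns=[
        "isolate_id", "fraction", "replicate", "od600",
    ])
    return readings, standard, fractions


# ---------------------------------------------------------------------------
# species prediction table


_PRODUCER_LABELS = ("very_likely_producer", "likely_producer", "possible_producer")
_NONPRODUCER_LABELS = ("likely_nonproducer", "very_likely_nonproducer")
_CATEGORY_ORDER = ("producer_G", "dependent_G", "independent_G")


def _attrs_for_category(category: str, rng: np.random.Generator) -> tuple:
    if category == "producer_G":
        return (_PRODUCER_LABELS[int(rng.integers(3))], int(rng.poisson(2.0)))
    if category == "dependent_G":
        return (_NONPRODUCER_LABELS[int(rng.integers(2))], 1 + int(rng.poisson(1.0)))
    if category == "independent_G":
        return (_NONPRODUCER_LABELS[int(rng.integers(2))], 0)
    raise ValueError(f"unknown category {category!r}")


def simulate_species_table(
    genus_specs: Sequence[tuple],
    seed: int,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Species prediction table with controlled genus sizes and category mixes.

    ``genus_specs`` holds ``(genus, n_species, mix)`` tuples where ``mix``
    maps categories to probabilities summing to 1.  With
    ``deterministic=True`` the category counts are exact largest-remainder
    roundings of ``n * p`` (for boundary fixtures such as exactly 19/20
    concordant); otherwise they are one multinomial draw.  Attributes are
    drawn so that species-level classification maps each record back to its
    intended category exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genus, n_species, mix in genus_specs:
        probs = {c: float(mix.get(c, 0.0)) for c in _CATEGORY_ORDER}
        total_p = sum(probs.values())
        if not math.isclose(total_p, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"{genus}: category mix must sum to 1, got {total_p}")
        if deterministic:
            raw = {c: n_species * probs[c] for c in _CATEGORY_ORDER}
            counts = {c: int(math.floor(raw[c])) for c in _CATEGORY_ORDER}
            short = n_species - sum(counts.values())
            for c in sorted(_CATEGORY_ORDER, key=lambda c: raw[c] - counts[c],
                            reverse=True)[:short]:
                counts[c] += 1
        else:
            draw = rng.multinomial(n_species, [probs[c] for c in _CATEGORY_ORDER])
            counts = dict(zip(_CATEGORY_ORDER, (int(d) for d in draw)))
        k = 0
        for category in _CATEGORY_ORDER:
            for _ in range(counts[category]):
                label, n_dep = _attrs_for_category(category, rng)
                rows.append({
                    "species_id": f"{genus}_sp{k:04d}",
                    "genus": genus,
                    "phylum": "SimulataPhylum",
                    "producer_class": label,
                    "n_dependent_functions": n_dep,
                })
                k += 1
    return pd.DataFrame(rows)


def default_genus_specs(n_extra_unclassified: int = 4) -> list:
    """Genus layout pairing the synthetic community's genera with concordant
    category mixes, plus discordant and below-cutoff genera for contrast."""
    specs = []
    for category, genera in (("producer_G", _GENUS_POOL["producer"]),
                             ("dependent_G", _GENUS_POOL["dependent"]),
                             ("independent_G", _GENUS_POOL["independent"])):
        others = [c for c in _CATEGORY_ORDER if c != category]
        for genus in genera:
            mix = {category: 0.96, others[0]: 0.02, others[1]: 0.02}
            specs.append((genus, 25, mix))
    for i in range(n_extra_unclassified):
        specs.append((f"Mixtomonas{i}", 24,
                      {"producer_G": 0.5, "dependent_G": 0.3, "independent_G": 0.2}))
    specs.append(("Paucimonas", 12, {"producer_G": 1.0}))
    return specs
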