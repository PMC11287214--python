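"""Pipeline orchestration: QC filters, stage wiring, configuration, and I/O.

Decision order mirrors the experimental workflow: sequence-identity QC,
serial-passage dependence testing (2-of-3 replicate vote against a
control-derived threshold), dose-response confirmation and preference
ranking for voted dependents, and the E. coli bioassay — applied only to
isolates that grow without corrinoid — to split producers from independents.
Producers' supernatant/pellet fractions are quantified against the bioassay
standard curve, identified providers are crossed with dependent EC50s in the
sufficiency analysis, and experimental categories are compared with
genus-level genomic predictions.  Stage failures mark the affected isolates
inconclusive (with machine-readable reasons) rather than aborting the batch,
and identical config + seed yields identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import bioassay as ba
from . import doseresponse as dr
from . import growth
from . import sharing
from . import simulate as sim
from . import taxonomy as tax

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "qc_contaminant_filter",
    "qc_novelty_flag",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds, sizes, seeds and paths for one reproducible run.

    Threshold defaults are the printed experimental values: growth floor OD
    0.1, bioassay metric 2.0 and indicator OD 0.1, genus cutoffs 20 species
    and 95% concordance, contaminant identity >99% (strict), novelty
    identity <98.6% (strict).
    """

    seed: int = 0
    outdir: Optional[str] = None

    # thresholds
    tau_default: float = 0.5          # fallback dependence threshold (log2 units)
    growth_floor: float = 0.1
    blank_floor: float = 0.01
    bioassay_metric_threshold: float = 2.0
    bioassay_od_threshold: float = 0.1
    wt_floor: float = 0.1
    repression_fraction: float = 0.5
    genus_min_n: int = 20
    genus_concordance: float = 0.95
    contaminant_identity: float = 99.0
    novelty_identity: float = 98.6

    # study conditions
    n_passages: int = 4
    n_replicates: int = 3
    carryover_fold: float = sim.DEFAULT_CARRYOVER_FOLD
    media_conc: float = sim.DEFAULT_MEDIA_CONC
    noise_sd: float = sim.DEFAULT_NOISE_SD

    # synthetic community sizes
    n_producers: int = 20
    n_dependents: int = 20
    n_independents: int = 20

    # slow-grower handling: isolates in the slowest saturation-ladder group
    # (or with no assignable group) are not phenotyped
    exclude_slowest_group: bool = True

    # optional input paths (synthetic mode generates these instead)
    growth_curves_csv: Optional[str] = None
    passages_csv: Optional[str] = None
    doseresponse_csv: Optional[str] = None
    bioassay_csv: Optional[str] = None
    standard_curve_csv: Optional[str] = None
    fractions_csv: Optional[str] = None
    species_tsv: Optional[str] = None
    identities_csv: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def qc_contaminant_filter(identities: pd.DataFrame,
                          threshold: float = 99.0) -> pd.DataFrame:
    """Drop isolates matching an uninoculated-well sequence too closely.

    Expects columns ``isolate_id, identity_to_control`` (percent).  An
    isolate is dropped when identity is strictly greater than the threshold;
    missing identities keep the isolate with a warning.
    """
    out = identities.copy()
    ident = pd.to_numeric(out["identity_to_control"], errors="coerce")
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("identities must be in [0, 100]")
    out["keep"] = ~(ident > threshold)
    for iid in out.loc[ident.isna(), "isolate_id"]:
        logger.warning("isolate %s has no control identity; keeping", iid)
    for _, row in out[~out["keep"]].iterrows():
        logger.info("dropping %s: %.2f%% identity to uninoculated-well sequence",
                    row["isolate_id"], row["identity_to_control"])
    return out


def qc_novelty_flag(identities: pd.DataFrame,
                    threshold: float = 98.6) -> pd.DataFrame:
    """Flag putative novel species from reference-database identity.

    Expects ``isolate_id, identity_to_reference`` (percent); novel when
    identity is strictly below the threshold.  Missing identities are not
    novel, flagged as missing.
    """
    out = identities.copy()
    ident = pd.to_numeric(out["identity_to_reference"], errors="coerce")
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("identities must be in [0, 100]")
    out["novel"] = ident < threshold
    out["identity_missing"] = ident.isna()
    out.loc[out["identity_missing"], "novel"] = False
    return out


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    tau: float
    truth: Optional[pd.DataFrame] = None
    replicate_calls: pd.DataFrame = field(default_factory=pd.DataFrame)
    fits: Dict[str, dr.PreferenceTable] = field(default_factory=dict)
    preferences: pd.DataFrame = field(default_factory=pd.DataFrame)
    quantified: pd.DataFrame = field(default_factory=pd.DataFrame)
    providers: List[sharing.ProviderProfile] = field(default_factory=list)
    sufficiency: Optional[sharing.SufficiencyResult] = None
    genus_calls: List[tax.GenusCall] = field(default_factory=list)
    conservation: Optional[tax.ConservationSummary] = None
    comparison: pd.DataFrame = field(default_factory=pd.DataFrame)

    def accuracy(self) -> float:
        """Fraction of ground-truth categories recovered (synthetic mode)."""
        if self.truth is None:
            raise ValueError("accuracy requires a synthetic ground truth")
        merged = self.calls.merge(self.truth[["isolate_id", "category"]],
                                  on="isolate_id", suffixes=("_called", "_true"))
        mapped = merged["category_called"].map({
            "producer_E": "producer",
            "dependent_E": "dependent",
            "independent_E": "independent",
        })
        return float((mapped == merged["category_true"]).mean())


def _series_from_table(passages: pd.DataFrame) -> Dict[tuple, growth.PassageSeries]:
    out = {}
    for (iid, rep), grp in passages.groupby(["isolate_id", "replicate"], sort=True):
        grp = grp.sort_values("passage")
        w = grp[grp["arm"] == "corrinoid"]["od600"].to_numpy()
        n = grp[grp["arm"] == "NOC"]["od600"].to_numpy()
        out[(str(iid), int(rep))] = growth.PassageSeries(str(iid), int(rep), w, n)
    return out


def run_pipeline(config: PipelineConfig, synthetic: bool = True) -> PipelineResult:
    """Execute the full classification pipeline under one config + seed.

    In synthetic mode the generators produce every stage input from the
    configured community sizes and noise; otherwise the configured CSV/TSV
    paths are read.  Returns a :class:`PipelineResult`; when ``outdir`` is
    set, stage outputs are also written as TSV.
    """
    # stage seeds derived deterministically from the run seed
    ss = np.random.SeedSequence(config.seed)
    stage_seed = [int(s) % (2 ** 31) for s in ss.generate_state(5)]

    community = None
    truth = None
    if synthetic:
        community = sim.make_community(
            n_producers=config.n_producers,
            n_dependents=config.n_dependents,
            n_independents=config.n_independents,
            seed=stage_seed[0], noise_sd=config.noise_sd,
        )
        truth = community.truth_table()
        passages = sim.simulate_passages(
            community, seed=stage_seed[1], n_passages=config.n_passages,
            n_replicates=config.n_replicates,
            carryover_fold=config.carryover_fold, media_conc=config.media_conc,
        )
    else:
        if config.passages_csv is None:
            raise ValueError("passages_csv required when synthetic=False")
        passages = pd.read_csv(config.passages_csv)

    if passages.empty:
        logger.warning("no passage data: producing empty outputs")
        return PipelineResult(calls=pd.DataFrame(
            columns=["isolate_id", "category", "reason"]), tau=config.tau_default,
            truth=truth)

    # optional sequence QC
    if config.identities_csv is not None:
        identities = pd.read_csv(config.identities_csv)
        flags = qc_contaminant_filter(identities, config.contaminant_identity)
        dropped = set(flags.loc[~flags["keep"], "isolate_id"].astype(str))
        passages = passages[~passages["isolate_id"].astype(str).isin(dropped)]

    # slow/inconsistent growers (slowest saturation group or unassignable)
    # are excluded from phenotyping and reported as untested
    excluded: Dict[str, str] = {}
    if config.growth_curves_csv is not None and config.exclude_slowest_group:
        curves = pd.read_csv(config.growth_curves_csv)
        ladder_max = max(growth.SATURATION_LADDER_H)
        for iid, grp in curves.groupby("isolate_id", sort=True):
            mean_od = grp.groupby("time_h")["od600"].mean()
            curve = growth.GrowthCurve(str(iid), "",
                                       mean_od.index.to_numpy(dtype=float),
                                       mean_od.to_numpy(dtype=float))
            g = growth.time_to_saturation_group(curve)
            if g.group is None or g.group == ladder_max:
                excluded[str(iid)] = "slow-or-inconsistent-growth"
                logger.info("excluding %s from phenotyping (saturation group %s)",
                            iid, g.group)
        passages = passages[~passages["isolate_id"].astype(str).isin(excluded)]

    series = _series_from_table(passages)

    # dependence threshold from NOC-isolation controls
    noc_ids = set(
        passages.loc[passages["isolation_condition"] == sim.NOC, "isolate_id"]
        .astype(str)
    )
    control_E = []
    for (iid, rep), s in series.items():
        if iid in noc_ids:
            call, e = growth.classify_replicate(
                s, tau=math.inf, growth_floor=config.growth_floor,
                blank_floor=config.blank_floor)
            if math.isfinite(e):
                control_E.append(e)
    try:
        tau = growth.dependence_threshold(control_E)
    except ValueError:
        logger.warning("fewer than 2 NOC control values; falling back to "
                       "default tau = %.3f", config.tau_default)
        tau = config.tau_default
    logger.info("dependence threshold tau = %.4f (from %d NOC control values)",
                tau, len(control_E))

    # replicate classification and isolate-level vote
    rep_rows = []
    votes: Dict[str, str] = {}
    e_by_isolate: Dict[str, List[float]] = {}
    for iid in sorted({i for i, _ in series}):
        reps = [series[(iid, r)] for (i2, r) in sorted(series) if i2 == iid]
        calls = []
        for s in reps:
            call, e = growth.classify_replicate(
                s, tau, growth_floor=config.growth_floor,
                blank_floor=config.blank_floor)
            calls.append(call)
            e_by_isolate.setdefault(iid, []).append(e)
            rep_rows.append({"isolate_id": iid, "replicate": s.replicate,
                             "call": call, "E": e})
        votes[iid] = growth.vote_dependence(calls)
    replicate_calls = pd.DataFrame(rep_rows)

    dependents = sorted(i for i, v in votes.items() if v == "dependent")
    non_dependents = sorted(i for i, v in votes.items() if v == "non-dependent")

    # dose-response for voted dependents
    fits: Dict[str, dr.PreferenceTable] = {}
    pref_rows = []
    if synthetic:
        dose_df = sim.simulate_dose_response(
            community, seed=stage_seed[2], isolate_ids=dependents,
            top_conc=config.media_conc)
    elif config.doseresponse_csv is not None:
        dose_df = pd.read_csv(config.doseresponse_csv)
        dose_df = dose_df[dose_df["isolate_id"].astype(str).isin(dependents)]
    else:
        dose_df = pd.DataFrame(columns=["isolate_id", "corrinoid",
                                        "concentration_molar", "od600"])
    for iid, grp in dose_df.groupby("isolate_id", sort=True):
        per_corr = {}
        for code, sub in grp.groupby("corrinoid", sort=True):
            data = dr.DoseResponseDataset(
                str(iid), str(code),
                sub["concentration_molar"].to_numpy(),
                sub["od600"].to_numpy())
            per_corr[str(code)] = dr.fit_fourpl(data,
                                                growth_floor=config.growth_floor)
        table = dr.preference_ranking(str(iid), per_corr)
        fits[str(iid)] = table
        for code, f in sorted(per_corr.items()):
            pref_rows.append({
                "isolate_id": iid, "corrinoid": code, "status": f.status,
                "ec50_molar": f.ec50, "ec50_ci_low": f.ec50_ci_low,
                "ec50_ci_high": f.ec50_ci_high, "ci": f.ci_text(),
                "preferred": code == table.preferred,
            })
    preferences = pd.DataFrame(pref_rows)

    # bioassay for isolates that grow without corrinoid
    if synthetic:
        readings_df, standard_df, fractions_df = sim.simulate_bioassay(
            community, seed=stage_seed[3])
    else:
        readings_df = (pd.read_csv(config.bioassay_csv)
                       if config.bioassay_csv else pd.DataFrame())
        standard_df = (pd.read_csv(config.standard_curve_csv)
                       if config.standard_curve_csv else pd.DataFrame())
        fractions_df = (pd.read_csv(config.fractions_csv)
                        if config.fractions_csv else pd.DataFrame())

    production: Dict[str, ba.ProductionCall] = {}
    repression: Dict[str, bool] = {}
    if not readings_df.empty:
        wide = readings_df.pivot_table(
            index=["sample_id", "replicate"], columns="strain", values="od600"
        ).reset_index()
        plate_wt_median = float(wide["wt"].median())
        for iid in non_dependents:
            rows = wide[wide["sample_id"].astype(str) == iid]
            if rows.empty:
                continue
            readings = [
                ba.BioassayReading(iid, od_dmetE=r.dmetE, od_double=r.dmetE_dmetH,
                                   od_wt=r.wt)
                for r in rows.itertuples()
            ]
            repression[iid] = any(
                ba.growth_repression_flag(r.od_wt, plate_wt_median,
                                          config.repression_fraction)
                for r in readings
            )
            production[iid] = ba.call_production_replicates(
                readings, config.bioassay_metric_threshold,
                config.bioassay_od_threshold, config.wt_floor)

    # standard curve + producer fraction quantification
    quant_rows = []
    providers: List[sharing.ProviderProfile] = []
    standard_fit = None
    if not standard_df.empty:
        standard_fit = ba.fit_standard_curve(
            standard_df["concentration_molar"].to_numpy(),
            standard_df["od600"].to_numpy())
    if standard_fit is not None and standard_fit.status == "fit" \
            and not fractions_df.empty:
        mean_od = fractions_df.groupby(["isolate_id", "fraction"])["od600"].mean()
        for iid in sorted({i for i, _ in mean_od.index}):
            amounts = {}
            detected = {}
            for frac in ("supernatant", "pellet"):
                if (iid, frac) not in mean_od.index:
                    continue
                q = ba.quantify_from_standard_curve(
                    float(mean_od[(iid, frac)]), standard_fit)
                amounts[frac] = q.value if q.detected else 0.0
                detected[frac] = q.detected
            if not amounts:
                continue
            qf = ba.QuantifiedFraction(
                iid, intracellular_amount=amounts.get("pellet", 0.0),
                extracellular_amount=amounts.get("supernatant", 0.0))
            quant_rows.append({
                "isolate_id": iid,
                "intracellular_molar": qf.intracellular_amount,
                "extracellular_molar": qf.extracellular_amount,
                "percent_provided": qf.percent_provided,
                "status": qf.status,
            })
            providers.append(sharing.ProviderProfile(
                isolate_id=iid, corrinoid="B12",
                extracellular_concentration=(
                    qf.extracellular_amount
                    if detected.get("supernatant") else math.nan),
                percent_provided=qf.percent_provided))
    quantified = pd.DataFrame(quant_rows)

    # category assembly
    call_rows = []
    for iid in sorted(votes):
        vote = votes[iid]
        e_mean = float(np.nanmean(e_by_isolate[iid])) if e_by_isolate.get(iid) else math.nan
        row = {"isolate_id": iid, "vote": vote, "E_mean": e_mean,
               "tau": tau, "bioassay_metric": math.nan, "reason": ""}
        if vote == "no-growth":
            row["category"] = "untested"
            row["reason"] = "no-reproducible-growth"
        elif vote == "inconclusive":
            row["category"] = "inconclusive"
            row["reason"] = "replicate-inconsistency"
        elif vote == "dependent":
            row["category"] = "dependent_E"
        else:
            pc = production.get(iid)
            if pc is None:
                row["category"] = "inconclusive"
                row["reason"] = "no-bioassay-data"
            elif repression.get(iid, False):
                row["category"] = "inconclusive"
                row["reason"] = "growth-repression"
            elif pc.call == "inconclusive":
                row["category"] = "inconclusive"
                row["reason"] = pc.reason
                row["bioassay_metric"] = pc.metric
            else:
                row["bioassay_metric"] = pc.metric
                row["category"] = ("producer_E" if pc.call == "producer"
                                   else "independent_E")
        call_rows.append(row)
    for iid, reason in sorted(excluded.items()):
        call_rows.append({"isolate_id": iid, "category": "untested",
                          "vote": "", "E_mean": math.nan, "tau": tau,
                          "bioassay_metric": math.nan, "reason": reason})
    calls = pd.DataFrame(call_rows)[[
        "isolate_id", "category", "vote", "E_mean", "tau",
        "bioassay_metric", "reason",
    ]]

    # sufficiency analysis: providers x dependents on B12
    sufficiency = None
    true_providers = [p for p in providers if p.provider_flag]
    if true_providers and fits:
        sufficiency = sharing.build_sufficiency_matrix(true_providers, fits)

    # taxonomy: genomic genus calls and comparison with experimental calls
    genus_calls: List[tax.GenusCall] = []
    conservation = None
    comparison = pd.DataFrame()
    if synthetic:
        # deterministic composition: the table stands in for a fixed external
        # prediction dataset, not a fresh random draw per run
        species = sim.simulate_species_table(sim.default_genus_specs(),
                                             seed=stage_seed[4],
                                             deterministic=True)
    elif config.species_tsv is not None:
        species = pd.read_csv(config.species_tsv, sep="\t")
    else:
        species = pd.DataFrame()
    if not species.empty:
        genus_calls = tax.classify_genera(
            species, min_n=config.genus_min_n,
            concordance=config.genus_concordance)
        conservation = tax.summarize_conservation(genus_calls)
        if truth is not None:
            experimental = calls.merge(
                truth[["isolate_id", "genus"]], on="isolate_id")
            experimental = experimental[experimental["category"].isin(
                ["producer_E", "dependent_E", "independent_E"])]
            comparison = tax.compare_calls(
                genus_calls,
                experimental.rename(columns={"category": "category"})[
                    ["isolate_id", "genus", "category"]])

    result = PipelineResult(
        calls=calls, tau=tau, truth=truth, replicate_calls=replicate_calls,
        fits=fits, preferences=preferences, quantified=quantified,
        providers=providers, sufficiency=sufficiency, genus_calls=genus_calls,
        conservation=conservation, comparison=comparison,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(outdir / "isolate_calls.tsv", sep="\t", index=False)
    result.replicate_calls.to_csv(outdir / "replicate_calls.tsv", sep="\t",
                                  index=False)
    if not result.preferences.empty:
        result.preferences.to_csv(outdir / "ec50_preferences.tsv", sep="\t",
                                  index=False)
    if not result.quantified.empty:
        result.quantified.to_csv(outdir / "quantified_fractions.tsv", sep="\t",
                                 index=False)
    if result.sufficiency is not None:
        result.sufficiency.matrix.to_csv(outdir / "sufficiency_matrix.tsv",
                                         sep="\t")
        result.sufficiency.summary.to_csv(outdir / "provider_summary.tsv",
                                          sep="\t", index=False)
        (outdir / "sufficiency_definition.txt").write_text(
            result.sufficiency.definition + "\n")
    if result.conservation is not None:
        result.conservation.table.to_csv(outdir / "genus_calls.tsv", sep="\t",
                                         index=False)
        result.conservation.table.to_csv(outdir / "tree_annotation.tsv",
                                         sep="\t", index=False)
    if not result.comparison.empty:
        result.comparison.to_csv(outdir / "genomic_vs_experimental.tsv",
                                 sep="\t", index=False)
    if result.truth is not None:
        result.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
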