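"""Synthetic-data generators: determinism, statistical structure, round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from corrikit.dilution import clonal_fraction, positive_fraction_from_lambda
from corrikit.growth import growth_enhancement
from corrikit.simulate import (
    DEFAULT_CARRYOVER_FOLD,
    IsolationDesign,
    StandardCurveTruth,
    default_genus_specs,
    make_community,
    simulate_bioassay,
    simulate_dose_response,
    simulate_passages,
    simulate_species_table,
    simulate_wells,
)
from corrikit.taxonomy import classify_genus, classify_species


class TestWells:
    def test_zero_rate_all_empty(self):
        df = simulate_wells(IsolationDesign(n_wells=500, lambda_=0.0), seed=1)
        assert not df["positive"].any()

    def test_fractions_match_poisson_expectation(self):
        lam = 0.35667
        n = 100_000
        df = simulate_wells(IsolationDesign(n_wells=n, lambda_=lam), seed=42)
        p = positive_fraction_from_lambda(lam)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(df["positive"].mean() - p) < 3 * se
        pos = df[df["positive"]]
        c = clonal_fraction(lam)
        se_c = math.sqrt(c * (1 - c) / len(pos))
        assert abs(pos["clonal"].mean() - c) < 3 * se_c

    def test_deterministic_under_seed(self):
        d = IsolationDesign(n_wells=1000, lambda_=0.4)
        pd.testing.assert_frame_equal(simulate_wells(d, 7), simulate_wells(d, 7))


@pytest.fixture(scope="module")
def community():
    return make_community(n_producers=6, n_dependents=6, n_independents=6, seed=11)


class TestPassages:
    def test_carryover_decay_reaches_sub_ec50(self, community):
        # passage-4 carried concentration from 10 nM: 10 nM / (200/3)^4 ~ 0.51 fM
        carried = 10e-9 / DEFAULT_CARRYOVER_FOLD ** 4
        assert carried == pytest.approx(5.06e-16, rel=1e-2)
        spec = next(s for s in community.isolates if s.category == "dependent")
        truth = spec.dose_response[
            spec.isolation_corrinoid if spec.isolation_corrinoid != "NOC" else "B12"]
        # carried corrinoid is far below the EC50, so the NOC plateau collapses
        assert truth.predict(carried) < spec.baseline + 0.05 * (spec.top - spec.baseline)

    def test_dependent_loses_noc_growth_by_final_passage(self, community):
        zero_noise = make_community(6, 6, 6, seed=11, noise_sd=0.0)
        df = simulate_passages(zero_noise, seed=2)
        final = df[df["passage"] == 4]
        for spec in zero_noise.isolates:
            sub = final[final["isolate_id"] == spec.isolate_id]
            ow = sub[sub["arm"] == "corrinoid"]["od600"].iloc[0]
            on = sub[sub["arm"] == "NOC"]["od600"].iloc[0]
            e = growth_enhancement(ow, on)
            if spec.category == "dependent":
                assert e > 2.0
            else:
                # producers and independents keep growing without corrinoid
                assert e == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self, community):
        a = simulate_passages(community, seed=5)
        b = simulate_passages(community, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_ods_physical(self, community):
        df = simulate_passages(community, seed=5)
        assert df["od600"].between(0, 2).all()


class TestDoseResponse:
    def test_only_usable_corrinoids_respond(self, community):
        zero_noise = make_community(6, 6, 6, seed=11, noise_sd=0.0)
        dep = next(s for s in zero_noise.isolates if s.category == "dependent")
        df = simulate_dose_response(zero_noise, seed=3,
                                    isolate_ids=[dep.isolate_id])
        for code, sub in df.groupby("corrinoid"):
            span = sub["od600"].max() - sub["od600"].min()
            if dep.dose_response.get(str(code)) is None:
                assert span < 0.01  # NG corrinoid: flat baseline
            else:
                assert span > 0.2


class TestBioassay:
    def test_independent_lysate_called_non_producer(self, community):
        from corrikit.bioassay import BioassayReading, call_production_replicates

        readings, _, _ = simulate_bioassay(community, seed=9)
        wide = readings.pivot_table(index=["sample_id", "replicate"],
                                    columns="strain", values="od600").reset_index()
        for spec in community.isolates:
            if spec.category != "independent":
                continue
            rows = wide[wide["sample_id"] == spec.isolate_id]
            reads = [BioassayReading(spec.isolate_id, r.dmetE, r.dmetE_dmetH, r.wt)
                     for r in rows.itertuples()]
            assert call_production_replicates(reads).call == "non-producer"

    def test_producers_detected_across_seeds(self, community):
        from corrikit.bioassay import BioassayReading, call_production_replicates

        n_calls = n_producer = 0
        for seed in range(10):
            readings, _, _ = simulate_bioassay(community, seed=seed)
            wide = readings.pivot_table(index=["sample_id", "replicate"],
                                        columns="strain", values="od600"
                                        ).reset_index()
            for spec in community.isolates:
                if spec.category != "producer":
                    continue
                rows = wide[wide["sample_id"] == spec.isolate_id]
                reads = [BioassayReading(spec.isolate_id, r.dmetE,
                                         r.dmetE_dmetH, r.wt)
                         for r in rows.itertuples()]
                n_calls += 1
                n_producer += call_production_replicates(reads).call == "producer"
        assert n_producer / n_calls >= 0.99

    def test_provided_fraction_recovered(self):
        """Quantified percent provided lands within 3 points of truth."""
        from corrikit.bioassay import fit_standard_curve, percent_provided, \
            quantify_from_standard_curve
        from corrikit.simulate import CommunitySpec, IsolateSpec

        spec = IsolateSpec("PROD_X", "producer", "G", "B12", top=0.8,
                           baseline=0.05, production_total=3e-10,
                           provided_fraction=0.2)
        comm = CommunitySpec([spec])
        _, standard, fractions = simulate_bioassay(comm, seed=21)
        curve = fit_standard_curve(standard["concentration_molar"],
                                   standard["od600"])
        mean_od = fractions.groupby("fraction")["od600"].mean()
        extra = quantify_from_standard_curve(mean_od["supernatant"], curve)
        intra = quantify_from_standard_curve(mean_od["pellet"], curve)
        assert extra.detected and intra.detected
        pct, _ = percent_provided(intra.value, extra.value)
        assert pct == pytest.approx(20.0, abs=3.0)


class TestSpeciesTable:
    def test_round_trip_categories(self):
        specs = [("GA", 30, {"producer_G": 0.5, "dependent_G": 0.3,
                             "independent_G": 0.2})]
        df = simulate_species_table(specs, seed=4)
        assert len(df) == 30
        for _, row in df.iterrows():
            cat = classify_species(row["producer_class"],
                                   row["n_dependent_functions"])
            assert cat in ("producer_G", "dependent_G", "independent_G")

    def test_deterministic_boundary_fixture(self):
        # exactly 19/20 producers: classifies at the inclusive 95% boundary
        df = simulate_species_table(
            [("GB", 20, {"producer_G": 0.95, "dependent_G": 0.05})],
            seed=4, deterministic=True)
        cats = [classify_species(r["producer_class"], r["n_dependent_functions"])
                for _, r in df.iterrows()]
        assert cats.count("producer_G") == 19
        assert classify_genus(cats, "GB").call == "producer_G"

    def test_nineteen_species_below_cutoff(self):
        df = simulate_species_table([("GC", 19, {"producer_G": 1.0})],
                                    seed=4, deterministic=True)
        cats = [classify_species(r["producer_class"], r["n_dependent_functions"])
                for _, r in df.iterrows()]
        assert classify_genus(cats, "GC").call == "below_cutoff"

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_table([("GD", 10, {"producer_G": 0.5})], seed=1)

    def test_default_specs_have_concordant_and_discordant_genera(self):
        df = simulate_species_table(default_genus_specs(), seed=8)
        assert df["genus"].nunique() >= 10
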