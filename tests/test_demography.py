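import pytest
import yaml

from coalboot.demography import (
    ARTHEMIS_STEM_NE,
    CONTEMPORARY_NE,
    HYBRIDIZATION_ONSET_YBP,
    Deme,
    DemographicModel,
    MigrationPhase,
    SamplingScheme,
    SplitEvent,
    build_limenitis_models,
    model_from_dict,
    model_to_dict,
    to_coalescent_scale,
)

# published split times (years) for the builtin suite
PUBLISHED_TIMES = {
    "MM1": (117_500, 235_000),
    "MM2": (211_500, 235_000),
    "MM3": (327_500, 655_000),
    "MM4": (589_500, 655_000),
    "MM5": (537_000, 1_075_000),
    "MM6": (966_600, 1_075_000),
    "MM7": (117_500, 235_000),
    "MM8": (211_500, 235_000),
    "MM9": (327_500, 655_000),
    "MM10": (589_500, 655_000),
    "MM11": (537_000, 1_075_000),
    "MM12": (966_600, 1_075_000),
    "R1": (235_000, 1_095_000),
    "R2": (655_000, 1_095_000),
    "R3": (1_075_000, 1_095_000),
}


def ingroup_times(model):
    """(T1, T2) read back from the split events."""
    t2 = model.split_time("anc_T1")
    t1 = next(s.time_years for s in model.splits if s.derived == "astyanax")
    return t1, t2


class TestBuiltinSuite:
    def test_fifteen_models(self, models):
        assert [m.model_id for m in models] == list(PUBLISHED_TIMES)

    @pytest.mark.parametrize("model_id", list(PUBLISHED_TIMES))
    def test_split_times_match_published_values(self, models_by_id, model_id):
        m = models_by_id[model_id]
        t1, t2 = ingroup_times(m)
        assert (t1, t2) == PUBLISHED_TIMES[model_id]
        assert t1 < t2

    def test_hypothesis_topologies(self, models_by_id):
        # MM: the two mimetic lineages coalesce first; R: arthemis+astyanax
        mm = models_by_id["MM1"]
        assert {s.derived for s in mm.splits if s.ancestral == "anc_T1"} == {
            "astyanax",
            "arizonensis",
        }
        r = models_by_id["R2"]
        assert {s.derived for s in r.splits if s.ancestral == "anc_T1"} == {
            "astyanax",
            "arthemis",
        }

    @pytest.mark.parametrize(
        "model_id, expected",
        [("MM1", (3.2, 0.14)), ("MM7", (17.71, 15.53)), ("R2", (3.2, 0.14))],
    )
    def test_migration_tiers(self, models_by_id, model_id, expected):
        m = models_by_id[model_id]
        into_arthemis = next(p for p in m.migrations if p.dest == "arthemis")
        into_astyanax = next(p for p in m.migrations if p.dest == "astyanax")
        assert into_arthemis.source == "astyanax"
        assert (into_arthemis.rate_migrants_per_gen,
                into_astyanax.rate_migrants_per_gen) == expected
        for p in (into_arthemis, into_astyanax):
            assert (p.start_years, p.end_years) == (0.0, HYBRIDIZATION_ONSET_YBP)

    def test_population_sizes(self, models):
        for m in models:
            for name in ("archippus", "arizonensis", "arthemis", "astyanax",
                         "lorquini", "weidemeyerii"):
                assert m.deme(name).effective_size == CONTEMPORARY_NE
                assert m.deme(name).generations_per_year == 2.0
            assert m.deme("arthemis_stem").effective_size == ARTHEMIS_STEM_NE

    def test_mm_and_r_share_outgroup_history(self, models_by_id):
        def outgroup_splits(m):
            ingroup = {"arthemis", "astyanax", "arizonensis", "anc_T1"}
            return {
                (s.time_years, s.derived, s.ancestral)
                for s in m.splits
                if s.derived not in ingroup
            }

        assert outgroup_splits(models_by_id["MM1"]) == outgroup_splits(
            models_by_id["R3"]
        )

    def test_all_models_validate(self, models):
        for m in models:
            m.validate()
            assert m.root_deme == "anc_root"

    def test_outgroup_time_overrides(self):
        ms = build_limenitis_models(outgroup_times={"lorquini": 1.2e6})
        assert any(s.time_years == 1.2e6 for s in ms[0].splits)
        with pytest.raises(ValueError):
            build_limenitis_models(outgroup_times={"lorquini": 1.0e6})  # < T2 of R
        with pytest.raises(ValueError):
            build_limenitis_models(outgroup_times={"lorquini": 3.0e6})  # ordering


class TestSampling:
    def test_table_counts(self, sampling):
        assert sampling["EF1a"] == {
            "archippus": 22, "arizonensis": 12, "arthemis": 14,
            "astyanax": 16, "lorquini": 17, "weidemeyerii": 15,
        }
        assert sampling.total_tips("EF1a") == 96
        assert sampling["Anon15"]["lorquini"] == 0
        assert sampling["Anon17"]["archippus"] == 0
        assert len(sampling) == 8

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            SamplingScheme({"L1": {"a": -1, "b": 3}})

    def test_rejects_all_singleton_loci(self):
        with pytest.raises(ValueError):
            SamplingScheme({"L1": {"a": 1, "b": 0}})


class TestScaling:
    def test_time_scaling_example(self, scaled_mm1):
        # 235,000 yr at 2 gen/yr over 4 * 2.5e6 generations
        assert scaled_mm1.years_to_scaled(235_000) == pytest.approx(0.047)
        assert scaled_mm1.years_to_scaled(0.0) == 0.0

    def test_migration_rate_conversion_literal_nm(self):
        model = DemographicModel(
            model_id="toy",
            hypothesis="user",
            demes=[Deme("a", 2.5e6), Deme("b", 2.5e6), Deme("anc", 2.5e6)],
            splits=[SplitEvent(1e6, "a", "anc"), SplitEvent(1e6, "b", "anc")],
            migrations=[MigrationPhase(0, 12_000, "a", "b", 3.2, rate_unit="Nm")],
            reference_size=2.5e6,
        )
        scaled = to_coalescent_scale(model)
        assert scaled.migrations[0].rate == pytest.approx(4 * 2.5e6 * 3.2 / 2.5e6)
        assert scaled.migrations[0].rate == pytest.approx(12.8)

    def test_ms_convention_rate_is_quarter_of_literal(self):
        kw = dict(start_years=0, end_years=1e4, source="a", dest="b",
                  rate_migrants_per_gen=3.2)
        literal = MigrationPhase(**kw, rate_unit="Nm")
        ms_style = MigrationPhase(**kw, rate_unit="4Nm")
        assert ms_style.effective_migrants_per_gen == pytest.approx(
            literal.effective_migrants_per_gen / 4.0
        )

    @pytest.mark.parametrize("t_years", [1.0, 12_000.0, 235_000.0, 3.5e6])
    def test_round_trip_times(self, scaled_r2, t_years):
        back = scaled_r2.scaled_to_years(scaled_r2.years_to_scaled(t_years))
        assert back == pytest.approx(t_years, rel=1e-12)

    def test_relative_sizes(self, scaled_r2):
        assert scaled_r2.relative_sizes["arthemis"] == 1.0
        assert scaled_r2.relative_sizes["arthemis_stem"] == pytest.approx(0.14)

    def test_split_times_sorted_and_scaled(self, scaled_r2):
        times = [s.time for s in scaled_r2.splits]
        assert times == sorted(times)
        assert times[0] == pytest.approx(655_000 * 2 / 1e7)


class TestValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            DemographicModel(
                model_id="bad", hypothesis="user",
                demes=[Deme("a", 1e4), Deme("b", 1e4)],
                splits=[],
            )

    def test_migration_beyond_deme_lifetime_rejected(self):
        with pytest.raises(ValueError, match="extant"):
            DemographicModel(
                model_id="bad", hypothesis="user",
                demes=[Deme("a", 1e4), Deme("b", 1e4), Deme("anc", 1e4)],
                splits=[SplitEvent(5e3, "a", "anc"), SplitEvent(5e3, "b", "anc")],
                migrations=[MigrationPhase(0, 1e4, "a", "b", 1.0)],
            )

    def test_duplicate_deme_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DemographicModel(
                model_id="bad", hypothesis="user",
                demes=[Deme("a", 1e4), Deme("a", 1e4), Deme("anc", 1e4)],
                splits=[SplitEvent(1e3, "a", "anc")],
            )


def test_serialization_round_trip(tmp_path, models_by_id):
    m = models_by_id["MM7"]
    data = model_to_dict(m)
    rebuilt = model_from_dict(data)
    assert model_to_dict(rebuilt) == data
    path = tmp_path / "mm7.yaml"
    path.write_text(yaml.safe_dump(data))
    from coalboot.demography import load_model

    loaded = load_model(path)
    assert model_to_dict(loaded) == data
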