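"""Genealogy simulation, reference tables and ms-dialect emission."""

import numpy as np
import pytest

from dentabc import demography as dg
from dentabc import coalescent as co
from dentabc.coalescent import GROUP_ORDER, SampleConfig
from dentabc.demography import Deme, RealizedDemography, SizeSegment

FIXED = dict(
    N_cW=1000.0, N_cE=1000.0, N_mpW=6000.0, N_mpE=6000.0,
    N_lpW=2000.0, N_lpE=2000.0, N_hW=9000.0, N_hE=9000.0,
    N_s=800.0, N_gs1=1500.0, N_gs2=1800.0, P_lgm=0.2,
    T_s1=16.0, T_s2=31.0, p_holo=0.6,
    m_mp=1e-4, m_lp=2e-4, m_lg=3e-4, mu=0.005,
)


def _single_deme(n=2000.0):
    return RealizedDemography(
        demes={"A": Deme("A", (SizeSegment(0, np.inf, n),))},
        migrations=[],
        moves=[],
        sample_demes={(r, p): "A" for r in ("West", "East")
                      for p in ("MPG", "LPG", "LG&EH")},
        root="A",
    )


class TestSimulateTraitFrequencies:
    def test_zero_mutation_rate_all_ancestral(self, rng):
        demog = dg.build_model(1).realize(FIXED)
        freqs = co.simulate_trait_frequencies(
            demog, {g: 10 for g in GROUP_ORDER}, mu=0.0, rng=rng
        )
        assert all(v == 0.0 for v in freqs.values())

    def test_masked_group_yields_no_value(self, rng):
        demog = dg.build_model(1).realize(FIXED)
        counts = {g: 10 for g in GROUP_ORDER}
        counts[("West", "MPG")] = 0
        freqs = co.simulate_trait_frequencies(demog, counts, mu=0.01, rng=rng)
        assert ("West", "MPG") not in freqs
        assert len(freqs) == 5

    def test_rejects_insufficient_lineages_and_bad_mode(self, rng):
        demog = _single_deme()
        with pytest.raises(ValueError):
            co.simulate_trait_frequencies(
                demog, {("West", "MPG"): 1}, mu=0.01, rng=rng
            )
        with pytest.raises(ValueError):
            co.simulate_trait_frequencies(
                demog, {("West", "MPG"): 5}, mu=0.01, rng=rng,
                mutation_mode="bogus",
            )

    def test_unreachable_ancestor_is_a_hard_error(self, rng):
        # two demes, no migration, no merge: lineages can never meet
        demog = RealizedDemography(
            demes={
                "A": Deme("A", (SizeSegment(0, np.inf, 100.0),)),
                "B": Deme("B", (SizeSegment(0, np.inf, 100.0),)),
            },
            migrations=[],
            moves=[],
            sample_demes={("West", "MPG"): "A", ("East", "MPG"): "B"},
            root="A",
        )
        with pytest.raises(RuntimeError, match="common ancestor"):
            co.simulate_trait_frequencies(
                demog,
                {("West", "MPG"): 5, ("East", "MPG"): 5},
                mu=0.01,
                rng=rng,
            )

    def test_conditioned_mode_always_polymorphic(self, rng):
        demog = _single_deme(500.0)
        counts = {("West", "LG&EH"): 20}
        for _ in range(20):
            f = co.simulate_trait_frequencies(
                demog, counts, mu=1e-4, rng=rng,
                condition_on_segregating=True,
            )
            assert 0.0 < f[("West", "LG&EH")] < 1.0

    def test_single_site_mode_polymorphic_and_mu_free(self, rng):
        demog = _single_deme(500.0)
        counts = {("West", "LG&EH"): 20}
        for _ in range(20):
            f = co.simulate_trait_frequencies(
                demog, counts, mu=0.05, rng=rng, mutation_mode="single_site"
            )
            assert 0.0 < f[("West", "LG&EH")] < 1.0

    def test_bottleneck_amplifies_drift(self, rng):
        """Stronger LGM reduction -> larger between-replicate variance of
        the post-LGM frequencies."""
        counts = {("West", "LG&EH"): 25}
        out = {}
        for p_lgm in (0.01, 1.0):
            demog = dg.build_model(3).realize(dict(FIXED, P_lgm=p_lgm))
            vals = [
                co.simulate_trait_frequencies(
                    demog, counts, mu=0.0, rng=rng,
                    mutation_mode="single_site",
                )[("West", "LG&EH")]
                for _ in range(600)
            ]
            out[p_lgm] = np.var(vals)
        assert out[0.01] > out[1.0]

    def test_migration_homogenizes_regions(self, rng):
        """High symmetric migration shrinks the mean West-East frequency
        gap relative to zero migration."""
        counts = {("West", "LG&EH"): 20, ("East", "LG&EH"): 20}
        gaps = {}
        for m in (1e-3, 0.0):
            params = dict(FIXED, m_mp=m, m_lp=m, m_lg=m)
            demog = dg.build_model(1).realize(params)
            diffs = []
            for _ in range(400):
                f = co.simulate_trait_frequencies(
                    demog, counts, mu=0.0, rng=rng,
                    mutation_mode="single_site",
                )
                diffs.append(
                    abs(f[("West", "LG&EH")] - f[("East", "LG&EH")])
                )
            gaps[m] = np.mean(diffs)
        assert gaps[1e-3] < gaps[0.0]

    def test_seeded_reproducibility(self):
        demog = dg.build_model(10).realize(FIXED)
        counts = {g: 8 for g in GROUP_ORDER}

        def run(seed):
            rng = np.random.default_rng(seed)
            return co.simulate_trait_frequencies(
                demog, counts, mu=0.01, rng=rng, mutation_mode="single_site"
            )

        assert run(77) == run(77)
        assert run(77) != run(78)


class TestReferenceTable:
    def test_bookkeeping_two_models(self):
        priors = dg.default_priors()
        cfg = SampleConfig.uniform(["T1", "T2"], 6)
        rt = co.build_reference_table([1, 3], priors, cfg,
                                      n_per_model=10, seed=3)
        assert rt.n_rows == 20
        assert rt.summaries.shape == (20, len(cfg.layout()))
        assert sorted(set(rt.model_ids)) == [1, 3]
        assert (rt.summaries >= 0).all() and (rt.summaries <= 1).all()

    def test_bit_identical_under_same_seed(self):
        priors = dg.default_priors()
        cfg = SampleConfig.uniform(["T1"], 5)
        a = co.build_reference_table([2], priors, cfg, n_per_model=6, seed=9)
        b = co.build_reference_table([2], priors, cfg, n_per_model=6, seed=9)
        assert np.array_equal(a.summaries, b.summaries)
        assert a.params.equals(b.params)

    def test_masked_cells_absent_from_layout(self):
        priors = dg.default_priors()
        counts = {("T1", g): 5 for g in GROUP_ORDER}
        counts[("T1", ("East", "LPG"))] = 0
        cfg = SampleConfig(("T1",), counts)
        rt = co.build_reference_table([1], priors, cfg, n_per_model=4, seed=1)
        assert ("T1", ("East", "LPG")) not in rt.layout
        assert rt.summaries.shape[1] == 5

    def test_save_load_round_trip(self, tmp_path):
        priors = dg.default_priors()
        cfg = SampleConfig.uniform(["T1"], 5)
        rt = co.build_reference_table([1, 2], priors, cfg,
                                      n_per_model=4, seed=2)
        prefix = str(tmp_path / "rt")
        rt.save(prefix)
        back = co.ReferenceTable.load(prefix)
        assert np.allclose(back.summaries, rt.summaries)
        assert list(back.model_ids) == list(rt.model_ids)
        assert back.layout == rt.layout

    def test_subset_and_missing_model(self):
        priors = dg.default_priors()
        cfg = SampleConfig.uniform(["T1"], 5)
        rt = co.build_reference_table([1, 2, 3], priors, cfg,
                                      n_per_model=3, seed=2)
        sub = rt.subset([1, 3])
        assert sorted(set(sub.model_ids)) == [1, 3]
        with pytest.raises(ValueError):
            rt.subset([1, 9])


class TestValidateAlignment:
    def _rt(self):
        priors = dg.default_priors()
        cfg = SampleConfig.uniform(["T1"], 4)
        return co.build_reference_table([1], priors, cfg, n_per_model=3, seed=5)

    def test_matching_layout_passes(self):
        rt = self._rt()
        obs = rt.summaries[0]
        report = co.validate_alignment(rt, obs, rt.layout)
        assert report.ok and not report.problems

    def test_extra_cell_fails_naming_it(self):
        rt = self._rt()
        layout = rt.layout + [("T9", ("West", "MPG"))]
        obs = np.append(rt.summaries[0], 0.5)
        report = co.validate_alignment(rt, obs, layout)
        assert not report.ok
        assert any("T9" in p for p in report.problems)

    def test_corrupted_frequency_fails_with_position(self):
        rt = self._rt()
        rt.summaries[1, 2] = 1.2
        report = co.validate_alignment(rt, rt.summaries[0], rt.layout)
        assert not report.ok
        assert any("row 1" in p and "column 2" in p for p in report.problems)


class TestMsEmission:
    def test_deterministic(self):
        cfg = SampleConfig.uniform(["T1"], 10)
        model = dg.build_model(1)
        a = co.emit_ms_command(model, FIXED, cfg)
        b = co.emit_ms_command(model, FIXED, cfg)
        assert a == b

    def test_model1_structure_and_serial_note(self):
        cfg = SampleConfig.uniform(["T1"], 10)
        cmd = co.emit_ms_command(dg.build_model(1), FIXED, cfg)
        assert "# NOTE: serial sampling" in cmd
        parsed = co.parse_ms_command(cmd)
        assert parsed["npop"] == 3  # W, E and the ancestral deme
        mig_on = [e for e in parsed["events"]
                  if e[0] == "migration" and e[4] > 0]
        # three bidirectional migration epochs -> six rate activations
        assert len(mig_on) == 6

    def test_round_trip_times_within_tolerance(self):
        cfg = SampleConfig.uniform(["T1"], 8)
        demog = dg.build_model(3).realize(FIXED)
        cmd = co.emit_ms_command(demog, FIXED, cfg)
        parsed = co.parse_ms_command(cmd)
        times = sorted({e[1] for e in parsed["events"]})
        for expected in (280.0, 588.0, 760.0, 1060.0, 1120.0, 1880.0):
            assert any(abs(t - expected) <= 1e-9 * max(1, expected)
                       for t in times), expected

    def test_admixture_emitted_as_split_plus_joins(self):
        cfg = SampleConfig.uniform(["T1"], 8)
        cmd = co.emit_ms_command(dg.build_model(10), FIXED, cfg)
        parsed = co.parse_ms_command(cmd)
        kinds = [e[0] for e in parsed["events"]]
        assert "split" in kinds
        split = next(e for e in parsed["events"] if e[0] == "split")
        assert split[3] == pytest.approx(FIXED["p_holo"])
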