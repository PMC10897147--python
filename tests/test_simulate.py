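"""Kinetic ground truth and the synthetic dataset emitters."""

import numpy as np
import pandas as pd
import pytest

from turnoverms import simulate as sim
from turnoverms.stats import PROTEASOME_COMPLEXES


class TestKineticFa:
    def test_zero_rate_keeps_everything_old(self):
        assert sim.kinetic_fa(0.0, 3.0) == 1.0

    def test_fast_rate_converges_to_long_lived_fraction(self):
        assert sim.kinetic_fa(1e6, 3.0, lam=0.1) == pytest.approx(0.1)

    def test_closed_form_value(self):
        assert sim.kinetic_fa(0.3, 3.0) == pytest.approx(np.exp(-0.9), abs=1e-12)
        assert sim.kinetic_fa(0.3, 3.0) == pytest.approx(0.40657, abs=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sim.kinetic_fa(-0.1, 3.0)


class TestDesignAndPanel:
    def test_default_windows_are_the_five_steps(self):
        design = sim.CohortDesign()
        assert design.windows == ((9, 12), (12, 15), (15, 18), (18, 21), (21, 24))

    def test_female_replicate_overrides(self):
        design = sim.CohortDesign()
        assert design.n_replicates("F", 15) == 3
        assert design.n_replicates("F", 24) == 3
        assert design.n_replicates("M", 15) == 4

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            sim.CohortDesign(replicates=2)

    def test_panel_archetypes_balanced_and_complexes_planted(self):
        panel = sim.make_panel(n_proteins=500, seed=0)
        counts = pd.Series([p.archetype for p in panel]).value_counts()
        assert counts.min() >= 40
        members = {p.gene for p in panel if p.complex == "20S"}
        assert members == set(PROTEASOME_COMPLEXES["20S"].members)
        assert all(len(p.peptides) >= 3 for p in panel)

    def test_panel_deterministic_given_seed(self):
        a = sim.make_panel(n_proteins=50, seed=3)
        b = sim.make_panel(n_proteins=50, seed=3)
        assert [p.gene for p in a] == [p.gene for p in b]
        assert [p.k0 for p in a] == [p.k0 for p in b]


class TestSimulateTruth:
    def test_all_truth_in_unit_interval(self, default_truth):
        assert ((default_truth.fa_true["fa_true"] >= 0)
                & (default_truth.fa_true["fa_true"] <= 1)).all()
        rep = default_truth.replicate_fa.to_numpy()
        assert rep.min() > 0 and rep.max() < 1

    def test_female_profile_is_male_shifted_by_nine_months(self):
        # archetype centers span 9-24 M, so compare the modulated rates directly
        design = sim.CohortDesign(seed=0)
        panel = sim.make_panel(n_proteins=20, seed=0)
        for spec in panel[:5]:
            for a_mid in (10.5, 16.5, 22.5):
                k_f = sim.modulated_rate(spec, a_mid, "F", design)
                k_m = sim.modulated_rate(spec, a_mid - 9.0, "M", design)
                assert k_f == pytest.approx(k_m, rel=1e-12)

    def test_replicate_jitter_centered_on_truth(self, default_truth):
        wide = default_truth.fa_true.pivot_table(
            index="gene", columns=["sex", "age"], values="fa_true"
        )
        m12 = default_truth.replicate_fa[
            [c for c in default_truth.replicate_fa.columns if c.startswith("M12")]
        ]
        base = wide[("M", 12)].reindex(m12.index)
        assert (m12.mean(axis=1) - base).abs().mean() < 0.03


class TestSpeciesTable:
    def test_no_mz_conflicts_within_a_slot(self, small_panel):
        table = sim.species_table(small_panel, 0.96, seed=2)
        for rt, grp in table.groupby("rt"):
            lines = np.sort(np.concatenate(list(grp["mz"])))
            rel = np.diff(lines) / lines[:-1]
            assert (rel > 10e-6).all()  # beyond XIC matching tolerance

    def test_old_new_pair_per_peptide(self, small_panel):
        table = sim.species_table(small_panel, 0.96, seed=2)
        pools = table.groupby("peptide_id")["pool"].apply(set)
        assert (pools == {"old", "new"}).all()


class TestTmtEmitter:
    def test_duplicated_plexes_have_unit_bridge_factors(self, small_truth):
        from turnoverms.tmt import bridge_scale, combine_pools

        plexes = sim.simulate_tmt_dataset(small_truth, seed=5)
        m = combine_pools(plexes[0]["old"], plexes[0]["new"])
        dup = combine_pools(plexes[0]["old"], plexes[0]["new"])
        assert bridge_scale([m, dup]) == pytest.approx([1.0, 1.0])

    def test_symmetric_truth_recovers_half(self, small_design, small_panel):
        truth = sim.simulate_truth(small_design, small_panel)
        truth.replicate_fa.iloc[:, :] = 0.5
        plexes = sim.simulate_tmt_dataset(truth, noise_cv=0.05, seed=6)
        from turnoverms.workflows import tmt_round_trip

        fa = tmt_round_trip(truth, plexes)
        assert abs(fa.values.to_numpy().mean() - 0.5) < 0.01

    def test_layout_covers_every_sample_with_one_bridge_each(self, small_truth):
        layout = sim.default_plex_layout(small_truth.samples)
        mapped = [s for e in layout for s in e["channel_map"].values()]
        assert mapped.count("bridge") == len(layout)
        assert set(mapped) - {"bridge"} == set(small_truth.samples.index)


class TestInhibition:
    def test_factor_one_means_identical_arm_kinetics(self):
        study = sim.simulate_inhibition(
            panel=sim.make_panel(n_proteins=60, seed=2), factor=1.0, seed=2
        )
        assert np.allclose(
            study.fa_true["vehicle"], study.fa_true["marizomib"], atol=1e-12
        )

    def test_half_inhibition_closed_form_relationship(self):
        study = sim.simulate_inhibition(
            panel=sim.make_panel(n_proteins=60, seed=3), factor=0.5, seed=3
        )
        subs = sorted(study.substrates)
        # exp(-k*0.5*t) == sqrt(exp(-k*t))
        assert np.allclose(
            study.fa_true.loc[subs, "marizomib"],
            np.sqrt(study.fa_true.loc[subs, "vehicle"]),
            atol=1e-12,
        )
        others = study.fa_true.index.difference(subs)
        assert np.allclose(
            study.fa_true.loc[others, "marizomib"],
            study.fa_true.loc[others, "vehicle"],
            atol=1e-12,
        )

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            sim.simulate_inhibition(panel=sim.make_panel(30, seed=1), factor=0.0)


class TestAnnotationFixture:
    def test_planted_terms_contain_their_clusters(self, small_panel):
        terms = sim.annotation_fixture(small_panel, seed=4)
        for comp in sim.ARCHETYPE_COMPARTMENTS:
            planted = {p.gene for p in small_panel if p.compartment == comp}
            assert planted <= terms.sets[f"CC:{comp}"]

    def test_gmt_round_trip_preserves_sets(self, small_panel, tmp_path):
        from turnoverms.io import read_gmt, write_gmt

        terms = sim.annotation_fixture(small_panel, seed=4)
        path = tmp_path / "terms.gmt"
        write_gmt(terms, path)
        back = read_gmt(path)
        assert back.sets == terms.sets
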