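"""The paired-repertoire generator: determinism, conservation, decay rules."""

import numpy as np
import pandas as pd
import pytest

from tcroverlap import (ConfigurationError, SynthConfig, aggregate,
                        annotation_filter, apply_time_decay,
                        sample_clone_universe, simulate_sequencing,
                        write_airr_table)

# scaled-down study conditions so unit tests stay fast; structure unchanged
SMALL = dict(n_background_clones=250, depth=30_000, public_pool_size=60)


def small_cfg(seed=3, **kw):
    return SynthConfig(seed=seed, n_mice=1, **{**SMALL, **kw})


class TestDeterminism:
    def test_identical_config_gives_identical_universe_and_tables(self):
        t1, _ = simulate_sequencing(sample_clone_universe(small_cfg()))
        t2, _ = simulate_sequencing(sample_clone_universe(small_cfg()))
        assert t1.keys() == t2.keys()
        for sid in t1:
            pd.testing.assert_frame_equal(t1[sid], t2[sid])

    def test_byte_identical_airr_files(self, tmp_path):
        t1, m1 = simulate_sequencing(sample_clone_universe(small_cfg()))
        sid = next(iter(t1))
        a = write_airr_table(t1[sid], tmp_path / "a.tsv").read_bytes()
        t2, _ = simulate_sequencing(sample_clone_universe(small_cfg()))
        b = write_airr_table(t2[sid], tmp_path / "b.tsv").read_bytes()
        assert a == b

    def test_different_seeds_differ(self):
        t1, _ = simulate_sequencing(sample_clone_universe(small_cfg(seed=3)))
        t2, _ = simulate_sequencing(sample_clone_universe(small_cfg(seed=4)))
        sid = next(iter(t1))
        assert not t1[sid].equals(t2[sid])


class TestUniverse:
    def test_latent_frequencies_sum_to_one_per_side(self):
        coh = sample_clone_universe(small_cfg())
        clones = coh.mice[0].clones
        assert clones["freq_left"].sum() == pytest.approx(1.0, abs=1e-9)
        assert clones["freq_right"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_control_group_has_no_dominant_block(self):
        coh = sample_clone_universe(small_cfg(group="PBS_like"))
        assert (coh.mice[0].clones["kind"] != "dominant").all()

    def test_full_correlation_gives_identical_sides(self):
        coh = sample_clone_universe(small_cfg(left_right_dominant_correlation=1.0))
        dom = coh.mice[0].clones.query("kind == 'dominant'")
        np.testing.assert_allclose(dom["freq_left"], dom["freq_right"])

    def test_dominant_block_carries_configured_mass(self):
        coh = sample_clone_universe(small_cfg(dominant_mass=0.5))
        dom = coh.mice[0].clones.query("kind == 'dominant'")
        assert dom["freq_left"].sum() == pytest.approx(0.5, abs=1e-9)

    def test_zero_dominants_with_positive_mass_rejected(self):
        with pytest.raises(ConfigurationError):
            small_cfg(n_dominant_shared=0, dominant_mass=0.5)

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            small_cfg(group="mystery")


class TestSequencing:
    def test_read_counts_sum_exactly_to_depth(self):
        tables, _ = simulate_sequencing(sample_clone_universe(small_cfg()))
        for t in tables.values():
            assert t["read_count"].sum() == SMALL["depth"]

    def test_latent_frequency_recovered_within_binomial_bound(self):
        # one dominant clone at latent frequency 0.5, deep sequencing,
        # no decoys: observed frequency within 3 binomial SEs
        cfg = SynthConfig(seed=11, n_mice=1, n_dominant_shared=1,
                          dominant_mass=0.5, left_right_dominant_correlation=1.0,
                          nonproductive_fraction=0.0, singleton_decoy_fraction=0.0,
                          n_background_clones=3000, depth=1_000_000)
        coh = sample_clone_universe(cfg)
        dom_nt = coh.mice[0].clones.query("kind == 'dominant'")["cdr3_nt"].iloc[0]
        tables, _ = simulate_sequencing(coh)
        t = next(iter(tables.values()))
        obs = t.loc[t["cdr3_nt"] == dom_nt, "read_count"].sum() / t["read_count"].sum()
        assert abs(obs - 0.5) < 3 * np.sqrt(0.25 / cfg.depth) + 1e-9

    def test_nonproductive_decoys_removed_by_annotation_filter(self):
        cfg = small_cfg(nonproductive_fraction=0.3, singleton_decoy_fraction=0.0)
        tables, _ = simulate_sequencing(sample_clone_universe(cfg))
        t = next(iter(tables.values()))
        n_np = int((~t["productive"]).sum())
        # ~30% of the universe clones were injected as out-of-frame decoys
        n_real = int(t["productive"].sum())
        assert n_np == pytest.approx(0.3 * n_real, rel=0.25)
        rep = annotation_filter(aggregate(t))
        assert rep.clonotypes["productive"].all()
        survivors = set(rep.clonotypes["cdr3_nt"])
        assert not survivors & set(t.loc[~t["productive"], "cdr3_nt"])


class TestTimeDecay:
    def test_identity_at_factor_one(self):
        coh = sample_clone_universe(small_cfg())
        late = apply_time_decay(coh, decay_factor=1.0, timepoint_weeks=7.0)
        pd.testing.assert_frame_equal(late.mice[0].clones, coh.mice[0].clones)
        assert late.mice[0].timepoint_weeks == 7.0

    def test_dominant_mass_scaled_by_factor(self):
        coh = sample_clone_universe(small_cfg(dominant_mass=0.5))
        late = apply_time_decay(coh, decay_factor=0.3)
        dom = late.mice[0].clones.query("kind == 'dominant'")
        assert dom["freq_left"].sum() == pytest.approx(0.15, abs=1e-9)
        assert dom["freq_right"].sum() == pytest.approx(0.15, abs=1e-9)

    def test_early_dominants_persist_and_late_ones_are_private(self):
        coh = sample_clone_universe(small_cfg())
        late = apply_time_decay(coh, decay_factor=0.3)
        clones = late.mice[0].clones
        dom = clones.query("kind == 'dominant'")
        assert (dom["freq_left"] > 0).all() and (dom["freq_right"] > 0).all()
        newly = clones.query("kind == 'late_dominant'")
        assert len(newly) > 0
        one_sided = (newly["freq_left"] > 0) ^ (newly["freq_right"] > 0)
        assert one_sided.all()
        assert clones["freq_left"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_factor_rejected(self):
        coh = sample_clone_universe(small_cfg())
        with pytest.raises(ConfigurationError):
            apply_time_decay(coh, decay_factor=0.0)
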