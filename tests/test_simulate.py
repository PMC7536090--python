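import numpy as np
import pandas as pd
import pytest

import crmimic as cm
from crmimic.errors import ValidationError


def _config(**kwargs):
    defaults = dict(
        n_genes=120, probes_per_gene=(1, 3), n_signatures=4, genes_per_signature=10,
        noise_sd=0.25, effect_size=1.0, n_control=4, n_treated=3,
        n_compounds=3, conditions_per_compound=2,
        mimetic_compounds=("CPD_01",),
        mimetic_directions={"SIG_01": 1, "SIG_02": -1},
        seed=5,
    )
    defaults.update(kwargs)
    return cm.SimulationConfig(**defaults)


class TestSimulateStudy:
    def test_same_seed_is_bit_identical(self):
        a = cm.simulate_study(_config())
        b = cm.simulate_study(_config())
        pd.testing.assert_frame_equal(a.study.values, b.study.values, check_exact=True)
        assert a.signatures.signatures == b.signatures.signatures
        assert a.truth == b.truth

    def test_different_seed_changes_values(self):
        a = cm.simulate_study(_config())
        b = cm.simulate_study(_config(seed=6))
        assert not a.study.values.equals(b.study.values)

    def test_probe_gene_map_is_many_to_one(self):
        res = cm.simulate_study(_config())
        per_gene = res.study.probe_gene.value_counts()
        assert per_gene.max() >= 2  # some genes carry several probes
        assert set(res.study.probe_gene) <= {f"G{i:05d}" for i in range(1, 121)}

    def test_planted_effect_recovered_in_group_means(self):
        """delta=+1 on SIG_01 genes: treated-minus-control mean over the
        signature's probes is ~1.0; elsewhere ~0."""
        res = cm.simulate_study(_config(noise_sd=0.25))
        study = res.study
        up_genes = set(res.signatures.genes("SIG_01"))
        down_genes = set(res.signatures.genes("SIG_02"))
        on_up = study.probe_gene.isin(up_genes).to_numpy()
        on_down = study.probe_gene.isin(down_genes).to_numpy()
        off = ~(on_up | on_down)
        treated = study.values[study.samples_in_group("CPD_01_c1")].mean(axis=1)
        control = study.values[study.samples_in_group("CTRL")].mean(axis=1)
        diff = (treated - control).to_numpy()
        # each probe diff has sd = noise*sqrt(1/3 + 1/4); mean over probes
        probe_sd = 0.25 * np.sqrt(1 / 3 + 1 / 4)
        assert abs(diff[on_up].mean() - 1.0) < 4 * probe_sd / np.sqrt(on_up.sum())
        assert abs(diff[on_down].mean() + 1.0) < 4 * probe_sd / np.sqrt(on_down.sum())
        assert abs(diff[off].mean()) < 4 * probe_sd / np.sqrt(off.sum())

    def test_control_replicates_match_configured_noise(self):
        cfg = _config(n_control=60, probes_per_gene=1)
        res = cm.simulate_study(cfg)
        ctrl = res.study.values[res.study.samples_in_group("CTRL")]
        sds = ctrl.std(axis=1, ddof=1)
        # mean probe-level sd within 4 SE of the configured noise sd
        se_sd = cfg.noise_sd / np.sqrt(2 * (60 - 1)) / np.sqrt(len(sds))
        assert abs(sds.mean() - cfg.noise_sd) < 4 * se_sd

    def test_signatures_disjoint_by_default(self):
        res = cm.simulate_study(_config())
        seen: set[str] = set()
        for name in res.signatures.names():
            genes = set(res.signatures.genes(name))
            assert not (genes & seen)
            seen |= genes

    def test_manifest_consistent_with_study(self):
        res = cm.simulate_study(_config())
        assert len(res.manifest) == 6
        res.manifest.validate_against(res.study)
        keys = {c.key for c in res.manifest.conditions}
        assert len(keys) == 6

    def test_ground_truth_matches_layout(self):
        res = cm.simulate_study(_config())
        assert res.truth.mimetics == {"CPD_01": True, "CPD_02": False, "CPD_03": False}
        assert res.truth.direction("CPD_01_c1", "SIG_01") == 1
        assert res.truth.direction("CPD_01_c2", "SIG_02") == -1
        assert res.truth.direction("CPD_02_c1", "SIG_01") == 0
        assert res.truth.direction("CTRL", "SIG_01") == 0

    def test_decoy_compounds_receive_decoy_effects(self):
        res = cm.simulate_study(_config(
            decoy_compounds=("CPD_03",), decoy_directions={"SIG_04": 1}))
        assert res.truth.direction("CPD_03_c1", "SIG_04") == 1
        assert res.truth.direction("CPD_03_c1", "SIG_01") == 0


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,match", [
        (dict(n_genes=0), "n_genes"),
        (dict(noise_sd=0.0), "noise_sd"),
        (dict(n_control=1), "n_control"),
        (dict(mimetic_compounds=("NOPE",)), "NOPE"),
        (dict(mimetic_directions={"SIG_99": 1}), "SIG_99"),
        (dict(mimetic_directions={"SIG_01": 2}), "direction"),
        (dict(n_signatures=20, genes_per_signature=10), "disjoint"),
        (dict(probes_per_gene=(3, 1)), "probes_per_gene"),
    ])
    def test_invalid_config_rejected_before_generation(self, kwargs, match):
        with pytest.raises(ValidationError, match=match):
            cm.simulate_study(_config(**kwargs))


class TestBaitAndProbe:
    def test_shared_structure_independent_values(self):
        cfg = _config()
        directions = {"SIG_01": 1, "SIG_03": -1}
        pair = cm.simulate_bait_and_probe(cfg, directions, n_bait_samples=4)
        assert pair.bait_study.probes == pair.probe_study.probes
        pd.testing.assert_series_equal(pair.bait_study.probe_gene,
                                       pair.probe_study.probe_gene)
        assert pair.bait_study.samples_in_group("CR") == [f"CR_r{i}" for i in range(1, 5)]
        assert pair.truth.direction("CR", "SIG_01") == 1
        assert pair.truth.direction("CPD_01_c1", "SIG_01") == 1  # mimetic copies bait
        assert pair.truth.direction("CPD_02_c1", "SIG_01") == 0

    def test_deterministic(self):
        cfg = _config()
        directions = {"SIG_01": 1}
        a = cm.simulate_bait_and_probe(cfg, directions)
        b = cm.simulate_bait_and_probe(cfg, directions)
        pd.testing.assert_frame_equal(a.bait_study.values, b.bait_study.values,
                                      check_exact=True)
        pd.testing.assert_frame_equal(a.probe_study.values, b.probe_study.values,
                                      check_exact=True)

    def test_invalid_bait_direction_rejected(self):
        with pytest.raises(ValidationError, match="SIG_99"):
            cm.simulate_bait_and_probe(_config(), {"SIG_99": 1})

    def test_null_construction_keeps_groups_exchangeable(self):
        """delta plays no role for non-mimetic compounds: treated vs control
        mean difference is centred on zero."""
        cfg = _config(mimetic_compounds=(), mimetic_directions={})
        res = cm.simulate_study(cfg)
        treated = res.study.values[res.study.samples_in_group("CPD_02_c1")].mean(axis=1)
        control = res.study.values[res.study.samples_in_group("CTRL")].mean(axis=1)
        diff = (treated - control).to_numpy()
        se = cfg.noise_sd * np.sqrt(1 / 3 + 1 / 4) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se
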