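"""The generator: determinism, configured fractions, planted structure."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import small_config
from pvnet import ingest
from pvnet.network import build_drug_target_network
from pvnet.similarity import tanimoto
from pvnet.synthetic_data import (
    GeneratorConfig,
    expected_mean_degree,
    generate_adverse_annotations,
    generate_drug_target_data,
    generate_fingerprint_library,
    generate_study,
    paper_like_config,
    write_study,
)
from pvnet.topology import degree_distribution


class TestGenerateDrugTargetData:
    def test_isolated_counts_at_default_scale(self):
        data = generate_drug_target_data(paper_like_config(seed=0))
        active_w = {it.drug_id for it in data.interactions_withdrawn}
        isolated_w = [d for d in data.drugs_withdrawn if d.drug_id not in active_w]
        assert len(isolated_w) == 23  # round(66 * 0.3485)
        active_a = {it.drug_id for it in data.interactions_approved}
        isolated_a = [d for d in data.drugs_approved if d.drug_id not in active_a]
        assert len(isolated_a) == 131  # round(1411 * 0.0928)

    def test_determinism_same_seed(self, tmp_path):
        s1 = generate_study(small_config(seed=11))
        s2 = generate_study(small_config(seed=11))
        write_study(s1, tmp_path / "one")
        write_study(s2, tmp_path / "two")
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        d1 = generate_drug_target_data(small_config(seed=1))
        d2 = generate_drug_target_data(small_config(seed=2))
        assert d1.interactions_withdrawn != d2.interactions_withdrawn

    def test_empirical_mean_degree_matches_closed_form(self):
        cfg0 = small_config(n_withdrawn=400, n_targets_withdrawn=60)
        expected = expected_mean_degree(cfg0, "withdrawn")
        means = []
        for seed in range(10):
            data = generate_drug_target_data(small_config(seed=seed, n_withdrawn=400, n_targets_withdrawn=60))
            degs = {}
            for it in data.interactions_withdrawn:
                degs.setdefault(it.drug_id, set()).add(it.target_id)
            total = sum(len(v) for v in degs.values())
            means.append(total / len(data.drugs_withdrawn))
        assert abs(np.mean(means) - expected) < 0.5

    def test_large_network_bins_match_profile_within_2_points(self):
        cfg = paper_like_config(seed=3)
        data = generate_drug_target_data(cfg)
        net = build_drug_target_network(
            data.drugs_approved, data.targets_approved, data.interactions_approved
        )
        dist = degree_distribution(net, "drug")
        for pct, weight in zip(dist.bins.values(), cfg.degree_profile_approved):
            assert abs(pct - weight) < 2.0

    def test_infeasible_degree_demand_is_hard_error(self):
        cfg = small_config(
            n_targets_approved=10,
            n_targets_withdrawn=10,
            overlap_targets=5,
            degree_profile_approved=(10.0, 10.0, 10.0, 10.0, 60.0),  # >20 needs 21 targets
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_drug_target_data(cfg)

    def test_outputs_pass_ingest_validators(self, tmp_path, small_study):
        write_study(small_study, tmp_path)
        drugs = ingest.read_drug_table(tmp_path / "drugs_withdrawn.tsv")
        assert len(drugs) == small_study.config.n_withdrawn
        targets = ingest.read_target_table(tmp_path / "targets_withdrawn.tsv")
        inter = ingest.read_interaction_table(tmp_path / "interactions_withdrawn.tsv")
        net = build_drug_target_network(drugs, targets, inter, strict=True)
        assert net.is_bipartite_by_role()
        lib = ingest.read_fingerprints(tmp_path / "fingerprints_np.tsv")
        assert len(lib) == small_study.config.n_natural_products


class TestGenerateFingerprintLibrary:
    def test_planted_pair_at_085_within_tolerance(self):
        cfg = small_config(seed=5)
        libs = generate_fingerprint_library(
            cfg,
            planted_assignments=[("withdrawn", "W00000", "approved", "A00000", 0.85)],
        )
        t = tanimoto(libs.withdrawn["W00000"], libs.approved["A00000"])
        assert 0.83 <= t <= 0.87
        assert libs.planted[0].achieved_tanimoto == pytest.approx(t)

    def test_planted_pair_at_one_is_identical(self):
        cfg = small_config(seed=5)
        libs = generate_fingerprint_library(
            cfg,
            planted_assignments=[("withdrawn", "W00001", "approved", "A00001", 1.0)],
        )
        assert libs.withdrawn["W00001"] == libs.approved["A00001"]

    def test_background_pairs_stay_below_cutoff(self):
        cfg = GeneratorConfig(
            n_approved=500, n_withdrawn=0, n_natural_products=0,
            n_targets_approved=50, n_targets_withdrawn=28, seed=12,
            n_planted_probes=0, n_np_approved_only=0, n_np_withdrawn_only=0, n_np_both=0,
        )
        libs = generate_fingerprint_library(cfg)
        ids, mat = libs.approved.matrix()
        m = mat.astype(float)
        c = m @ m.T
        pop = m.sum(axis=1)
        denom = pop[:, None] + pop[None, :] - c
        sims = c / denom
        np.fill_diagonal(sims, 0.0)
        assert sims.max() < 0.7

    def test_unreachable_target_is_hard_error(self):
        cfg = small_config(n_bits=64, sparsity=0.9)
        with pytest.raises(ValueError, match="unreachable"):
            generate_fingerprint_library(
                cfg,
                planted_assignments=[("withdrawn", "W00000", "approved", "A00000", 0.05)],
            )


class TestGenerateAdverseAnnotations:
    IDS = [f"W{i:03d}" for i in range(66)]

    def test_two_multi_effect_drugs(self):
        anns = generate_adverse_annotations(self.IDS, multi_effect_count=2, seed=1)
        per_drug = {}
        for a in anns:
            per_drug[a.drug_id] = per_drug.get(a.drug_id, 0) + 1
        assert sum(1 for c in per_drug.values() if c >= 2) == 2
        assert sum(1 for c in per_drug.values() if c == 1) == 64

    def test_zero_multi_effect(self):
        anns = generate_adverse_annotations(self.IDS, multi_effect_count=0, seed=1)
        assert len(anns) == len(self.IDS)

    def test_deterministic(self):
        a1 = generate_adverse_annotations(self.IDS, multi_effect_count=2, seed=9)
        a2 = generate_adverse_annotations(self.IDS, multi_effect_count=2, seed=9)
        assert a1 == a2

    def test_errors(self):
        with pytest.raises(ValueError, match="vocabulary"):
            generate_adverse_annotations(self.IDS, effect_vocabulary=(), seed=0)
        with pytest.raises(ValueError, match="multi_effect_count"):
            generate_adverse_annotations(["W1"], multi_effect_count=2, seed=0)


class TestGenerateStudy:
    def test_planted_probes_and_flags_recorded(self, small_study):
        cfg = small_study.config
        assert len(small_study.planted_probes) == cfg.n_planted_probes
        assert len(small_study.planted_flags) == cfg.n_planted_probes * cfg.planted_flags_per_probe
        for _w, _a, t in small_study.planted_flags:
            assert t > 0.7

    def test_np_truth_counts_match_config(self, small_study):
        cfg = small_study.config
        counts = {}
        for cls in small_study.np_classes_truth.values():
            counts[cls] = counts.get(cls, 0) + 1
        assert counts["approved_only"] == cfg.n_np_approved_only
        assert counts["withdrawn_only"] == cfg.n_np_withdrawn_only
        assert counts["both"] == cfg.n_np_both
        assert sum(counts.values()) == cfg.n_natural_products

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(isolated_fraction_withdrawn=1.5)
        with pytest.raises(ValueError):
            small_config(overlap_targets=1000)
        with pytest.raises(ValueError):
            small_config(n_np_approved_only=10**6)
        with pytest.raises(ValueError):
            generate_study(small_config(n_planted_probes=20, overlap_targets=10))
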