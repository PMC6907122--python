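import dataclasses
import re

import numpy as np
import pytest

from comorbinet import ingest, stats, synthetic


class TestConfigValidation:
    def test_rejects_more_modules_than_diseases(self):
        with pytest.raises(ValueError, match="n_diseases"):
            synthetic.make_cohort_config(100, 3, 4)

    def test_rejects_boost_reaching_clamp(self):
        cfg = synthetic.make_cohort_config(100, 10, 2, mean_prevalence=0.05)
        base = dict(cfg.baseline_prevalence)
        base[cfg.codes[0]] = 0.5
        with pytest.raises(ValueError, match="clamp"):
            dataclasses.replace(cfg, baseline_prevalence=base, within_module_boost=2.0)

    def test_rejects_single_visit_range(self):
        with pytest.raises(ValueError, match="n_visits_range"):
            synthetic.make_cohort_config(10, 4, 2, n_visits_range=(1, 3))

    def test_risk_rule_validation(self):
        with pytest.raises(ValueError):
            synthetic.RiskRuleConfig("T00", frozenset({"T00"}), 0.8, 0.05)
        with pytest.raises(ValueError):
            synthetic.RiskRuleConfig("T00", frozenset({"A00"}), 0.05, 0.8)

    def test_molecular_config_validation(self):
        with pytest.raises(ValueError):
            synthetic.MolecularConfig(n_genes=10, n_pathways=2, genes_per_disease_range=(5, 20))
        with pytest.raises(ValueError):
            synthetic.MolecularConfig(n_genes=100, n_pathways=2, coupling=1.5)


class TestGenerateCohort:
    def test_determinism(self, small_cohort_config):
        a = synthetic.generate_cohort(small_cohort_config)
        b = synthetic.generate_cohort(small_cohort_config)
        assert a == b

    def test_visit_indices_within_configured_range(self, small_cohort, small_cohort_config):
        lo, hi = small_cohort_config.n_visits_range
        visits: dict[str, set[int]] = {}
        for rec in small_cohort:
            visits.setdefault(rec.patient_id, set()).add(rec.visit_index)
        assert all(max(v) <= hi - 1 and min(v) >= 0 for v in visits.values())
        # encounters are sampled per patient with >= 2 visits; encounters
        # without any diagnosis leave no records, but multi-visit patients
        # must dominate
        multi = sum(1 for v in visits.values() if len(v) >= 2)
        assert multi / len(visits) > 0.5

    def test_codes_are_icd10_like(self, small_cohort):
        pat = re.compile(r"^[A-Z]\d{3}$")
        assert all(pat.match(r.code) for r in small_cohort)

    def test_chapter_aligns_with_module(self, small_cohort_config):
        letters = {}
        for code, module in small_cohort_config.module_assignment.items():
            letters.setdefault(module, set()).add(code[0])
        assert all(len(s) == 1 for s in letters.values())
        assert len(set.union(*letters.values())) == small_cohort_config.n_modules

    def test_no_boost_gives_independent_pairs(self):
        # within-module phi within 3 SE of 0 when boost = 1
        cfg = synthetic.make_cohort_config(
            20_000, 10, 2, mean_prevalence=0.05, within_module_boost=1.0, seed=7
        )
        profiles = ingest.build_profiles(synthetic.generate_cohort(cfg))
        pair_stats = stats.count_contingency(
            profiles, n_patients=cfg.n_patients, include_zero_pairs=True
        )
        se = 1 / np.sqrt(cfg.n_patients)
        within = [
            p.phi
            for p in pair_stats
            if cfg.module_assignment[p.disease_i] == cfg.module_assignment[p.disease_j]
        ]
        assert within, "no within-module pairs materialized"
        for phi in within:
            assert abs(phi) < 3 * se

    def test_boost_orders_within_vs_between_rr(self, boosted_cohort_config, boosted_profiles):
        cfg = boosted_cohort_config
        pair_stats = stats.count_contingency(boosted_profiles)
        within = [
            p.rr for p in pair_stats
            if cfg.module_assignment[p.disease_i] == cfg.module_assignment[p.disease_j]
        ]
        between = [
            p.rr for p in pair_stats
            if cfg.module_assignment[p.disease_i] != cfg.module_assignment[p.disease_j]
        ]
        assert np.mean(within) > np.mean(between)

    def test_planted_phi_ordering(self, boosted_cohort_config, boosted_profiles):
        cfg = boosted_cohort_config
        pair_stats = stats.count_contingency(boosted_profiles, include_zero_pairs=True)
        within = np.array([
            p.phi for p in pair_stats
            if cfg.module_assignment[p.disease_i] == cfg.module_assignment[p.disease_j]
        ])
        between = np.array([
            p.phi for p in pair_stats
            if cfg.module_assignment[p.disease_i] != cfg.module_assignment[p.disease_j]
        ])
        se = np.sqrt(within.var() / len(within) + between.var() / len(between))
        assert within.mean() - between.mean() > 3 * se


class TestHierarchicalCohort:
    def test_determinism(self):
        cfg = synthetic.make_cohort_config(300, 24, 3, within_module_boost=6, seed=9)
        a, mapa = synthetic.generate_hierarchical_cohort(cfg, 2, n_hubs=2)
        b, mapb = synthetic.generate_hierarchical_cohort(cfg, 2, n_hubs=2)
        assert a == b and mapa == mapb

    def test_hub_codes_use_reserved_chapter(self):
        cfg = synthetic.make_cohort_config(100, 12, 3, within_module_boost=4, seed=2)
        _, modmap = synthetic.generate_hierarchical_cohort(cfg, 2, n_hubs=3)
        hubs = [c for c, m in modmap.items() if m == -1]
        assert len(hubs) == 3
        assert all(c.startswith("Z") for c in hubs)

    def test_flat_level_without_hubs_is_valid(self):
        cfg = synthetic.make_cohort_config(200, 12, 3, within_module_boost=4, seed=2)
        records, modmap = synthetic.generate_hierarchical_cohort(cfg, 1, n_hubs=0)
        assert records
        assert set(modmap) == set(cfg.codes)

    def test_invalid_depth_rejected(self):
        cfg = synthetic.make_cohort_config(50, 12, 3)
        with pytest.raises(ValueError):
            synthetic.generate_hierarchical_cohort(cfg, 0)


class TestMolecularTables:
    def test_determinism(self):
        modules = {f"A{i:03d}": i % 3 for i in range(12)}
        mcfg = synthetic.MolecularConfig(n_genes=300, n_pathways=10, coupling=0.5, seed=4)
        a = synthetic.generate_molecular_tables(modules, mcfg)
        b = synthetic.generate_molecular_tables(modules, mcfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_no_duplicate_genes_per_disease(self):
        modules = {f"A{i:03d}": i % 2 for i in range(10)}
        mcfg = synthetic.MolecularConfig(n_genes=200, n_pathways=5, coupling=0.7, seed=1)
        dg, _ = synthetic.generate_molecular_tables(modules, mcfg)
        assert not dg.duplicated().any()

    def test_full_coupling_guarantees_gene_sharing(self):
        # coupling 1, pool 30, 10 genes each: same-module overlap prob
        # 1 - C(20,10)/C(30,10) ~ 0.9997 (hypergeometric)
        modules = {f"A{i:03d}": 0 for i in range(60)}
        mcfg = synthetic.MolecularConfig(
            n_genes=600, n_pathways=5, genes_per_disease_range=(10, 10),
            coupling=1.0, module_pool_size=30, seed=3,
        )
        dg, _ = synthetic.generate_molecular_tables(modules, mcfg)
        genes = {d: set(g) for d, g in dg.groupby("disease")["gene"]}
        diseases = sorted(genes)
        share = [
            len(genes[a] & genes[b]) >= 1
            for i, a in enumerate(diseases)
            for b in diseases[i + 1 :]
        ]
        assert np.mean(share) > 0.95

    def test_zero_coupling_shares_like_random(self):
        # same-module and cross-module sharing rates statistically equal
        rng = np.random.default_rng(0)
        modules = {f"{'AB'[i % 2]}{i:03d}": i % 2 for i in range(80)}
        mcfg = synthetic.MolecularConfig(
            n_genes=400, n_pathways=5, genes_per_disease_range=(10, 10),
            coupling=0.0, module_pool_size=30, seed=5,
        )
        dg, _ = synthetic.generate_molecular_tables(modules, mcfg)
        genes = {d: set(g) for d, g in dg.groupby("disease")["gene"]}
        diseases = sorted(genes)
        same, diff = [], []
        for i, a in enumerate(diseases):
            for b in diseases[i + 1 :]:
                n_shared = len(genes[a] & genes[b])
                (same if modules[a] == modules[b] else diff).append(n_shared)
        same, diff = np.array(same), np.array(diff)
        se = np.sqrt(same.var() / len(same) + diff.var() / len(diff))
        assert abs(same.mean() - diff.mean()) < 3 * se

    def test_rejects_pool_overflow(self):
        modules = {f"A{i:03d}": i for i in range(10)}  # 10 modules
        with pytest.raises(ValueError, match="pool"):
            synthetic.generate_molecular_tables(
                modules, synthetic.MolecularConfig(n_genes=100, n_pathways=2, module_pool_size=30)
            )


class TestTrajectoryCohort:
    def make_rule(self, cfg, trigger=0.8, background=0.05, n_risk=2):
        codes = cfg.codes
        return synthetic.RiskRuleConfig(
            target_disease=codes[0],
            risk_diseases=frozenset(codes[1 : 1 + n_risk]),
            trigger_probability=trigger,
            background_probability=background,
        )

    def test_determinism(self):
        cfg = synthetic.make_cohort_config(200, 10, 2, mean_prevalence=0.1, seed=6)
        rule = self.make_rule(cfg)
        assert synthetic.generate_trajectory_cohort(cfg, rule) == synthetic.generate_trajectory_cohort(cfg, rule)

    def test_degenerate_probabilities(self):
        # trigger ~1, background ~0: target occurs iff a risk disease occurred
        # at some non-final visit, and only at later visits
        cfg = synthetic.make_cohort_config(2_000, 10, 2, mean_prevalence=0.2, seed=8)
        rule = self.make_rule(cfg, trigger=1.0 - 1e-12, background=1e-12)
        records = synthetic.generate_trajectory_cohort(cfg, rule)
        profiles = ingest.build_profiles(records)
        for prof in profiles:
            has_target = rule.target_disease in prof.disease_set
            risk_before_last = any(
                prof.visit_sequence[v] & rule.risk_diseases
                for v in range(prof.n_visits - 1)
            )
            assert has_target == risk_before_last
            if has_target:
                first_target = min(
                    v for v, s in enumerate(prof.visit_sequence) if rule.target_disease in s
                )
                first_risk = min(
                    v for v, s in enumerate(prof.visit_sequence) if s & rule.risk_diseases
                )
                assert first_target > first_risk

    def test_conditional_frequencies_recovered(self):
        cfg = synthetic.make_cohort_config(10_000, 20, 2, mean_prevalence=0.1, seed=12)
        rule = self.make_rule(cfg, trigger=0.8, background=0.05, n_risk=3)
        records = synthetic.generate_trajectory_cohort(cfg, rule)
        profiles = ingest.build_profiles(records)
        trig_hits = trig_n = bg_hits = bg_n = 0
        for prof in profiles:
            risk_seen = False
            for v, visit in enumerate(prof.visit_sequence):
                has_target = rule.target_disease in visit
                if risk_seen:
                    trig_n += 1
                    trig_hits += has_target
                else:
                    bg_n += 1
                    bg_hits += has_target
                if visit & rule.risk_diseases:
                    risk_seen = True
        assert abs(trig_hits / trig_n - 0.8) < 0.03
        assert abs(bg_hits / bg_n - 0.05) < 0.03

    def test_rejects_unknown_target(self):
        cfg = synthetic.make_cohort_config(10, 5, 1)
        rule = synthetic.RiskRuleConfig("X999", frozenset({cfg.codes[0]}), 0.8, 0.05)
        with pytest.raises(ValueError, match="universe"):
            synthetic.generate_trajectory_cohort(cfg, rule)


class TestIndependenceNull:
    def test_rr_mean_near_one_without_boost(self):
        # downstream RR over >= 1000 pairs has mean in [0.95, 1.05]
        cfg = synthetic.make_cohort_config(
            20_000, 50, 5, mean_prevalence=0.05, within_module_boost=1.0, seed=21
        )
        profiles = ingest.build_profiles(synthetic.generate_cohort(cfg))
        pair_stats = stats.count_contingency(
            profiles, n_patients=cfg.n_patients, include_zero_pairs=True
        )
        assert len(pair_stats) >= 1000
        mean_rr = np.mean([p.rr for p in pair_stats])
        assert 0.95 < mean_rr < 1.05
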