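"""End-to-end pipeline: cohort -> network -> topology -> communities -> validation -> prediction.

Driven by a single YAML/JSON config; every stage writes plain-text outputs
whose SHA-256 checksums are recorded in a JSON run manifest.  Stage seeds
are derived from the global seed and the stage name so each stage is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from comorbinet import community as community_mod
from comorbinet import ingest, molecular, stats, synthetic, topology, trajectory

logger = logging.getLogger(__name__)

STAGES = ("cohort", "network", "topology", "communities", "validation", "prediction")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict[str, Any]) -> None:
    has_records = "records" in cfg
    has_synth = "synthetic" in cfg
    if has_records == has_synth:
        raise ValueError("config must contain exactly one of 'records' and 'synthetic'")
    if "output_dir" not in cfg:
        raise ValueError("config must name an output_dir")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_config(block: dict[str, Any], seed: int) -> synthetic.CohortConfig:
    return synthetic.make_cohort_config(
        n_patients=int(block["n_patients"]),
        n_diseases=int(block["n_diseases"]),
        n_modules=int(block["n_modules"]),
        mean_prevalence=float(block.get("mean_prevalence", 0.02)),
        prevalence_sigma=float(block.get("prevalence_sigma", 0.0)),
        within_module_boost=float(block.get("within_module_boost", 1.0)),
        n_visits_range=tuple(block.get("n_visits_range", (2, 4))),
        seed=seed,
    )


def run_pipeline(cfg: dict[str, Any]) -> dict[str, Any]:
    """Execute all configured stages in dependency order and write a manifest.

    Returns the manifest (also written to ``<output_dir>/manifest.json``).
    Re-running with an identical config reproduces identical checksums.
    """
    validate_config(cfg)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    global_seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": global_seed,
        "stages": {},
    }

    def record_stage(name: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][name] = {
            "seed": stage_seed(global_seed, name),
            "outputs": {str(p.name): _sha256(p) for p in outputs.values()},
        }
        logger.info("stage %s complete: %s", name, sorted(p.name for p in outputs.values()))

    current = "cohort"
    try:
        # ---- cohort ------------------------------------------------------
        module_map: dict[str, int] | None = None
        if "synthetic" in cfg:
            block = cfg["synthetic"]
            c_seed = stage_seed(global_seed, "cohort")
            base = _cohort_config(block, c_seed)
            kind = block.get("kind", "flat")
            if kind == "flat":
                records = synthetic.generate_cohort(base)
                module_map = dict(base.module_assignment)
            elif kind == "hierarchical":
                records, module_map = synthetic.generate_hierarchical_cohort(
                    base,
                    nesting_depth=int(block.get("nesting_depth", 2)),
                    n_hubs=int(block.get("n_hubs", 4)),
                )
            elif kind == "trajectory":
                rr = block["risk_rule"]
                rule = synthetic.RiskRuleConfig(
                    target_disease=rr["target"],
                    risk_diseases=frozenset(rr["risks"]),
                    trigger_probability=float(rr["trigger"]),
                    background_probability=float(rr["background"]),
                )
                records = synthetic.generate_trajectory_cohort(base, rule)
                module_map = dict(base.module_assignment)
            else:
                raise ValueError(f"unknown synthetic cohort kind: {kind!r}")
            records_path = out_dir / "cohort.csv"
            ingest.write_records(records, records_path)
        else:
            records_path = Path(cfg["records"])
            records, _ = ingest.read_records(records_path)
        record_stage("cohort", {"records": records_path} if "synthetic" in cfg else {})
        profiles = ingest.build_profiles(records)

        # ---- network -----------------------------------------------------
        current = "network"
        thr = cfg.get("thresholds", {})
        # synthetic cohorts know their true population size (patients without
        # any diagnosis leave no records but still belong to N)
        n_pop = int(cfg["synthetic"]["n_patients"]) if "synthetic" in cfg else None
        pair_stats = stats.count_contingency(profiles, n_patients=n_pop)
        net = stats.build_network(
            pair_stats,
            min_cooccurrence=thr.get("min_cooccurrence", 5),
            min_rr=thr.get("min_rr", 1.0),
            min_phi=thr.get("min_phi", 0.0),
        )
        edges_path = out_dir / "edges.tsv"
        pairs_path = out_dir / "pairs.tsv"
        stats.export_network(net, edges_path, fmt="tsv")
        stats.pair_stats_to_frame(pair_stats).to_csv(pairs_path, sep="\t", index=False, float_format="%.17g")
        record_stage("network", {"edges": edges_path, "pairs": pairs_path})

        # ---- topology ----------------------------------------------------
        current = "topology"
        profile = topology.compute_topology(net)
        prof_path = out_dir / "topology.tsv"
        corr_path = out_dir / "correlations.tsv"
        profile.nodes.to_csv(prof_path, sep="\t", float_format="%.17g", index_label="node")
        topology.measure_correlations(profile).to_csv(
            corr_path, sep="\t", index=False, float_format="%.17g"
        )
        record_stage("topology", {"profile": prof_path, "correlations": corr_path})

        # ---- communities -------------------------------------------------
        current = "communities"
        part = community_mod.louvain(net, seed=stage_seed(global_seed, "communities"))
        part_path = out_dir / "partition.tsv"
        comp_path = out_dir / "composition.tsv"
        pd.DataFrame(
            sorted(part.assignment.items()), columns=["node", "community"]
        ).to_csv(part_path, sep="\t", index=False)
        community_mod.community_composition(part).to_csv(
            comp_path, sep="\t", index=False, float_format="%.17g"
        )
        record_stage("communities", {"partition": part_path, "composition": comp_path})

        # ---- validation --------------------------------------------------
        current = "validation"
        mol_cfg = cfg.get("molecular")
        if mol_cfg is not None:
            if "synthetic" in mol_cfg:
                mb = mol_cfg["synthetic"]
                if module_map is None:
                    module_map = {c: ord(c[0]) for c in sorted({p for s in pair_stats for p in (s.disease_i, s.disease_j)})}
                mconf = synthetic.MolecularConfig(
                    n_genes=int(mb["n_genes"]),
                    n_pathways=int(mb["n_pathways"]),
                    genes_per_disease_range=tuple(mb.get("genes_per_disease_range", (5, 15))),
                    coupling=float(mb.get("coupling", 0.0)),
                    pathway_size_range=tuple(mb.get("pathway_size_range", (10, 50))),
                    module_pool_size=int(mb.get("module_pool_size", 30)),
                    seed=stage_seed(global_seed, "validation"),
                )
                dg_df, pg_df = synthetic.generate_molecular_tables(module_map, mconf)
                dg_path, pg_path = out_dir / "disease_gene.tsv", out_dir / "pathway_gene.tsv"
                dg_df.to_csv(dg_path, sep="\t", index=False)
                pg_df.to_csv(pg_path, sep="\t", index=False)
            else:
                dg_path, pg_path = Path(mol_cfg["disease_gene"]), Path(mol_cfg["pathway_gene"])
            disease_genes, _, disease_pathways = ingest.read_molecular_tables(dg_path, pg_path)
            pairs = [(p.disease_i, p.disease_j) for p in pair_stats]
            overlaps = molecular.overlap_statistics(pairs, disease_genes, disease_pathways)
            report = molecular.correlate_comorbidity_with_molecular(pair_stats, overlaps)
            curve = molecular.binned_strength_curve(pair_stats, overlaps)
            rep_path, bin_path = out_dir / "validation.tsv", out_dir / "strength_bins.tsv"
            report.to_csv(rep_path, sep="\t", index=False, float_format="%.17g")
            curve.to_csv(bin_path, sep="\t", index=False, float_format="%.17g")
            record_stage(
                "validation",
                {"disease_gene": dg_path, "pathway_gene": pg_path, "report": rep_path, "bins": bin_path},
            )

        # ---- prediction --------------------------------------------------
        current = "prediction"
        pred_cfg = cfg.get("prediction")
        if pred_cfg is not None:
            target: str | frozenset[str] = pred_cfg["target"]
            if isinstance(target, list):
                target = frozenset(target)
            dataset = trajectory.build_dataset(profiles, target)
            p_seed = stage_seed(global_seed, "prediction")
            spec_ = trajectory.BenchmarkSpec(
                target_disease=str(pred_cfg["target"]),
                n_positive=int(pred_cfg["n_positive"]),
                n_negative=int(pred_cfg["n_negative"]),
                sampling_seed=p_seed,
            )
            bench = trajectory.assemble_benchmark(dataset, spec_)
            models = trajectory.default_models(p_seed)
            wanted = pred_cfg.get("models")
            if wanted:
                models = {k: v for k, v in models.items() if k in wanted}
            report_ = trajectory.train_evaluate(
                bench, models, n_folds=int(pred_cfg.get("n_folds", 10)), seed=p_seed
            )
            ranked = trajectory.extract_risk_features(
                report_.fitted, bench.feature_names, k=int(pred_cfg.get("top_k", 10))
            )
            met_path = out_dir / "prediction_metrics.tsv"
            report_.metrics.to_csv(met_path, sep="\t", index=False, float_format="%.17g")
            risk_path = out_dir / "risk_factors.tsv"
            frames = []
            for name, df in sorted(ranked.items()):
                df = df.copy()
                df.insert(0, "model", name)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                risk_path, sep="\t", index=False, float_format="%.17g"
            )
            record_stage("prediction", {"metrics": met_path, "risk_factors": risk_path})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
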