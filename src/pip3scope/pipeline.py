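"""End-to-end orchestration: simulate → de → sets → cluster → motifs →
compare → enrich → qc, with stage logging, checksums and a summary report.

Every stage consumes and produces plain TSV files in the run directory,
so any stage can be re-run standalone; all randomness flows from the
named seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pip3scope import cluster_stability, motif_activity, set_logic, stats_compare
from pip3scope.core_io import (
    Dataset,
    GeneSetCollection,
    read_dataset,
    read_motif_matrix,
    write_dataset,
    write_gene_sets,
    write_motif_matrix,
)
from pip3scope.de_engine import ComparisonSpec, DEResult, run_comparison
from pip3scope.synthetic_data import (
    GeneratorConfig,
    generate_annotation,
    generate_dataset,
    write_truth,
)


@dataclasses.dataclass
class PipelineConfig:
    """Paths, seeds, comparison names and thresholds for one run."""

    out_dir: str = "pip3scope_run"
    seed: int = 0
    generator: dict = dataclasses.field(default_factory=dict)
    alpha_pairwise: float = 0.05
    alpha_timecourse: float = 0.01
    jaccard_median: float = 0.75
    jaccard_sd_frac: float = 0.10
    s_threshold: float = 20.0
    z_threshold: float = 2.0
    n_boot: int = 100
    k_max: int = 6
    cluster_max_genes: int = 150
    cluster_sets: tuple[str, ...] = ("set1", "set2", "set3", "set4")
    compare_sets: tuple[str, str] = ("A", "B")
    ridge_lambda: object = "cv"

    def validate(self) -> None:
        for name in ("alpha_pairwise", "alpha_timecourse"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not 0 < self.jaccard_median <= 1:
            raise ValueError("jaccard_median outside (0, 1]")
        if not 0 < self.jaccard_sd_frac <= 1:
            raise ValueError("jaccard_sd_frac outside (0, 1]")
        if self.n_boot < 1 or self.k_max < 2:
            raise ValueError("n_boot must be >= 1 and k_max >= 2")
        if self.s_threshold < 0 or self.z_threshold < 0:
            raise ValueError("score/z thresholds must be non-negative")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def standard_comparisons(
    alpha_pairwise: float = 0.05, alpha_timecourse: float = 0.01
) -> dict[str, ComparisonSpec]:
    """The seven named contrasts of the study design."""
    return {
        "basal_pi3k": ComparisonSpec(
            "basal_pi3k", "pairwise", "A66_noEGF", "WT",
            time_a=300, time_b=0, alpha=alpha_pairwise,
        ),
        "induced_pi3k": ComparisonSpec(
            "induced_pi3k", "interaction", "A66", "WT", alpha=alpha_timecourse
        ),
        "egf_dep_wt": ComparisonSpec(
            "egf_dep_wt", "timecourse", "WT", alpha=alpha_timecourse
        ),
        "chronic_pten": ComparisonSpec(
            "chronic_pten", "pairwise", "PTEN_KO", "WT",
            time_a=0, time_b=0, alpha=alpha_pairwise,
        ),
        "chronic_pik3ca": ComparisonSpec(
            "chronic_pik3ca", "pairwise", "PIK3CA_H1047R", "WT",
            time_a=0, time_b=0, alpha=alpha_pairwise,
        ),
        "induced_pten": ComparisonSpec(
            "induced_pten", "interaction", "PTEN_KO", "WT", alpha=alpha_timecourse
        ),
        "induced_pik3ca": ComparisonSpec(
            "induced_pik3ca", "interaction", "PIK3CA_H1047R", "WT",
            alpha=alpha_timecourse,
        ),
    }


def run_de_stage(dataset: Dataset, cfg: PipelineConfig, out_dir: Path, log):
    results: dict[str, DEResult] = {}
    for name, spec in standard_comparisons(cfg.alpha_pairwise, cfg.alpha_timecourse).items():
        t0 = time.perf_counter()
        res = run_comparison(dataset, spec)
        results[name] = res
        res.table.rename_axis("gene_id").to_csv(out_dir / f"de_{name}.tsv", sep="\t")
        log(
            f"de:{name} design={spec.design_kind} alpha={spec.alpha} "
            f"n_significant={len(res.significant)} wall={time.perf_counter() - t0:.1f}s"
        )
    return results


def build_gene_sets(results: dict[str, DEResult], universe: set[str]):
    """Venn sets 1–4, A–H and the coherence filter from named DE results."""
    wt = set_logic.build_wt_sets(
        results["basal_pi3k"].significant,
        results["induced_pi3k"].significant,
        results["egf_dep_wt"].significant,
    )
    induced_combined = (
        results["induced_pten"].significant | results["induced_pik3ca"].significant
    )
    mut = set_logic.build_mutant_sets(
        results["chronic_pten"].significant,
        results["chronic_pik3ca"].significant,
        induced_combined,
        results["egf_dep_wt"].significant,
    )
    outcomes = set_logic.signed_outcomes(results).rename(
        columns={"induced_pi3k": "a66_vs_wt", "basal_pi3k": "a66_noegf"}
    )
    coherent_up, coherent_down = set_logic.coherence_filter(outcomes)
    sets = {k: v for k, v in wt.items() if not k.startswith("_")}
    sets.update({k: v for k, v in mut.items() if not k.startswith("_")})
    sets["coherent_up"] = coherent_up
    sets["coherent_down"] = coherent_down
    return GeneSetCollection(sets=sets, universe=set(universe))


def run_all(config: PipelineConfig):
    """Execute the full pipeline on a synthetic dataset; returns the run dir.

    Any stage error aborts with the failing stage named; partial outputs
    are retained and MANIFEST.tsv marks the run incomplete.
    """
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    stage = "simulate"
    summary: dict = {"seed": cfg.seed}
    try:
        # --- simulate ---
        t0 = time.perf_counter()
        gen_cfg = GeneratorConfig(seed=cfg.seed, **cfg.generator)
        dataset, truth = generate_dataset(gen_cfg)
        ann, designated = generate_annotation(truth, seed=cfg.seed + 1)
        dataset.genes["terms"] = ann.loc[dataset.genes.index]
        write_dataset(dataset, out)
        write_motif_matrix(truth.motif_sites, truth.promoter_map, out / "promoters.tsv")
        write_truth(truth, out / "truth.tsv")
        log(
            f"simulate seed={cfg.seed} n_genes={gen_cfg.n_genes} "
            f"n_samples={len(dataset.samples)} wall={time.perf_counter() - t0:.1f}s"
        )

        # --- de ---
        stage = "de"
        results = run_de_stage(dataset, cfg, out, log)

        # --- sets ---
        stage = "sets"
        collection = build_gene_sets(results, set(dataset.gene_ids))
        write_gene_sets(collection, out / "genesets.tsv")
        sizes = {k: len(v) for k, v in collection.sets.items()}
        pd.Series(sizes, name="n_genes").rename_axis("set_label").to_csv(
            out / "set_sizes.tsv", sep="\t"
        )
        summary["set_sizes"] = sizes
        n_chronic = len(
            results["chronic_pten"].significant | results["chronic_pik3ca"].significant
        )
        n_acute = max(len(results["induced_pi3k"].significant), 1)
        summary["butterfly_ratio"] = n_chronic / n_acute
        log(f"sets sizes={sizes} butterfly_ratio={summary['butterfly_ratio']:.2f}")

        # --- cluster ---
        stage = "cluster"
        from pip3scope.de_engine import normalize

        norm = normalize(dataset, "sizefactor")
        rng = np.random.default_rng(cfg.seed + 1000)
        cluster_rows, stab_rows = [], []
        summary["optimal_k"] = {}
        for label in cfg.cluster_sets:
            genes = sorted(collection.sets.get(label, set()))
            if len(genes) < 40:
                log(f"cluster:{label} skipped (only {len(genes)} genes)")
                continue
            if len(genes) > cfg.cluster_max_genes:
                genes = sorted(
                    rng.choice(genes, size=cfg.cluster_max_genes, replace=False)
                )
            X, _ = cluster_stability.scale_center_profiles(norm.loc[genes].to_numpy())
            report = cluster_stability.stability_profile(
                X,
                k_max=cfg.k_max,
                n_boot=cfg.n_boot,
                seed=cfg.seed + 2000,
                median_threshold=cfg.jaccard_median,
                sd_fraction=cfg.jaccard_sd_frac,
            )
            summary["optimal_k"][label] = report.optimal_k
            k_use = report.optimal_k or 2
            sol = report.solutions[k_use]
            cluster_rows.extend(
                (g, label, k_use, int(c)) for g, c in zip(genes, sol.labels)
            )
            for k in report.k_values:
                for c in range(k):
                    stab_rows.append(
                        (
                            label,
                            k,
                            c + 1,
                            report.median[k][c],
                            report.sd[k][c],
                            bool(report.stable[k][c]),
                        )
                    )
            log(f"cluster:{label} n={len(genes)} optimal_k={report.optimal_k}")
        pd.DataFrame(
            cluster_rows, columns=["gene_id", "set_label", "k_opt", "cluster"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(
            stab_rows,
            columns=["set_label", "k", "cluster", "median_jaccard", "sd_jaccard", "stable"],
        ).to_csv(out / "stability.tsv", sep="\t", index=False)

        # --- motifs ---
        stage = "motifs"
        t0 = time.perf_counter()
        sites, promoter_map = read_motif_matrix(out / "promoters.tsv")
        E = motif_activity.promoter_expression(dataset, promoter_map)
        model = motif_activity.fit_motif_activities(
            E, sites, ridge_lambda=cfg.ridge_lambda, cv_seed=cfg.seed + 3000
        )
        scores = motif_activity.dedup_to_genes(
            motif_activity.target_scores(model, sites), promoter_map
        )
        strong = motif_activity.strongly_regulated(
            scores, model, collection, cfg.s_threshold, cfg.z_threshold
        )
        model.activities.rename_axis("motif").to_csv(out / "activities.tsv", sep="\t")
        model.z_values.rename_axis("motif").to_csv(out / "motif_z.tsv", sep="\t")
        scores.s_m.rename_axis("gene_id").to_csv(out / "sm_scores.tsv", sep="\t")
        strong.to_csv(out / "strong_targets.tsv", sep="\t", index=False)
        top_z = model.z_values.sort_values(ascending=False).head(5)
        summary["top_motifs_by_z"] = {m: float(z) for m, z in top_z.items()}
        log(
            f"motifs lambda={model.ridge_lambda:.3g} n_strong={len(strong)} "
            f"wall={time.perf_counter() - t0:.1f}s"
        )

        # --- compare ---
        stage = "compare"
        set_a = collection.sets.get(cfg.compare_sets[0], set())
        set_b = collection.sets.get(cfg.compare_sets[1], set())
        if set_a and set_b:
            comp = stats_compare.compare_sm_distributions(
                scores, set_a, set_b, model, z_threshold=cfg.z_threshold
            )
            comp.table.to_csv(out / "comparison.tsv", sep="\t", index=False)
            if len(comp.table):
                summary["top_motif_by_d"] = str(comp.table.iloc[0]["motif"])
            log(f"compare {cfg.compare_sets} n_motifs={len(comp.table)}")
        else:
            log(f"compare skipped: empty set among {cfg.compare_sets}")

        # --- enrich ---
        stage = "enrich"
        ann_series = dataset.genes["terms"]
        universe = set(dataset.gene_ids)
        enrich_rows = []
        for label in ("set1", "set2", "set3", "set4", "coherent_up", "coherent_down"):
            members = collection.sets.get(label, set())
            if not members:
                continue
            table = stats_compare.fisher_enrichment(members, universe, ann_series)
            table.insert(0, "set_label", label)
            enrich_rows.append(table)
        if enrich_rows:
            pd.concat(enrich_rows, ignore_index=True).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
        log("enrich done")

        # --- qc ---
        stage = "qc"
        corr = stats_compare.sample_correlation_matrix(norm)
        coords, frac = stats_compare.pca_samples(norm)
        corr.rename_axis("sample_id").to_csv(out / "corr.tsv", sep="\t")
        coords.iloc[:, :5].rename_axis("sample_id").to_csv(
            out / "pca.tsv", sep="\t"
        )
        summary["pc_variance_fractions"] = [float(f) for f in frac[:3]]
        log("qc done")

        stage = "summary"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        _write_manifest(out, complete=True)
        log("run complete")
    except Exception as exc:
        _write_manifest(out, complete=False)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _write_manifest(out: Path, complete: bool) -> None:
    rows = []
    for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append((path.name, digest))
    rows.append(("__status__", "complete" if complete else "INCOMPLETE"))
    pd.DataFrame(rows, columns=["file", "sha256"]).to_csv(
        out / "MANIFEST.tsv", sep="\t", index=False
    )


def manifest_checksums(out_dir) -> dict[str, str]:
    df = pd.read_csv(Path(out_dir) / "MANIFEST.tsv", sep="\t")
    return dict(zip(df["file"], df["sha256"]))
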