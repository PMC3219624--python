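"""Pipeline configuration and the end-to-end driver.

``run_pipeline`` executes the stages in method order --
simulate -> fitness -> zscores -> phenotypes -> cofitness -> qc -> predict
-> regulon -- against an output directory, writing every result as a
stamped TSV. Each stage can also be run on its own (it reads its inputs
back from the directory), which is what the command-line interface exposes.

A single global seed is expanded deterministically into per-stage seeds, so
the same configuration and seed always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    compendium,
    function_prediction,
    gene_scoring,
    io,
    strain_fitness,
    synthetic,
)
from .util import ParameterError, StageError, derive_seed

logger = logging.getLogger(__name__)

STAGES = ["simulate", "fitness", "zscores", "phenotypes", "cofitness", "qc",
          "predict", "regulon"]


@dataclass
class PipelineConfig:
    """Flat parameter set for an end-to-end run.

    The simulation block fixes the synthetic compendium (genome size, pool
    structure, noise levels); the analysis block holds the method's
    documented constants (5x detection, 2% start filter, central 5--80%
    insertion window, P<0.001 phenotype test, Bonferroni alpha 0.01,
    sick/healthy thresholds -2/-1, |fitness|>1 & |Z|>2.5 change gates,
    20 significance bins, 10 operon-wise CV folds, 500 trees).
    """

    # simulation
    n_genes: int = 400
    megaplasmid_fraction: float = 0.04
    mean_operon_size: float = 2.5
    n_subroles: int = 8
    subrole_fraction: float = 0.25
    n_insertions: int = 800
    intergenic_fraction: float = 0.05
    n_tag_modules: int = 0            # 0 = automatic (strains + spare)
    plate_size: int = 96
    detect_failure_rate: float = 0.02
    both_pool_fraction: float = 0.4
    n_conditions: int = 40
    n_controls: int = 14
    sparsity: float = 0.05
    effect_scale: float = 2.0
    operon_share: float = 0.75
    edge_attenuation: float = 0.5
    probe_sd: float = 0.25
    plate_sd: float = 0.25
    replicon_shift: float = 0.25
    background_level: float = 5.0
    n_probes: int = 5
    n_tfs: int = 10
    targets_per_tf: int = 4
    expression_experiments: int = 60
    expression_coupling: float = 0.6
    # analysis
    detect_multiplier: float = 5.0
    low_start_fraction: float = 0.02
    good_window_low: float = 0.05
    good_window_high: float = 0.80
    phenotype_alpha: float = 0.001
    bonferroni_alpha: float = 0.01
    sick_thresh: float = -2.0
    healthy_thresh: float = -1.0
    change_fitness_gate: float = 1.0
    change_z_gate: float = 2.5
    n_bins: int = 20
    cv_folds: int = 10
    n_trees: int = 500
    min_cofit_experiments: int = 10
    cofit_report_threshold: float = 0.4
    n_shuffles: int = 100
    plate_normalization: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_genes >= 10, "n_genes must be >= 10"),
            (0 <= self.megaplasmid_fraction < 1, "megaplasmid_fraction in [0,1)"),
            (self.mean_operon_size >= 1, "mean_operon_size must be >= 1"),
            (self.n_insertions >= 1, "n_insertions must be >= 1"),
            (0 <= self.intergenic_fraction <= 1, "intergenic_fraction in [0,1]"),
            (self.n_controls >= 2, "n_controls must be >= 2"),
            (0 <= self.sparsity <= 1, "sparsity in [0,1]"),
            (self.probe_sd > 0, "probe_sd must be > 0"),
            (self.detect_multiplier > 0, "detect_multiplier must be > 0"),
            (0 <= self.low_start_fraction < 1, "low_start_fraction in [0,1)"),
            (0 <= self.good_window_low <= self.good_window_high <= 1,
             "good window must satisfy 0 <= low <= high <= 1"),
            (0 < self.phenotype_alpha < 1, "phenotype_alpha in (0,1)"),
            (0 < self.bonferroni_alpha < 1, "bonferroni_alpha in (0,1)"),
            (self.sick_thresh < self.healthy_thresh, "sick_thresh < healthy_thresh"),
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (self.n_trees >= 1, "n_trees must be >= 1"),
            (self.seed >= 0, "seed must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path} line {ln}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParameterError(f"{path} line {ln}: unknown key {key!r}")
            kwargs[key] = _coerce(value, fields[key])
        return cls(**kwargs)

    def hash(self) -> str:
        return io.config_hash(dataclasses.asdict(self))

    def stamp(self, seed: int | None = None) -> list[str]:
        s = self.seed if seed is None else seed
        return [f"poolfit config_hash={self.hash()} seed={s}"]


def _coerce(value: str, typ: str):
    t = str(typ)
    if "bool" in t:
        return value.lower() in ("1", "true", "yes", "on")
    if "int" in t:
        return int(value)
    if "float" in t:
        return float(value)
    return value


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    seed = config.seed
    genome = synthetic.simulate_genome(
        config.n_genes, config.megaplasmid_fraction, config.mean_operon_size,
        config.n_subroles, seed=derive_seed(seed, "genome"),
        subrole_fraction=config.subrole_fraction)
    strains = synthetic.simulate_insertion_library(
        genome, config.n_insertions, config.intergenic_fraction,
        seed=derive_seed(seed, "library"))
    pools = synthetic.assemble_pools(
        strains, n_tag_modules=config.n_tag_modules or None,
        plate_size=config.plate_size,
        detect_failure_rate=config.detect_failure_rate,
        both_pool_fraction=config.both_pool_fraction,
        seed=derive_seed(seed, "pools"))
    truth = synthetic.simulate_truth(
        genome, config.n_conditions, config.n_controls, config.sparsity,
        config.effect_scale, config.operon_share,
        seed=derive_seed(seed, "truth"), edge_attenuation=config.edge_attenuation)
    table = synthetic.simulate_intensities(
        pools, truth, probe_sd=config.probe_sd, plate_sd=config.plate_sd,
        replicon_shift=config.replicon_shift,
        background_level=config.background_level, n_probes=config.n_probes,
        seed=derive_seed(seed, "intensities"))
    regulons = synthetic.simulate_regulons(
        genome, config.n_tfs, config.targets_per_tf,
        seed=derive_seed(seed, "regulons"))
    expression = synthetic.simulate_expression(
        genome, regulons, config.expression_experiments,
        coupling=config.expression_coupling, seed=derive_seed(seed, "expression"))

    stamp = config.stamp()
    io.write_genes(genome, out / "genes.tsv", stamp=stamp)
    io.write_strains(pools.strains, out / "strains.tsv", stamp=stamp)
    io.write_experiments(table.experiments, out / "experiments.tsv", stamp=stamp)
    io.write_intensities(table.intensities, out / "intensities.tsv", stamp=stamp)
    io.write_truth(truth.matrix, out / "truth.tsv", stamp=stamp)
    io.write_matrix(expression, out / "expression.tsv", stamp=stamp)
    io.write_table(pd.DataFrame(regulons, columns=["tf", "target"]),
                   out / "regulons.tsv", stamp=stamp)
    # pool provenance the schema does not carry but downstream needs
    io.write_table(pools.strains[["strain_id", "pool", "undetectable"]],
                   out / "pool_flags.tsv", stamp=stamp)
    counts = {"genes": len(genome.genes), "strains": len(strains),
              "memberships": len(pools.strains),
              "hybridizations": len(table.experiments)}
    logger.info("simulate: %s", counts)
    return counts


def _load_inputs(out: Path):
    genome = io.read_genome(out / "genes.tsv")
    strains = io.read_strains(out / "strains.tsv", genome.genes)
    table = io.read_intensity_table(out / "intensities.tsv", out / "experiments.tsv")
    return genome, strains, table


def stage_fitness(config: PipelineConfig, out: Path) -> dict:
    genome, strains, table = _load_inputs(out)
    matrix = strain_fitness.compute_strain_fitness(
        table, strains, genome,
        detect_multiplier=config.detect_multiplier,
        low_start_fraction=config.low_start_fraction,
        plate_pass=config.plate_normalization)
    io.write_matrix(matrix.values, out / "strain_fitness.tsv", stamp=config.stamp())
    logger.info("fitness: %s", matrix.stats)
    return matrix.stats


def _rebuild_matrix(config: PipelineConfig, out: Path) -> strain_fitness.StrainFitnessMatrix:
    genome = io.read_genome(out / "genes.tsv")
    strains = io.read_strains(out / "strains.tsv", genome.genes)
    experiments = io.read_experiments(out / "experiments.tsv")
    values = io.read_matrix(out / "strain_fitness.tsv",
                            index_cols=["strain_id", "pool"])
    prov = strain_fitness.strain_provenance(strains, genome).loc[values.index]
    fit_exps = experiments[experiments["class"].isin(["condition", "control"])]
    return strain_fitness.StrainFitnessMatrix(
        values=values, provenance=prov, experiments=fit_exps)


def stage_zscores(config: PipelineConfig, out: Path) -> dict:
    matrix = _rebuild_matrix(config, out)
    scores = gene_scoring.score_genes(
        matrix, alpha=config.phenotype_alpha,
        fitness_gate=config.change_fitness_gate, z_gate=config.change_z_gate,
        window=(config.good_window_low, config.good_window_high))
    stamp = config.stamp()
    io.write_matrix(scores.fitness.rename_axis("gene_id"),
                    out / "gene_fitness.tsv", stamp=stamp)
    io.write_matrix(scores.z.rename_axis("gene_id"), out / "zscores.tsv", stamp=stamp)
    counts = {"genes_scored": len(scores.fitness), "psi": round(scores.psi, 4)}
    logger.info("zscores: %s", counts)
    return counts


def _load_scores(config: PipelineConfig, out: Path) -> gene_scoring.GeneScores:
    matrix = _rebuild_matrix(config, out)
    return gene_scoring.score_genes(
        matrix, alpha=config.phenotype_alpha,
        fitness_gate=config.change_fitness_gate, z_gate=config.change_z_gate,
        window=(config.good_window_low, config.good_window_high))


def stage_phenotypes(config: PipelineConfig, out: Path) -> dict:
    scores = _load_scores(config, out)
    experiments = io.read_experiments(out / "experiments.tsv")
    n_cond = int((experiments["class"] == "condition").sum())
    zstar = gene_scoring.bonferroni_z_threshold(config.bonferroni_alpha, n_cond)
    strong = gene_scoring.strong_pattern_genes(scores.phenotypes, scores.z, zstar)
    phen = scores.phenotypes.copy()
    phen["strong_pattern"] = phen.index.isin(strong)
    phen = phen.join(scores.changes)
    io.write_matrix(phen.rename_axis("gene_id"), out / "phenotypes.tsv",
                    float_format="%.6g", stamp=config.stamp())
    counts = {"significant": int(phen["significant"].sum()),
              "strong_pattern": int(phen["strong_pattern"].sum()),
              "bonferroni_z": round(zstar, 3)}
    logger.info("phenotypes: %s", counts)
    return counts


def stage_cofitness(config: PipelineConfig, out: Path) -> dict:
    fitness = io.read_matrix(out / "gene_fitness.tsv", index_cols=["gene_id"])
    experiments = io.read_experiments(out / "experiments.tsv")
    cond = experiments.loc[experiments["class"] == "condition", "experiment_id"]
    cof = compendium.cofitness(
        fitness[[c for c in cond if c in fitness.columns]],
        min_experiments=config.min_cofit_experiments,
        report_threshold=config.cofit_report_threshold)
    io.write_table(cof, out / "cofitness.tsv", stamp=config.stamp())
    counts = {"pairs_reported": len(cof)}
    logger.info("cofitness: %s", counts)
    return counts


def stage_qc(config: PipelineConfig, out: Path) -> dict:
    matrix = _rebuild_matrix(config, out)
    genome = io.read_genome(out / "genes.tsv")
    fitness = io.read_matrix(out / "gene_fitness.tsv", index_cols=["gene_id"])
    pairs = genome.operon_pairs()
    qc = compendium.experiment_qc(matrix, pairs, fitness)
    io.write_table(qc, out / "qc.tsv", stamp=config.stamp())
    experiments = io.read_experiments(out / "experiments.tsv")
    cond = [c for c in experiments.loc[experiments["class"] == "condition",
                                       "experiment_id"] if c in fitness.columns]
    pol = compendium.polarity_counts(
        fitness[cond], pairs,
        sick_thresh=config.sick_thresh, healthy_thresh=config.healthy_thresh)
    (out / "polarity.txt").write_text(
        f"up_only\t{pol.up_only}\ndown_only\t{pol.down_only}\n"
        f"binomial_pvalue\t{pol.pvalue:.6g}\n")
    counts = {"up_only": pol.up_only, "down_only": pol.down_only,
              "polarity_p": pol.pvalue}
    logger.info("qc: %s", counts)
    return counts


def stage_predict(config: PipelineConfig, out: Path) -> dict:
    genome = io.read_genome(out / "genes.tsv")
    fitness = io.read_matrix(out / "gene_fitness.tsv", index_cols=["gene_id"])
    labels_table = pd.DataFrame({
        "gene_id": genome.genes["gene_id"],
        "role": "assigned",
        "subrole": genome.genes["subrole"].replace(io.MISSING, np.nan),
    })
    labels_table = function_prediction.filter_subroles(labels_table.dropna())
    labels = labels_table.set_index("gene_id")["subrole"]
    features = function_prediction.prepare_features(fitness)
    operon_of = genome.genes.set_index("gene_id")["operon_id"]
    folds = function_prediction.operonwise_folds(
        operon_of, k=config.cv_folds, seed=derive_seed(config.seed, "folds"))
    preds = function_prediction.predict_subroles(
        features, labels, folds, n_trees=config.n_trees,
        seed=derive_seed(config.seed, "forest"))
    io.write_table(preds, out / "predictions.tsv", stamp=config.stamp())
    evaluable = preds[preds["correct"].notna()]
    counts = {"labeled": len(evaluable),
              "accuracy": round(float(evaluable["correct"].astype(bool).mean()), 3)
              if len(evaluable) else None}
    logger.info("predict: %s", counts)
    return counts


def stage_regulon(config: PipelineConfig, out: Path) -> dict:
    expression = io.read_matrix(out / "expression.tsv", index_cols=["gene_id"])
    pairs = io.read_table(out / "regulons.tsv")
    result = function_prediction.regulon_correlation(
        pairs, expression, n_shuffles=config.n_shuffles,
        seed=derive_seed(config.seed, "shuffle"))
    table = result.observed.copy()
    table["shuffled_quantile"] = result.shuffled_quantile
    io.write_table(table, out / "regulon.tsv", stamp=config.stamp())
    counts = {"pairs": len(table), "median_shift": round(result.shift, 3)}
    logger.info("regulon: %s", counts)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fitness": stage_fitness,
    "zscores": stage_zscores,
    "phenotypes": stage_phenotypes,
    "cofitness": stage_cofitness,
    "qc": stage_qc,
    "predict": stage_predict,
    "regulon": stage_regulon,
}


def run_stage(name: str, config: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[name](config, out)
    except KeyError:
        raise ParameterError(f"unknown stage {name!r}") from None
    except Exception as exc:  # halt with stage name and cause
        raise StageError(name, exc) from exc


def run_pipeline(config: PipelineConfig, out: str | Path) -> dict:
    """Run every stage in order; returns per-stage counters."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={config.hash()} seed={config.seed}"]
    results = {}
    for name in STAGES:
        t0 = time.time()
        results[name] = run_stage(name, config, out)
        logger.info("stage %s finished in %.1fs", name, time.time() - t0)
        log_lines.append(f"{name}\t{results[name]}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
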