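"""Compendium-level analytics over the gene fitness matrix.

Cofitness (the Pearson correlation of two genes' fitness profiles across
experiments) is the workhorse for function annotation: genes that rise and
fall together across a diverse compendium tend to act in the same pathway.
This module also houses the per-experiment quality metrics (correlation of
identical strains across the two pools, and of adjacent co-operonic genes),
the operon polarity test, concordance of predicted auxotrophs with
minimal-vs-rich media fitness, the chi-squared-bin versus operon-correlation
profile, and the gene-level comparison of fitness and expression changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .strain_fitness import StrainFitnessMatrix
from .util import ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cofitness
# ---------------------------------------------------------------------------

def cofitness_pvalue(r, n):
    """Two-sided P for a Pearson correlation via the t transform.

    t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1 maps
    to P = 0 by convention.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ParameterError("correlation P-value needs n >= 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p if p.shape else float(p)


def cofitness(
    fitness: pd.DataFrame,
    min_experiments: int = 10,
    report_threshold: float | None = None,
) -> pd.DataFrame:
    """All-pairs cofitness entries (gene_a, gene_b, r, n, pvalue).

    Correlations use pairwise-complete experiments; pairs with fewer than
    ``min_experiments`` shared measurements, or with a constant profile, are
    omitted. ``report_threshold`` keeps only pairs with |r| above it.
    """
    if fitness.shape[1] < min_experiments:
        raise ParameterError(
            f"matrix has {fitness.shape[1]} experiments; need >= {min_experiments}")
    corr = fitness.T.corr(min_periods=max(min_experiments, 3))
    present = fitness.notna().astype(float)
    overlap = present @ present.T

    genes = corr.index
    iu = np.triu_indices(len(genes), k=1)
    r = corr.to_numpy()[iu]
    n = overlap.to_numpy()[iu]
    a = genes.to_numpy()[iu[0]]
    b = genes.to_numpy()[iu[1]]
    ok = np.isfinite(r) & (n >= min_experiments)
    out = pd.DataFrame({"gene_a": a[ok], "gene_b": b[ok],
                        "r": r[ok], "n": n[ok].astype(int)})
    out["pvalue"] = cofitness_pvalue(out["r"], out["n"]) if len(out) else []
    if report_threshold is not None:
        out = out[out["r"].abs() > report_threshold].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# experiment quality control
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, n
    return float(np.corrcoef(x[ok], y[ok])[0, 1]), n


def experiment_qc(
    matrix: StrainFitnessMatrix,
    operon_pairs: pd.DataFrame,
    gene_fitness: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-experiment r(Same) and r(Operon) quality metrics.

    r(Same) correlates the fitness of identical strains read out in both
    pools (uptag vs downtag); r(Operon) correlates the fitness of adjacent
    co-operonic gene pairs. Either is missing (with a warning) when fewer
    than ``min_pairs`` pairs are available.
    """
    vals = matrix.values
    strain_ids = vals.index.get_level_values("strain_id")
    pools = vals.index.get_level_values("pool")
    up = vals[pools == "up"].droplevel("pool")
    dn = vals[pools == "dn"].droplevel("pool")
    shared = up.index.intersection(dn.index)
    up, dn = up.loc[shared], dn.loc[shared]

    upstream = operon_pairs["upstream"]
    downstream = operon_pairs["downstream"]
    gf_up = gene_fitness.reindex(upstream)
    gf_dn = gene_fitness.reindex(downstream)

    rows = []
    for exp in vals.columns:
        r_same, n_same = _pearson(up[exp].to_numpy(), dn[exp].to_numpy())
        if exp in gene_fitness.columns:
            r_op, n_op = _pearson(gf_up[exp].to_numpy(), gf_dn[exp].to_numpy())
        else:
            r_op, n_op = np.nan, 0
        if n_same < min_pairs or n_op < min_pairs:
            logger.warning("experiment %s: too few pairs for QC (same=%d, operon=%d)",
                           exp, n_same, n_op)
        rows.append((exp, r_same, n_same, r_op, n_op))
    return pd.DataFrame(rows, columns=["experiment_id", "r_same", "n_same",
                                       "r_operon", "n_operon"])


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

@dataclass
class PolarityResult:
    up_only: int
    down_only: int
    pvalue: float


def polarity_binomial_pvalue(up_only: int, down_only: int) -> float:
    """Two-sided binomial P that up-only and down-only events are equally
    frequent."""
    total = up_only + down_only
    if total == 0:
        return 1.0
    return float(stats.binomtest(up_only, total, 0.5, alternative="two-sided").pvalue)


def polarity_counts(
    gene_fitness: pd.DataFrame,
    ordered_pairs: pd.DataFrame,
    sick_thresh: float = -2.0,
    healthy_thresh: float = -1.0,
) -> PolarityResult:
    """Count upstream-only-sick vs downstream-only-sick operon pair events.

    If polarity dominated the data, an insertion in the upstream gene would
    usually impair the downstream gene too, so downstream-only-sick events
    (downstream fitness below ``sick_thresh`` while the upstream gene stays
    above ``healthy_thresh``) would be rare. Events are counted per
    (pair, experiment) and compared with a two-sided binomial test against
    equal rates.
    """
    up = gene_fitness.reindex(ordered_pairs["upstream"]).to_numpy()
    dn = gene_fitness.reindex(ordered_pairs["downstream"]).to_numpy()
    up_only = int(((up < sick_thresh) & (dn > healthy_thresh)).sum())
    down_only = int(((dn < sick_thresh) & (up > healthy_thresh)).sum())
    p = polarity_binomial_pvalue(up_only, down_only)
    return PolarityResult(up_only=up_only, down_only=down_only, pvalue=p)


# ---------------------------------------------------------------------------
# auxotroph concordance
# ---------------------------------------------------------------------------

@dataclass
class AuxotrophConcordance:
    fraction_minimal: float
    fraction_rich: float
    n_used: int
    missing: list[str] = field(default_factory=list)


def auxotroph_concordance(
    gene_fitness: pd.DataFrame,
    predicted_genes: list[str],
    minimal_experiment: str,
    rich_experiment: str,
    cutoff: float = -2.0,
) -> AuxotrophConcordance:
    """Fraction of predicted auxotrophs at or below ``cutoff`` fitness.

    Computed separately for a minimal-media and a rich-media experiment;
    predicted genes absent from the matrix are excluded and reported.
    """
    if len(predicted_genes) == 0:
        raise ParameterError("predicted gene set is empty")
    for exp in (minimal_experiment, rich_experiment):
        if exp not in gene_fitness.columns:
            raise ParameterError(f"experiment {exp!r} not in fitness matrix")
    present = [g for g in predicted_genes if g in gene_fitness.index]
    missing = [g for g in predicted_genes if g not in gene_fitness.index]
    if missing:
        logger.warning("%d predicted auxotroph genes absent from matrix", len(missing))
    if not present:
        raise ParameterError("no predicted gene is present in the matrix")
    mini = gene_fitness.loc[present, minimal_experiment]
    rich = gene_fitness.loc[present, rich_experiment]
    return AuxotrophConcordance(
        fraction_minimal=float((mini <= cutoff).mean()),
        fraction_rich=float((rich <= cutoff).mean()),
        n_used=len(present),
        missing=missing,
    )


# ---------------------------------------------------------------------------
# chi-squared bins vs operon correlation
# ---------------------------------------------------------------------------

def operon_neighbor_correlation(
    gene_fitness: pd.DataFrame,
    ordered_pairs: pd.DataFrame,
    min_experiments: int = 10,
) -> pd.Series:
    """Per-gene mean cofitness with its adjacent co-operonic neighbors."""
    per_gene: dict[str, list[float]] = {}
    for _, row in ordered_pairs.iterrows():
        a, b = row["upstream"], row["downstream"]
        if a not in gene_fitness.index or b not in gene_fitness.index:
            continue
        x = gene_fitness.loc[a].to_numpy(dtype=float)
        y = gene_fitness.loc[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_experiments or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        per_gene.setdefault(a, []).append(r)
        per_gene.setdefault(b, []).append(r)
    return pd.Series({g: float(np.mean(v)) for g, v in per_gene.items()},
                     name="operon_r", dtype=float)


def operon_cofitness_by_significance(
    tests: pd.DataFrame,
    neighbor_corr: pd.Series,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Summaries of operon cofitness across chi-squared significance bins.

    Genes with at least one co-operonic neighbor are ranked by their
    chi-squared statistic and split into ``n_bins`` equal-count bins; each
    bin reports the median and quartiles of the genes' neighbor
    correlations.
    """
    shared = tests.index.intersection(neighbor_corr.index)
    if n_bins < 1 or n_bins > len(shared):
        raise ParameterError(
            f"n_bins={n_bins} incompatible with {len(shared)} eligible genes")
    chisq = tests.loc[shared, "chisq"]
    rank = chisq.rank(method="first")
    bins = pd.qcut(rank, n_bins, labels=False)
    corr = neighbor_corr.loc[shared]
    out = pd.DataFrame({
        "bin": np.arange(n_bins),
        "chisq_median": chisq.groupby(bins).median().to_numpy(),
        "r_q1": corr.groupby(bins).quantile(0.25).to_numpy(),
        "r_median": corr.groupby(bins).median().to_numpy(),
        "r_q3": corr.groupby(bins).quantile(0.75).to_numpy(),
        "n_genes": corr.groupby(bins).size().to_numpy(),
    })
    return out


# ---------------------------------------------------------------------------
# fitness vs expression
# ---------------------------------------------------------------------------

@dataclass
class FitnessExpressionComparison:
    relative_fitness: pd.Series
    relative_expression: pd.Series
    correlation: float
    quadrants: dict[str, list[str]]
    excluded: list[str] = field(default_factory=list)


def fitness_expression_comparison(
    fitness_a: pd.Series,
    fitness_b: pd.Series,
    expression_logratio: pd.Series,
    exclude: pd.Series | None = None,
) -> FitnessExpressionComparison:
    """Compare relative fitness (A - B) with relative expression (A vs B).

    A perfect agreement between "up-regulated in A" and "more important in
    A" corresponds to a correlation of -1 (important genes have negative
    fitness). ``exclude`` flags genes to drop (e.g. sick on rich media, or
    represented only by edge insertions); they are reported, not silently
    lost. Genes are also partitioned into sign quadrants of
    (relative expression, relative fitness).
    """
    shared = fitness_a.index.intersection(fitness_b.index).intersection(
        expression_logratio.index)
    if len(shared) == 0:
        raise ParameterError("no shared genes between fitness and expression")
    if len(shared) < 10:
        logger.warning("only %d shared genes; comparison is fragile", len(shared))
    excluded: list[str] = []
    if exclude is not None:
        flagged = exclude.reindex(shared).fillna(False).astype(bool)
        excluded = list(shared[flagged])
        shared = shared[~flagged.to_numpy()]
    dfit = (fitness_a.loc[shared] - fitness_b.loc[shared]).astype(float)
    dexp = expression_logratio.loc[shared].astype(float)
    ok = dfit.notna() & dexp.notna()
    dfit, dexp = dfit[ok], dexp[ok]
    r = float(np.corrcoef(dexp.to_numpy(), dfit.to_numpy())[0, 1]) if len(dfit) >= 3 else np.nan
    quads = {
        "up_regulated_more_important": list(dfit.index[(dexp > 0) & (dfit < 0)]),
        "up_regulated_less_important": list(dfit.index[(dexp > 0) & (dfit > 0)]),
        "down_regulated_more_important": list(dfit.index[(dexp < 0) & (dfit < 0)]),
        "down_regulated_less_important": list(dfit.index[(dexp < 0) & (dfit > 0)]),
    }
    return FitnessExpressionComparison(
        relative_fitness=dfit, relative_expression=dexp,
        correlation=r, quadrants=quads, excluded=excluded,
    )
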