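"""Gene-level fitness, moderated t statistics, empirical-null Z calibration.

A gene's fitness in an experiment is the mean of its strain fitness values,
restricted to "good" insertions (central 5--80% of the gene) whenever at
least one exists. Reliability is quantified by a t-like statistic

    T = mu * sqrt(n) / (Psi + s)

where ``mu`` and ``s`` are the mean and sample SD of the gene's ``n``
measurements and ``Psi = median(STD(x))`` is the median, across genes with
more than one measurement, of the per-gene SD. Adding ``Psi`` to the
denominator shrinks the variance estimate of small-n genes and keeps T
finite for singletons (``s = 0`` when ``n = 1``).

T has no analytic null distribution, so it is transformed to a Z score
empirically: control experiments (independent recoveries of the start pools
with no treatment) supply the null T distribution, stratified by the
measurement count (n = 1, 2, 3, >=4), and Z is the standard-normal quantile
of T's mid-rank position in its stratum. Outside the observed control range
the map extends linearly with a robust normal fit (median, scaled MAD) so
extreme statistics stay finite and monotone.

A gene's phenotype over the compendium is tested by combining its Z scores
across all non-control experiments with a chi-squared statistic X^2 = sum
Z^2 on df = number of non-missing Z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .strain_fitness import StrainFitnessMatrix
from .synthetic import GOOD_WINDOW
from .util import CalibrationError, ParameterError

logger = logging.getLogger(__name__)

MIN_STRATUM_SIZE = 50


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def good_insertions(gene_fraction, window: tuple[float, float] = GOOD_WINDOW):
    """True where the insertion sits in the central 5--80% of the gene.

    Both boundaries are inclusive; a missing fraction (e.g. intergenic) is
    not good.
    """
    frac = np.asarray(gene_fraction, dtype=float)
    out = (frac >= window[0]) & (frac <= window[1])
    return out if out.shape else bool(out)


@dataclass
class GeneMeasurements:
    """Per (gene, experiment): mean, sample SD and count of strain values."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    good_only: pd.Series  # per gene: whether only good insertions were used


def gene_measurements(matrix: StrainFitnessMatrix,
                      window: tuple[float, float] = GOOD_WINDOW) -> GeneMeasurements:
    """Aggregate strain fitness to gene-level measurement summaries.

    For each gene, if any of its insertions is good, only the good
    insertions' memberships enter; otherwise all of them do (so genes with
    only edge insertions still get a, possibly attenuated, value).
    """
    prov = matrix.provenance
    genic = prov["gene_id"].notna() & (prov["gene_id"] != "-")
    prov = prov[genic]
    values = matrix.values.loc[prov.index]

    good = pd.Series(good_insertions(prov["gene_fraction"], window), index=prov.index)
    has_good = good.groupby(prov["gene_id"]).any()
    use = good | ~prov["gene_id"].map(has_good)

    used_vals = values[use]
    used_genes = prov.loc[use, "gene_id"]
    grouped = used_vals.groupby(used_genes.to_numpy())
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.count()
    sd = sd.where(n > 1, 0.0)
    return GeneMeasurements(mean=mean, sd=sd, n=n, good_only=has_good)


def gene_fitness(matrix: StrainFitnessMatrix) -> pd.DataFrame:
    """Gene-by-experiment fitness (mean over the used insertions)."""
    return gene_measurements(matrix).mean


# ---------------------------------------------------------------------------
# t-like statistic
# ---------------------------------------------------------------------------

def compute_psi(measurements: GeneMeasurements) -> float:
    """Psi = median over multi-measurement (gene, experiment) cells of the SD."""
    mask = measurements.n >= 2
    sds = measurements.sd.to_numpy()[mask.to_numpy()]
    sds = sds[np.isfinite(sds)]
    if sds.size == 0:
        raise CalibrationError("no gene has more than one measurement")
    psi = float(np.median(sds))
    if psi <= 0:
        raise CalibrationError("Psi must be positive; got %r" % psi)
    return psi


def moderated_t(
    mean: pd.DataFrame | float,
    n: pd.DataFrame | float,
    sd: pd.DataFrame | float,
    psi: float,
):
    """T = mean * sqrt(n) / (Psi + sd); sd is 0 for singletons."""
    if psi <= 0:
        raise CalibrationError("Psi must be > 0")
    return mean * np.sqrt(n) / (psi + sd)


# ---------------------------------------------------------------------------
# empirical-null calibration
# ---------------------------------------------------------------------------

@dataclass
class _Stratum:
    ns: tuple[int, ...]          # measurement counts mapped to this stratum
    sorted_t: np.ndarray
    center: float
    scale: float

    def z(self, t: np.ndarray) -> np.ndarray:
        st = self.sorted_t
        N = st.size
        z_knots = stats.norm.ppf((np.arange(1, N + 1) - 0.5) / N)
        t = np.asarray(t, dtype=float)
        out = np.interp(t, st, z_knots)
        below = t < st[0]
        above = t > st[-1]
        out[below] = z_knots[0] + (t[below] - st[0]) / self.scale
        out[above] = z_knots[-1] + (t[above] - st[-1]) / self.scale
        return out


@dataclass
class NullCalibration:
    """Per-stratum empirical quantile maps built from control experiments."""

    psi: float
    strata: list[_Stratum] = field(default_factory=list)

    def stratum_for(self, n: int) -> _Stratum:
        key = min(int(n), 4)
        for st in self.strata:
            if key in st.ns:
                return st
        raise CalibrationError(f"no calibration stratum covers n={n}")


def calibrate_null(
    t: pd.DataFrame,
    n: pd.DataFrame,
    control_experiments: list[str],
    psi: float,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> NullCalibration:
    """Build the stratified empirical-null quantile maps.

    Control T values are split by measurement count (1, 2, 3, >=4); strata
    with fewer than ``min_stratum_size`` values are merged upward into the
    next stratum (and the >=4 stratum, if still short, absorbs everything).
    """
    controls = [c for c in control_experiments if c in t.columns]
    if len(controls) < 2:
        raise CalibrationError("at least 2 control experiments are required")
    tc = t[controls].to_numpy()
    nc = n[controls].to_numpy()
    ok = np.isfinite(tc) & (nc >= 1)
    nkey = np.minimum(nc, 4)

    buckets = {k: tc[ok & (nkey == k)] for k in (1, 2, 3, 4)}
    strata: list[_Stratum] = []
    pending: list[int] = []
    pool = np.array([], dtype=float)
    for k in (1, 2, 3, 4):
        pool = np.concatenate([pool, buckets[k]])
        pending.append(k)
        if pool.size >= min_stratum_size or k == 4:
            if pool.size < min_stratum_size and strata:
                # fold the short tail stratum back into the previous one
                logger.warning(
                    "stratum n in %s has only %d control values; merged",
                    pending, pool.size)
                prev = strata.pop()
                pool = np.concatenate([prev.sorted_t, pool])
                pending = list(prev.ns) + pending
            elif pool.size < min_stratum_size:
                logger.warning(
                    "only %d control T values in total; single stratum", pool.size)
            if len(pending) > 1:
                logger.warning("strata n in %s merged (sparse controls)", pending)
            strata.append(_make_stratum(tuple(pending), pool))
            pending, pool = [], np.array([], dtype=float)
    return NullCalibration(psi=psi, strata=strata)


def _make_stratum(ns: tuple[int, ...], values: np.ndarray) -> _Stratum:
    if values.size == 0:
        raise CalibrationError(f"no control T values for strata {ns}")
    srt = np.sort(values)
    center = float(np.median(srt))
    mad = float(np.median(np.abs(srt - center)))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = float(np.std(srt)) or 1.0
    return _Stratum(ns=ns, sorted_t=srt, center=center, scale=scale)


def z_transform(
    t: pd.DataFrame,
    n: pd.DataFrame,
    calibration: NullCalibration,
) -> pd.DataFrame:
    """Map T to Z using the stratum matching each cell's measurement count."""
    tv = t.to_numpy(dtype=float)
    nv = n.reindex(index=t.index, columns=t.columns).to_numpy(dtype=float)
    out = np.full_like(tv, np.nan)
    nkey = np.where(np.isfinite(nv), np.minimum(nv, 4), 0).astype(int)
    for st in calibration.strata:
        mask = np.isin(nkey, st.ns) & np.isfinite(tv)
        if mask.any():
            out[mask] = st.z(tv[mask])
    return pd.DataFrame(out, index=t.index, columns=t.columns)


# ---------------------------------------------------------------------------
# phenotype classification
# ---------------------------------------------------------------------------

def phenotype_test(
    z: pd.DataFrame,
    experiments: pd.DataFrame | list[str],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Chi-squared combination of Z scores over the condition experiments.

    X^2 = sum of Z^2 over non-missing cells, df = their count; P is the
    upper-tail chi-squared probability. Genes with no usable Z are excluded.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if isinstance(experiments, pd.DataFrame):
        cols = experiments.loc[
            experiments["class"] == "condition", "experiment_id"].tolist()
    else:
        cols = list(experiments)
    cols = [c for c in cols if c in z.columns]
    zz = z[cols]
    df = zz.notna().sum(axis=1)
    chisq = (zz**2).sum(axis=1, min_count=1)
    keep = df > 0
    chisq, df = chisq[keep], df[keep]
    pval = stats.chi2.sf(chisq, df)
    res = pd.DataFrame({
        "chisq": chisq,
        "df": df.astype(int),
        "pvalue": pval,
        "significant": pval < alpha,
    })
    res.index.name = "gene_id"
    return res


def bonferroni_z_threshold(alpha: float = 0.01, n_experiments: int = 1) -> float:
    """One-sided lower-tail Z threshold at family-wise level ``alpha``."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if n_experiments < 1:
        raise ParameterError("n_experiments must be >= 1")
    return float(stats.norm.ppf(alpha / n_experiments))


def strong_pattern_genes(
    tests: pd.DataFrame,
    z: pd.DataFrame,
    z_threshold: float,
    top_fraction: float = 1 / 3,
) -> pd.Index:
    """Genes with a strong fitness pattern.

    Union of (a) the top third of chi-squared values among all tested genes
    (boundary ties included) and (b) genes with a highly significant defect
    in at least one experiment (min Z below ``z_threshold``).
    """
    n = len(tests)
    k = math.ceil(n * top_fraction)
    if k > 0:
        cutoff = tests["chisq"].sort_values(ascending=False).iloc[k - 1]
        top = tests.index[tests["chisq"] >= cutoff]
    else:
        top = tests.index[:0]
    minz = z.reindex(index=tests.index).min(axis=1)
    extreme = tests.index[minz < z_threshold]
    return top.union(extreme)


def count_significant_changes(
    fitness: pd.DataFrame,
    z: pd.DataFrame,
    fitness_gate: float = 1.0,
    z_gate: float = 2.5,
) -> pd.DataFrame:
    """Per-gene counts of experiments with a significant fitness change.

    A significant change requires |fitness| > ``fitness_gate`` and
    |Z| > ``z_gate``. Sick classes are nested (fitness < -1, < -2, < -3);
    the positive class is fitness > +1.
    """
    z = z.reindex(index=fitness.index, columns=fitness.columns)
    gate = z.abs() > z_gate
    return pd.DataFrame({
        "n_sick1": ((fitness < -fitness_gate) & gate).sum(axis=1),
        "n_sick2": ((fitness < -2.0) & gate).sum(axis=1),
        "n_sick3": ((fitness < -3.0) & gate).sum(axis=1),
        "n_positive": ((fitness > fitness_gate) & gate).sum(axis=1),
    }, index=fitness.index)


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

@dataclass
class GeneScores:
    """Bundle of gene-level outputs for one compendium."""

    fitness: pd.DataFrame
    n: pd.DataFrame
    t: pd.DataFrame
    z: pd.DataFrame
    psi: float
    calibration: NullCalibration
    phenotypes: pd.DataFrame
    changes: pd.DataFrame


def score_genes(
    matrix: StrainFitnessMatrix,
    alpha: float = 0.001,
    fitness_gate: float = 1.0,
    z_gate: float = 2.5,
    window: tuple[float, float] = GOOD_WINDOW,
) -> GeneScores:
    """Full gene-scoring chain: measurements -> T -> calibrated Z -> tests."""
    meas = gene_measurements(matrix, window=window)
    psi = compute_psi(meas)
    t = moderated_t(meas.mean, meas.n, meas.sd, psi)
    exps = matrix.experiments
    controls = exps.loc[exps["class"] == "control", "experiment_id"].tolist()
    calibration = calibrate_null(t, meas.n, controls, psi)
    z = z_transform(t, meas.n, calibration)
    phen = phenotype_test(z, exps, alpha=alpha)
    cond = exps.loc[exps["class"] == "condition", "experiment_id"].tolist()
    changes = count_significant_changes(
        meas.mean[cond], z[cond], fitness_gate=fitness_gate, z_gate=z_gate)
    return GeneScores(
        fitness=meas.mean, n=meas.n, t=t, z=z, psi=psi,
        calibration=calibration, phenotypes=phen, changes=changes,
    )
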