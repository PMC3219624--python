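"""From tag intensities to normalized per-strain fitness.

The chain of operations is:

1. ``summarize_tags`` -- average the log2 intensities of the replicate
   probes of each tag, per hybridization;
2. ``detect_strains`` -- keep strains whose tag rises at least 5x over
   background (the median level of unused tags) in the average start array;
3. ``filter_low_start`` -- drop the strains with the lowest 2% of average
   start levels (per pool);
4. ``strain_log_ratios`` -- fitness = condition level minus start level
   (log2 units), using the experiment's own start hybridization(s) or, when
   absent, the average of all start arrays;
5. ``normalize_strain_fitness`` -- set the median fitness of each
   (pool, replicon) group and then of each 96-well plate group to zero.

``compute_strain_fitness`` runs the whole chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import IntensityTable
from .util import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

DETECT_MULTIPLIER = 5.0
LOW_START_FRACTION = 0.02


@dataclass
class TagLevels:
    """Mean log2 intensity per tag per hybridization (tags x experiments)."""

    levels: pd.DataFrame

    def average_start(self, experiments: pd.DataFrame) -> pd.Series:
        """Mean log2 level per tag over all start hybridizations."""
        start_ids = experiments.loc[experiments["class"] == "start", "experiment_id"]
        cols = [c for c in start_ids if c in self.levels.columns]
        if not cols:
            raise ConfigurationError("no start hybridizations in the experiment set")
        return self.levels[cols].mean(axis=1)


@dataclass
class StrainFitnessMatrix:
    """Normalized strain-by-experiment log2 fitness with provenance.

    Rows are (strain_id, pool) memberships -- a strain present in both pools
    contributes two independent tag read-outs. ``provenance`` aligns with
    the rows and carries pool, replicon and plate group.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    experiments: pd.DataFrame
    stats: dict = field(default_factory=dict)


def summarize_tags(intensities: IntensityTable | pd.DataFrame) -> TagLevels:
    """Average log2 intensities across the replicate probes of each tag."""
    df = intensities.intensities if isinstance(intensities, IntensityTable) else intensities
    levels = (
        df.groupby(["tag_id", "experiment_id"], sort=True)["log2_intensity"]
        .mean()
        .unstack("experiment_id")
    )
    return TagLevels(levels=levels)


def detect_strains(
    tag_levels: TagLevels,
    strains: pd.DataFrame,
    experiments: pd.DataFrame,
    multiplier: float = DETECT_MULTIPLIER,
) -> pd.Series:
    """Flag memberships detected at ``multiplier``x over background.

    Background is the median linear-scale level of unused tags (tags present
    on the array but assigned to no strain) in the average start array. The
    threshold is inclusive. Returns a boolean Series indexed by
    (strain_id, pool).
    """
    if multiplier <= 0:
        raise ParameterError("multiplier must be > 0")
    avg_start = tag_levels.average_start(experiments)
    used = set(strains["tag_id"])
    unused = avg_start.index.difference(used)
    if len(unused) == 0:
        raise ConfigurationError(
            "no unused tags available for background estimation")
    background = float(np.median(np.exp2(avg_start.loc[unused])))
    threshold = math.log2(multiplier * background)
    mem = strains.set_index(["strain_id", "pool"])
    level = avg_start.reindex(mem["tag_id"]).to_numpy()
    detected = pd.Series(level >= threshold - 1e-12, index=mem.index, name="detected")
    return detected


def filter_low_start(
    start_levels: pd.Series,
    pools: pd.Series,
    fraction: float = LOW_START_FRACTION,
) -> pd.Series:
    """Drop the lowest-``fraction`` start levels, separately per pool.

    ``start_levels`` are average start log2 levels of detected memberships,
    indexed by (strain_id, pool); ``pools`` gives the pool of each entry.
    Exactly ``floor(fraction * N_pool)`` entries are removed per pool; ties
    are broken by lexicographic strain_id so the rule is deterministic.
    Returns a boolean retention mask aligned with ``start_levels``.
    """
    if not 0 <= fraction < 1:
        raise ParameterError("fraction must be in [0, 1)")
    keep = pd.Series(True, index=start_levels.index)
    for pool, grp in start_levels.groupby(pools):
        n_remove = int(math.floor(fraction * len(grp)))
        if n_remove == 0:
            continue
        ranked = grp.to_frame("level").reset_index()
        ranked = ranked.sort_values(["level", "strain_id"], kind="mergesort")
        drop = ranked.head(n_remove)
        keep.loc[list(zip(drop["strain_id"], drop["pool"]))] = False
    return keep


def strain_log_ratios(
    tag_levels: TagLevels,
    strains: pd.DataFrame,
    experiments: pd.DataFrame,
) -> pd.DataFrame:
    """Raw fitness: condition tag level minus start tag level, in log2 units.

    Each fitness experiment (class ``condition`` or ``control``) is compared
    to the start hybridization(s) sharing its ``group``. When an experiment
    has no start of its own, the average of all start arrays substitutes.
    Returns a (strain_id, pool) x experiment DataFrame.
    """
    mem = strains.set_index(["strain_id", "pool"])
    lv = tag_levels.levels
    fit_exps = experiments[experiments["class"].isin(["condition", "control"])]
    start_of_group: dict[str, list[str]] = {}
    for _, row in experiments[experiments["class"] == "start"].iterrows():
        start_of_group.setdefault(row["group"], []).append(row["experiment_id"])
    all_start = tag_levels.average_start(experiments)

    out = {}
    for _, row in fit_exps.iterrows():
        exp = row["experiment_id"]
        if exp not in lv.columns:
            continue
        starts = [s for s in start_of_group.get(row["group"], []) if s in lv.columns]
        if starts:
            ref = lv[starts].mean(axis=1)
        else:
            logger.warning("experiment %s has no paired start; using average start array", exp)
            ref = all_start
        ratio = lv[exp] - ref
        out[exp] = ratio.reindex(mem["tag_id"]).to_numpy()
    return pd.DataFrame(out, index=mem.index)


def strain_provenance(strains: pd.DataFrame, genome) -> pd.DataFrame:
    """Pool, replicon and plate group per (strain_id, pool) membership.

    Replicon comes from the disrupted gene; intergenic insertions are
    assigned to the chromosome (the dominant replicon) for the purpose of
    the replicon-median normalization.
    """
    mem = strains.set_index(["strain_id", "pool"])
    replicon_map = genome.replicon_of()
    replicon = mem["gene_id"].map(replicon_map).fillna("chromosome")
    return pd.DataFrame({
        "pool": mem.index.get_level_values("pool"),
        "replicon": replicon.to_numpy(),
        "plate": mem["plate"].to_numpy(),
        "gene_id": mem["gene_id"].to_numpy(),
        "gene_fraction": mem["gene_fraction"].to_numpy(),
    }, index=mem.index)


def normalize_strain_fitness(
    raw: pd.DataFrame,
    provenance: pd.DataFrame,
    experiments: pd.DataFrame | None = None,
    plate_pass: bool = True,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> StrainFitnessMatrix:
    """Median-center fitness within (pool x replicon) and plate groups.

    Per experiment the median is subtracted first within each
    (pool, replicon) group, then within each plate group of strains. The
    two passes cross-cut, so they are repeated in that order until every
    group median is zero within ``tol``; when the groups are nested this
    reduces to a single pass of each. ``plate_pass=False`` skips the plate
    stage (for ablation).
    """
    prov = provenance.loc[raw.index]
    values = raw.copy()
    group_pr = (prov["pool"].astype(str) + "|" + prov["replicon"].astype(str)).to_numpy()
    group_plate = prov["plate"]

    for _ in range(max_iter):
        med_pr = values.groupby(group_pr).transform("median")
        values = values - med_pr
        if plate_pass:
            med_plate = values.groupby(group_plate.to_numpy()).transform("median")
            values = values - med_plate
        else:
            med_plate = med_pr * 0.0
        shift = np.nanmax(np.abs(med_pr.to_numpy())) if med_pr.size else 0.0
        shift = max(shift, np.nanmax(np.abs(med_plate.to_numpy())) if med_plate.size else 0.0)
        if not np.isfinite(shift) or shift < tol:
            break

    empty = values.notna().groupby(group_pr).sum()
    if (empty == 0).any().any():
        logger.warning("some (pool, replicon) groups have no measured strains; skipped")
    return StrainFitnessMatrix(
        values=values,
        provenance=prov,
        experiments=experiments if experiments is not None else pd.DataFrame(),
    )


def compute_strain_fitness(
    intensities: IntensityTable | pd.DataFrame,
    strains: pd.DataFrame,
    genome,
    experiments: pd.DataFrame | None = None,
    detect_multiplier: float = DETECT_MULTIPLIER,
    low_start_fraction: float = LOW_START_FRACTION,
    plate_pass: bool = True,
) -> StrainFitnessMatrix:
    """Run the full intensity -> normalized strain fitness chain."""
    if isinstance(intensities, IntensityTable) and experiments is None:
        experiments = intensities.experiments
    if experiments is None:
        raise ParameterError("experiment metadata is required")
    tags = summarize_tags(intensities)
    detected = detect_strains(tags, strains, experiments, multiplier=detect_multiplier)
    avg_start = tags.average_start(experiments)
    mem = strains.set_index(["strain_id", "pool"])
    start_per_mem = avg_start.reindex(mem["tag_id"])
    start_per_mem.index = mem.index

    det_levels = start_per_mem[detected]
    pools = pd.Series(det_levels.index.get_level_values("pool"), index=det_levels.index)
    kept = filter_low_start(det_levels, pools, fraction=low_start_fraction)
    retained = kept[kept].index

    raw = strain_log_ratios(tags, strains, experiments).loc[retained]
    prov = strain_provenance(strains, genome).loc[retained]
    fit_exps = experiments[experiments["class"].isin(["condition", "control"])]
    matrix = normalize_strain_fitness(raw, prov, experiments=fit_exps, plate_pass=plate_pass)
    matrix.stats = {
        "n_memberships": int(len(mem)),
        "n_detected": int(detected.sum()),
        "n_low_start_removed": int((~kept).sum()),
        "n_retained": int(len(retained)),
    }
    return matrix
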