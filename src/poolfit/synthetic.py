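"""Synthetic pooled-fitness data with known ground truth.

This module generates everything the analysis pipeline consumes: a bacterial
genome with operon structure on a main chromosome plus a megaplasmid, a
transposon insertion library, two tagged mutant pools (upPool/dnPool) with
96-well plate provenance, sparse condition-specific true fitness effects that
are shared within operons, tag-level hybridization intensities with probe
replicates, and a gene-by-experiment expression matrix with regulator-target
coupling.

The generative model mirrors the statistical structure of a DNA-tag pooled
fitness compendium:

* each strain carries a TagModule (an uptag read out in the upPool and a
  downtag read out in the dnPool); tags are unique within a pool and both
  pools are measured on a single array per sample;
* every fitness experiment -- a growth condition or a no-treatment control
  recovery -- is paired with its own "start" hybridization, so log-ratios are
  independent across experiments;
* start log2 levels are drawn from N(10, 1) with a small low tail near
  background, so the low-level start filter downstream is exercised;
* condition levels are start + true strain fitness + a per-(plate, experiment)
  batch effect + a per-experiment megaplasmid shift + probe noise;
* a small fraction of strains is truly undetectable and sits at background,
  as do all unused tags (these anchor background estimation).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import CapacityError, ParameterError, ReferenceError_

GOOD_WINDOW = (0.05, 0.80)  # central portion of a gene counted as a clean knockout

GENE_COLUMNS = [
    "gene_id", "replicon", "start", "end", "strand",
    "operon_id", "subrole", "hypothetical",
]
STRAIN_COLUMNS = [
    "strain_id", "pool", "tag_id", "plate", "well",
    "gene_id", "insertion_pos", "gene_fraction", "transposon",
]
EXPERIMENT_COLUMNS = ["experiment_id", "pool", "class", "condition_name", "group"]
INTENSITY_COLUMNS = ["experiment_id", "tag_id", "probe_index", "log2_intensity"]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Gene table on two replicons with operon structure.

    ``genes`` columns: gene_id, replicon ('chromosome'|'megaplasmid'),
    start, end (1-based inclusive), strand ('+'|'-'), operon_id,
    subrole ('-' when unlabeled), hypothetical (bool).
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if (g["start"] > g["end"]).any():
            raise ParameterError("gene start must be <= end")
        if g["gene_id"].duplicated().any():
            raise ParameterError("gene_ids must be unique")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def replicon_of(self) -> pd.Series:
        return self.genes.set_index("gene_id")["replicon"]

    def operon_pairs(self) -> pd.DataFrame:
        """Adjacent co-operonic gene pairs ordered by transcription.

        Returns columns (upstream, downstream): for '+' strand operons the
        upstream gene is the one with the lower coordinate, for '-' strand
        the higher.
        """
        rows = []
        for _, block in self.genes.groupby("operon_id", sort=False):
            if len(block) < 2:
                continue
            block = block.sort_values("start")
            order = block["gene_id"].tolist()
            if block["strand"].iloc[0] == "-":
                order = order[::-1]
            for up, down in zip(order[:-1], order[1:]):
                rows.append((up, down))
        return pd.DataFrame(rows, columns=["upstream", "downstream"])


@dataclass
class PoolSet:
    """Two mutant pools with tag, plate and well assignments.

    ``strains`` has one row per (strain, pool) membership; a strain present
    in both pools appears twice with distinct tags. ``undetectable`` marks
    strains that never rise above background. ``replicon`` is carried for
    simulation convenience and is not part of the emitted schema.
    """

    strains: pd.DataFrame
    n_tag_modules: int
    tag_universe: dict[str, list[str]] = field(default_factory=dict)

    def memberships(self, pool: str) -> pd.DataFrame:
        return self.strains[self.strains["pool"] == pool]


@dataclass
class TrueFitness:
    """Ground-truth gene-by-condition log2 fitness effects.

    Control columns are all zero. ``edge_attenuation`` is the multiplier
    applied to the effect of insertions outside the central gene window;
    ``operon_share`` is the probability a seeded effect was copied to the
    whole operon.
    """

    matrix: pd.DataFrame
    conditions: list[str]
    controls: list[str]
    edge_attenuation: float = 0.5
    operon_share: float = 0.75


@dataclass
class IntensityTable:
    """Long-format tag intensities plus hybridization metadata."""

    intensities: pd.DataFrame
    experiments: pd.DataFrame


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    megaplasmid_fraction: float = 0.04,
    mean_operon_size: float = 2.5,
    n_subroles: int = 8,
    seed: int = 0,
    subrole_fraction: float = 0.25,
    hypothetical_fraction: float = 0.3,
) -> Genome:
    """Simulate a two-replicon genome with operons and optional subrole labels.

    Operon sizes are geometric with the stated mean; genes within an operon
    are adjacent, co-oriented and on the same replicon. A ``subrole_fraction``
    of genes carries one of ``n_subroles`` functional subrole labels,
    assigned per operon so that co-operonic genes share a label (as
    co-transcribed genes tend to share function).
    """
    if n_genes < 10:
        raise ParameterError("n_genes must be >= 10")
    if mean_operon_size < 1:
        raise ParameterError("mean_operon_size must be >= 1")
    if not 0 <= megaplasmid_fraction < 1:
        raise ParameterError("megaplasmid_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    # operon sizes: geometric on {1, 2, ...} with mean = mean_operon_size
    p = 1.0 / mean_operon_size
    sizes: list[int] = []
    total = 0
    while total < n_genes:
        k = int(rng.geometric(p))
        k = min(k, n_genes - total)
        sizes.append(k)
        total += k

    # last operons go to the megaplasmid until its gene quota is filled
    target_mp = int(round(n_genes * megaplasmid_fraction))
    replicon_of_operon = []
    mp_count = 0
    for k in reversed(sizes):
        if mp_count < target_mp:
            replicon_of_operon.append("megaplasmid")
            mp_count += k
        else:
            replicon_of_operon.append("chromosome")
    replicon_of_operon.reverse()

    width = max(4, len(str(n_genes)))
    rows = []
    cursor = {"chromosome": 1, "megaplasmid": 1}
    gene_idx = 0
    for op_idx, (k, repl) in enumerate(zip(sizes, replicon_of_operon)):
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"op{op_idx + 1:0{width}d}"
        labeled = n_subroles > 0 and rng.random() < subrole_fraction
        subrole = f"SR{rng.integers(1, n_subroles + 1):02d}" if labeled else "-"
        cursor[repl] += int(rng.integers(100, 400))  # inter-operon gap
        for _ in range(k):
            gene_idx += 1
            length = int(rng.integers(300, 3000))
            start = cursor[repl]
            end = start + length - 1
            cursor[repl] = end + 1 + int(rng.integers(20, 80))  # intra-operon gap
            hypo = (not labeled) and rng.random() < hypothetical_fraction
            rows.append((
                f"g{gene_idx:0{width}d}", repl, start, end, strand,
                operon_id, subrole, hypo,
            ))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return Genome(genes)


# ---------------------------------------------------------------------------
# insertion library
# ---------------------------------------------------------------------------

def simulate_insertion_library(
    genome: Genome,
    n_insertions: int,
    intergenic_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate transposon insertion strains.

    Genic insertions pick a gene with probability proportional to its length
    and a position uniform within it; ``gene_fraction`` is the relative
    position on the transcribed strand (0 at the start codon, 1 at the stop).
    An ``intergenic_fraction`` of insertions lands between genes and maps to
    no gene.
    """
    if n_insertions < 1:
        raise ParameterError("n_insertions must be >= 1")
    if not 0 <= intergenic_fraction <= 1:
        raise ParameterError("intergenic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = genome.genes
    lengths = (g["end"] - g["start"] + 1).to_numpy()
    weights = lengths / lengths.sum()

    n_inter = int(round(n_insertions * intergenic_fraction))
    n_genic = n_insertions - n_inter
    gene_idx = rng.choice(len(g), size=n_genic, p=weights)
    u = rng.random(n_genic)
    starts = g["start"].to_numpy()[gene_idx]
    ends = g["end"].to_numpy()[gene_idx]
    pos = starts + np.floor(u * (ends - starts + 1)).astype(int)
    pos = np.minimum(pos, ends)
    plus = g["strand"].to_numpy()[gene_idx] == "+"
    frac = np.where(
        plus,
        (pos - starts) / (ends - starts),
        (ends - pos) / (ends - starts),
    )
    chrom_span = int(g.loc[g["replicon"] == "chromosome", "end"].max())
    inter_pos = rng.integers(1, chrom_span + 1, size=n_inter)

    n_total = n_genic + n_inter
    width = max(5, len(str(n_total)))
    records = pd.DataFrame({
        "gene_id": np.concatenate([g["gene_id"].to_numpy()[gene_idx],
                                   np.full(n_inter, "-", dtype=object)]),
        "insertion_pos": np.concatenate([pos, inter_pos]).astype(int),
        "gene_fraction": np.concatenate([frac, np.full(n_inter, np.nan)]),
        "replicon": np.concatenate([g["replicon"].to_numpy()[gene_idx],
                                    np.full(n_inter, "chromosome", dtype=object)]),
    })
    # shuffle so intergenic strains are interleaved, then assign stable ids
    records = records.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1)))
    records = records.reset_index(drop=True)
    records.insert(0, "strain_id", [f"s{i + 1:0{width}d}" for i in range(n_total)])
    records["transposon"] = np.where(rng.random(n_total) < 0.5, "Tn5", "mariner")
    return records


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def _well_names(plate_size: int) -> list[str]:
    n_cols = max(1, plate_size // 8)
    wells = [f"{r}{c:02d}" for r in string.ascii_uppercase[:8] for c in range(1, n_cols + 1)]
    if len(wells) < plate_size:  # non-96 plate sizes
        wells = [f"W{i + 1:03d}" for i in range(plate_size)]
    return wells[:plate_size]


def assemble_pools(
    strains: pd.DataFrame,
    n_tag_modules: int | None = None,
    plate_size: int = 96,
    detect_failure_rate: float = 0.02,
    both_pool_fraction: float = 0.4,
    seed: int = 0,
) -> PoolSet:
    """Assign strains to the upPool/dnPool, TagModules, and plate wells.

    Each strain owns one TagModule; its uptag reads the strain out in the
    upPool and its downtag in the dnPool. With probability
    ``both_pool_fraction`` a strain is placed in both pools (two independent
    tag read-outs of the same mutant); otherwise it goes to one pool at
    random. Strains are archived in consecutive wells of ``plate_size``-well
    plates, and a ``detect_failure_rate`` fraction is flagged as truly
    undetectable.
    """
    if plate_size < 1:
        raise ParameterError("plate_size must be >= 1")
    if not 0 <= detect_failure_rate < 1:
        raise ParameterError("detect_failure_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(strains)
    if n_tag_modules is None:
        n_tag_modules = n + 64
    if n_tag_modules < 1:
        raise ParameterError("n_tag_modules must be >= 1")

    in_both = rng.random(n) < both_pool_fraction
    up_only = (~in_both) & (rng.random(n) < 0.5)
    in_up = in_both | up_only
    in_dn = in_both | ~up_only
    if int(in_up.sum()) > n_tag_modules or int(in_dn.sum()) > n_tag_modules:
        raise CapacityError(
            f"pool needs more than {n_tag_modules} tag modules")

    twidth = max(5, len(str(n_tag_modules)))
    module = np.arange(1, n + 1)
    wells = _well_names(plate_size)
    plate = [f"P{i // plate_size + 1:03d}" for i in range(n)]
    well = [wells[i % plate_size] for i in range(n)]
    undetectable = rng.random(n) < detect_failure_rate

    base = strains.reset_index(drop=True).copy()
    base["plate"] = plate
    base["well"] = well
    base["_module"] = module
    base["undetectable"] = undetectable

    parts = []
    for pool, mask, suffix in (("up", in_up, "u"), ("dn", in_dn, "d")):
        part = base.loc[mask].copy()
        part["pool"] = pool
        part["tag_id"] = [f"t{m:0{twidth}d}{suffix}" for m in part["_module"]]
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    cols = STRAIN_COLUMNS + ["replicon", "undetectable"]
    out = out[[c for c in cols if c in out.columns]]

    universe = {
        "up": [f"t{m:0{twidth}d}u" for m in range(1, n_tag_modules + 1)],
        "dn": [f"t{m:0{twidth}d}d" for m in range(1, n_tag_modules + 1)],
    }
    return PoolSet(strains=out, n_tag_modules=int(n_tag_modules), tag_universe=universe)


# ---------------------------------------------------------------------------
# ground-truth fitness effects
# ---------------------------------------------------------------------------

def simulate_truth(
    genome: Genome,
    n_conditions: int,
    n_controls: int = 14,
    sparsity: float = 0.05,
    effect_scale: float = 2.0,
    operon_share: float = 0.75,
    seed: int = 0,
    edge_attenuation: float = 0.5,
) -> TrueFitness:
    """Draw sparse condition-specific true fitness effects.

    Per condition, genes are seeded with effects until a ``sparsity``
    fraction of the genome is affected; with probability ``operon_share`` a
    seeded effect is copied (same value, hence same sign) to the whole
    operon, modelling co-transcribed pathway blocks. Effect magnitudes are
    ``effect_scale`` times Uniform(0.5, 1.5) log2 units, negative (a growth
    defect) with probability 0.85. Control columns are identically zero.
    """
    if n_controls < 2:
        raise ParameterError("n_controls must be >= 2")
    if not 0 <= sparsity <= 1:
        raise ParameterError("sparsity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = genome.gene_ids
    n_genes = len(gene_ids)
    operon_members = genome.genes.groupby("operon_id")["gene_id"].apply(list)
    operon_of = genome.genes.set_index("gene_id")["operon_id"]

    conditions = [f"cond{i + 1:02d}" for i in range(n_conditions)]
    controls = [f"ctrl{i + 1:02d}" for i in range(n_controls)]
    mat = pd.DataFrame(0.0, index=gene_ids, columns=conditions + controls)

    target = int(round(sparsity * n_genes))
    for cond in conditions:
        affected: set[str] = set()
        while len(affected) < target:
            gid = gene_ids[int(rng.integers(n_genes))]
            if gid in affected:
                continue
            mag = effect_scale * rng.uniform(0.5, 1.5)
            eff = -mag if rng.random() < 0.85 else mag
            if rng.random() < operon_share:
                block = operon_members[operon_of[gid]]
            else:
                block = [gid]
            for member in block:
                mat.loc[member, cond] = eff
                affected.add(member)
    return TrueFitness(
        matrix=mat, conditions=conditions, controls=controls,
        edge_attenuation=edge_attenuation, operon_share=operon_share,
    )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def simulate_intensities(
    poolset: PoolSet,
    truth: TrueFitness,
    probe_sd: float = 0.25,
    plate_sd: float = 0.25,
    replicon_shift: float = 0.25,
    background_level: float = 5.0,
    n_probes: int = 5,
    seed: int = 0,
    start_mean: float = 10.0,
    start_sd: float = 1.0,
    low_tail_fraction: float = 0.03,
) -> IntensityTable:
    """Emit tag hybridization intensities for the whole experiment set.

    Every fitness experiment (each condition and each control recovery) gets
    its own start hybridization; the two share a ``group`` id in the
    experiment metadata. Uptags and downtags are read on the same array, so
    one hybridization covers both pools. Tags of truly-undetectable strains
    and all unused tags sit at ``background_level``.
    """
    if probe_sd <= 0:
        raise ParameterError("probe_sd must be > 0")
    if n_probes < 1:
        raise ParameterError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)

    members = poolset.strains.reset_index(drop=True)
    n_mem = len(members)
    all_tags = poolset.tag_universe["up"] + poolset.tag_universe["dn"]
    tag_index = {t: i for i, t in enumerate(all_tags)}
    mem_tag_idx = members["tag_id"].map(tag_index).to_numpy()
    n_tags = len(all_tags)

    # per-membership baseline (start) level
    baseline = rng.normal(start_mean, start_sd, size=n_mem)
    low_tail = rng.random(n_mem) < low_tail_fraction
    baseline[low_tail] = background_level + 2.8 + rng.normal(0.0, 0.8, low_tail.sum())
    undet = members["undetectable"].to_numpy(bool)
    baseline[undet] = background_level + rng.normal(0.0, 0.2, undet.sum())

    # per-membership effect multiplier for insertion position
    frac = members["gene_fraction"].to_numpy(float)
    good = (frac >= GOOD_WINDOW[0]) & (frac <= GOOD_WINDOW[1])
    multiplier = np.where(good, 1.0, truth.edge_attenuation)
    multiplier = np.where(np.isnan(frac), 0.0, multiplier)  # intergenic: neutral
    multiplier[undet] = 0.0

    gene_ids = members["gene_id"].to_numpy(object)
    in_truth = pd.Index(gene_ids).isin(truth.matrix.index)
    mega = (members["replicon"] == "megaplasmid").to_numpy(bool) if "replicon" in members else np.zeros(n_mem, bool)
    plates = members["plate"].to_numpy(object)
    plate_codes, plate_names = pd.factorize(plates)

    exp_rows = []
    hyb_levels = {}  # experiment_id -> level vector over all tags
    for name in truth.conditions + truth.controls:
        cls = "condition" if name in truth.conditions else "control"
        group = f"x_{name}"
        start_id = f"{name}_start"
        exp_rows.append((start_id, "both", "start", "-", group))
        exp_rows.append((name, "both", cls, name, group))

        start_levels = np.full(n_tags, background_level)
        start_levels[mem_tag_idx] = baseline

        eff = np.zeros(n_mem)
        if cls == "condition":
            true_col = truth.matrix[name]
            gene_eff = np.zeros(n_mem)
            gene_eff[in_truth] = true_col.reindex(gene_ids[in_truth]).to_numpy()
            eff = gene_eff * multiplier
        if plate_sd > 0:
            plate_effects = rng.normal(0.0, plate_sd, size=len(plate_names))
            eff = eff + np.where(undet, 0.0, plate_effects[plate_codes])
        if replicon_shift > 0 and mega.any():
            shift = rng.normal(0.0, replicon_shift)
            eff = eff + np.where(mega & ~undet, shift, 0.0)

        sample_levels = np.full(n_tags, background_level)
        sample_levels[mem_tag_idx] = baseline + eff
        hyb_levels[start_id] = start_levels
        hyb_levels[name] = sample_levels

    experiments = pd.DataFrame(exp_rows, columns=EXPERIMENT_COLUMNS)

    frames = []
    probe_idx = np.tile(np.arange(1, n_probes + 1), n_tags)
    tags_rep = np.repeat(np.array(all_tags, dtype=object), n_probes)
    for exp_id in experiments["experiment_id"]:
        level = np.repeat(hyb_levels[exp_id], n_probes)
        noise = rng.normal(0.0, probe_sd, size=level.size)
        frames.append(pd.DataFrame({
            "experiment_id": exp_id,
            "tag_id": tags_rep,
            "probe_index": probe_idx,
            "log2_intensity": level + noise,
        }))
    intensities = pd.concat(frames, ignore_index=True)
    return IntensityTable(intensities=intensities, experiments=experiments)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_regulons(
    genome: Genome,
    n_tfs: int,
    targets_per_tf: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw a synthetic TF -> target pair list over the genome's genes."""
    rng = np.random.default_rng(seed)
    ids = list(genome.gene_ids)
    if n_tfs * (1 + targets_per_tf) > len(ids):
        raise ParameterError("not enough genes for the requested regulons")
    chosen = rng.choice(len(ids), size=n_tfs * (1 + targets_per_tf), replace=False)
    pairs = []
    k = 0
    for _ in range(n_tfs):
        tf = ids[chosen[k]]
        k += 1
        for _ in range(targets_per_tf):
            pairs.append((tf, ids[chosen[k]]))
            k += 1
    return pairs


def simulate_expression(
    genome: Genome,
    regulons: list[tuple[str, str]] | dict[str, list[str]],
    n_experiments: int,
    coupling: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene-by-experiment expression log-ratio matrix.

    Target genes track their TF's profile with correlation ``coupling``;
    unrelated genes are independent standard normal log-ratios.
    """
    if n_experiments < 2:
        raise ParameterError("n_experiments must be >= 2 for correlations to exist")
    if not -1 <= coupling <= 1:
        raise ParameterError("coupling must be in [-1, 1]")
    if isinstance(regulons, dict):
        pairs = [(tf, t) for tf, targets in regulons.items() for t in targets]
    else:
        pairs = list(regulons)
    ids = set(genome.gene_ids)
    for tf, target in pairs:
        if tf not in ids or target not in ids:
            raise ReferenceError_(f"regulon pair ({tf}, {target}) not in genome")

    rng = np.random.default_rng(seed)
    cols = [f"ex{i + 1:03d}" for i in range(n_experiments)]
    mat = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(ids), n_experiments)),
        index=genome.gene_ids, columns=cols,
    )
    for tf, target in pairs:
        if tf == target:
            continue
        noise = rng.normal(0.0, 1.0, size=n_experiments)
        mat.loc[target] = coupling * mat.loc[tf].to_numpy() + np.sqrt(1 - coupling**2) * noise
    return mat
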