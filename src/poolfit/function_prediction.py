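"""Gene function prediction from fitness and expression profiles.

Functional subroles (fine-grained categories such as "Amino acid synthesis:
Aspartate family") are predicted with a random forest on gene-by-experiment
profiles. Because co-operonic genes share both function and highly similar
fitness profiles, naive cross-validation would leak: a gene's operon mates
in the training set make its test prediction look far better than it would
be for a truly novel gene. Folds are therefore assigned to whole operons,
never splitting one.

The forest's vote fraction serves as a confidence score; its usefulness is
evaluated by comparing the confidence distributions of correct and
incorrect cross-validated predictions (two-sample Kolmogorov-Smirnov) and
by precision at increasing confidence thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .util import ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# features and labels
# ---------------------------------------------------------------------------

def prepare_features(*matrices: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each experiment, impute missing values with zero.

    Centering uses the observed values of each column; after centering, a
    missing value becomes 0 (the column mean), a neutral imputation.
    Multiple matrices (e.g. fitness and expression) are concatenated
    column-wise on the union of their genes; all-missing columns are
    dropped with a warning.
    """
    if not matrices:
        raise ParameterError("at least one matrix is required")
    parts = []
    for i, m in enumerate(matrices):
        empty = m.columns[m.notna().sum(axis=0) == 0]
        if len(empty):
            logger.warning("dropping %d all-missing experiment columns", len(empty))
            m = m.drop(columns=empty)
        centered = m - m.mean(axis=0)
        part = centered.fillna(0.0)
        part.columns = [f"m{i}:{c}" if len(matrices) > 1 else c for c in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1, join="outer").fillna(0.0)


def filter_subroles(labels: pd.DataFrame) -> pd.DataFrame:
    """Drop non-specific functional assignments.

    Records lacking a subrole, or whose role or subrole contains "unknown"
    or "other" (case-insensitive substring), are removed.
    """
    lab = labels.copy()
    sub = lab["subrole"].fillna("").astype(str)
    role = lab.get("role", pd.Series("", index=lab.index)).fillna("").astype(str)
    bad = (sub.str.strip().isin(["", "-"])
           | sub.str.lower().str.contains("unknown")
           | sub.str.lower().str.contains("other")
           | role.str.lower().str.contains("unknown")
           | role.str.lower().str.contains("other"))
    return lab[~bad].reset_index(drop=True)


# ---------------------------------------------------------------------------
# operon-wise cross-validation
# ---------------------------------------------------------------------------

def operonwise_folds(
    operon_of: pd.Series,
    k: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Assign genes to ``k`` folds without ever splitting an operon.

    Operons are shuffled and then greedily assigned to the currently
    smallest fold, which keeps gene counts balanced within the largest
    operon size. Returns a gene_id -> fold index Series.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    operons = operon_of.groupby(operon_of).groups  # operon_id -> gene index
    if len(operons) < k:
        raise ParameterError(f"only {len(operons)} operons for k={k} folds")
    rng = np.random.default_rng(seed)
    names = sorted(operons)
    rng.shuffle(names)
    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for name in names:
        genes = operons[name]
        f = int(np.argmin(fold_sizes))
        fold_sizes[f] += len(genes)
        for g in genes:
            assignment[g] = f
    return pd.Series(assignment, name="fold").loc[operon_of.index]


# ---------------------------------------------------------------------------
# random-forest subrole prediction
# ---------------------------------------------------------------------------

def predict_subroles(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated subrole predictions with vote-fraction confidence.

    For each fold, a forest is trained on the labeled genes of the other
    folds and predicts the fold's labeled genes; the confidence of a
    prediction is the fraction of trees voting for it. Genes present in
    ``features`` but unlabeled are predicted by a final forest trained on
    all labeled genes (fold -1).
    """
    labeled = labels.dropna()
    labeled = labeled[labeled.index.isin(features.index)]
    if labeled.nunique() < 2:
        raise ParameterError("need at least 2 subrole classes")
    rows = []
    all_classes = set(labeled.unique())
    for f in sorted(folds.loc[labeled.index].unique()):
        test_genes = labeled.index[folds.loc[labeled.index] == f]
        train_genes = labeled.index[folds.loc[labeled.index] != f]
        y_train = labeled.loc[train_genes]
        missing = all_classes - set(y_train.unique())
        if missing:
            logger.warning("fold %s: classes %s absent from training split",
                           f, sorted(missing))
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(features.loc[train_genes], y_train)
        proba = model.predict_proba(features.loc[test_genes])
        pred_idx = np.argmax(proba, axis=1)
        for g, pi, pr in zip(test_genes, pred_idx, proba):
            pred = model.classes_[pi]
            rows.append((g, pred, float(pr[pi]), int(f), labeled.loc[g],
                         bool(pred == labeled.loc[g])))

    unlabeled = features.index.difference(labeled.index)
    if len(unlabeled):
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(features.loc[labeled.index], labeled)
        proba = model.predict_proba(features.loc[unlabeled])
        pred_idx = np.argmax(proba, axis=1)
        for g, pi, pr in zip(unlabeled, pred_idx, proba):
            rows.append((g, model.classes_[pi], float(pr[pi]), -1, None, None))
    out = pd.DataFrame(rows, columns=["gene_id", "predicted_subrole", "confidence",
                                      "fold", "truth", "correct"])
    return out


@dataclass
class ConfidenceEvaluation:
    ks_d: float
    ks_pvalue: float
    precision_table: pd.DataFrame


def evaluate_confidence(predictions: pd.DataFrame) -> ConfidenceEvaluation:
    """Compare confidence of correct vs incorrect predictions.

    Returns the two-sample KS statistic/P-value and a precision table at
    confidence thresholds 0.1 .. 0.9.
    """
    evaluable = predictions[predictions["correct"].notna()]
    correct = evaluable.loc[evaluable["correct"].astype(bool), "confidence"]
    incorrect = evaluable.loc[~evaluable["correct"].astype(bool), "confidence"]
    if len(correct) == 0 or len(incorrect) == 0:
        raise ParameterError("need at least one correct and one incorrect prediction")
    ks = stats.ks_2samp(correct.to_numpy(), incorrect.to_numpy())
    rows = []
    for thr in np.arange(0.1, 0.95, 0.1):
        sel = evaluable[evaluable["confidence"] >= thr]
        prec = float(sel["correct"].astype(bool).mean()) if len(sel) else np.nan
        rows.append((round(float(thr), 1), len(sel), prec))
    table = pd.DataFrame(rows, columns=["threshold", "n", "precision"])
    return ConfidenceEvaluation(
        ks_d=float(ks.statistic), ks_pvalue=float(ks.pvalue), precision_table=table)


# ---------------------------------------------------------------------------
# regulon coexpression / cofitness
# ---------------------------------------------------------------------------

@dataclass
class RegulonCorrelation:
    observed: pd.DataFrame          # tf, target, r
    shuffled: np.ndarray            # pooled correlations of shuffled pairs
    shift: float                    # observed median - shuffled median
    n_excluded_autoregulatory: int
    n_excluded_missing: int
    shuffled_quantile: pd.Series = field(default=None)


def _pair_correlations(pairs: list[tuple[str, str]], matrix: pd.DataFrame) -> list[float]:
    out = []
    for tf, tg in pairs:
        x = matrix.loc[tf].to_numpy(dtype=float)
        y = matrix.loc[tg].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out.append(np.nan)
        else:
            out.append(float(np.corrcoef(x[ok], y[ok])[0, 1]))
    return out


def regulon_correlation(
    pairs: list[tuple[str, str]] | pd.DataFrame,
    matrix: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
) -> RegulonCorrelation:
    """Correlation of regulator-target pairs against a shuffled null.

    Autoregulatory pairs (TF = target) are excluded from both the observed
    pairs and every shuffled control. The null redraws target assignments
    by permuting targets across pairs ``n_shuffles`` times. The ``shift``
    statistic is the difference of medians (observed - shuffled).
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = list(zip(pairs.iloc[:, 0], pairs.iloc[:, 1]))
    n_missing = sum(1 for tf, tg in pairs
                    if tf not in matrix.index or tg not in matrix.index)
    usable = [(tf, tg) for tf, tg in pairs
              if tf in matrix.index and tg in matrix.index]
    n_auto = sum(1 for tf, tg in usable if tf == tg)
    usable = [(tf, tg) for tf, tg in usable if tf != tg]
    if not usable:
        raise ParameterError("no usable regulator-target pairs")

    obs_r = _pair_correlations(usable, matrix)
    observed = pd.DataFrame(usable, columns=["tf", "target"])
    observed["r"] = obs_r

    rng = np.random.default_rng(seed)
    tfs = [tf for tf, _ in usable]
    targets = np.array([tg for _, tg in usable], dtype=object)
    pooled = []
    for _ in range(n_shuffles):
        perm = rng.permutation(targets)
        shuffled_pairs = [(tf, tg) for tf, tg in zip(tfs, perm) if tf != tg]
        pooled.extend(_pair_correlations(shuffled_pairs, matrix))
    shuffled = np.array([v for v in pooled if np.isfinite(v)])

    obs_vals = observed["r"].dropna().to_numpy()
    shift = float(np.median(obs_vals) - np.median(shuffled)) if len(shuffled) else np.nan
    quant = pd.Series(
        [float((shuffled <= r).mean()) if np.isfinite(r) else np.nan
         for r in observed["r"]],
        index=observed.index, name="shuffled_quantile",
    )
    return RegulonCorrelation(
        observed=observed, shuffled=shuffled, shift=shift,
        n_excluded_autoregulatory=n_auto, n_excluded_missing=n_missing,
        shuffled_quantile=quant,
    )
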