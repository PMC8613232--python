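"""Statistical evaluation of descriptor tables.

Three analyses mirror the evaluation protocol the descriptors are used in:

1. :func:`group_comparison` — Kruskal-Wallis omnibus per descriptor with
   Benjamini-Hochberg adjustment across descriptors, then Dunn pairwise
   post-hoc z tests Bonferroni-corrected within each descriptor.
2. :func:`bootstrap_feature_importance` — balanced bootstrap resampling,
   regularised logistic regression (lasso / ridge / elastic-net) along a
   lambda path with fivefold cross-validated AUC selecting lambda_min and
   lambda_1SE, and non-zero coefficient counts as feature importance.
3. :func:`agreement_analysis` — manual-vs-automatic agreement: Dice overlap
   of masks, relative errors of descriptor values (manual as reference),
   Pearson correlation, and Wilcoxon rank-sum group contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from ._enet import enet_logistic_path, lambda_path
from .errors import DegenerateInputError
from .morphology import Mask

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonReport",
    "BootstrapConfig",
    "ImportanceReport",
    "AgreementReport",
    "group_comparison",
    "dunn_posthoc",
    "bootstrap_feature_importance",
    "dice",
    "relative_error",
    "agreement_analysis",
]

REGULARISER_MIXING = {"lasso": 1.0, "ridge": 0.0, "elastic_net": 0.5}


# --------------------------------------------------------------------------
# experiment 1: group comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonReport:
    """Per-parameter omnibus and post-hoc results.

    ``omnibus`` rows: parameter, H, p_raw, p_adjusted, significant, plus one
    ``mean_<group>`` / ``sd_<group>`` column pair per group.  ``posthoc``
    rows: parameter, group_a, group_b, z, p_raw, p_bonferroni, significant
    (present only for parameters whose adjusted omnibus p survives).
    """

    omnibus: pd.DataFrame
    posthoc: pd.DataFrame
    alpha_level: float


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank tests with tie correction and Bonferroni.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with
    T = sum(t^3 - t) / (12(N-1)) over tie groups; two-sided normal p-values
    multiplied by the number of pairs (capped at 1).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start: start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "z": z,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return pd.DataFrame(rows)


def group_comparison(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    *,
    group_column: str = "group_label",
    alpha_level: float = 0.05,
) -> GroupComparisonReport:
    """Kruskal-Wallis per parameter, BH across parameters, Dunn post-hoc.

    ``table`` holds one row per image with descriptor columns and a group
    column.  Parameters where any group has fewer than 2 observations are
    skipped with a warning.  Post-hoc tables are reported only for
    parameters whose BH-adjusted omnibus p-value falls below
    ``alpha_level``.
    """
    if parameters is None:
        parameters = [
            c for c in table.columns
            if c not in (group_column, "image_id") and pd.api.types.is_numeric_dtype(table[c])
        ]
    group_names = list(pd.unique(table[group_column]))
    if len(group_names) < 2:
        raise DegenerateInputError("group comparison needs >= 2 groups")
    omnibus_rows, usable = [], []
    for param in parameters:
        groups = {
            g: table.loc[table[group_column] == g, param].dropna().to_numpy()
            for g in group_names
        }
        if any(len(v) < 2 for v in groups.values()):
            logger.warning("parameter %r skipped: a group has < 2 observations", param)
            continue
        if np.ptp(np.concatenate(list(groups.values()))) == 0:
            h_stat, p_raw = 0.0, 1.0  # all observations tied
        else:
            h_stat, p_raw = sps.kruskal(*groups.values())
        row = {"parameter": param, "H": float(h_stat), "p_raw": float(p_raw)}
        for g in group_names:
            row[f"mean_{g}"] = float(groups[g].mean())
            row[f"sd_{g}"] = float(groups[g].std(ddof=1))
        omnibus_rows.append(row)
        usable.append((param, groups))
    if not omnibus_rows:
        raise DegenerateInputError("no parameter had enough data in every group")
    omnibus = pd.DataFrame(omnibus_rows)
    reject, p_adj, *_ = multipletests(
        omnibus["p_raw"].to_numpy(), alpha=alpha_level, method="fdr_bh"
    )
    omnibus["p_adjusted"] = p_adj
    omnibus["significant"] = reject
    posthoc_frames = []
    for (param, groups), sig in zip(usable, reject):
        if not sig:
            continue
        ph = dunn_posthoc(groups)
        ph.insert(0, "parameter", param)
        ph["significant"] = ph["p_bonferroni"] < alpha_level
        posthoc_frames.append(ph)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(
            columns=["parameter", "group_a", "group_b", "z", "p_raw",
                     "p_bonferroni", "significant"]
        )
    )
    return GroupComparisonReport(omnibus=omnibus, posthoc=posthoc, alpha_level=alpha_level)


# --------------------------------------------------------------------------
# experiment 2: bootstrapped feature importance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapConfig:
    n_trials: int = 500
    per_class: int = 40
    n_folds: int = 5
    regularisers: tuple = ("lasso", "ridge", "elastic_net")
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4


@dataclass(frozen=True)
class ImportanceReport:
    """Non-zero counts per (regulariser, lambda rule) and AUC per regulariser.

    ``counts`` maps (regulariser, "lambda_min" | "lambda_1se") to a
    feature-name -> count dict; ``auc`` maps regulariser to
    (mean, ci_low, ci_high) over trials.
    """

    counts: dict
    auc: dict
    feature_names: tuple
    config: BootstrapConfig
    seed: int

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for (reg, rule), d in self.counts.items():
            row = {"regulariser": reg, "lambda_rule": rule}
            row.update(d)
            mean, lo, hi = self.auc[reg]
            row["auc_mean"], row["auc_ci_low"], row["auc_ci_high"] = mean, lo, hi
            rows.append(row)
        return pd.DataFrame(rows)


def _standardise(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC per column of ``scores`` (midranks, ties averaged).

    Equivalent to scikit-learn's ``roc_auc_score`` (asserted in the tests)
    but vectorised over a whole lambda path at once.
    """
    y = np.asarray(y, bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = sps.rankdata(scores, method="average", axis=0)
    pos_rank_sum = ranks[y].sum(axis=0)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _cv_auc_per_lambda(X, y, lambdas, l1_ratio, n_folds, rs):
    """(n_folds, L) validation AUC matrix for a fixed lambda grid."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    aucs = np.full((n_folds, len(lambdas)), np.nan)
    for f, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, Xva = _standardise(X[tr], X[va])
        B, b0 = enet_logistic_path(Xtr, y[tr], lambdas, l1_ratio)
        scores = Xva @ B.T + b0  # (n_va, L)
        aucs[f] = _rank_auc(scores, y[va])
    return aucs


def bootstrap_feature_importance(
    features,
    labels,
    config: BootstrapConfig | None = None,
    seed: int = 0,
) -> ImportanceReport:
    """Balanced-bootstrap feature importance for a binary outcome.

    Per trial: ``per_class`` members are resampled with replacement from
    each class; a lambda path is fitted per regulariser on the standardised
    trial sample; fivefold cross-validated AUC (per-fold mean) selects
    lambda_min (AUC maximiser) and lambda_1SE (largest lambda within one
    standard error of the maximum); non-zero coefficients of the full-sample
    fit at both lambdas are tallied per feature.  The reported AUC per
    regulariser is the mean over trials of the trial's cross-validated AUC
    at lambda_min, with a normal-approximation 95% CI across trials.
    """
    config = config or BootstrapConfig()
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X_all = features.to_numpy(dtype=float)
    else:
        X_all = np.asarray(features, dtype=float)
        names = tuple(f"feature_{i}" for i in range(X_all.shape[1]))
    y_all = np.asarray(labels).astype(int)
    if set(np.unique(y_all)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    keep = [i for i in range(X_all.shape[1]) if np.ptp(X_all[:, i]) > 0]
    if len(keep) < X_all.shape[1]:
        dropped = [names[i] for i in range(len(names)) if i not in keep]
        logger.warning("dropping constant feature(s): %s", dropped)
        X_all = X_all[:, keep]
        names = tuple(names[i] for i in keep)
    if X_all.shape[1] == 0:
        raise DegenerateInputError("no non-degenerate features left")
    pos = np.flatnonzero(y_all == 1)
    neg = np.flatnonzero(y_all == 0)
    if min(len(pos), len(neg)) < 2:
        raise DegenerateInputError(
            "both classes need >= 2 members for balanced bootstrap resampling"
        )
    rng = np.random.default_rng(seed)
    counts = {
        (reg, rule): np.zeros(X_all.shape[1], dtype=int)
        for reg in config.regularisers
        for rule in ("lambda_min", "lambda_1se")
    }
    trial_aucs = {reg: np.empty(config.n_trials) for reg in config.regularisers}
    for t in range(config.n_trials):
        idx = np.concatenate(
            [
                rng.choice(pos, size=config.per_class, replace=True),
                rng.choice(neg, size=config.per_class, replace=True),
            ]
        )
        X, y = X_all[idx], y_all[idx]
        fold_seed = int(rng.integers(2**31 - 1))
        for reg in config.regularisers:
            l1 = REGULARISER_MIXING[reg]
            Xs, = _standardise(X)
            lambdas = lambda_path(
                Xs, y, l1, n_lambdas=config.n_lambdas,
                min_ratio=config.lambda_min_ratio,
            )
            aucs = _cv_auc_per_lambda(X, y, lambdas, l1, config.n_folds, fold_seed)
            mean_auc = aucs.mean(axis=0)
            i_min = int(np.argmax(mean_auc))
            se = aucs[:, i_min].std(ddof=1) / np.sqrt(config.n_folds)
            ok = mean_auc >= mean_auc[i_min] - se
            i_1se = int(np.flatnonzero(ok)[0])  # lambdas are decreasing
            B, _b0 = enet_logistic_path(Xs, y, lambdas, l1)
            counts[(reg, "lambda_min")] += B[i_min] != 0
            counts[(reg, "lambda_1se")] += B[i_1se] != 0
            trial_aucs[reg][t] = mean_auc[i_min]
    auc_summary = {}
    for reg in config.regularisers:
        vals = trial_aucs[reg]
        mean = float(vals.mean())
        half = 1.959963984540054 * float(vals.std(ddof=1)) / np.sqrt(config.n_trials)
        auc_summary[reg] = (mean, mean - half, mean + half)
    count_dicts = {
        key: dict(zip(names, map(int, vec))) for key, vec in counts.items()
    }
    return ImportanceReport(
        counts=count_dicts, auc=auc_summary, feature_names=names,
        config=config, seed=seed,
    )


# --------------------------------------------------------------------------
# experiment 3: manual vs automatic agreement
# --------------------------------------------------------------------------

def dice(a: Mask | np.ndarray, b: Mask | np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of two same-shape masks."""
    ga = a.grid if isinstance(a, Mask) else np.asarray(a, bool)
    gb = b.grid if isinstance(b, Mask) else np.asarray(b, bool)
    if ga.shape != gb.shape:
        raise ValueError(f"mask shapes differ: {ga.shape} vs {gb.shape}")
    total = int(ga.sum()) + int(gb.sum())
    if total == 0:
        raise DegenerateInputError("Dice of two empty masks is undefined")
    return 2.0 * int((ga & gb).sum()) / total


def relative_error(reference_value: float, measured_value: float) -> float:
    """|AV - MV| / |AV| with the reference (manual) value AV."""
    if reference_value == 0:
        raise ValueError("relative error undefined for a zero reference value")
    return abs(reference_value - measured_value) / abs(reference_value)


@dataclass(frozen=True)
class AgreementReport:
    """Manual-vs-automatic agreement tables.

    ``per_parameter`` rows: parameter, mre, max_re, pearson_r, pearson_p,
    and rank-sum p-values between the two groups within the manual and
    within the automatic measurements.  ``per_image`` rows: image_id, dsc,
    group_label.  ``dsc_by_group``: group -> (mean, sd).
    """

    per_parameter: pd.DataFrame
    per_image: pd.DataFrame
    dsc_by_group: dict


def agreement_analysis(
    manual: pd.DataFrame,
    automatic: pd.DataFrame,
    parameters: list[str] | None = None,
    *,
    manual_masks: dict | None = None,
    automatic_masks: dict | None = None,
    group_column: str = "group_label",
) -> AgreementReport:
    """Compare descriptor tables (and optionally masks) paired by image_id."""
    man = manual.set_index("image_id")
    aut = automatic.set_index("image_id")
    unpaired = sorted(set(man.index) ^ set(aut.index))
    if unpaired:
        raise ValueError(f"unpaired image ids: {unpaired}")
    ids = list(man.index)
    if len(ids) < 3:
        raise DegenerateInputError("agreement analysis needs >= 3 paired images")
    aut = aut.loc[ids]
    if parameters is None:
        parameters = [
            c for c in man.columns
            if c != group_column and pd.api.types.is_numeric_dtype(man[c])
            and man[c].notna().all() and aut[c].notna().all()
        ]
    group_names = list(pd.unique(man[group_column])) if group_column in man else []
    rows = []
    for param in parameters:
        av = man[param].to_numpy(dtype=float)
        mv = aut[param].to_numpy(dtype=float)
        res = np.array([relative_error(a, m) for a, m in zip(av, mv)])
        if np.ptp(av) == 0 or np.ptp(mv) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(av, mv)
        row = {
            "parameter": param,
            "mre": float(res.mean()),
            "max_re": float(res.max()),
            "pearson_r": float(r),
            "pearson_p": float(p),
        }
        if len(group_names) == 2:
            g0, g1 = group_names
            m0 = man.loc[man[group_column] == g0, param]
            m1 = man.loc[man[group_column] == g1, param]
            a0 = aut.loc[man[group_column] == g0, param]
            a1 = aut.loc[man[group_column] == g1, param]
            row["ranksum_p_manual"] = float(sps.ranksums(m0, m1).pvalue)
            row["ranksum_p_automatic"] = float(sps.ranksums(a0, a1).pvalue)
        rows.append(row)
    per_image_rows = []
    dsc_by_group: dict = {}
    if manual_masks is not None and automatic_masks is not None:
        for image_id in ids:
            d = dice(manual_masks[image_id], automatic_masks[image_id])
            per_image_rows.append(
                {
                    "image_id": image_id,
                    "dsc": d,
                    "group_label": man.loc[image_id, group_column]
                    if group_column in man
                    else None,
                }
            )
        per_image = pd.DataFrame(per_image_rows)
        for g, sub in per_image.groupby("group_label"):
            dsc_by_group[g] = (
                float(sub["dsc"].mean()),
                float(sub["dsc"].std(ddof=1)) if len(sub) > 1 else 0.0,
            )
    per_image = (
        pd.DataFrame(per_image_rows)
        if per_image_rows
        else pd.DataFrame(columns=["image_id", "dsc", "group_label"])
    )
    return AgreementReport(
        per_parameter=pd.DataFrame(rows),
        per_image=per_image,
        dsc_by_group=dsc_by_group,
    )
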