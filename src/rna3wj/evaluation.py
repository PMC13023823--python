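"""Evaluation metrics for angle predictions and skeleton reconstructions.

Angular error is the plain absolute difference per angle (both predicted
and native values live on the half-circle [0, 180], so no circular wrap is
applied).  ACC(tau) comes in three flavours: per-angle (fraction of
samples within tau for one angle), overall (mean of the three per-angle
accuracies, equivalently the double-sum form 1/(3N) sum_i sum_k I(.)),
and joint (all three angles of a junction within tau simultaneously).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import Rna3wjError
from .features import FEATURE_GROUPS
from .geometry import AngleSet, SkeletonStar, skeleton_rmsd


def angular_error(pred: AngleSet, truth: AngleSet) -> np.ndarray:
    """|predicted - native| per angle, degrees, no circular wrap."""
    return np.abs(pred.as_array() - truth.as_array())


@dataclass(frozen=True)
class AccResult:
    per_angle: tuple  # ACC(tau) for theta1..theta3
    overall: float  # 1/(3N) double sum
    joint: float  # all three within tau


def acc(errors, tau: float) -> AccResult:
    """Accuracy under tolerance ``tau`` from an (N, 3) array of |errors|."""
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise Rna3wjError("acc of an empty error list is undefined")
    if tau <= 0:
        raise ValueError("tau must be positive")
    hits = errors <= tau
    per_angle = tuple(float(h) for h in hits.mean(axis=0))
    return AccResult(per_angle, float(hits.mean()), float(hits.all(axis=1).mean()))


def mae(errors) -> float:
    """Mean absolute deviation across the three angles of one junction."""
    e = np.asarray(errors, dtype=float).reshape(3)
    return float(np.mean(e))


@dataclass(frozen=True)
class RmsdReport:
    values: tuple
    mean: float
    bins: dict  # counts for "0-1", "1-2", ">2" Angstrom ranges


def rmsd_report(pairs) -> RmsdReport:
    """Per-instance skeleton RMSD for (predicted, native) star pairs."""
    pairs = list(pairs)
    if not pairs:
        raise Rna3wjError("rmsd_report of an empty input is undefined")
    values = tuple(skeleton_rmsd(p, n) for p, n in pairs)
    arr = np.asarray(values)
    bins = {
        "0-1": int(np.sum(arr < 1.0)),
        "1-2": int(np.sum((arr >= 1.0) & (arr < 2.0))),
        ">2": int(np.sum(arr >= 2.0)),
    }
    return RmsdReport(values, float(arr.mean()), bins)


def _group_slice(feature_group: str) -> slice:
    if feature_group not in FEATURE_GROUPS:
        raise KeyError(
            f"unknown feature group {feature_group!r}; expected one of {FEATURE_GROUPS}")
    k = FEATURE_GROUPS.index(feature_group)
    return slice(3 * k, 3 * k + 3)


def permutation_importance(results, dataset, feature_group: str,
                           repeats: int = 5, seed: int = 0,
                           tau: float = 20.0) -> float:
    """Mean drop in joint ACC(tau) when a tree-node feature group is
    shuffled across junction samples.

    The group's three columns are permuted among the junction nodes of the
    dataset's chains (non-junction nodes keep their values), predictions
    are recomputed, and the decrease in joint accuracy relative to the
    unpermuted dataset is averaged over ``repeats`` draws.
    """
    from .evaluation import acc as _acc  # noqa: PLW0406 (self, for clarity)
    from .model import JunctionDataset

    sl = _group_slice(feature_group)
    rng = np.random.default_rng(seed)
    truth = dataset.truth()

    def joint(ds):
        preds = results.predict_dataset(ds)
        errors = np.vstack([angular_error(p, t) for p, t in zip(preds, truth)])
        return _acc(errors, tau).joint

    base = joint(dataset)
    # gather the group's rows over all junction nodes
    locs = [(si, jid) for si, s in enumerate(dataset.samples)
            for jid in s.fc.junction_node_ids]
    block = np.vstack([dataset.samples[si].fc.tree_node_x[jid, sl]
                       for si, jid in locs])
    drops = []
    for _ in range(repeats):
        perm = rng.permutation(len(locs))
        import copy

        samples = []
        for s in dataset.samples:
            s2 = copy.copy(s)
            s2.fc = copy.copy(s.fc)
            s2.fc.tree_node_x = s.fc.tree_node_x.copy()
            samples.append(s2)
        for (si, jid), row in zip(locs, block[perm]):
            samples[si].fc.tree_node_x[jid, sl] = row
        drops.append(base - joint(JunctionDataset(samples)))
    return float(np.mean(drops))


def error_correlation(errors_a, errors_b):
    """Pearson correlation (r, p) between two per-sample error series."""
    from scipy.stats import pearsonr

    r, p = pearsonr(np.asarray(errors_a, float), np.asarray(errors_b, float))
    return float(r), float(p)


def report_to_csv(report: dict, path) -> None:
    import pandas as pd

    flat = {k: [v] if np.isscalar(v) else [str(v)] for k, v in report.items()}
    pd.DataFrame(flat).round(3).to_csv(path, index=False)
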