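"""Designed-truth ROC curves and AUC from the mixture comparison.

The tissue-selective subsets provide labels with known truth: miRNAs
selective for a variable component (brain, placenta) are designed true
positives — their between-mixture ratio is designed in — and the 1-to-1
class members are designed true negatives.  Non-selective miRNAs are
excluded.  With replicates, miRNAs are ranked by the p-value of a paired
t-test of the replicate-paired Mix1 vs Mix2 log2 signals; without
replication, by the absolute observed log2 ratio.  AUC is the
Mann-Whitney probability that a random true positive outranks a random
true negative (ties share midranks, giving diagonal ROC segments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .design import SampleManifest
from .ingest import Log2Table
from .mixture_model import RatioTable
from .performance import ReliableRange
from .selectivity import SelectivityClassification

__all__ = [
    "RocResult",
    "paired_pvalues",
    "unreplicated_scores",
    "roc_auc",
]


def paired_pvalues(
    log2_table: Log2Table, manifest: Optional[SampleManifest] = None
) -> pd.DataFrame:
    """Two-sided paired t-test of Mix1 vs Mix2 log2 signals per miRNA.

    Replicates are paired by replicate index.  Returns a DataFrame with a
    ``pvalue`` column and a ``note`` column flagging the degenerate cases:
    paired differences with zero variance and a nonzero mean get the
    machine-minimum p-value (perfectly consistent difference), and
    all-zero differences get p = 1 (null exactly true).
    """
    manifest = manifest or log2_table.manifest
    mixes = manifest.mixtures()
    if len(mixes) != 2:
        raise ValueError(f"paired test needs exactly 2 mixtures, found {mixes}")
    cols = {}
    for m in mixes:
        entries = sorted(
            (e for e in manifest.entries if e.role == f"mix:{m}"),
            key=lambda e: e.replicate_index,
        )
        cols[m] = [e.sample_id for e in entries]
        reps = [e.replicate_index for e in entries]
        if len(set(reps)) != len(reps):
            raise ValueError(f"duplicate replicate indices for mixture {m!r}")
    if len(cols[mixes[0]]) != len(cols[mixes[1]]):
        raise ValueError("mixtures have unequal replicate counts; pairing undefined")
    n = len(cols[mixes[0]])
    if n < 2:
        raise ValueError("paired t-test needs at least 2 replicates per mixture")

    diff = (
        log2_table.values[cols[mixes[0]]].to_numpy()
        - log2_table.values[cols[mixes[1]]].to_numpy()
    )
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    p = np.ones(len(diff))
    note = np.full(len(diff), "", dtype=object)

    # degenerate rows are judged at a small absolute tolerance so numeric
    # residue from normalization is not mistaken for a real difference (a
    # log2 difference of 1e-6 is far below any platform's resolution)
    atol = 1e-6
    regular = sd > atol
    with np.errstate(divide="ignore"):
        t = mean[regular] / (sd[regular] / np.sqrt(n))
    p[regular] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = ~regular & (np.abs(mean) > atol)
    p[zero_var] = np.finfo(float).tiny
    note[zero_var] = "zero_variance_nonzero_mean"
    note[~regular & (np.abs(mean) <= atol)] = "all_differences_zero"
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"pvalue": p, "note": note}, index=log2_table.values.index)


def unreplicated_scores(observed: RatioTable) -> pd.Series:
    """Ranking scores for the no-replication protocol: |observed M|."""
    return observed["M"].abs().rename("score")


@dataclass
class RocResult:
    """ROC points and AUC, or the not-determined (ND) outcome.

    ``points`` is an (n, 2) array of (false-positive rate, true-positive
    rate) starting at (0, 0) and ending at (1, 1).
    """

    points: Optional[np.ndarray]
    auc: Optional[float]
    n_true_pos: int
    n_true_neg: int
    restricted_to_range: bool
    defined: bool
    reason: Optional[str] = None


def roc_auc(
    values: pd.Series,
    classification: SelectivityClassification,
    kind: Literal["pvalue", "score"],
    range_filter: Optional[ReliableRange] = None,
    A_values: Optional[pd.Series] = None,
) -> RocResult:
    """Threshold-sweep ROC over the designed truth labels.

    ``values`` maps miRNA to a p-value (smaller = more positive) or a
    score (larger = more positive).  True positives are the
    variable-component selective classes, true negatives the 1-to-1
    class; non-selective miRNAs never enter.  With ``range_filter`` the
    label set is restricted to miRNAs whose ``A_values`` fall inside the
    reliable range (scores are unchanged).  Returns an ND result when
    either label set is empty after filtering, or when the filter itself
    is not determined.
    """
    if kind not in ("pvalue", "score"):
        raise ValueError(f"kind must be 'pvalue' or 'score', got {kind!r}")
    restricted = range_filter is not None
    tp = classification.true_positives()
    tn = classification.true_negatives()
    keep = tp.union(tn).intersection(values.index)
    if restricted:
        if not range_filter.defined:
            return RocResult(None, None, 0, 0, True, False,
                             reason="reliable range not determined")
        if A_values is None:
            raise ValueError("A_values required to restrict to the reliable range")
        inside = A_values.index[range_filter.contains(A_values)]
        keep = keep.intersection(inside)
    y = pd.Series(0, index=keep)
    y[keep.intersection(tp)] = 1
    n_tp, n_tn = int((y == 1).sum()), int((y == 0).sum())
    if n_tp == 0 or n_tn == 0:
        return RocResult(
            None, None, n_tp, n_tn, restricted, False,
            reason="insufficient true positives or true negatives",
        )
    score = values.loc[keep].astype(float)
    if kind == "pvalue":
        score = -score
    fpr, tpr, _ = roc_curve(y.to_numpy(), score.to_numpy(), drop_intermediate=False)
    auc = float(roc_auc_score(y.to_numpy(), score.to_numpy()))
    return RocResult(
        points=np.column_stack([fpr, tpr]),
        auc=auc,
        n_true_pos=n_tp,
        n_true_neg=n_tn,
        restricted_to_range=restricted,
        defined=True,
    )
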