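"""Tissue-selectivity classification of miRNAs from pure-component profiles.

A miRNA is *tissue-selective* when its mean signal in one pure component
is at least ``fold`` (default 10) times its mean in each of the others.
Selectivity in a *variable* component (one whose mixture fraction differs
between the two mixtures, e.g. brain or placenta) makes the miRNA a
designed true positive.  The designed true negatives form the *1-to-1*
class: miRNAs selective for the invariant component (liver, whose
fraction is the same in both mixtures) plus miRNAs with approximately
equal signal in the two variable components.  Everything else detected is
non-selective and sits between the design's ratio limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .ingest import ExpressionTable

__all__ = [
    "NON_SELECTIVE",
    "ONE_TO_ONE",
    "PureProfile",
    "SelectivityClassification",
    "pure_profile",
    "classify_selectivity",
    "class_counts",
]

NON_SELECTIVE = "non_selective"
ONE_TO_ONE = "one_to_one"
SUBTYPE_NONE = "none"

_CANONICAL = ("liver", "brain", "placenta")


@dataclass
class PureProfile:
    """Linear-scale mean signal of each miRNA in each pure component.

    Means are taken across the pure-sample replicates of the processed
    (filtered, normalized) table; one column per design component.
    """

    linear_means: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.linear_means.to_numpy() < 0).any():
            raise ValueError("pure-profile means must be nonnegative")
        if self.linear_means.columns.has_duplicates or self.linear_means.index.has_duplicates:
            raise ValueError("duplicate component or miRNA labels in profile")

    @property
    def components(self) -> list[str]:
        return self.linear_means.columns.tolist()

    @property
    def mirna_ids(self) -> list[str]:
        return self.linear_means.index.tolist()


def pure_profile(table: ExpressionTable) -> PureProfile:
    """Average the pure-sample replicate columns of a linear-scale table."""
    comps = table.manifest.pure_components()
    if not comps:
        raise ValueError("manifest contains no pure samples")
    cols = {
        c: table.values[table.manifest.samples_for_role(f"pure:{c}")].mean(axis=1)
        for c in comps
    }
    return PureProfile(pd.DataFrame(cols))


@dataclass
class SelectivityClassification:
    """Per-miRNA selectivity class plus the subtype of 1-to-1 members.

    ``class_of`` maps each miRNA to ``"<component>_selective"`` (variable
    components), ``one_to_one`` or ``non_selective``.  ``subtype_of``
    distinguishes the two ways into the 1-to-1 class
    (``"<invariant>_selective"`` or ``"<b>_equals_<p>"``); it is
    ``"none"`` outside that class.
    """

    class_of: pd.Series
    subtype_of: pd.Series
    true_positive_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.class_of.index.equals(self.subtype_of.index):
            raise ValueError("class and subtype series must share an index")
        bad = (self.class_of == ONE_TO_ONE) & (self.subtype_of == SUBTYPE_NONE)
        if bad.any():
            raise ValueError("one_to_one members must carry a subtype")

    def labels(self) -> pd.Series:
        return self.class_of

    def true_positives(self) -> pd.Index:
        return self.class_of.index[self.class_of.isin(self.true_positive_classes)]

    def true_negatives(self) -> pd.Index:
        return self.class_of.index[self.class_of == ONE_TO_ONE]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"class": self.class_of, "subtype": self.subtype_of}).to_csv(
            path, sep="\t", index_label="mirna_id"
        )


def _split_components(
    components: list[str], design: Optional[MixtureDesign]
) -> tuple[list[str], list[str]]:
    """Partition components into invariant (equal fractions) and variable."""
    if design is not None:
        inv = [c for c in design.invariant_components() if c in components]
        var = [c for c in components if c not in inv]
        return inv, var
    if set(components) == set(_CANONICAL):
        return ["liver"], [c for c in components if c != "liver"]
    raise ValueError(
        "cannot infer which component is invariant; pass the mixture design"
    )


def classify_selectivity(
    profile: PureProfile,
    fold: float = 10.0,
    equality_tol_log2: float = 0.5,
    design: Optional[MixtureDesign] = None,
) -> SelectivityClassification:
    """Assign each miRNA a tissue-selectivity class.

    A miRNA is selective for component ``c`` iff its mean there is at
    least ``fold`` times its mean in every other component (the rule is
    exclusive for ``fold > 1``; all-zero rows are non-selective).
    Selectivity in the invariant component folds into ``one_to_one``.
    Non-selective miRNAs whose two variable-component means are both
    positive and within ``equality_tol_log2`` of each other on the log2
    scale are also ``one_to_one``.  Ratios are linear-scale statements, so
    classification is invariant to any global rescaling of the profile.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if equality_tol_log2 <= 0:
        raise ValueError("equality_tol_log2 must be > 0")
    comps = profile.components
    invariant, variable = _split_components(comps, design)
    if len(variable) != 2:
        raise ValueError(
            f"equality-based 1-to-1 classification needs exactly 2 variable "
            f"components, got {variable}"
        )
    means = profile.linear_means
    m = means.to_numpy()
    nonzero_row = m.max(axis=1) > 0

    cls = pd.Series(NON_SELECTIVE, index=means.index, dtype=object)
    sub = pd.Series(SUBTYPE_NONE, index=means.index, dtype=object)

    for j, comp in enumerate(comps):
        others = [k for k in range(len(comps)) if k != j]
        selective = nonzero_row & np.all(
            m[:, [j]] >= fold * m[:, others], axis=1
        ) & (m[:, j] > 0)
        if comp in invariant:
            cls[selective] = ONE_TO_ONE
            sub[selective] = f"{comp}_selective"
        else:
            cls[selective] = f"{comp}_selective"

    b, p = variable
    vb, vp = means[b].to_numpy(), means[p].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.abs(np.log2(vb) - np.log2(vp))
    equalish = (
        (cls == NON_SELECTIVE).to_numpy()
        & (vb > 0)
        & (vp > 0)
        & (gap <= equality_tol_log2)
    )
    cls[equalish] = ONE_TO_ONE
    sub[equalish] = f"{b}_equals_{p}"

    return SelectivityClassification(
        class_of=cls,
        subtype_of=sub,
        true_positive_classes=tuple(f"{c}_selective" for c in variable),
    )


def class_counts(classification: SelectivityClassification) -> dict[str, int]:
    """Tally detected miRNAs per class (the dashboard's detection metrics).

    Keys: ``non_selective``, ``one_to_one`` and one ``<component>_selective``
    entry per variable component; values sum to the number detected.
    """
    counts = {NON_SELECTIVE: 0, ONE_TO_ONE: 0}
    counts.update({c: 0 for c in classification.true_positive_classes})
    for label, n in classification.class_of.value_counts().items():
        counts[label] = int(n)
    return counts
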