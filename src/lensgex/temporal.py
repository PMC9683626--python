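"""Trajectory classification of cataract-progression marker genes.

Two steps define a gene's trajectory: control → galactose Day 4 (step 1) and
galactose Day 4 → Day 6 (step 2).  The control arm has a single array, so
step 1 is judged on the fold change of group means against the 1.5-fold
threshold; step 2 has three arrays per side and is judged on both fold
(>1.5) and a two-tailed equal-variance t-test (p < 0.05) across samples.

Classes (mutually exclusive, collectively exhaustive over tested genes):

* ``early_plateau`` — up at step 1, no significant move at step 2 (the
  dominant pattern: expression peaks with initial opacity and stays there);
* ``monotonic_rise`` — up at step 1 and significantly up ≥ fold at step 2
  (the Hspa1b pattern, tracking cataract progression);
* ``early_peak`` — up at step 1, significantly down ≥ fold at step 2;
* ``late_rise`` — *no* step-1 increase (fold < threshold) but significantly
  up ≥ fold at step 2 (markers of the late stage);
* ``unchanged`` — neither step moves;
* ``other`` — remaining combinations (e.g. the mirrored down arm of step 1,
  for which the same thresholds are applied symmetrically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .errors import ConfigurationError
from .io import DEFAULT_EPSILON, SignalMatrix
from .screen import group_contrast

CLASSES = ("early_plateau", "monotonic_rise", "early_peak", "late_rise", "unchanged", "other")


def classify_temporal(
    matrix: SignalMatrix,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Classify every gene of ``matrix`` into a trajectory class.

    Returns a DataFrame indexed by gene with columns ``class``,
    ``fold_step1``, ``fold_step2``, ``p_step2``.
    """
    control = matrix.samples_where(condition="control")
    day4 = matrix.samples_where(condition="galactose", day=4)
    day6 = matrix.samples_where(condition="galactose", day=6)
    if not control or not day4 or not day6:
        raise ConfigurationError("temporal classification needs control, Day-4 and Day-6 samples")
    if len(day4) < 2 or len(day6) < 2:
        raise ConfigurationError("need >= 2 replicates per galactose day for the step-2 test")

    step1 = group_contrast(matrix, control, day4, epsilon=epsilon)
    step2 = group_contrast(matrix, day4, day6, epsilon=epsilon)

    f1 = step1["fold_change"]
    f2 = step2["fold_change"]
    p2 = step2["p_value"]

    up1 = f1 > fold_threshold
    down1 = f1 < 1.0 / fold_threshold
    sig_up2 = (p2 < alpha) & (f2 > fold_threshold)
    sig_down2 = (p2 < alpha) & (f2 < 1.0 / fold_threshold)
    flat2 = ~(sig_up2 | sig_down2)

    cls = pd.Series("other", index=f1.index, name="class")
    cls[up1 & flat2] = "early_plateau"
    cls[up1 & sig_up2] = "monotonic_rise"
    cls[up1 & sig_down2] = "early_peak"
    cls[~up1 & ~down1 & sig_up2] = "late_rise"
    cls[~up1 & ~down1 & flat2] = "unchanged"

    return pd.DataFrame(
        {"class": cls, "fold_step1": f1, "fold_step2": f2, "p_step2": p2},
        index=f1.index,
    )


class TemporalMarkerModel:
    """Trajectory-class model over a signal matrix.

    ``fit()`` returns :class:`TemporalResults` with the per-gene
    classification, class counts, and a ``summary()`` table.
    """

    def __init__(self, matrix: SignalMatrix, fold_threshold: float = 1.5, alpha: float = 0.05):
        if fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not 0 < alpha < 1:
            raise ValueError("alpha outside (0, 1)")
        self.matrix = matrix
        self.fold_threshold = fold_threshold
        self.alpha = alpha

    def fit(self) -> "TemporalResults":
        table = classify_temporal(self.matrix, self.fold_threshold, self.alpha)
        return TemporalResults(self, table)


@dataclass
class TemporalResults:
    model: TemporalMarkerModel
    classification: pd.DataFrame

    @property
    def class_counts(self) -> pd.Series:
        counts = self.classification["class"].value_counts()
        return counts.reindex(CLASSES, fill_value=0)

    def genes_of(self, cls: str) -> list[str]:
        table = self.classification
        return list(table.index[table["class"] == cls])

    def accuracy(self, truth_labels: pd.Series, classes: tuple[str, ...] = CLASSES[:4]) -> float:
        """Recovery accuracy over planted trajectory-class genes.

        Scored over the planted genes present in the classified matrix;
        genes dropped upstream (e.g. by the low-signal filter) were never
        tested and are excluded from the denominator.
        """
        planted = truth_labels[truth_labels.isin(classes)]
        planted = planted[planted.index.isin(self.classification.index)]
        if planted.empty:
            return float("nan")
        predicted = self.classification.loc[planted.index, "class"]
        return float((predicted == planted).mean())

    def summary(self) -> SimpleTable:
        rows = [[c, str(int(n))] for c, n in self.class_counts.items()]
        return SimpleTable(
            rows,
            headers=["class", "genes"],
            title=(
                f"Temporal trajectory classes (fold>{self.model.fold_threshold:g}, "
                f"p<{self.model.alpha:g})"
            ),
        )
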