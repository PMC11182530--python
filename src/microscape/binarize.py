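"""Occurrence-state binarization of assemblage abundances.

An assemblage is "activated" (+1) in a sample when its abundance exceeds the
upper 25th percentile of that assemblage's abundances across all samples of
the same disease class; otherwise the state is -1.  The percentile is the
order statistic of rank ceil(q*N) with no interpolation, and the comparison
is strict, so with distinct values exactly floor(N/4) samples per assemblage
are activated at the default quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import AssemblageAbundance

__all__ = ["OccurrenceMatrix", "binarize_occurrences", "binarize_by_class"]


@dataclass
class OccurrenceMatrix:
    """N x I matrix of +/-1 assemblage occurrence states for one class.

    ``thresholds`` records the per-assemblage cutoffs used; it is ``None``
    for occurrence matrices that did not come from binarization (e.g. draws
    from the model distribution).
    """

    states: np.ndarray
    sample_ids: list
    class_label: str
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("states must be a non-empty 2-D matrix")
        if not np.isin(self.states, (-1, 1)).all():
            raise ValueError("occurrence states must be +1 or -1")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if not np.isfinite(self.thresholds).all():
                raise ValueError("thresholds must be finite")
            if self.thresholds.shape != (self.states.shape[1],):
                raise ValueError("one threshold per assemblage required")
        if len(self.sample_ids) != self.states.shape[0]:
            raise ValueError("sample_ids length does not match states")

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def I(self) -> int:
        return self.states.shape[1]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.states,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"assemblage_{i}" for i in range(1, self.I + 1)],
        )
        df.insert(0, "class_label", self.class_label)
        df.to_csv(path, sep="\t")


def _upper_quartile_thresholds(theta: np.ndarray, quantile: float) -> np.ndarray:
    """Per-column order statistic of rank ceil((1-quantile)*N), 1-based."""
    n = theta.shape[0]
    rank = math.ceil((1.0 - quantile) * n)
    rank = min(max(rank, 1), n)
    return np.sort(theta, axis=0)[rank - 1]


def binarize_occurrences(
    abund: AssemblageAbundance,
    quantile: float = 0.25,
    thresholds: np.ndarray | None = None,
) -> OccurrenceMatrix:
    """Binarize one class's abundances into +/-1 occurrence states.

    ``abund`` must contain samples of exactly one class.  Entries strictly
    greater than the per-assemblage threshold become +1, everything else -1
    (ties at the threshold are inactive).  ``thresholds`` overrides the
    within-class computation, e.g. with cutoffs pooled across classes.
    """
    if abund.n_samples < 1:
        raise ValueError("empty input")
    labels = set(abund.class_labels) if abund.class_labels is not None else {"all"}
    if len(labels) > 1:
        raise ValueError(
            f"binarization thresholds are per-class; got mixed classes {sorted(labels)}"
        )
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if thresholds is None:
        thresholds = _upper_quartile_thresholds(abund.theta, quantile)
    thresholds = np.asarray(thresholds, dtype=float)
    states = np.where(abund.theta > thresholds[None, :], 1, -1).astype(np.int8)
    return OccurrenceMatrix(
        states=states,
        sample_ids=list(abund.sample_ids),
        class_label=next(iter(labels)),
        thresholds=thresholds,
    )


def binarize_by_class(
    abund: AssemblageAbundance,
    quantile: float = 0.25,
    pool_classes: bool = False,
) -> dict:
    """Binarize a multi-class abundance table, one occurrence matrix per class.

    With ``pool_classes=True`` a single threshold vector is computed on all
    samples together and applied to every class (off by default: the standard
    rule conditions the percentile on the class).
    """
    if abund.class_labels is None:
        raise ValueError("class labels required")
    shared = (
        _upper_quartile_thresholds(abund.theta, quantile) if pool_classes else None
    )
    return {
        label: binarize_occurrences(abund.for_class(label), quantile, thresholds=shared)
        for label in sorted(set(abund.class_labels))
    }
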