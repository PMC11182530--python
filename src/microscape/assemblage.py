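"""Latent Dirichlet allocation of genera into co-occurrence assemblages.

A microbiome sample is treated as a bag of "occurrence events": each 16S read
(or count unit) carries a latent assemblage attribute drawn from the sample's
assemblage-abundance vector theta, and a genus drawn from that assemblage's
composition vector phi.  Fitting the model on one sample per participant fixes
the assemblage compositions phi (an I x F row-stochastic matrix); the fitted
model is then applied with phi held fixed to obtain theta for every sample.

Fitting and inference delegate to scikit-learn's batch variational
``LatentDirichletAllocation``.  In this module's convention ``alpha`` is the
Dirichlet prior of the assemblage compositions phi and ``beta`` the prior of
the per-sample abundances theta (both symmetric, default 1/I).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import psi
from scipy.stats import kruskal
from sklearn.decomposition import LatentDirichletAllocation

from .cohort import TaxonProfileTable, ValidationError

__all__ = [
    "AssemblageModel",
    "AssemblageAbundance",
    "to_counts",
    "fit_assemblages",
    "infer_abundances",
    "dominant_genera",
    "shared_genus_network",
    "compare_class_abundance",
]


def to_counts(table: TaxonProfileTable, depth: int = 10_000) -> TaxonProfileTable:
    """Convert relative abundances to integer counts at a fixed depth.

    Each row is rescaled to sum to ``depth`` and rounded half-even; any
    rounding drift is repaired by largest-remainder adjustment so every
    non-zero row sums to exactly ``depth``.  All-zero rows stay all-zero.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    values = table.values.astype(float)
    out = np.zeros_like(values, dtype=np.int64)
    for r, row in enumerate(values):
        total = row.sum()
        if total == 0:
            continue
        scaled = row / total * depth
        rounded = np.rint(scaled).astype(np.int64)
        deficit = depth - int(rounded.sum())
        if deficit != 0:
            # push the correction onto the cells rounded farthest from their
            # real value, one unit at a time
            residual = scaled - rounded
            order = np.argsort(-np.sign(deficit) * residual, kind="stable")
            for idx in order[: abs(deficit)]:
                rounded[idx] += int(np.sign(deficit))
        out[r] = rounded
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return TaxonProfileTable(df, is_counts=True)


@dataclass
class AssemblageModel:
    """A fitted assemblage-composition model.

    ``phi`` is the I x F row-stochastic matrix of genus weights per
    assemblage; ``components`` keeps the unnormalised variational
    topic-word parameters so inference after (de)serialisation reproduces the
    original fit exactly.
    """

    phi: np.ndarray
    alpha: float
    beta: float
    I: int
    genus_names: list
    seed: int
    components: np.ndarray
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.I < 1:
            raise ValueError("I must be >= 1")
        if (self.phi < 0).any():
            raise ValueError("phi has negative entries")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")

    def _estimator(self) -> LatentDirichletAllocation:
        lda = LatentDirichletAllocation(
            n_components=self.I,
            topic_word_prior=self.alpha,
            doc_topic_prior=self.beta,
            random_state=self.seed,
        )
        lda.components_ = self.components
        dirichlet_expectation = psi(self.components) - psi(
            self.components.sum(axis=1)
        )[:, None]
        lda.exp_dirichlet_component_ = np.exp(dirichlet_expectation)
        lda.doc_topic_prior_ = self.beta
        lda.topic_word_prior_ = self.alpha
        lda.n_features_in_ = len(self.genus_names)
        return lda

    def save(self, directory) -> None:
        """Serialise the model to a directory of TSV/JSON files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        idx = [f"assemblage_{i}" for i in range(1, self.I + 1)]
        pd.DataFrame(self.phi, index=idx, columns=self.genus_names).to_csv(
            directory / "phi.tsv", sep="\t", index_label="assemblage"
        )
        pd.DataFrame(self.components, index=idx, columns=self.genus_names).to_csv(
            directory / "components.tsv", sep="\t", index_label="assemblage"
        )
        meta = {
            "alpha": self.alpha,
            "beta": self.beta,
            "I": self.I,
            "seed": self.seed,
            "fit_diagnostics": {
                k: v for k, v in self.fit_diagnostics.items() if k != "bound_trace"
            },
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "AssemblageModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        phi = pd.read_csv(directory / "phi.tsv", sep="\t", index_col=0)
        comp = pd.read_csv(directory / "components.tsv", sep="\t", index_col=0)
        return cls(
            phi=phi.to_numpy(),
            alpha=meta["alpha"],
            beta=meta["beta"],
            I=meta["I"],
            genus_names=list(phi.columns),
            seed=meta["seed"],
            components=comp.to_numpy(),
            fit_diagnostics=meta.get("fit_diagnostics", {}),
        )


@dataclass
class AssemblageAbundance:
    """Per-sample assemblage abundances theta (N x I, row-stochastic)."""

    theta: np.ndarray
    sample_ids: list
    class_labels: list | None = None

    def __post_init__(self) -> None:
        if (self.theta < 0).any():
            raise ValueError("theta has negative entries")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        if len(self.sample_ids) != self.theta.shape[0]:
            raise ValueError("sample_ids length does not match theta rows")

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def I(self) -> int:
        return self.theta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.theta,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"assemblage_{i}" for i in range(1, self.I + 1)],
        )
        if self.class_labels is not None:
            df.insert(0, "class_label", list(self.class_labels))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def for_class(self, label) -> "AssemblageAbundance":
        if self.class_labels is None:
            raise ValueError("no class labels attached")
        mask = np.array([c == label for c in self.class_labels])
        return AssemblageAbundance(
            theta=self.theta[mask],
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            class_labels=[label] * int(mask.sum()),
        )


def _check_count_input(counts: TaxonProfileTable) -> np.ndarray:
    values = counts.values
    if not counts.is_counts or not np.allclose(values, np.round(values)):
        raise ValidationError(
            "assemblage model requires integer counts; convert relative "
            "abundances with to_counts() first"
        )
    empty = np.asarray(counts.sample_ids)[values.sum(axis=1) == 0]
    if empty.size:
        raise ValidationError(f"all-zero samples cannot be modelled: {empty[:5].tolist()}")
    return values.astype(np.int64)


def fit_assemblages(
    counts: TaxonProfileTable,
    I: int = 9,
    alpha: float | None = None,
    beta: float | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> AssemblageModel:
    """Fit the I-assemblage composition model to an integer count table.

    Uses batch variational inference; the same seed and inputs give an
    identical ``phi``.  ``alpha``/``beta`` default to the symmetric 1/I prior.
    """
    X = _check_count_input(counts)
    if counts.n_samples < I:
        raise ValueError(f"need at least I={I} samples, got {counts.n_samples}")
    alpha = 1.0 / I if alpha is None else alpha
    beta = 1.0 / I if beta is None else beta
    lda = LatentDirichletAllocation(
        n_components=I,
        topic_word_prior=alpha,
        doc_topic_prior=beta,
        learning_method="batch",
        max_iter=max_iter,
        evaluate_every=5,
        perp_tol=tol,
        random_state=seed,
    )
    lda.fit(X)
    components = lda.components_
    phi = components / components.sum(axis=1, keepdims=True)
    diagnostics = {
        "algorithm": "batch variational Bayes",
        "iterations": int(lda.n_iter_),
        "final_bound": float(lda.bound_),
        "max_iter": max_iter,
        "tol": tol,
    }
    return AssemblageModel(
        phi=phi,
        alpha=alpha,
        beta=beta,
        I=I,
        genus_names=counts.genus_names,
        seed=seed,
        components=components,
        fit_diagnostics=diagnostics,
    )


def infer_abundances(
    model: AssemblageModel,
    counts: TaxonProfileTable,
    class_labels=None,
) -> AssemblageAbundance:
    """Infer per-sample assemblage abundances theta with phi held fixed."""
    if counts.genus_names != model.genus_names:
        missing = sorted(set(model.genus_names) - set(counts.genus_names))
        extra = sorted(set(counts.genus_names) - set(model.genus_names))
        raise ValidationError(
            f"genus vocabulary mismatch (missing: {missing[:5]}, extra: {extra[:5]})"
        )
    X = _check_count_input(counts)
    theta = model._estimator().transform(X)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return AssemblageAbundance(
        theta=theta,
        sample_ids=counts.sample_ids,
        class_labels=list(class_labels) if class_labels is not None else None,
    )


def _ranked_genera(phi_row: np.ndarray, genus_names, top_k: int):
    # descending weight, ties alphabetical
    order = sorted(range(len(genus_names)), key=lambda f: (-phi_row[f], genus_names[f]))
    return [(genus_names[f], float(phi_row[f])) for f in order[:top_k]]


def dominant_genera(model: AssemblageModel, top_k: int = 5):
    """Per-assemblage ranked list of the ``top_k`` heaviest genera.

    Returns a dict mapping assemblage index (1-based) to a list of
    ``(genus, weight)`` pairs sorted by descending weight, ties alphabetical.
    """
    if not 1 <= top_k <= len(model.genus_names):
        raise ValueError(f"top_k must be in [1, {len(model.genus_names)}]")
    return {
        i + 1: _ranked_genera(model.phi[i], model.genus_names, top_k)
        for i in range(model.I)
    }


def format_dominant_genera(model: AssemblageModel, top_k: int = 5) -> str:
    """Human-readable dominant-genus table, weights to 2 decimals."""
    lines = []
    for i, ranked in dominant_genera(model, top_k).items():
        entries = " and ".join(f"{g} ({w:.2f})" for g, w in ranked)
        lines.append(f"{i}\t{entries}")
    return "\n".join(lines)


def shared_genus_network(model: AssemblageModel, top_k: int = 5) -> nx.Graph:
    """Assemblage relation network weighted by shared dominant genera.

    Nodes are assemblage indices 1..I; an edge joins two assemblages whose
    top-``top_k`` genus sets intersect, weighted by the intersection size.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    top_k = min(top_k, len(model.genus_names))
    top_sets = {
        i: {g for g, _ in ranked} for i, ranked in dominant_genera(model, top_k).items()
    }
    G = nx.Graph()
    G.add_nodes_from(range(1, model.I + 1))
    for i in range(1, model.I + 1):
        for j in range(i + 1, model.I + 1):
            shared = top_sets[i] & top_sets[j]
            if shared:
                G.add_edge(i, j, weight=len(shared), genera=sorted(shared))
    return G


def compare_class_abundance(abund: AssemblageAbundance, class_labels=None) -> pd.DataFrame:
    """Kruskal-Wallis comparison of assemblage abundances across classes.

    Returns one row per assemblage with per-class mean abundances, the H
    statistic and the (uncorrected) p-value.  Identical samples in every
    class (all ties) yield statistic 0 and p-value 1.
    """
    labels = np.asarray(
        class_labels if class_labels is not None else abund.class_labels
    )
    if labels is None or len(labels) != abund.n_samples:
        raise ValueError("class labels must be provided for every sample")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in groups_idx.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rows = []
    for i in range(abund.I):
        col = abund.theta[:, i]
        groups = [col[idx] for idx in groups_idx.values()]
        try:
            stat, pval = kruskal(*groups)
        except ValueError:
            stat, pval = 0.0, 1.0
        if np.isnan(stat):  # all values identical: tie correction divides by 0
            stat, pval = 0.0, 1.0
        row = {"assemblage": i + 1}
        for c in classes:
            row[f"mean_{c}"] = float(col[groups_idx[c]].mean())
        row["statistic"] = float(stat)
        row["pvalue"] = float(pval)
        rows.append(row)
    return pd.DataFrame(rows)
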