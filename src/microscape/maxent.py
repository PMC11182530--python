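"""Exact pairwise maximum-entropy (Ising / Boltzmann) model over +/-1 patterns.

The maximum-entropy distribution constrained to match the first moments
<sigma_i> and second moments <sigma_i sigma_j> of the data is the Boltzmann
distribution

    P(sigma | h, g) = exp(-E(sigma)) / Z,
    E(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} g_ij sigma_i sigma_j,

with fields ``h`` (occurrence tendency of single assemblages) and symmetric
zero-diagonal couplings ``g`` (pairwise promotion/inhibition); kT is absorbed
into the parameters.  With I assemblages there are 2^I patterns, enumerated
exactly (no sampling), so the maximum-likelihood fit reduces to gradient
ascent on the concave log-likelihood, whose gradient is the gap between
empirical and model moments:

    h_i  <- h_i  + eps * (<sigma_i>_emp - <sigma_i>_model)
    g_ij <- g_ij + eps * (<sigma_i sigma_j>_emp - <sigma_i sigma_j>_model)

Pattern ids are 1-based: id = 1 + sum_{i active} 2^(i-1), so the all-inactive
pattern has id 1 and, at I = 9, the pattern with only assemblage 6 active has
id 33.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MAX_I",
    "MaxEntParams",
    "MomentPair",
    "FitReport",
    "enumerate_patterns",
    "pattern_id",
    "decode_pattern",
    "energy",
    "all_energies",
    "pattern_distribution",
    "empirical_moments",
    "model_moments",
    "fit_maxent",
    "log_likelihood",
]

#: enumeration guard: 2^I patterns are materialised
MAX_I = 20

__all__ += ["save_params", "load_params"]


def _check_I(I: int) -> None:
    if not 1 <= I <= MAX_I:
        raise ValueError(
            f"I={I} out of range [1, {MAX_I}]: exact enumeration requires 2^I patterns"
        )


@dataclass
class MaxEntParams:
    """Fields ``h`` (length I) and couplings ``g`` (I x I, symmetric, zero diag)."""

    h: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        I = self.h.shape[0]
        if self.h.ndim != 1 or self.g.shape != (I, I):
            raise ValueError("h must be length I and g I x I")
        if not np.allclose(self.g, self.g.T, atol=1e-12):
            raise ValueError("g must be symmetric")
        if np.any(self.g.diagonal() != 0):
            raise ValueError("g must have zero diagonal")

    @property
    def I(self) -> int:
        return self.h.shape[0]

    @classmethod
    def zeros(cls, I: int) -> "MaxEntParams":
        return cls(h=np.zeros(I), g=np.zeros((I, I)))


@dataclass
class MomentPair:
    """First moments <sigma_i> and second moments <sigma_i sigma_j>."""

    first: np.ndarray
    second: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        I = self.first.shape[0]
        if self.second.shape != (I, I):
            raise ValueError("second must be I x I")
        if np.any(np.abs(self.first) > 1 + 1e-12) or np.any(np.abs(self.second) > 1 + 1e-12):
            raise ValueError("moments of +/-1 variables must lie in [-1, 1]")
        if not np.allclose(self.second.diagonal(), 1.0):
            raise ValueError("second-moment diagonal must be 1 (sigma_i^2 = 1)")

    def max_gap(self, other: "MomentPair") -> float:
        """Largest absolute difference over all first and second moments."""
        off = ~np.eye(self.first.shape[0], dtype=bool)
        return max(
            float(np.abs(self.first - other.first).max()),
            float(np.abs((self.second - other.second)[off]).max(initial=0.0)),
        )


@dataclass
class FitReport:
    iterations: int
    max_moment_gap: float
    log_likelihood_trace: np.ndarray
    epsilon: float
    converged: bool
    tol: float = field(default=np.nan)


def enumerate_patterns(I: int) -> np.ndarray:
    """All 2^I patterns as a (2^I, I) matrix of +/-1, ordered by pattern id.

    Row ``p`` (0-based) is the pattern with id ``p + 1``; assemblage ``i``
    (1-based) is active in row ``p`` iff bit ``i-1`` of ``p`` is set.  The
    first row is the all-inactive pattern.
    """
    _check_I(I)
    ids = np.arange(2**I, dtype=np.int64)
    bits = (ids[:, None] >> np.arange(I)) & 1
    return (2 * bits - 1).astype(np.int8)


def pattern_id(sigma) -> int:
    """Encode a +/-1 pattern as its 1-based id: 1 + sum_{active i} 2^(i-1)."""
    sigma = np.asarray(sigma)
    if not np.isin(sigma, (-1, 1)).all():
        raise ValueError("pattern entries must be +1 or -1")
    active = np.flatnonzero(sigma == 1)
    return int(1 + (1 << active).sum())


def decode_pattern(pid: int, I: int) -> np.ndarray:
    """Inverse of :func:`pattern_id`: the +/-1 pattern with the given id."""
    _check_I(I)
    if not 1 <= pid <= 2**I:
        raise ValueError(f"pattern id {pid} out of range [1, {2**I}]")
    bits = ((pid - 1) >> np.arange(I)) & 1
    return (2 * bits - 1).astype(np.int8)


def active_assemblages(pid: int, I: int) -> tuple:
    """1-based indices of the assemblages active in pattern ``pid``."""
    sigma = decode_pattern(pid, I)
    return tuple(int(i) + 1 for i in np.flatnonzero(sigma == 1))


def energy(sigma, params: MaxEntParams) -> float:
    """E(sigma) = -sum_i h_i sigma_i - 1/2 sum_{i != j} g_ij sigma_i sigma_j."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (params.I,):
        raise ValueError(f"pattern length {sigma.shape} does not match I={params.I}")
    return float(-params.h @ sigma - 0.5 * sigma @ params.g @ sigma)


def all_energies(params: MaxEntParams, patterns: np.ndarray | None = None) -> np.ndarray:
    """Energies of all 2^I patterns, indexed by pattern id - 1."""
    S = enumerate_patterns(params.I) if patterns is None else patterns
    Sf = S.astype(float)
    return -Sf @ params.h - 0.5 * np.einsum("pi,ij,pj->p", Sf, params.g, Sf)


def pattern_distribution(params: MaxEntParams) -> np.ndarray:
    """Boltzmann probability of each of the 2^I patterns (log-sum-exp stable)."""
    neg_E = -all_energies(params)
    return np.exp(neg_E - logsumexp(neg_E))


def empirical_moments(occ) -> MomentPair:
    """Sample moments of an occurrence matrix (rows = samples of +/-1)."""
    states = occ.states if hasattr(occ, "states") else np.asarray(occ)
    if states.size == 0:
        raise ValueError("empty occurrence matrix")
    if not np.isin(states, (-1, 1)).all():
        raise ValueError("occurrence states must be +1 or -1")
    Sf = states.astype(float)
    first = Sf.mean(axis=0)
    second = (Sf.T @ Sf) / Sf.shape[0]
    np.fill_diagonal(second, 1.0)
    return MomentPair(first=first, second=second)


def model_moments(params: MaxEntParams, patterns: np.ndarray | None = None) -> MomentPair:
    """Exact expectations <sigma_i> and <sigma_i sigma_j> under the model."""
    S = enumerate_patterns(params.I) if patterns is None else patterns
    p = pattern_distribution(params)
    Sf = S.astype(float)
    first = Sf.T @ p
    second = (Sf * p[:, None]).T @ Sf
    np.fill_diagonal(second, 1.0)
    return MomentPair(first=first, second=second)


def log_likelihood(occ, params: MaxEntParams) -> float:
    """Sum over samples of log P(sigma_n | h, g); always <= 0."""
    states = occ.states if hasattr(occ, "states") else np.asarray(occ)
    if states.shape[1] != params.I:
        raise ValueError("occurrence matrix width does not match I")
    neg_E = -all_energies(params)
    log_p = neg_E - logsumexp(neg_E)
    ids0 = ((states == 1) << np.arange(params.I)).sum(axis=1)
    return float(log_p[ids0].sum())


def fit_maxent(
    occ,
    epsilon: float = 0.1,
    tol: float = 1e-5,
    max_iter: int = 50_000,
    weights: np.ndarray | None = None,
) -> tuple[MaxEntParams, FitReport]:
    """Maximum-likelihood fit of (h, g) by exact moment-matching gradient ascent.

    Starts from the uniform model (h = 0, g = 0) and iterates

        h  += eps * (first_emp - first_model)
        g  += eps * (second_emp - second_model)   (off-diagonal only)

    with model moments computed by exact enumeration, stopping when the
    largest absolute moment gap falls below ``tol``.  The log-likelihood is
    concave in (h, g) so the trace is non-decreasing for moderate ``eps``.
    ``g`` is updated on the upper triangle and mirrored, keeping it symmetric
    with a zero diagonal by construction.

    ``weights`` assigns a positive multiplicity to each row of ``occ``
    (default 1), so a distribution over patterns can be matched exactly by
    passing every pattern once with its probability as weight.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    states = occ.states if hasattr(occ, "states") else np.asarray(occ)
    if not np.isin(states, (-1, 1)).all():
        raise ValueError("occurrence states must be +1 or -1")
    I = states.shape[1]
    _check_I(I)
    if weights is None:
        w = np.ones(states.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (states.shape[0],) or (w <= 0).any():
            raise ValueError("weights must be positive, one per row")
    N = w.sum()
    Sf_data = states.astype(float)
    emp_first = (Sf_data.T @ w) / N
    emp_second = (Sf_data * w[:, None]).T @ Sf_data / N
    np.fill_diagonal(emp_second, 1.0)
    emp = MomentPair(first=emp_first, second=emp_second)
    S = enumerate_patterns(I)
    Sf = S.astype(float)
    # sufficient statistics: (weighted) frequency of each observed pattern
    ids0 = ((states == 1) << np.arange(I)).sum(axis=1)
    pattern_counts = np.bincount(ids0, weights=w, minlength=2**I)

    h = np.zeros(I)
    g = np.zeros((I, I))
    upper = np.triu_indices(I, k=1)
    ll_trace = np.empty(max_iter + 1)
    converged = False
    gap = np.inf
    it = 0
    for it in range(max_iter + 1):
        neg_E = Sf @ h + 0.5 * np.einsum("pi,ij,pj->p", Sf, g, Sf)
        log_Z = logsumexp(neg_E)
        p = np.exp(neg_E - log_Z)
        ll_trace[it] = float(pattern_counts @ neg_E - N * log_Z)
        first = Sf.T @ p
        second = (Sf * p[:, None]).T @ Sf
        np.fill_diagonal(second, 1.0)
        d_first = emp.first - first
        d_second = emp.second - second
        off = ~np.eye(I, dtype=bool)
        gap = max(
            float(np.abs(d_first).max()),
            float(np.abs(d_second[off]).max(initial=0.0)),
        )
        if gap < tol:
            converged = True
            break
        if it == max_iter:
            break
        h += epsilon * d_first
        dg = np.zeros((I, I))
        dg[upper] = epsilon * d_second[upper]
        g += dg + dg.T

    if not converged:
        warnings.warn(
            f"maxent fit did not reach tol={tol} after {max_iter} iterations "
            f"(max moment gap {gap:.3e})"
        )
    params = MaxEntParams(h=h, g=g)
    report = FitReport(
        iterations=it,
        max_moment_gap=gap,
        log_likelihood_trace=ll_trace[: it + 1].copy(),
        epsilon=epsilon,
        converged=converged,
        tol=tol,
    )
    return params, report


def save_params(params: MaxEntParams, prefix, report: FitReport | None = None) -> dict:
    """Write h and g as TSV blocks plus a JSON sidecar with fit metadata."""
    import json
    import pandas as pd

    prefix = str(prefix)
    labels = [f"assemblage_{i}" for i in range(1, params.I + 1)]
    h_path, g_path = f"{prefix}_h.tsv", f"{prefix}_g.tsv"
    pd.Series(params.h, index=labels, name="h").to_csv(
        h_path, sep="\t", index_label="assemblage", float_format="%.17g"
    )
    pd.DataFrame(params.g, index=labels, columns=labels).to_csv(
        g_path, sep="\t", index_label="assemblage", float_format="%.17g"
    )
    meta: dict = {"I": params.I}
    if report is not None:
        meta.update(
            epsilon=report.epsilon,
            tol=None if np.isnan(report.tol) else report.tol,
            iterations=report.iterations,
            converged=report.converged,
            max_moment_gap=report.max_moment_gap,
        )
    json_path = f"{prefix}_fit.json"
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    return {"h": h_path, "g": g_path, "meta": json_path}


def load_params(prefix) -> MaxEntParams:
    """Read back parameters written by :func:`save_params`."""
    import pandas as pd

    prefix = str(prefix)
    h = pd.read_csv(f"{prefix}_h.tsv", sep="\t", index_col=0)["h"].to_numpy()
    g = pd.read_csv(f"{prefix}_g.tsv", sep="\t", index_col=0).to_numpy()
    g = 0.5 * (g + g.T)
    np.fill_diagonal(g, 0.0)
    return MaxEntParams(h=h, g=g)
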