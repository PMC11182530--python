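"""Energy-landscape construction over all 2^I assemblage patterns.

Each pattern is linked to its lowest-energy Hamming-1 neighbor when that
neighbor's energy is strictly lower (steepest descent); a pattern with no
strictly lower neighbor is a local minimal pattern (LMP) and links to itself.
Following descent links partitions the 2^I patterns into energy basins, one
per LMP.  Low energy corresponds to high Boltzmann probability and is read
as high stability of the community configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .maxent import (
    MaxEntParams,
    all_energies,
    active_assemblages,
    decode_pattern,
    energy,
    pattern_id,
)

__all__ = [
    "EnergyLandscape",
    "neighbor_patterns",
    "build_landscape",
    "build_landscape_from_params",
    "find_lmps_bruteforce",
    "landscape_summary",
    "sample_energy_series",
    "export_landscape",
]


@dataclass
class EnergyLandscape:
    """Energies, steepest-descent links, LMPs and basins over all patterns.

    Arrays are indexed by pattern id - 1; ``descent_link`` and
    ``basin_label`` store 1-based pattern ids.  An LMP links to itself.
    """

    energies: np.ndarray
    descent_link: np.ndarray
    lmp_ids: frozenset
    basin_label: np.ndarray
    params: MaxEntParams | None = None

    def __post_init__(self) -> None:
        n = len(self.energies)
        self.I = int(n).bit_length() - 1
        if 2**self.I != n:
            raise ValueError("energies length must be a power of two")

    @property
    def n_patterns(self) -> int:
        return len(self.energies)

    def basin_sizes(self) -> dict:
        ids, counts = np.unique(self.basin_label, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def neighbor_patterns(sigma) -> list[np.ndarray]:
    """The I patterns at Hamming distance 1, ordered by flipped index."""
    sigma = np.asarray(sigma)
    if not np.isin(sigma, (-1, 1)).all():
        raise ValueError("pattern entries must be +1 or -1")
    out = []
    for i in range(len(sigma)):
        nb = sigma.copy()
        nb[i] = -nb[i]
        out.append(nb)
    return out


def _neighbor_index_matrix(I: int) -> np.ndarray:
    """(2^I, I) matrix of 0-based neighbor indices (bit flips)."""
    idx = np.arange(2**I, dtype=np.int64)
    return idx[:, None] ^ (1 << np.arange(I, dtype=np.int64))


def build_landscape(
    energies: np.ndarray, params: MaxEntParams | None = None
) -> EnergyLandscape:
    """Construct descent links, LMPs and basins from a full energy table.

    The steepest-descent link of a pattern is its minimum-energy neighbor if
    that energy is strictly below the pattern's own, with ties among equally
    minimal strictly-lower neighbors broken by lowest pattern id; otherwise
    the pattern links to itself and is an LMP.  Basins follow descent links
    to their terminal LMP (termination is guaranteed by strict descent).
    """
    energies = np.asarray(energies, dtype=float)
    n = len(energies)
    I = int(n).bit_length() - 1
    if 2**I != n:
        raise ValueError("energies must cover all 2^I patterns")
    neigh = _neighbor_index_matrix(I)
    nE = energies[neigh]
    n_min = nE.min(axis=1)
    # among neighbors at the minimal energy, take the lowest pattern id
    candidates = np.where(nE == n_min[:, None], neigh, n)
    best = candidates.min(axis=1)
    self_idx = np.arange(n)
    link = np.where(n_min < energies, best, self_idx)
    lmps = frozenset((np.flatnonzero(link == self_idx) + 1).tolist())
    basin = link.copy()
    while True:
        nxt = link[basin]
        if np.array_equal(nxt, basin):
            break
        basin = nxt
    return EnergyLandscape(
        energies=energies,
        descent_link=(link + 1).astype(np.int64),
        lmp_ids=lmps,
        basin_label=(basin + 1).astype(np.int64),
        params=params,
    )


def build_landscape_from_params(params: MaxEntParams) -> EnergyLandscape:
    """Evaluate E(sigma) for all 2^I patterns and build the landscape."""
    return build_landscape(all_energies(params), params=params)


def find_lmps_bruteforce(energies: np.ndarray) -> frozenset:
    """Local minima by direct definition: no Hamming-1 neighbor strictly lower.

    Independent oracle for :func:`build_landscape`: enumerates each pattern's
    neighbors by explicit single-bit flips rather than via descent links.
    """
    energies = np.asarray(energies, dtype=float)
    n = len(energies)
    I = int(n).bit_length() - 1
    if 2**I != n:
        raise ValueError("energies must cover all 2^I patterns")
    lmps = set()
    for p in range(n):
        sigma = decode_pattern(p + 1, I)
        is_min = True
        for nb in neighbor_patterns(sigma):
            if energies[pattern_id(nb) - 1] < energies[p]:
                is_min = False
                break
        if is_min:
            lmps.add(p + 1)
    return frozenset(lmps)


def landscape_summary(ls: EnergyLandscape) -> pd.DataFrame:
    """One row per LMP: id, active assemblages, energy, basin size (by energy)."""
    sizes = ls.basin_sizes()
    rows = [
        {
            "pattern_id": pid,
            "active_assemblages": active_assemblages(pid, ls.I),
            "energy": float(ls.energies[pid - 1]),
            "basin_size": sizes.get(pid, 0),
        }
        for pid in sorted(ls.lmp_ids)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["energy", "pattern_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def sample_energy_series(occ, params: MaxEntParams, metadata: pd.DataFrame):
    """Per-sample energies ordered by participant and visit, plus class pools.

    Returns ``(series, pooled)``: ``series`` is a DataFrame with one row per
    sample (participant_id, visit_index, sample_id, class_label, energy)
    sorted by participant then visit; ``pooled`` maps each class label to the
    array of its sample energies (the class-level energy distribution).
    """
    md = metadata.set_index("sample_id")
    missing = [s for s in occ.sample_ids if s not in md.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    energies = [energy(row, params) for row in occ.states]
    df = pd.DataFrame(
        {
            "sample_id": occ.sample_ids,
            "participant_id": md.loc[occ.sample_ids, "participant_id"].to_numpy(),
            "visit_index": md.loc[occ.sample_ids, "visit_index"].to_numpy(),
            "class_label": md.loc[occ.sample_ids, "class_label"].to_numpy(),
            "energy": energies,
        }
    )
    df = df.sort_values(["participant_id", "visit_index"], kind="mergesort")
    df = df.reset_index(drop=True)
    pooled = {
        label: grp["energy"].to_numpy() for label, grp in df.groupby("class_label")
    }
    return df, pooled


def _state_string(pid: int, I: int) -> str:
    return "".join("+" if s == 1 else "-" for s in decode_pattern(pid, I))


def landscape_table(ls: EnergyLandscape) -> pd.DataFrame:
    """Full per-pattern table: id, state string, energy, link, basin, LMP flag."""
    ids = np.arange(1, ls.n_patterns + 1)
    return pd.DataFrame(
        {
            "pattern_id": ids,
            "state": [_state_string(int(p), ls.I) for p in ids],
            "energy": ls.energies,
            "descent_link": ls.descent_link,
            "basin_label": ls.basin_label,
            "is_lmp": [int(p) in ls.lmp_ids for p in ids],
        }
    )


def landscape_graph(ls: EnergyLandscape) -> nx.DiGraph:
    """Descent graph: one node per pattern, one edge per non-LMP descent link.

    LMPs carry no self-loop; they are flagged by the ``is_lmp`` node attribute.
    """
    G = nx.DiGraph()
    for pid in range(1, ls.n_patterns + 1):
        G.add_node(
            pid,
            energy=float(ls.energies[pid - 1]),
            is_lmp=pid in ls.lmp_ids,
            basin=int(ls.basin_label[pid - 1]),
            state=_state_string(pid, ls.I),
        )
    for pid in range(1, ls.n_patterns + 1):
        link = int(ls.descent_link[pid - 1])
        if link != pid:
            G.add_edge(pid, link)
    return G


def export_landscape(ls: EnergyLandscape, prefix, plot: bool = False) -> dict:
    """Write the landscape as TSV + GraphML (+ optional basin-colored plot).

    ``prefix`` is a path prefix; files written are ``<prefix>_energy.tsv``
    (full float precision: round-trips bit-exactly when re-read with a
    correctly rounded parser, e.g. pandas ``float_precision="round_trip"``),
    ``<prefix>.graphml`` and optionally ``<prefix>_energy.png``.  Returns
    the paths written.
    """
    prefix = str(prefix)
    paths = {}
    table = landscape_table(ls)
    tsv_path = f"{prefix}_energy.tsv"
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    paths["energy_tsv"] = tsv_path
    graphml_path = f"{prefix}.graphml"
    nx.write_graphml(landscape_graph(ls), graphml_path)
    paths["graphml"] = graphml_path
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4))
        basins = sorted(set(ls.basin_label.tolist()))
        cmap = matplotlib.colormaps["tab10"]
        for b_i, b in enumerate(basins):
            mask = ls.basin_label == b
            ax.scatter(
                np.flatnonzero(mask) + 1,
                ls.energies[mask],
                s=8,
                color=cmap(b_i % 10),
                label=f"basin of P-#{b}",
            )
        for pid in sorted(ls.lmp_ids):
            ax.scatter([pid], [ls.energies[pid - 1]], marker="*", s=120, color="black")
        ax.set_xlabel("pattern id")
        ax.set_ylabel("energy")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        png_path = f"{prefix}_energy.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths["plot"] = png_path
    return paths
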