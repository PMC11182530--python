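"""Synthetic cohorts with the generative structure the method assumes.

The simulator instantiates the occurrence-event story behind the assemblage
model: each sample draws its assemblage-abundance vector theta from a
Dirichlet prior, then builds its genus counts by repeatedly picking an
assemblage from Multinomial(theta) and a genus from that assemblage's
composition phi*.  Participants contribute a fixed number of visits, split
into three disease classes sized like the study cohort (65 CD / 38 UC /
27 nonIBD participants with full series, plus short participants that the
first-k filter must drop), so every selection and modelling stage can be
exercised end to end without external data.

Samples are drawn independently within a participant: the generator
reproduces the cohort's size structure and compositional statistics, not
temporal autocorrelation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binarize import OccurrenceMatrix
from .cohort import TaxonProfileTable, validate_metadata
from .maxent import MaxEntParams, enumerate_patterns, pattern_distribution

__all__ = [
    "SyntheticCohortSpec",
    "simulate_cohort",
    "sample_boltzmann_patterns",
    "make_demo_fixture",
]

DEFAULT_PARTICIPANTS = {"CD": 65, "UC": 38, "nonIBD": 27}


@dataclass
class SyntheticCohortSpec:
    """Configuration of a simulated cohort.

    Defaults mirror the study design: 65/38/27 participants per class with
    ``visits_per_participant`` = 10 complete series each, 20 extra "short"
    participants (fewer than 10 visits) so the first-k filter is non-trivial,
    I = 9 planted assemblages over F = 40 genera, theta prior beta = 0.5
    (sparse enough to produce the strong assemblage-abundance imbalance seen
    in real profiles), sequencing depth 10,000 reads per sample.
    """

    participants_per_class: dict = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANTS)
    )
    visits_per_participant: int = 10
    n_short_participants: int = 20
    n_genera: int = 40
    n_assemblages: int = 9
    phi_star: np.ndarray | None = None
    beta: float = 0.5
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.participants_per_class.values()):
            raise ValueError("participant counts must be positive")
        if self.visits_per_participant < 1 or self.depth < 1:
            raise ValueError("visits and depth must be >= 1")
        if self.phi_star is not None:
            self.phi_star = np.asarray(self.phi_star, dtype=float)
            I, F = self.phi_star.shape
            if (self.phi_star < 0).any() or not np.allclose(
                self.phi_star.sum(axis=1), 1.0, atol=1e-9
            ):
                raise ValueError("phi_star rows must be probability vectors")
            self.n_assemblages, self.n_genera = I, F

    def to_yaml(self, path) -> None:
        doc = {
            "participants_per_class": dict(self.participants_per_class),
            "visits_per_participant": self.visits_per_participant,
            "n_short_participants": self.n_short_participants,
            "n_genera": self.n_genera,
            "n_assemblages": self.n_assemblages,
            "beta": self.beta,
            "depth": self.depth,
            "seed": self.seed,
        }
        if self.phi_star is not None:
            doc["phi_star"] = self.phi_star.tolist()
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        if "phi_star" in doc:
            doc["phi_star"] = np.asarray(doc["phi_star"], dtype=float)
        return cls(**doc)


def _default_phi_star(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    # sparse Dirichlet rows give each assemblage a few dominant genera,
    # mimicking the dominance structure of fitted assemblage compositions
    return rng.dirichlet(np.full(spec.n_genera, 0.1), size=spec.n_assemblages)


def simulate_cohort(spec: SyntheticCohortSpec):
    """Simulate a (TaxonProfileTable, metadata) pair from a cohort spec.

    Per sample: theta ~ Dirichlet(beta * 1_I); genus counts are a
    depth-sized multinomial over theta @ phi*, the marginal genus law of the
    assemblage-then-genus occurrence process.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    phi = spec.phi_star if spec.phi_star is not None else _default_phi_star(spec, rng)
    I, F = phi.shape
    genus_names = [f"genus_{f:03d}" for f in range(1, F + 1)]

    classes = sorted(spec.participants_per_class)
    plan = []  # (participant_id, class_label, n_visits)
    for label in classes:
        for p in range(spec.participants_per_class[label]):
            plan.append((f"{label}_P{p + 1:03d}", label, spec.visits_per_participant))
    if spec.visits_per_participant > 1:
        for s in range(spec.n_short_participants):
            label = classes[s % len(classes)]
            n_visits = int(rng.integers(1, spec.visits_per_participant))
            plan.append((f"{label}_S{s + 1:03d}", label, n_visits))

    rows, meta = [], []
    sample_no = 0
    for pid, label, n_visits in plan:
        for visit in range(1, n_visits + 1):
            sample_no += 1
            sid = f"S{sample_no:05d}"
            theta = rng.dirichlet(np.full(I, spec.beta))
            counts = rng.multinomial(spec.depth, theta @ phi)
            rows.append(counts)
            meta.append(
                {
                    "sample_id": sid,
                    "participant_id": pid,
                    "visit_index": visit,
                    "class_label": label,
                }
            )
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index([m["sample_id"] for m in meta], name="sample_id"),
        columns=genus_names,
    )
    metadata = validate_metadata(pd.DataFrame(meta), class_labels=classes)
    table = TaxonProfileTable(data, is_counts=True)
    table.data.attrs["phi_star"] = phi
    return table, metadata


def sample_boltzmann_patterns(
    params: MaxEntParams, n: int, seed: int = 0
) -> OccurrenceMatrix:
    """Draw ``n`` iid patterns from the exact Boltzmann distribution.

    Enumerates all 2^I pattern probabilities and samples categorically, so
    empirical moments converge to the model moments at the 1/sqrt(n) rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = pattern_distribution(params)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(probs), size=n, p=probs)
    states = enumerate_patterns(params.I)[idx]
    return OccurrenceMatrix(
        states=states,
        sample_ids=[f"draw_{k + 1}" for k in range(n)],
        class_label="boltzmann",
        thresholds=None,
    )


def make_demo_fixture(seed: int = 0, out_dir=None) -> dict:
    """Write a miniature end-to-end dataset (3 x 26 participants x 10 visits).

    Produces ``profile.tsv``, ``metadata.tsv``, ``cohort.yaml`` and a
    ``checksums.json`` of the data files.  Returns the paths plus the spec.
    """
    out_dir = Path(out_dir) if out_dir is not None else Path("demo_fixture")
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticCohortSpec(
        participants_per_class={"CD": 26, "UC": 26, "nonIBD": 26},
        visits_per_participant=10,
        n_short_participants=6,
        n_genera=40,
        n_assemblages=9,
        depth=2_000,
        seed=seed,
    )
    table, metadata = simulate_cohort(spec)
    profile_path = out_dir / "profile.tsv"
    metadata_path = out_dir / "metadata.tsv"
    table.to_tsv(profile_path)
    metadata.to_csv(metadata_path, sep="\t", index=False)
    spec.to_yaml(out_dir / "cohort.yaml")
    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in (profile_path, metadata_path)
    }
    (out_dir / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return {
        "profile": profile_path,
        "metadata": metadata_path,
        "spec": spec,
        "checksums": checksums,
    }
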