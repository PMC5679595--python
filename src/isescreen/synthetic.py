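"""Planted-signal descriptor tables for testing the optimizer end to end.

The generator emulates the screening problem's shape — a modest active set
against a several-fold larger inactive background — without any chemistry:
each of ``d_informative`` descriptors carries a planted interval inside
which actives fall with probability ``inside_prob``, while inactives (and
every noise descriptor) are drawn from the background distribution.  With a
uniform background the overlap between planted range and background is
analytically tractable, so the best attainable AUC of an interval-count
score has a closed form (:func:`theoretical_best_auc`).

What this does not emulate: correlated descriptors, heavy-tailed property
distributions, activity cliffs, or label noise beyond the inside/outside
mixture — a green recovery test shows the optimizer finds planted
rectangular signal, not that it reproduces any particular chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedSpec",
    "generate_planted",
    "theoretical_best_auc",
    "TOY_SMILES",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Stated world for one planted dataset.

    Defaults mirror the screening setting the package targets: an active
    set several times smaller than the inactive background (500 vs 2,500),
    a few informative descriptors among mostly uninformative ones, and a
    0.9 probability that an active respects each planted range.  The
    planted ranges default to [0.3, 0.7] on a unit background: a 0.4
    per-descriptor overlap with the inactive distribution, matching the
    character of published screening filters whose per-descriptor ranges
    are individually wide and only jointly specific.
    """

    n_active: int = 500
    n_inactive: int = 2500
    d_informative: int = 2
    d_noise: int = 8
    planted_ranges: Optional[tuple[tuple[float, float], ...]] = None
    inside_prob: float = 0.9
    background: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")
        if self.n_inactive < 1:
            raise ValueError("n_inactive must be >= 1")
        if self.d_informative < 0 or self.d_noise < 0:
            raise ValueError("descriptor counts must be >= 0")
        if not (0.5 < self.inside_prob <= 1.0):
            raise ValueError("inside_prob must be in (0.5, 1]")
        lo, hi = self.background
        if not lo < hi:
            raise ValueError("background support must be non-empty")
        ranges = self.ranges()
        if len(ranges) != self.d_informative:
            raise ValueError("one planted range per informative descriptor")
        for a, b in ranges:
            if a > b:
                raise ValueError(f"empty planted interval [{a}, {b}]")
            if a < lo or b > hi:
                raise ValueError("planted interval must lie inside background support")

    def ranges(self) -> tuple[tuple[float, float], ...]:
        if self.planted_ranges is not None:
            return tuple(tuple(r) for r in self.planted_ranges)
        return tuple((0.3, 0.7) for _ in range(self.d_informative))

    def overlap_fractions(self) -> np.ndarray:
        """Per informative descriptor, the probability a background draw
        lands inside the planted range."""
        lo, hi = self.background
        width = hi - lo
        return np.array([(b - a) / width for a, b in self.ranges()])


def generate_planted(
    spec: PlantedSpec = PlantedSpec(),
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Draw one planted dataset.

    Returns ``(table, labels, truth)``: a descriptor table with columns
    ``inf_0..`` then ``noise_0..``, boolean labels (True = active), and a
    truth record of the planted ranges and generation parameters.  Fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.background
    n = spec.n_active + spec.n_inactive
    ranges = spec.ranges()
    cols: dict[str, np.ndarray] = {}
    for j, (a, b) in enumerate(ranges):
        col = rng.uniform(lo, hi, size=n)
        inside = rng.random(spec.n_active) < spec.inside_prob
        draws = rng.uniform(a, b, size=spec.n_active)
        col[: spec.n_active][inside] = draws[inside]
        cols[f"inf_{j}"] = col
    for j in range(spec.d_noise):
        cols[f"noise_{j}"] = rng.uniform(lo, hi, size=n)
    labels = np.zeros(n, dtype=bool)
    labels[: spec.n_active] = True
    ids = [f"act_{i}" for i in range(spec.n_active)] + [
        f"inact_{i}" for i in range(spec.n_inactive)
    ]
    table = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    truth = {
        "planted_ranges": {f"inf_{j}": list(r) for j, r in enumerate(ranges)},
        "inside_prob": spec.inside_prob,
        "background": list(spec.background),
        "seed": spec.seed,
    }
    return table, labels, truth


def _pass_count_distribution(probs: np.ndarray) -> np.ndarray:
    """Poisson-binomial pmf of how many planted ranges a draw satisfies."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def theoretical_best_auc(spec: PlantedSpec) -> float:
    """Closed-form AUC of the Bayes-optimal interval-count score.

    The optimal score of a molecule under the generative model is the
    number of planted ranges it satisfies; actives satisfy range j with
    probability ``p + (1-p) q_j`` and inactives with ``q_j`` (q_j = planted
    width / background width).  The AUC is the exact win-plus-half-tie
    probability between the two resulting Poisson-binomial pass-count
    distributions.
    """
    q = spec.overlap_fractions()
    if len(q) == 0:
        return 0.5
    p_act = spec.inside_prob + (1.0 - spec.inside_prob) * q
    pmf_a = _pass_count_distribution(p_act)
    pmf_i = _pass_count_distribution(q)
    cdf_i = np.cumsum(pmf_i)
    auc = 0.0
    for s_a, pa in enumerate(pmf_a):
        win = cdf_i[s_a - 1] if s_a > 0 else 0.0
        tie = pmf_i[s_a]
        auc += pa * (win + 0.5 * tie)
    return float(auc)


# ~20 well-known molecules for end-to-end I/O tests; chemistry-agnostic
# algorithm tests use generate_planted instead.
TOY_SMILES: tuple[tuple[str, str], ...] = (
    ("CCO", "ethanol"),
    ("c1ccccc1", "benzene"),
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("CC(=O)Nc1ccc(O)cc1", "paracetamol"),
    ("CN1C=NC2=C1C(=O)N(C)C(=O)N2C", "caffeine"),
    ("CC(C)Cc1ccc(cc1)C(C)C(=O)O", "ibuprofen"),
    ("C1CC1", "cyclopropane"),
    ("O=C(O)c1ccccc1O", "salicylic acid"),
    ("Clc1ccccc1", "chlorobenzene"),
    ("NCCc1ccc(O)c(O)c1", "dopamine"),
    ("CN(C)CCc1c[nH]c2ccccc12", "dimethyltryptamine"),
    ("OC(=O)CC(O)(CC(=O)O)C(=O)O", "citric acid"),
    ("C(C1C(C(C(C(O1)O)O)O)O)O", "glucose"),
    ("N[C@@H](C)C(=O)O", "L-alanine"),
    ("N[C@@H](Cc1ccccc1)C(=O)O", "L-phenylalanine"),
    ("CCCCCCCCCCCCCCCC(=O)O", "palmitic acid"),
    ("C1=CC=C2C=CC=CC2=C1", "naphthalene"),
    ("O=C1NC(=O)NC(=O)C1", "barbituric acid"),
    ("CSCC[C@H](N)C(=O)O", "L-methionine"),
    ("OCC(O)CO", "glycerol"),
)


def toy_records(label: str = "unknown"):
    """The bundled toy set as MoleculeRecord objects."""
    from .chemio import MoleculeRecord
    from rdkit import Chem

    out = []
    for i, (smi, name) in enumerate(TOY_SMILES):
        out.append(
            MoleculeRecord(
                id=f"toy_{i}", smiles=smi,
                canonical_smiles=Chem.MolToSmiles(Chem.MolFromSmiles(smi)),
                name=name, label=label,
            )
        )
    return out
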