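"""Open 1D/2D molecular descriptor registry, drug-likeness rules, diversity.

The descriptor names mirror the vocabulary of commercial descriptor engines
(``GCUT_SLOGP_0``, ``PEOE_VSA+4``, ``vsa_don``, ...) but every definition
here is an open, documented analogue computed with RDKit primitives:

* ``GCUT_SLOGP_*`` / ``BCUT_SLOGP_*`` — eigenvalue descriptors of an
  atomic-logP-weighted graph-distance (GCUT) or Burden (BCUT) matrix, with
  Crippen atomic logP contributions on the diagonal.  ``_0`` is the lowest
  eigenvalue, ``_3`` the highest.
* ``PEOE_VSA+n`` / ``PEOE_VSA-n`` — Labute approximate-surface-area summed
  over atoms whose Gasteiger partial charge falls in the 0.05-wide bin
  ``[0.05 n, 0.05 (n+1))`` (mirrored for negative bins).
* ``PEOE_VSA_FPNEG`` — fraction of the total surface area carried by atoms
  with partial charge <= -0.2.
* ``vsa_don`` — surface area summed over H-bond donor atoms (N/O bearing H).
* ``a_ICM`` — Shannon entropy (bits) of the element composition over all
  atoms, hydrogens included: the mean atom information content.
* ``chiral_u`` — number of unassigned (unconstrained) stereocenters.
* ``b_rotR`` — rotatable bonds / heavy-atom bonds; ``b_1rotR`` — rotatable
  bonds / acyclic single heavy-atom bonds.
* ``logS`` — ESOL-style aqueous solubility estimate (Delaney 2004).
* ``lip_druglike`` — 1.0 if the molecule has at most one Lipinski violation.
* ``chi1_C`` — Kier-Hall chi-1 connectivity restricted to C-C bonds.
* ``Nmol`` — no open analogue exists; registered but always not-computable.

No numerical agreement with any proprietary engine is claimed; the screening
pipeline is descriptor-engine-agnostic and every definition is deterministic
per canonical SMILES and registry version.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

REGISTRY_VERSION = "open-1.0"

__all__ = [
    "REGISTRY_VERSION",
    "registry",
    "list_descriptors",
    "compute_descriptors",
    "DescriptorCalculator",
    "lipinski_violations",
    "oprea_leadlike",
    "DruglikenessRuleSet",
    "LIPINSKI_RULES",
    "OPREA_RULES",
    "ruleset_compliance",
    "tanimoto_matrix",
    "DiversityReport",
]


# --------------------------------------------------------------------------
# atomic helpers

def _mol_from(record) -> Optional[Chem.Mol]:
    if isinstance(record, Chem.Mol):
        return record
    if isinstance(record, MoleculeRecord):
        return Chem.MolFromSmiles(record.smiles)
    return Chem.MolFromSmiles(str(record))


def _vsa_contribs(mol) -> np.ndarray:
    contribs, _h = rdMolDescriptors._CalcLabuteASAContribs(mol)
    return np.asarray(list(contribs), dtype=float)


def _gasteiger_charges(mol) -> np.ndarray:
    m = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(m)
    q = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()], dtype=float
    )
    return q


def _atom_logp(mol) -> np.ndarray:
    return np.array([c[0] for c in Crippen._GetAtomContribs(mol)], dtype=float)


def _eigen_cut(matrix: np.ndarray, which: int) -> float:
    """Sorted-eigenvalue pick: index 0 = lowest, 3 = highest."""
    w = np.linalg.eigvalsh(matrix)
    return float(w[0] if which == 0 else w[-1])


def _gcut_slogp(mol, which: int) -> float:
    n = mol.GetNumAtoms()
    diag = _atom_logp(mol)
    if n == 1:
        return float(diag[0])
    d = Chem.GetDistanceMatrix(mol)
    with np.errstate(divide="ignore"):
        off = 1.0 / d**2
    off[~np.isfinite(off)] = 0.0
    np.fill_diagonal(off, 0.0)
    m = off.copy()
    np.fill_diagonal(m, diag)
    return _eigen_cut(m, which)


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def _bcut_slogp(mol, which: int) -> float:
    n = mol.GetNumAtoms()
    diag = _atom_logp(mol)
    if n == 1:
        return float(diag[0])
    m = np.full((n, n), 0.001)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        m[i, j] = m[j, i] = 0.1 * _BOND_ORDER.get(b.GetBondType(), 1.0)
    np.fill_diagonal(m, diag)
    return _eigen_cut(m, which)


_DONOR_SMARTS = Chem.MolFromSmarts("[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]")


def _vsa_don(mol) -> float:
    contribs = _vsa_contribs(mol)
    donors = {i for (i,) in mol.GetSubstructMatches(_DONOR_SMARTS)}
    return float(sum(contribs[i] for i in donors))


def _peoe_vsa_bin(mol, lo: float, hi: float) -> float:
    """VSA summed over atoms with Gasteiger charge in [lo, hi)."""
    q = _gasteiger_charges(mol)
    if not np.all(np.isfinite(q)):
        return float("nan")
    contribs = _vsa_contribs(mol)
    return float(contribs[(q >= lo) & (q < hi)].sum())


def _peoe_vsa_fpneg(mol) -> float:
    q = _gasteiger_charges(mol)
    if not np.all(np.isfinite(q)):
        return float("nan")
    contribs = _vsa_contribs(mol)
    total = contribs.sum()
    if total <= 0:
        return float("nan")
    return float(contribs[q <= -0.2].sum() / total)


def _a_icm(mol) -> float:
    m = Chem.AddHs(mol)
    counts = Counter(a.GetAtomicNum() for a in m.GetAtoms())
    n = m.GetNumAtoms()
    probs = np.array([c / n for c in counts.values()])
    return float(-(probs * np.log2(probs)).sum())


def _chiral_u(mol) -> float:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return float(sum(1 for _i, tag in centers if tag == "?"))


def _n_rotatable(mol) -> int:
    return int(Lipinski.NumRotatableBonds(mol))


def _b_rotR(mol) -> float:
    nb = mol.GetNumBonds()
    return _n_rotatable(mol) / nb if nb else 0.0


def _b_1rotR(mol) -> float:
    singles = sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    )
    return _n_rotatable(mol) / singles if singles else 0.0


def _logS_esol(mol) -> float:
    # Delaney ESOL linear model on clogP, MW, rotatable bonds, aromatic
    # proportion.
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rb = _n_rotatable(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    )
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _chi1_C(mol) -> float:
    total = 0.0
    for b in mol.GetBonds():
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if a1.GetAtomicNum() == 6 and a2.GetAtomicNum() == 6:
            d1, d2 = a1.GetDegree(), a2.GetDegree()
            if d1 and d2:
                total += 1.0 / math.sqrt(d1 * d2)
    return total


def _lip_druglike(mol) -> float:
    row = {
        "MW": Descriptors.MolWt(mol),
        "logP": Crippen.MolLogP(mol),
        "lip_don": Lipinski.NumHDonors(mol),
        "lip_acc": Lipinski.NumHAcceptors(mol),
    }
    return 1.0 if lipinski_violations(row) <= 1 else 0.0


def _not_computable(mol) -> float:
    return float("nan")


# --------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class DescriptorDef:
    name: str
    func: Callable
    description: str
    supported: bool = True


def _make_registry() -> dict[str, DescriptorDef]:
    defs = [
        DescriptorDef("MW", Descriptors.MolWt, "molecular weight (average, Da)"),
        DescriptorDef("logP", Crippen.MolLogP, "Crippen/Wildman octanol-water logP"),
        DescriptorDef("lip_don", lambda m: float(Lipinski.NumHDonors(m)),
                      "H-bond donor count (Lipinski)"),
        DescriptorDef("lip_acc", lambda m: float(Lipinski.NumHAcceptors(m)),
                      "H-bond acceptor count (Lipinski)"),
        DescriptorDef("b_rotatable", lambda m: float(_n_rotatable(m)),
                      "rotatable bond count (strict)"),
        DescriptorDef("b_rigid", lambda m: float(m.GetNumBonds() - _n_rotatable(m)),
                      "rigid (non-rotatable) heavy-atom bond count"),
        DescriptorDef("a_aromatic",
                      lambda m: float(sum(1 for a in m.GetAtoms() if a.GetIsAromatic())),
                      "aromatic atom count"),
        DescriptorDef("rings", lambda m: float(rdMolDescriptors.CalcNumRings(m)),
                      "SSSR ring count"),
        DescriptorDef("GCUT_SLOGP_0", lambda m: _gcut_slogp(m, 0),
                      "lowest eigenvalue of logP-weighted inverse-square graph-distance matrix"),
        DescriptorDef("GCUT_SLOGP_3", lambda m: _gcut_slogp(m, 3),
                      "highest eigenvalue of logP-weighted inverse-square graph-distance matrix"),
        DescriptorDef("BCUT_SLOGP_0", lambda m: _bcut_slogp(m, 0),
                      "lowest eigenvalue of logP-weighted Burden matrix"),
        DescriptorDef("BCUT_SLOGP_3", lambda m: _bcut_slogp(m, 3),
                      "highest eigenvalue of logP-weighted Burden matrix"),
        DescriptorDef("vsa_don", _vsa_don, "approximate surface area of H-bond donor atoms"),
        DescriptorDef("PEOE_VSA+0", lambda m: _peoe_vsa_bin(m, 0.00, 0.05),
                      "surface area of atoms with partial charge in [0.00, 0.05)"),
        DescriptorDef("PEOE_VSA+4", lambda m: _peoe_vsa_bin(m, 0.20, 0.25),
                      "surface area of atoms with partial charge in [0.20, 0.25)"),
        DescriptorDef("PEOE_VSA-5", lambda m: _peoe_vsa_bin(m, -0.30, -0.25),
                      "surface area of atoms with partial charge in [-0.30, -0.25)"),
        DescriptorDef("PEOE_VSA_FPNEG", _peoe_vsa_fpneg,
                      "fractional surface area of atoms with partial charge <= -0.2"),
        DescriptorDef("a_ICM", _a_icm, "entropy (bits) of the element composition"),
        DescriptorDef("chiral_u", _chiral_u, "unassigned stereocenter count"),
        DescriptorDef("b_rotR", _b_rotR, "rotatable / heavy-atom bond ratio"),
        DescriptorDef("b_1rotR", _b_1rotR, "rotatable / acyclic-single bond ratio"),
        DescriptorDef("SMR_VSA1", Descriptors.SMR_VSA1,
                      "surface area of atoms with molar refractivity contribution in bin 1"),
        DescriptorDef("logS", _logS_esol, "ESOL aqueous solubility estimate, log mol/L"),
        DescriptorDef("lip_druglike", _lip_druglike,
                      "1 if at most one Lipinski violation, else 0"),
        DescriptorDef("chi1_C", _chi1_C, "chi-1 connectivity index over C-C bonds"),
        DescriptorDef("Nmol", _not_computable,
                      "no open analogue; always not-computable", supported=False),
    ]
    return {d.name: d for d in defs}


registry: dict[str, DescriptorDef] = _make_registry()

DEFAULT_DESCRIPTORS: tuple[str, ...] = tuple(
    d.name for d in registry.values() if d.supported
)


def list_descriptors() -> pd.DataFrame:
    """The registry as a table of (name, supported, description)."""
    return pd.DataFrame(
        [(d.name, d.supported, d.description) for d in registry.values()],
        columns=["name", "supported", "description"],
    )


def compute_descriptors(
    records: Sequence, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Compute named descriptors for each molecule.

    Parameters
    ----------
    records
        ``MoleculeRecord`` objects, RDKit mols, or raw SMILES strings.
    names
        Registered descriptor names; defaults to every supported name.

    Returns
    -------
    DataFrame indexed by molecule id (record id or positional index), one
    column per descriptor, NaN marking not-computable cells.  The registry
    version is stamped on ``df.attrs["registry_version"]``.
    """
    if names is None:
        names = list(DEFAULT_DESCRIPTORS)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise KeyError(f"unregistered descriptor names: {unknown}")
    ids, rows = [], []
    for i, rec in enumerate(records):
        mol = _mol_from(rec)
        rid = rec.id if isinstance(rec, MoleculeRecord) else str(i)
        ids.append(rid)
        if mol is None:
            rows.append([float("nan")] * len(names))
            logger.warning("unparseable molecule %r; descriptor row is NaN", rid)
            continue
        row = []
        for n in names:
            try:
                row.append(float(registry[n].func(mol)))
            except Exception:  # not-computable cell, never fatal
                row.append(float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=list(names))
    df.attrs["registry_version"] = REGISTRY_VERSION
    return df


class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: molecules in, descriptor table out.

    ``transform`` accepts a sequence of SMILES strings, RDKit mols, or
    ``MoleculeRecord`` objects and returns a :class:`pandas.DataFrame`, so
    it composes with :class:`~isescreen.estimator.ISEClassifier` in a
    :class:`sklearn.pipeline.Pipeline`.
    """

    def __init__(self, names: Sequence[str] | None = None):
        self.names = names

    def fit(self, X, y=None):
        names = list(self.names) if self.names is not None else list(DEFAULT_DESCRIPTORS)
        unknown = [n for n in names if n not in registry]
        if unknown:
            raise KeyError(f"unregistered descriptor names: {unknown}")
        self.names_ = names
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "names_"):
            self.fit(X)
        return compute_descriptors(X, self.names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.names_ if hasattr(self, "names_") else self.names)


# --------------------------------------------------------------------------
# drug-likeness rules

def lipinski_violations(row: Mapping[str, float]) -> float:
    """Count Lipinski rule-of-five violations (0-4) for one descriptor row.

    Violations are strict: MW > 500, logP > 5, donors > 5, acceptors > 10;
    a value exactly at a threshold is not a violation.  Returns NaN when a
    component descriptor is missing or not-computable.
    """
    needed = ("MW", "logP", "lip_don", "lip_acc")
    vals = [row.get(n, float("nan")) for n in needed]
    if any(isinstance(v, float) and math.isnan(v) for v in vals):
        return float("nan")
    mw, logp, don, acc = vals
    return float((mw > 500) + (logp > 5) + (don > 5) + (acc > 10))


def oprea_leadlike(row: Mapping[str, float]) -> float:
    """1.0 if the row satisfies the lead-likeness ranges, 0.0 if not, NaN if
    a component is missing.

    Default rule set (all bounds closed): MW <= 450, -3.5 <= logP <= 4.5,
    donors <= 5, acceptors <= 8, rotatable bonds <= 10, rings <= 4.
    """
    needed = ("MW", "logP", "lip_don", "lip_acc", "b_rotatable", "rings")
    vals = [row.get(n, float("nan")) for n in needed]
    if any(isinstance(v, float) and math.isnan(v) for v in vals):
        return float("nan")
    mw, logp, don, acc, rot, rings = vals
    ok = (
        mw <= 450
        and -3.5 <= logp <= 4.5
        and don <= 5
        and acc <= 8
        and rot <= 10
        and rings <= 4
    )
    return 1.0 if ok else 0.0


@dataclass(frozen=True)
class DruglikenessRuleSet:
    """A named list of (descriptor, comparator, threshold) conditions.

    Comparators are ``"le"``, ``"ge"`` (closed bounds) and ``"lt"``, ``"gt"``.
    A molecule complies when every condition holds; a missing/NaN component
    makes the molecule non-evaluable.
    """

    name: str
    rules: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        for desc, cmp_, _thr in self.rules:
            if cmp_ not in ("le", "ge", "lt", "gt"):
                raise ValueError(f"unknown comparator {cmp_!r}")
            if desc not in registry:
                raise ValueError(f"rule references unregistered descriptor {desc!r}")

    def evaluate(self, row: Mapping[str, float]) -> float:
        """1.0 compliant, 0.0 not, NaN non-evaluable."""
        for desc, cmp_, thr in self.rules:
            v = row.get(desc, float("nan"))
            if isinstance(v, float) and math.isnan(v):
                return float("nan")
            ok = {
                "le": v <= thr,
                "ge": v >= thr,
                "lt": v < thr,
                "gt": v > thr,
            }[cmp_]
            if not ok:
                return 0.0
        return 1.0


LIPINSKI_RULES = DruglikenessRuleSet(
    "lipinski",
    (
        ("MW", "le", 500.0),
        ("logP", "le", 5.0),
        ("lip_don", "le", 5.0),
        ("lip_acc", "le", 10.0),
    ),
)

OPREA_RULES = DruglikenessRuleSet(
    "oprea",
    (
        ("MW", "le", 450.0),
        ("logP", "ge", -3.5),
        ("logP", "le", 4.5),
        ("lip_don", "le", 5.0),
        ("lip_acc", "le", 8.0),
        ("b_rotatable", "le", 10.0),
        ("rings", "le", 4.0),
    ),
)


def ruleset_compliance(
    table: pd.DataFrame, rules: DruglikenessRuleSet
) -> tuple[float, pd.DataFrame]:
    """Fraction of evaluable molecules complying with a rule set.

    Returns ``(fraction, report)`` where the report holds one row per
    molecule with a ``compliant`` column (1/0/NaN).  Raises if no molecule
    is evaluable.
    """
    flags = table.apply(lambda r: rules.evaluate(r), axis=1)
    report = pd.DataFrame({"compliant": flags})
    evaluable = report["compliant"].notna()
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError("no evaluable molecules for rule set " + rules.name)
    n_ok = int(report.loc[evaluable, "compliant"].sum())
    report.attrs["n_compliant"] = n_ok
    report.attrs["n_evaluable"] = n_eval
    return n_ok / n_eval, report


# --------------------------------------------------------------------------
# fingerprint diversity

@dataclass
class DiversityReport:
    """Pairwise Tanimoto similarity summary of a compound set."""

    ids: list[str]
    matrix: np.ndarray                # symmetric, unit diagonal
    max_similarity: np.ndarray        # per molecule, max over the others
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges) over pairs
    excluded: list[str] = field(default_factory=list)

    def n_molecules_below(self, cutoff: float) -> int:
        """Molecules whose nearest neighbour is less similar than ``cutoff``."""
        return int(np.sum(self.max_similarity < cutoff))

    def n_pairs_below(self, cutoff: float) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.sum(self.matrix[iu] < cutoff))


def _fingerprint_bits(mol, kind: str, radius: int, n_bits: int) -> set[int]:
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    elif kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    fp = gen.GetFingerprint(mol)
    return set(fp.GetOnBits())


def tanimoto_matrix(
    records: Sequence,
    fingerprint_kind: str = "morgan",
    radius: int = 2,
    n_bits: int = 2048,
    n_histogram_bins: int = 20,
) -> DiversityReport:
    """Pairwise Tanimoto similarity over fingerprint bit sets.

    similarity(A, B) = |A ∩ B| / |A ∪ B|.  Molecules with an empty
    fingerprint are excluded with a warning.  Requires at least two usable
    molecules.
    """
    ids, bitsets, excluded = [], [], []
    for i, rec in enumerate(records):
        mol = _mol_from(rec)
        rid = rec.id if isinstance(rec, MoleculeRecord) else str(i)
        if mol is None:
            excluded.append(rid)
            continue
        bits = _fingerprint_bits(mol, fingerprint_kind, radius, n_bits)
        if not bits:
            logger.warning("empty fingerprint for %r; excluded from diversity", rid)
            excluded.append(rid)
            continue
        ids.append(rid)
        bitsets.append(bits)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two molecules with non-empty fingerprints")
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(bitsets[i] & bitsets[j])
            union = len(bitsets[i] | bitsets[j])
            sim[i, j] = sim[j, i] = inter / union
    off = sim + np.diag([-np.inf] * n)
    max_sim = off.max(axis=1)
    iu = np.triu_indices(n, k=1)
    counts, edges = np.histogram(sim[iu], bins=n_histogram_bins, range=(0.0, 1.0))
    return DiversityReport(
        ids=ids, matrix=sim, max_similarity=max_sim,
        histogram=(counts, edges), excluded=excluded,
    )
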