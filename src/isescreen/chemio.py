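"""Compound-set, model, and score-table I/O plus the stratified split.

File formats:

* ``.smi`` — one molecule per line, ``SMILES[ whitespace name]``; blank
  lines and ``#`` comments ignored.
* SDF (v2000) via RDKit.
* Model files — versioned JSON holding the filter list with interval bounds
  at full float precision, the descriptor-registry version, and provenance.
* Score tables — tab-separated ``id, name, mbi, rank``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .rangefilter import DescriptorInterval, FilterStats, RangeFilter

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = "1"

__all__ = [
    "MoleculeRecord",
    "ParseResult",
    "SplitSpec",
    "read_smiles_file",
    "read_sdf",
    "split_dataset",
    "write_model",
    "read_model",
    "write_scores",
    "read_scores",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One parsed compound.

    ``smiles`` is the input string verbatim; ``canonical_smiles`` is the
    canonical form, kept so duplicates are detectable while provenance is
    preserved.
    """

    id: str
    smiles: str
    canonical_smiles: str = ""
    name: Optional[str] = None
    label: str = "unknown"

    def __post_init__(self):
        if self.label not in ("active", "inactive", "unknown"):
            raise ValueError(f"bad label {self.label!r}")


class ParseResult(list):
    """List of records with parse bookkeeping (``skipped`` line numbers)."""

    def __init__(self, records: Iterable[MoleculeRecord], skipped: list[tuple[int, str]]):
        super().__init__(records)
        self.skipped = skipped

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _canonical(smiles: str) -> Optional[str]:
    from rdkit import Chem  # local import keeps chemio importable without RDKit use

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def read_smiles_file(
    path: str | Path,
    label: str = "unknown",
    id_prefix: str = "",
    standardizer=None,
) -> ParseResult:
    """Read a ``.smi`` file into records, skipping unparseable lines.

    Records keep file order; each skipped line is counted and logged with
    its line number.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` when no line parses.  ``standardizer`` is an optional
    SMILES -> SMILES hook (salt stripping, charge normalization, ...)
    applied before parsing; the default is pass-through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    skipped: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else None
        canonical = _canonical(standardizer(smiles) if standardizer else smiles)
        if canonical is None:
            skipped.append((lineno, raw))
            logger.warning("%s:%d unparseable SMILES %r — skipped", path, lineno, smiles)
            continue
        rid = f"{id_prefix}{len(records)}"
        if rid in seen_ids:  # cannot happen with positional ids; guard anyway
            raise ValueError(f"duplicate id {rid}")
        seen_ids.add(rid)
        records.append(
            MoleculeRecord(id=rid, smiles=smiles, canonical_smiles=canonical,
                           name=name, label=label)
        )
    if not records:
        raise ValueError(f"no parseable records in {path}")
    if skipped:
        logger.warning("%s: skipped %d unparseable line(s)", path, len(skipped))
    return ParseResult(records, skipped)


def read_sdf(path: str | Path, label: str = "unknown", id_prefix: str = "") -> ParseResult:
    """Read a v2000 SDF into records (molecule title becomes the name)."""
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    skipped: list[tuple[int, str]] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped.append((i, "<unparseable SDF block>"))
            continue
        smiles = Chem.MolToSmiles(mol)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        records.append(
            MoleculeRecord(id=f"{id_prefix}{len(records)}", smiles=smiles,
                           canonical_smiles=smiles, name=name or None, label=label)
        )
    if not records:
        raise ValueError(f"no parseable records in {path}")
    return ParseResult(records, skipped)


def warn_cross_set_duplicates(
    actives: Sequence[MoleculeRecord], inactives: Sequence[MoleculeRecord]
) -> set[str]:
    """Warn about structures present in both sets; nothing is removed."""
    a = {r.canonical_smiles for r in actives if r.canonical_smiles}
    b = {r.canonical_smiles for r in inactives if r.canonical_smiles}
    dupes = a & b
    if dupes:
        logger.warning(
            "%d structure(s) occur in both the active and inactive sets", len(dupes)
        )
    return dupes


# --------------------------------------------------------------------------
# train/test split

@dataclass(frozen=True)
class SplitSpec:
    """Stratified split: per label class, floor(train_fraction * n) records
    train, the remainder test; selection driven only by the seed."""

    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(
    records: Sequence[MoleculeRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Stratified, seeded train/test partition of labeled records."""
    classes: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        if r.label not in ("active", "inactive"):
            raise ValueError(f"record {r.id} has non-binary label {r.label!r}")
        classes.setdefault(r.label, []).append(r)
    rng = np.random.default_rng(spec.seed)
    train: list[MoleculeRecord] = []
    test: list[MoleculeRecord] = []
    for label in sorted(classes):
        members = classes[label]
        if len(members) < 2:
            raise ValueError(f"label class {label!r} has fewer than 2 records")
        n_train = int(np.floor(spec.train_fraction * len(members)))
        perm = rng.permutation(len(members))
        chosen = set(perm[:n_train].tolist())
        for i, rec in enumerate(members):
            (train if i in chosen else test).append(rec)
    return train, test


# --------------------------------------------------------------------------
# model serialization

def _filter_to_json(f: RangeFilter) -> dict:
    d: dict = {
        "intervals": [
            {"descriptor": iv.descriptor, "low": iv.low, "high": iv.high}
            for iv in f.intervals
        ]
    }
    if f.stats is not None:
        d["stats"] = f.stats.to_dict()
    return d


def _filter_from_json(d: dict, known: set[str]) -> RangeFilter:
    intervals = tuple(
        DescriptorInterval(iv["descriptor"], float(iv["low"]), float(iv["high"]))
        for iv in d["intervals"]
    )
    stats = None
    if "stats" in d:
        s = d["stats"]
        stats = FilterStats(tp=int(s["tp"]), fp=int(s["fp"]),
                            tn=int(s["tn"]), fn=int(s["fn"]))
    unknown = [iv.descriptor for iv in intervals if iv.descriptor not in known]
    usable = not unknown
    if unknown:
        logger.warning(
            "filter references unknown descriptor(s) %s — flagged unusable", unknown
        )
    return RangeFilter(intervals=intervals, stats=stats, usable=usable)


def write_model(model, path: str | Path) -> None:
    """Serialize a FilterModel to versioned JSON (full float precision)."""
    path = Path(path)
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "registry_version": model.registry_version,
        "weighting": model.weighting,
        "provenance": model.provenance,
        "filters": [_filter_to_json(f) for f in model.filters],
    }
    path.write_text(json.dumps(doc, indent=1))


def read_model(path: str | Path, known_descriptors: Optional[set[str]] = None):
    """Load a FilterModel; unknown descriptors flag their filter unusable."""
    from .indexer import FilterModel  # deferred to avoid an import cycle

    path = Path(path)
    doc = json.loads(path.read_text())
    version = str(doc.get("schema_version"))
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION!r})"
        )
    if known_descriptors is None:
        from .descriptors import registry

        known_descriptors = set(registry)
    filters = tuple(_filter_from_json(d, known_descriptors) for d in doc["filters"])
    return FilterModel(
        filters=filters,
        weighting=doc.get("weighting", "unit"),
        registry_version=doc.get("registry_version", ""),
        provenance=doc.get("provenance", {}),
    )


# --------------------------------------------------------------------------
# score tables and descriptor tables

def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table (columns id, name, mbi, rank) as TSV."""
    cols = [c for c in ("id", "name", "mbi", "rank") if c in scores.columns]
    scores.to_csv(path, sep="\t", index=False, columns=cols)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a descriptor table as TSV with the id index as first column."""
    table.to_csv(path, sep="\t", index=True)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
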