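"""Readers and validators for drug, target, interaction and structure files.

File formats are the plain-text shapes DrugBank-style exports come in:
SDF V2000 for structures, headered TSV for drug/target/interaction/annotation
tables, and an id TAB bitstring TSV for precomputed binary fingerprints.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .similarity import Fingerprint, FingerprintLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "DrugStatus",
    "DrugRecord",
    "TargetRecord",
    "Interaction",
    "CompoundRecord",
    "AdverseEffectAnnotation",
    "SDFResult",
    "read_sdf",
    "read_drug_table",
    "write_drug_table",
    "read_target_table",
    "read_interaction_table",
    "read_annotation_table",
    "filter_small_molecules",
    "read_fingerprints",
    "write_fingerprints",
]

DEFAULT_SDF_ID_PROPERTY = "DATABASE_ID"


class DrugStatus(str, Enum):
    APPROVED = "approved"
    WITHDRAWN = "withdrawn"


@dataclass(frozen=True)
class DrugRecord:
    """A small-molecule drug with market status and optional structure."""

    drug_id: str
    name: str
    status: DrugStatus
    smiles: str | None = None
    is_small_molecule: bool = False

    def __post_init__(self) -> None:
        if self.smiles is not None and not self.smiles:
            raise ValueError(f"drug {self.drug_id!r}: smiles, when present, must be non-empty")


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    name: str = ""


@dataclass(frozen=True)
class Interaction:
    """One drug-target link; duplicates collapse during network construction."""

    drug_id: str
    target_id: str


@dataclass(frozen=True)
class CompoundRecord:
    """A structure-bearing compound (drug or natural product)."""

    compound_id: str
    name: str
    smiles: str
    source: str = "drug"  # "drug" | "natural_product"

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"compound {self.compound_id!r}: smiles must be non-empty")


@dataclass(frozen=True)
class AdverseEffectAnnotation:
    """A withdrawn drug annotated with one adverse-effect category."""

    drug_id: str
    effect: str


@dataclass
class SDFResult:
    """Parsed compounds plus bookkeeping on rejected molecule blocks."""

    records: list[CompoundRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (block index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _count_sdf_blocks(text: str) -> int:
    return sum(1 for line in text.splitlines() if line.strip() == "$$$$")


def read_sdf(
    path: str | Path,
    *,
    id_property: str = DEFAULT_SDF_ID_PROPERTY,
    name_property: str | None = None,
    source: str = "drug",
) -> SDFResult:
    """Read a multi-record SDF V2000 file into CompoundRecords.

    SMILES is regenerated canonically from the connection table, so records
    compare by structure, not by the depositor's SMILES spelling. Molecule
    blocks that fail structure parsing, lack the id property, or use the
    V3000 dialect are skipped and counted, never abort the whole file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SDFResult(records=[])

    RDLogger.DisableLog("rdApp.error")
    try:
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text)
        result = SDFResult(records=[])
        seen: set[str] = set()
        for idx, mol in enumerate(supplier):
            raw = supplier.GetItemText(idx)
            if " V3000" in raw or "\tV3000" in raw:
                result.rejected.append((idx, "V3000 records are not supported; export as V2000"))
                continue
            if mol is None:
                result.rejected.append((idx, "structure failed to parse"))
                continue
            if not mol.HasProp(id_property):
                result.rejected.append((idx, f"missing id property {id_property!r}"))
                continue
            cid = mol.GetProp(id_property).strip()
            if not cid:
                result.rejected.append((idx, f"empty id property {id_property!r}"))
                continue
            if cid in seen:
                result.rejected.append((idx, f"duplicate compound id {cid!r}"))
                continue
            seen.add(cid)
            if name_property and mol.HasProp(name_property):
                name = mol.GetProp(name_property).strip()
            else:
                name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else cid
            result.records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=name or cid,
                    smiles=Chem.MolToSmiles(mol),
                    source=source,
                )
            )
    finally:
        RDLogger.EnableLog("rdApp.error")

    for idx, reason in result.rejected:
        logger.info("%s: rejected molecule block %d: %s", path.name, idx, reason)
    return result


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path.name}: missing required columns {missing}")
        return [dict(row) for row in reader]


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a headered TSV of drugs (columns: drug_id, name, status, smiles).

    Status strings are mapped case-insensitively onto {approved, withdrawn};
    rows with any other status are rejected and logged. A duplicated drug_id
    is a hard error.
    """
    rows = _read_tsv(path, ["drug_id", "name", "status"])
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        drug_id = row["drug_id"].strip()
        if drug_id in seen:
            raise ValueError(f"duplicate drug_id {drug_id!r} in {Path(path).name}")
        status_raw = row["status"].strip().lower()
        try:
            status = DrugStatus(status_raw)
        except ValueError:
            logger.info("%s: row %d rejected: unknown status %r", Path(path).name, i, row["status"])
            continue
        seen.add(drug_id)
        smiles = (row.get("smiles") or "").strip() or None
        is_sm = (row.get("is_small_molecule") or "").strip().lower() in {"1", "true", "yes"}
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=row["name"].strip(),
                status=status,
                smiles=smiles,
                is_small_molecule=is_sm,
            )
        )
    return records


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_id", "name", "status", "smiles", "is_small_molecule"])
        for d in drugs:
            writer.writerow(
                [d.drug_id, d.name, d.status.value, d.smiles or "", str(d.is_small_molecule).lower()]
            )


def read_target_table(path: str | Path) -> list[TargetRecord]:
    rows = _read_tsv(path, ["target_id"])
    records: list[TargetRecord] = []
    seen: set[str] = set()
    for row in rows:
        tid = row["target_id"].strip()
        if tid in seen:
            raise ValueError(f"duplicate target_id {tid!r} in {Path(path).name}")
        seen.add(tid)
        records.append(TargetRecord(target_id=tid, name=(row.get("name") or "").strip()))
    return records


def read_interaction_table(path: str | Path) -> list[Interaction]:
    rows = _read_tsv(path, ["drug_id", "target_id"])
    return [
        Interaction(drug_id=row["drug_id"].strip(), target_id=row["target_id"].strip())
        for row in rows
    ]


def read_annotation_table(path: str | Path) -> list[AdverseEffectAnnotation]:
    rows = _read_tsv(path, ["drug_id", "effect"])
    return [
        AdverseEffectAnnotation(drug_id=row["drug_id"].strip(), effect=row["effect"].strip())
        for row in rows
    ]


def filter_small_molecules(
    drugs: Sequence[DrugRecord], small_molecule_ids: set[str]
) -> list[DrugRecord]:
    """Keep only the drugs whose id is in the small-molecule membership set.

    Mirrors filtering an export against a small-molecule id list to drop
    biotech entries before any network is built. Order preserved; kept
    records are marked is_small_molecule=True. An empty intersection is a
    valid (logged) outcome, not an error.
    """
    kept = [replace(d, is_small_molecule=True) for d in drugs if d.drug_id in small_molecule_ids]
    if drugs and not kept:
        logger.info("small-molecule filter removed every drug (%d in)", len(drugs))
    return kept


def read_fingerprints(path: str | Path) -> FingerprintLibrary:
    """Read an id TAB bitstring TSV into a FingerprintLibrary.

    All bitstrings must share one length; ragged lengths or characters
    outside {0,1} are hard errors.
    """
    lib = FingerprintLibrary()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 'id<TAB>bitstring'")
            key, bitstring = parts[0].strip(), parts[1].strip()
            try:
                fp = Fingerprint.from_bitstring(bitstring)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
            try:
                lib.add(key, fp)
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from None
    return lib


def write_fingerprints(lib: FingerprintLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for key, fp in lib.items():
            fh.write(f"{key}\t{fp.to_bitstring()}\n")
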