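"""Binary 2D fingerprints and Tanimoto similarity.

The similarity machinery is deliberately scheme-agnostic: any fixed-length
binary fingerprint can be loaded from file and searched. For structures we
generate a hashed linear-path fingerprint (Daylight-style): all linear bond
paths of 1..max_path bonds are enumerated, each path is hashed and sets
2 bits in a 1024-bit vector. Identical canonical molecules therefore always
yield identical fingerprints, regardless of the SMILES spelling they came
from.

Tanimoto similarity between binary fingerprints i and j is

    sim = c / (a + b - c)

where a and b are the popcounts of i and j and c is the popcount of their
bitwise AND (the Jaccard index of the two bit sets).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "FingerprintLibrary",
    "SimilarityHit",
    "path_fingerprint",
    "tanimoto",
    "bulk_tanimoto",
    "similarity_search",
]

DEFAULT_N_BITS = 1024
DEFAULT_MAX_PATH = 7


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary fingerprint."""

    bits: np.ndarray  # uint8 vector of 0/1

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.all((arr == 0) | (arr == 1)):
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", arr)
        arr.setflags(write=False)

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @classmethod
    def from_bitstring(cls, s: str) -> "Fingerprint":
        if not s or set(s) - {"0", "1"}:
            raise ValueError("bitstring must be a non-empty run of '0'/'1'")
        return cls(np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0"))

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.bits.shape == other.bits.shape and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


class FingerprintLibrary(Mapping[str, Fingerprint]):
    """A mapping id -> Fingerprint with a uniform bit length.

    Also exposes a dense 0/1 matrix view for vectorised bulk Tanimoto
    calculations over thousands of compounds.
    """

    def __init__(self, entries: Mapping[str, Fingerprint] | Iterable[tuple[str, Fingerprint]] = ()):
        self._fps: dict[str, Fingerprint] = {}
        self.n_bits: int | None = None
        items = entries.items() if isinstance(entries, Mapping) else entries
        for key, fp in items:
            self.add(key, fp)
        self._matrix: np.ndarray | None = None
        self._order: list[str] | None = None

    def add(self, key: str, fp: Fingerprint) -> None:
        if self.n_bits is None:
            self.n_bits = fp.n_bits
        elif fp.n_bits != self.n_bits:
            raise ValueError(
                f"fingerprint length mismatch for {key!r}: got {fp.n_bits}, library is {self.n_bits}"
            )
        if key in self._fps:
            raise ValueError(f"duplicate fingerprint id {key!r}")
        self._fps[key] = fp
        self._matrix = None

    def __getitem__(self, key: str) -> Fingerprint:
        return self._fps[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._fps)

    def __len__(self) -> int:
        return len(self._fps)

    def matrix(self) -> tuple[list[str], np.ndarray]:
        """Return (ordered ids, len(lib) x n_bits uint8 matrix)."""
        if self._matrix is None:
            self._order = list(self._fps)
            if self._order:
                self._matrix = np.stack([self._fps[k].bits for k in self._order])
            else:
                self._matrix = np.zeros((0, self.n_bits or 0), dtype=np.uint8)
        return list(self._order or []), self._matrix


@dataclass(frozen=True, order=True)
class SimilarityHit:
    """A library member whose Tanimoto to the query passed the cutoff."""

    query_id: str
    hit_id: str
    tanimoto: float
    hit_status: str | None = field(default=None, compare=False)


def path_fingerprint(
    smiles: str,
    n_bits: int = DEFAULT_N_BITS,
    max_path: int = DEFAULT_MAX_PATH,
    *,
    compound_id: str | None = None,
) -> Fingerprint:
    """Hashed linear-path fingerprint of a molecule given as SMILES.

    Paths of 1..max_path bonds are enumerated and hashed, 2 bits per path,
    into an n_bits-long vector. Deterministic: two SMILES spellings of the
    same molecule give identical bits.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for {compound_id!r}" if compound_id else ""
        raise ValueError(f"unparseable SMILES{label}: {smiles!r}")
    bv = rdmolops.RDKFingerprint(
        mol, minPath=1, maxPath=max_path, fpSize=n_bits, nBitsPerHash=2
    )
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits)


def tanimoto(i: Fingerprint, j: Fingerprint) -> float:
    """Tanimoto coefficient c/(a+b-c) of two equal-length fingerprints.

    Two all-zero fingerprints carry no evidence of similarity; that pair is
    defined as 0 and warned about rather than raising on the 0/0 form.
    """
    if i.n_bits != j.n_bits:
        raise ValueError(f"fingerprint length mismatch: {i.n_bits} != {j.n_bits}")
    a = i.popcount
    b = j.popcount
    if a == 0 and b == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    c = int(np.bitwise_and(i.bits, j.bits).sum())
    return c / (a + b - c)


def bulk_tanimoto(query: Fingerprint, library: FingerprintLibrary) -> tuple[list[str], np.ndarray]:
    """Tanimoto of one query against every library member, vectorised.

    Returns (ids, similarities) in library order. Pairs where both the query
    and the member are empty come out as 0.
    """
    if library.n_bits is not None and query.n_bits != library.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: query {query.n_bits}, library {library.n_bits}"
        )
    ids, mat = library.matrix()
    if not ids:
        return [], np.zeros(0)
    q = query.bits.astype(np.float64)
    c = mat.astype(np.float64) @ q
    a = float(q.sum())
    b = mat.sum(axis=1).astype(np.float64)
    denom = a + b - c
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), 0.0)
    return ids, sims


def similarity_search(
    query: Fingerprint,
    library: FingerprintLibrary | Mapping[str, Fingerprint],
    cutoff: float = 0.7,
    strict: bool = True,
    *,
    query_id: str = "query",
    statuses: Mapping[str, str] | None = None,
) -> list[SimilarityHit]:
    """All library members whose Tanimoto to the query passes the cutoff.

    ``strict`` keeps only similarities > cutoff ("more than 0.7"); with
    strict=False the boundary value itself is kept (>=). Hits are sorted by
    descending similarity, ties broken by hit id.
    """
    if not isinstance(library, FingerprintLibrary):
        library = FingerprintLibrary(library)
    ids, sims = bulk_tanimoto(query, library)
    keep = sims > cutoff if strict else sims >= cutoff
    hits = [
        SimilarityHit(
            query_id=query_id,
            hit_id=hid,
            tanimoto=float(s),
            hit_status=statuses.get(hid) if statuses else None,
        )
        for hid, s, k in zip(ids, sims, keep)
        if k
    ]
    hits.sort(key=lambda h: (-h.tanimoto, h.hit_id))
    return hits
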