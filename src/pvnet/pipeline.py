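"""End-to-end pharmacovigilance triage.

The procedure, given the two drug-target networks and binary fingerprints:

1. derive the withdrawn-approved drug-drug network (shared targets);
2. select probe withdrawn drugs — those linked to more than ``min_neighbors``
   (default 8) distinct approved drugs, a proxy for targets under heavy
   research attention;
3. flag each probe's approved neighbors whose fingerprint Tanimoto to the
   probe passes the cutoff (default strictly greater than 0.7) — similarity
   is computed only within shared-target pairs;
4. independently, triage a natural-product library by Tanimoto against ALL
   approved and ALL withdrawn drugs into four classes:
   approved_only / withdrawn_only / both / neither.

The asymmetry between steps 3 (shared-target partners only) and 4 (all
drugs) is intentional: approved drugs come with target annotations, natural
products generally do not, so the fingerprint is their only handle.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import round_half_up
from .network import DrugDrugNetwork
from .similarity import Fingerprint, FingerprintLibrary, SimilarityHit

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSet",
    "FlagRow",
    "FlagReport",
    "NPClassification",
    "NP_CLASSES",
    "select_probes",
    "flag_approved",
    "classify_natural_products",
    "summarize_flags",
]

NP_CLASSES = ("approved_only", "withdrawn_only", "both", "neither")


@dataclass(frozen=True)
class ProbeSet:
    """Withdrawn drugs with more than ``threshold`` distinct approved partners."""

    probes: tuple[tuple[str, int], ...]  # (withdrawn_id, approved_neighbor_count)
    threshold: int

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.probes)


@dataclass(frozen=True)
class FlagRow:
    approved_id: str
    withdrawn_id: str
    tanimoto: float
    shared_target_ids: frozenset[str]


@dataclass(frozen=True)
class FlagReport:
    """Approved drugs similar (above cutoff) to a probe withdrawn drug."""

    flags: tuple[FlagRow, ...]
    cutoff: float
    strict: bool

    @property
    def n_flagged_approved(self) -> int:
        return len({row.approved_id for row in self.flags})

    @property
    def flagged_approved_ids(self) -> frozenset[str]:
        return frozenset(row.approved_id for row in self.flags)


@dataclass
class NPClassification:
    """Four-class triage of a natural-product library.

    classes partition the library; a compound's class is a pure function of
    whether its approved hit list and withdrawn hit list are empty.
    """

    classes: dict[str, str]  # compound_id -> class
    approved_hits: dict[str, list[SimilarityHit]]
    withdrawn_hits: dict[str, list[SimilarityHit]]
    cutoff: float
    class_counts: Counter = field(default_factory=Counter)
    class_percents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = Counter(self.classes.values())
        n = len(self.classes)
        if n and not self.class_percents:
            self.class_percents = {
                cls: round_half_up(100 * self.class_counts.get(cls, 0) / n, 2)
                for cls in NP_CLASSES
            }


def select_probes(ddnet: DrugDrugNetwork, min_neighbors: int = 8) -> ProbeSet:
    """Withdrawn drugs whose distinct approved-neighbor count exceeds min_neighbors.

    The boundary is strict: exactly min_neighbors partners is not enough.
    An empty probe set is valid and logged.
    """
    counts: dict[str, int] = {w: 0 for w in ddnet.withdrawn_nodes}
    for w, _a in ddnet.edges:
        counts[w] += 1
    probes = tuple(
        sorted((w, c) for w, c in counts.items() if c > min_neighbors)
    )
    if not probes:
        logger.info("no withdrawn drug exceeds %d approved neighbors", min_neighbors)
    return ProbeSet(probes=probes, threshold=min_neighbors)


def flag_approved(
    probes: ProbeSet,
    ddnet: DrugDrugNetwork,
    fingerprints: Mapping[str, Fingerprint],
    cutoff: float = 0.7,
    strict: bool = True,
) -> FlagReport:
    """Tanimoto-screen each probe against its own approved neighbors.

    Only pairs already linked by a shared target are compared. Pairs with a
    missing fingerprint on either side are skipped and logged, never abort.
    Output order is canonical (probe id, descending similarity, approved id),
    so the report is invariant to input ordering.
    """
    from .similarity import tanimoto

    rows: list[FlagRow] = []
    n_skipped = 0
    for w in probes.ids:
        fp_w = fingerprints.get(w)
        if fp_w is None:
            n_skipped += len(ddnet.approved_neighbors(w))
            logger.info("probe %r has no fingerprint; all its pairs skipped", w)
            continue
        for a in ddnet.approved_neighbors(w):
            fp_a = fingerprints.get(a)
            if fp_a is None:
                n_skipped += 1
                logger.info("approved drug %r has no fingerprint; pair (%s, %s) skipped", a, w, a)
                continue
            t = tanimoto(fp_w, fp_a)
            if (t > cutoff) if strict else (t >= cutoff):
                rows.append(
                    FlagRow(
                        approved_id=a,
                        withdrawn_id=w,
                        tanimoto=t,
                        shared_target_ids=ddnet.shared_targets(w, a),
                    )
                )
    if n_skipped:
        logger.info("%d probe-neighbor pairs skipped for missing fingerprints", n_skipped)
    rows.sort(key=lambda r: (r.withdrawn_id, -r.tanimoto, r.approved_id))
    return FlagReport(flags=tuple(rows), cutoff=cutoff, strict=strict)


def classify_natural_products(
    np_fps: FingerprintLibrary,
    approved_fps: FingerprintLibrary,
    withdrawn_fps: FingerprintLibrary,
    cutoff: float = 0.7,
    strict: bool = True,
) -> NPClassification:
    """Triage natural products by similarity hits against all drugs.

    Every natural product is compared against every approved and every
    withdrawn drug (not just probes); the class follows from which hit
    lists are non-empty. Percentages are half-up to 2 decimals. An empty
    natural-product library is a hard error.
    """
    if len(np_fps) == 0:
        raise ValueError("natural-product library is empty")
    for lib, name in ((approved_fps, "approved"), (withdrawn_fps, "withdrawn")):
        if lib.n_bits is not None and np_fps.n_bits != lib.n_bits:
            raise ValueError(
                f"fingerprint length mismatch: natural products {np_fps.n_bits}, "
                f"{name} drugs {lib.n_bits}"
            )

    np_ids, np_mat = np_fps.matrix()
    classes: dict[str, str] = {}
    approved_hits: dict[str, list[SimilarityHit]] = {}
    withdrawn_hits: dict[str, list[SimilarityHit]] = {}

    def _hits(lib: FingerprintLibrary, status: str) -> dict[str, list[SimilarityHit]]:
        ids, mat = lib.matrix()
        out: dict[str, list[SimilarityHit]] = {q: [] for q in np_ids}
        if not ids:
            return out
        a = np_mat.sum(axis=1, dtype=np.float64)  # popcounts of queries
        b = mat.sum(axis=1, dtype=np.float64)
        c = np_mat.astype(np.float64) @ mat.astype(np.float64).T
        denom = a[:, None] + b[None, :] - c
        sims = np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), 0.0)
        passing = sims > cutoff if strict else sims >= cutoff
        for qi, qid in enumerate(np_ids):
            hits = [
                SimilarityHit(query_id=qid, hit_id=ids[hi], tanimoto=float(sims[qi, hi]),
                              hit_status=status)
                for hi in np.nonzero(passing[qi])[0]
            ]
            hits.sort(key=lambda h: (-h.tanimoto, h.hit_id))
            out[qid] = hits
        return out

    approved_hits = _hits(approved_fps, "approved")
    withdrawn_hits = _hits(withdrawn_fps, "withdrawn")
    for qid in np_ids:
        has_a = bool(approved_hits[qid])
        has_w = bool(withdrawn_hits[qid])
        if has_a and has_w:
            classes[qid] = "both"
        elif has_a:
            classes[qid] = "approved_only"
        elif has_w:
            classes[qid] = "withdrawn_only"
        else:
            classes[qid] = "neither"
    return NPClassification(
        classes=classes,
        approved_hits=approved_hits,
        withdrawn_hits=withdrawn_hits,
        cutoff=cutoff,
    )


def summarize_flags(
    report: FlagReport,
    status_annotations: Mapping[str, str],
) -> dict[str, dict[str, float | int]]:
    """Market-status proportions of the flagged approved drugs.

    Each distinct flagged approved drug is bucketed by its annotation
    (typically "discontinued" vs "launched"; missing annotations land in
    "unknown"). Percentages are half-up to 1 decimal. An empty report yields
    an empty summary — no division by zero.
    """
    flagged = sorted(report.flagged_approved_ids)
    if not flagged:
        return {}
    buckets = Counter(status_annotations.get(a, "unknown") for a in flagged)
    n = len(flagged)
    return {
        status: {"count": count, "percent": round_half_up(100 * count / n, 1)}
        for status, count in sorted(buckets.items())
    }
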