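"""DrugBank-shaped synthetic data with planted, recoverable structure.

The generator emulates the statistical shape the analysis assumes, so every
stage is testable without any database download:

* two drug-target networks with contrasting drug-degree profiles — the
  withdrawn-like network small, sparse and centralized with a high isolated
  fraction, the approved-like network large with a heavier degree tail;
* an overlap set of targets shared by both networks, a few of which are
  "hubs" that attract interactions preferentially, so the derived
  withdrawn-approved drug-drug network is non-trivial and probe drugs
  (withdrawn drugs with many approved partners) exist by construction;
* binary fingerprint libraries whose background members are independent
  sparse random vectors (expected pairwise Tanimoto far below 0.7), with
  selected pairs planted at a chosen Tanimoto so the similarity pipeline has
  an exact ground truth to recover;
* adverse-effect annotations where almost every withdrawn drug carries one
  effect and a configurable couple carry several.

A single integer seed drives one named pseudo-random stream; identical
configurations produce byte-identical outputs. The default configuration
(``paper_like``) uses the published study's scale: 1411 approved / 66
withdrawn drugs, isolated fractions 9.28% / 34.85%, the published five-bin
degree profiles, and a 2156-compound natural-product library.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ingest import (
    AdverseEffectAnnotation,
    DrugRecord,
    DrugStatus,
    Interaction,
    TargetRecord,
)
from .similarity import Fingerprint, FingerprintLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "DrugTargetData",
    "FingerprintLibraries",
    "PlantedPair",
    "SyntheticStudy",
    "paper_like_config",
    "generate_drug_target_data",
    "generate_fingerprint_library",
    "generate_adverse_annotations",
    "generate_study",
    "expected_mean_degree",
]

# five right-closed degree bins: <=2, (2,4], (4,6], (6,20], >20
_BIN_RANGES = ((1, 2), (3, 4), (5, 6), (7, 20), (21, 40))

DEFAULT_EFFECT_VOCABULARY = (
    "hemopathy",
    "cardiovascular toxicity",
    "neurotoxicity",
    "hepatotoxicity",
    "nephrotoxicity",
    "carcinogenicity",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults reproduce the published scale."""

    n_approved: int = 1411
    n_withdrawn: int = 66
    n_targets_approved: int = 1478
    n_targets_withdrawn: int = 106
    overlap_targets: int = 28
    # five-bin percentage weights over drug degrees (including isolated drugs)
    degree_profile_approved: tuple[float, ...] = (37.42, 30.26, 11.91, 18.57, 1.84)
    degree_profile_withdrawn: tuple[float, ...] = (59.09, 16.67, 12.12, 12.12, 0.0)
    isolated_fraction_approved: float = 0.0928
    isolated_fraction_withdrawn: float = 0.3485
    n_natural_products: int = 2156
    # fingerprints
    n_bits: int = 1024
    sparsity: float = 0.05  # expected fraction of set bits in background vectors
    planted_tanimoto: float = 0.85
    # planted pipeline structure
    n_planted_probes: int = 2
    probe_neighbor_count: int = 12
    planted_flags_per_probe: int = 2
    # natural-product triage ground truth
    n_np_approved_only: int = 1092
    n_np_withdrawn_only: int = 1
    n_np_both: int = 75
    # hub structure: a fraction of targets attracts interactions preferentially
    hub_fraction: float = 0.1
    hub_weight: float = 10.0
    multi_effect_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("isolated_fraction_approved", "isolated_fraction_withdrawn", "sparsity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.planted_tanimoto <= 1.0:
            raise ValueError("planted_tanimoto must be in [0, 1]")
        for name in ("degree_profile_approved", "degree_profile_withdrawn"):
            prof = getattr(self, name)
            if len(prof) != 5 or any(w < 0 for w in prof):
                raise ValueError(f"{name} must be 5 non-negative bin weights")
        if self.overlap_targets > min(self.n_targets_approved, self.n_targets_withdrawn):
            raise ValueError("overlap_targets exceeds a network's target pool")
        if self.n_bits < 64:
            raise ValueError("n_bits must be at least 64")
        n_planted_np = self.n_np_approved_only + self.n_np_withdrawn_only + self.n_np_both
        if n_planted_np > self.n_natural_products:
            raise ValueError("planted natural-product classes exceed library size")


def paper_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default configuration at the published study's scale."""
    return GeneratorConfig(seed=seed, **overrides)


@dataclass
class DrugTargetData:
    drugs_approved: list[DrugRecord]
    drugs_withdrawn: list[DrugRecord]
    targets_approved: list[TargetRecord]
    targets_withdrawn: list[TargetRecord]
    interactions_approved: list[Interaction]
    interactions_withdrawn: list[Interaction]


@dataclass(frozen=True)
class PlantedPair:
    id_a: str
    status_a: str
    id_b: str
    status_b: str
    target_tanimoto: float
    achieved_tanimoto: float


@dataclass
class FingerprintLibraries:
    approved: FingerprintLibrary
    withdrawn: FingerprintLibrary
    natural_products: FingerprintLibrary
    planted: list[PlantedPair] = field(default_factory=list)

    def by_status(self, status: str) -> FingerprintLibrary:
        return {
            "approved": self.approved,
            "withdrawn": self.withdrawn,
            "natural_product": self.natural_products,
        }[status]


def expected_mean_degree(cfg: GeneratorConfig, status: str) -> float:
    """Closed-form expected drug degree under the binned sampler."""
    if status == "approved":
        profile = cfg.degree_profile_approved
        iso = cfg.isolated_fraction_approved
        n_targets = cfg.n_targets_approved
    else:
        profile = cfg.degree_profile_withdrawn
        iso = cfg.isolated_fraction_withdrawn
        n_targets = cfg.n_targets_withdrawn
    weights = _conditional_bin_weights(profile, iso)
    mean_active = sum(
        w * (lo + min(hi, n_targets)) / 2 for w, (lo, hi) in zip(weights, _BIN_RANGES)
    )
    return (1 - iso) * mean_active


def _conditional_bin_weights(profile: Sequence[float], isolated_fraction: float) -> list[float]:
    """Bin weights for non-isolated drugs.

    The configured profile covers all drugs, isolated ones included; isolated
    drugs (degree 0) sit in the <=2 bin, so that bin's weight is reduced by
    the isolated share before renormalizing.
    """
    w = list(profile)
    w[0] = max(w[0] - 100.0 * isolated_fraction, 0.0)
    total = sum(w)
    if total <= 0:
        raise ValueError("degree profile is entirely consumed by the isolated fraction")
    return [x / total for x in w]


def _sample_degrees(
    n_active: int, weights: Sequence[float], n_targets: int, rng: np.random.Generator
) -> np.ndarray:
    for w, (lo, _hi) in zip(weights, _BIN_RANGES):
        if w > 0 and lo > n_targets:
            raise ValueError(
                f"infeasible config: degree bin starting at {lo} demanded with only "
                f"{n_targets} targets"
            )
    bins = rng.choice(len(_BIN_RANGES), size=n_active, p=np.asarray(weights))
    degrees = np.empty(n_active, dtype=int)
    for i, b in enumerate(bins):
        lo, hi = _BIN_RANGES[b]
        degrees[i] = rng.integers(lo, min(hi, n_targets) + 1)
    return degrees


def _target_weights(n_targets: int, hub_fraction: float, hub_weight: float) -> np.ndarray:
    w = np.ones(n_targets)
    n_hubs = max(1, math.ceil(hub_fraction * n_targets))
    w[:n_hubs] = hub_weight
    return w / w.sum()


def _generate_one_network(
    status: DrugStatus,
    n_drugs: int,
    target_ids: list[str],
    profile: Sequence[float],
    isolated_fraction: float,
    hub_fraction: float,
    hub_weight: float,
    rng: np.random.Generator,
) -> tuple[list[DrugRecord], list[Interaction]]:
    prefix = "A" if status is DrugStatus.APPROVED else "W"
    drugs = [
        DrugRecord(
            drug_id=f"{prefix}{i:05d}",
            name=f"{status.value} drug {i}",
            status=status,
            is_small_molecule=True,
        )
        for i in range(n_drugs)
    ]
    n_isolated = int(round(n_drugs * isolated_fraction))
    n_active = n_drugs - n_isolated
    weights = _conditional_bin_weights(profile, isolated_fraction)
    degrees = _sample_degrees(n_active, weights, len(target_ids), rng)
    # isolated drugs are the tail of the id range; active drugs come first
    p = _target_weights(len(target_ids), hub_fraction, hub_weight)
    interactions: list[Interaction] = []
    for drug, deg in zip(drugs[:n_active], degrees):
        chosen = rng.choice(len(target_ids), size=int(deg), replace=False, p=p)
        interactions.extend(
            Interaction(drug_id=drug.drug_id, target_id=target_ids[int(t)]) for t in sorted(chosen)
        )
    return drugs, interactions


def generate_drug_target_data(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> DrugTargetData:
    """Generate both drug-target networks' drugs, targets and interactions.

    Shared targets (the overlap pool) head both networks' target lists and
    double as the preferential "hub" subset, so hub and bottleneck structure
    exists and the two networks genuinely intersect.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shared = [f"T{i:05d}" for i in range(cfg.overlap_targets)]
    targets_approved = shared + [
        f"TA{i:05d}" for i in range(cfg.n_targets_approved - cfg.overlap_targets)
    ]
    targets_withdrawn = shared + [
        f"TW{i:05d}" for i in range(cfg.n_targets_withdrawn - cfg.overlap_targets)
    ]
    drugs_w, inter_w = _generate_one_network(
        DrugStatus.WITHDRAWN,
        cfg.n_withdrawn,
        targets_withdrawn,
        cfg.degree_profile_withdrawn,
        cfg.isolated_fraction_withdrawn,
        cfg.hub_fraction,
        cfg.hub_weight,
        rng,
    )
    drugs_a, inter_a = _generate_one_network(
        DrugStatus.APPROVED,
        cfg.n_approved,
        targets_approved,
        cfg.degree_profile_approved,
        cfg.isolated_fraction_approved,
        cfg.hub_fraction,
        cfg.hub_weight,
        rng,
    )
    return DrugTargetData(
        drugs_approved=drugs_a,
        drugs_withdrawn=drugs_w,
        targets_approved=[TargetRecord(t, f"target {t}") for t in targets_approved],
        targets_withdrawn=[TargetRecord(t, f"target {t}") for t in targets_withdrawn],
        interactions_approved=inter_a,
        interactions_withdrawn=inter_w,
    )


def _background_fingerprint(cfg: GeneratorConfig, rng: np.random.Generator) -> Fingerprint:
    k = max(1, int(round(cfg.n_bits * cfg.sparsity)))
    bits = np.zeros(cfg.n_bits, dtype=np.uint8)
    bits[rng.choice(cfg.n_bits, size=k, replace=False)] = 1
    return Fingerprint(bits)


def _plant_partner(
    base: Fingerprint, target_tanimoto: float, rng: np.random.Generator, tol: float = 0.02
) -> tuple[Fingerprint, float]:
    """A superset vector of ``base`` whose Tanimoto to it is ~target_tanimoto.

    Keeping all of the base's bits (c = a) and adding m fresh bits gives
    Tanimoto a/(a+m); m is chosen to land within ``tol`` of the target, and
    an unreachable target (not enough zero positions, or too sparse a base)
    is a hard error.
    """
    k = base.popcount
    if k == 0:
        raise ValueError("cannot plant similarity on an empty base fingerprint")
    if target_tanimoto >= 1.0:
        return Fingerprint(base.bits.copy()), 1.0
    if target_tanimoto <= 0.0:
        raise ValueError("planted Tanimoto must be positive (disjoint pairs are background)")
    m = int(round(k * (1.0 - target_tanimoto) / target_tanimoto))
    zeros = np.flatnonzero(base.bits == 0)
    if m > len(zeros):
        raise ValueError(
            f"target Tanimoto {target_tanimoto} unreachable: needs {m} free bits, "
            f"{len(zeros)} available"
        )
    achieved = k / (k + m)
    if abs(achieved - target_tanimoto) > tol:
        raise ValueError(
            f"target Tanimoto {target_tanimoto} unreachable within ±{tol} "
            f"(closest achievable {achieved:.4f} at this sparsity)"
        )
    bits = base.bits.copy()
    if m:
        bits[rng.choice(zeros, size=m, replace=False)] = 1
    return Fingerprint(bits), achieved


def generate_fingerprint_library(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    ids: Mapping[str, Sequence[str]] | None = None,
    planted_assignments: Sequence[tuple[str, str, str, str, float]] | None = None,
) -> FingerprintLibraries:
    """Background fingerprint libraries with planted high-similarity pairs.

    ``ids`` maps each status ("approved" / "withdrawn" / "natural_product")
    to the id list to use; defaults are generated schematically.
    ``planted_assignments`` is a list of (status_a, id_a, status_b, id_b, t):
    id_b's vector is re-planted from id_a's so their Tanimoto is within
    ±0.02 of t. Planted pairs are recorded as ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if ids is None:
        ids = {
            "approved": [f"A{i:05d}" for i in range(cfg.n_approved)],
            "withdrawn": [f"W{i:05d}" for i in range(cfg.n_withdrawn)],
            "natural_product": [f"NP{i:05d}" for i in range(cfg.n_natural_products)],
        }
    libs = FingerprintLibraries(
        approved=FingerprintLibrary(),
        withdrawn=FingerprintLibrary(),
        natural_products=FingerprintLibrary(),
    )
    store: dict[str, dict[str, Fingerprint]] = {
        "approved": {},
        "withdrawn": {},
        "natural_product": {},
    }
    for status in ("approved", "withdrawn", "natural_product"):
        for key in ids.get(status, ()):
            store[status][key] = _background_fingerprint(cfg, rng)
    for status_a, id_a, status_b, id_b, t in planted_assignments or ():
        base = store[status_a][id_a]
        partner, achieved = _plant_partner(base, t, rng)
        store[status_b][id_b] = partner
        libs.planted.append(
            PlantedPair(
                id_a=id_a,
                status_a=status_a,
                id_b=id_b,
                status_b=status_b,
                target_tanimoto=t,
                achieved_tanimoto=achieved,
            )
        )
    for status, lib in (
        ("approved", libs.approved),
        ("withdrawn", libs.withdrawn),
        ("natural_product", libs.natural_products),
    ):
        for key, fp in store[status].items():
            lib.add(key, fp)
    return libs


def generate_adverse_annotations(
    withdrawn_ids: Sequence[str],
    effect_vocabulary: Sequence[str] = DEFAULT_EFFECT_VOCABULARY,
    multi_effect_count: int = 2,
    seed: int | np.random.Generator = 0,
) -> list[AdverseEffectAnnotation]:
    """One adverse effect per withdrawn drug, a chosen few with two.

    Emulates the shape where nearly every withdrawn drug maps to a single
    dominant adverse-event category and only a couple carry a syndrome of
    several.
    """
    if not effect_vocabulary:
        raise ValueError("effect vocabulary is empty")
    if multi_effect_count > len(withdrawn_ids):
        raise ValueError("multi_effect_count exceeds the number of withdrawn drugs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    multi = set(
        rng.choice(len(withdrawn_ids), size=multi_effect_count, replace=False).tolist()
    ) if multi_effect_count else set()
    annotations: list[AdverseEffectAnnotation] = []
    vocab = list(effect_vocabulary)
    for i, drug_id in enumerate(withdrawn_ids):
        n_effects = 2 if i in multi else 1
        if n_effects > len(vocab):
            raise ValueError("effect vocabulary too small for multi-effect drugs")
        chosen = rng.choice(len(vocab), size=n_effects, replace=False)
        annotations.extend(AdverseEffectAnnotation(drug_id, vocab[int(e)]) for e in sorted(chosen))
    return annotations


@dataclass
class SyntheticStudy:
    """A full coherent input set plus the planted ground truth."""

    config: GeneratorConfig
    data: DrugTargetData
    fingerprints: FingerprintLibraries
    annotations: list[AdverseEffectAnnotation]
    planted_probes: list[str]
    planted_flags: list[tuple[str, str, float]]  # (withdrawn_id, approved_id, achieved tanimoto)
    np_classes_truth: dict[str, str]

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "planted_probes": self.planted_probes,
                "planted_flags": [
                    {"withdrawn_id": w, "approved_id": a, "tanimoto": t}
                    for w, a, t in self.planted_flags
                ],
                "np_class_counts": {
                    cls: sum(1 for c in self.np_classes_truth.values() if c == cls)
                    for cls in ("approved_only", "withdrawn_only", "both", "neither")
                },
            },
            indent=2,
        )


def generate_study(cfg: GeneratorConfig) -> SyntheticStudy:
    """Generate everything the pipeline consumes, with exact ground truth.

    Planted structure, on top of the background networks and libraries:

    * ``n_planted_probes`` withdrawn drugs are wired, via a dedicated shared
      hub target each, to ``probe_neighbor_count`` approved drugs (> 8, so
      they are probes by construction);
    * for each probe, ``planted_flags_per_probe`` of those neighbors get
      fingerprints planted at ``planted_tanimoto`` to the probe — the flag
      set the pipeline must recover exactly;
    * natural products are planted into the four triage classes at the
      configured counts: similar to a clean approved drug (approved_only),
      to a clean withdrawn drug (withdrawn_only), or to an approved drug
      that itself has a withdrawn twin (both); the rest stay background
      (neither).
    """
    rng = np.random.default_rng(cfg.seed)
    data = generate_drug_target_data(cfg, rng)

    need_appr = cfg.n_planted_probes * cfg.probe_neighbor_count
    if cfg.n_planted_probes > cfg.n_withdrawn or need_appr > cfg.n_approved:
        raise ValueError("not enough drugs for the requested planted probes")
    if cfg.n_planted_probes > cfg.overlap_targets:
        raise ValueError("need one shared hub target per planted probe")
    if cfg.planted_flags_per_probe > cfg.probe_neighbor_count:
        raise ValueError("cannot plant more flags than probe neighbors")

    shared_ids = [t.target_id for t in data.targets_withdrawn[: cfg.overlap_targets]]
    probe_ids = [d.drug_id for d in data.drugs_withdrawn[: cfg.n_planted_probes]]
    planted_flags_idx: list[tuple[str, str]] = []
    neighbor_pool = [d.drug_id for d in data.drugs_approved]
    pool_pos = 0
    for pi, w in enumerate(probe_ids):
        hub = shared_ids[pi]
        data.interactions_withdrawn.append(Interaction(drug_id=w, target_id=hub))
        neighbors = neighbor_pool[pool_pos : pool_pos + cfg.probe_neighbor_count]
        pool_pos += cfg.probe_neighbor_count
        for a in neighbors:
            data.interactions_approved.append(Interaction(drug_id=a, target_id=hub))
        planted_flags_idx.extend((w, a) for a in neighbors[: cfg.planted_flags_per_probe])

    # --- fingerprint planting plan ---------------------------------------
    flagged_neighbors = {a for _w, a in planted_flags_idx}
    plan: list[tuple[str, str, str, str, float]] = [
        ("withdrawn", w, "approved", a, cfg.planted_tanimoto) for w, a in planted_flags_idx
    ]
    approved_ids = [d.drug_id for d in data.drugs_approved]
    withdrawn_ids = [d.drug_id for d in data.drugs_withdrawn]
    np_ids = [f"NP{i:05d}" for i in range(cfg.n_natural_products)]

    # "both" anchor: one clean approved drug acquires a withdrawn twin, so a
    # natural product similar to the anchor is similar to drugs of both kinds
    clean_approved = [a for a in approved_ids if a not in flagged_neighbors]
    clean_withdrawn = [w for w in withdrawn_ids if w not in probe_ids]
    np_classes_truth: dict[str, str] = {}
    np_cursor = 0
    if cfg.n_np_both:
        if not clean_approved or not clean_withdrawn:
            raise ValueError("no clean drugs left to anchor the 'both' class")
        anchor_a = clean_approved.pop()
        anchor_w = clean_withdrawn.pop()
        plan.append(("approved", anchor_a, "withdrawn", anchor_w, cfg.planted_tanimoto))
        for _ in range(cfg.n_np_both):
            nid = np_ids[np_cursor]
            np_cursor += 1
            plan.append(("approved", anchor_a, "natural_product", nid, 0.95))
            np_classes_truth[nid] = "both"
    for _ in range(cfg.n_np_withdrawn_only):
        if not clean_withdrawn:
            raise ValueError("no clean withdrawn drugs left for withdrawn_only plants")
        nid = np_ids[np_cursor]
        np_cursor += 1
        base = clean_withdrawn[np_cursor % len(clean_withdrawn)]
        plan.append(("withdrawn", base, "natural_product", nid, cfg.planted_tanimoto))
        np_classes_truth[nid] = "withdrawn_only"
    for j in range(cfg.n_np_approved_only):
        if not clean_approved:
            raise ValueError("no clean approved drugs left for approved_only plants")
        nid = np_ids[np_cursor]
        np_cursor += 1
        base = clean_approved[j % len(clean_approved)]
        plan.append(("approved", base, "natural_product", nid, cfg.planted_tanimoto))
        np_classes_truth[nid] = "approved_only"
    for nid in np_ids[np_cursor:]:
        np_classes_truth[nid] = "neither"

    libs = generate_fingerprint_library(
        cfg,
        rng,
        ids={"approved": approved_ids, "withdrawn": withdrawn_ids, "natural_product": np_ids},
        planted_assignments=plan,
    )
    achieved = {
        (p.id_a, p.id_b): p.achieved_tanimoto
        for p in libs.planted
        if p.status_a == "withdrawn" and p.status_b == "approved"
    }
    planted_flags = [(w, a, achieved[(w, a)]) for w, a in planted_flags_idx]

    annotations = generate_adverse_annotations(
        withdrawn_ids, DEFAULT_EFFECT_VOCABULARY, cfg.multi_effect_count, rng
    )
    return SyntheticStudy(
        config=cfg,
        data=data,
        fingerprints=libs,
        annotations=annotations,
        planted_probes=probe_ids,
        planted_flags=planted_flags,
        np_classes_truth=np_classes_truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the full input set as plain-text files plus ground-truth JSON."""
    from .ingest import write_drug_table, write_fingerprints

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_drug_table(study.data.drugs_approved, out / "drugs_approved.tsv")
    write_drug_table(study.data.drugs_withdrawn, out / "drugs_withdrawn.tsv")
    for name, targets in (
        ("targets_approved.tsv", study.data.targets_approved),
        ("targets_withdrawn.tsv", study.data.targets_withdrawn),
    ):
        with (out / name).open("w") as fh:
            fh.write("target_id\tname\n")
            for t in targets:
                fh.write(f"{t.target_id}\t{t.name}\n")
    for name, inter in (
        ("interactions_approved.tsv", study.data.interactions_approved),
        ("interactions_withdrawn.tsv", study.data.interactions_withdrawn),
    ):
        with (out / name).open("w") as fh:
            fh.write("drug_id\ttarget_id\n")
            for it in inter:
                fh.write(f"{it.drug_id}\t{it.target_id}\n")
    with (out / "adverse_annotations.tsv").open("w") as fh:
        fh.write("drug_id\teffect\n")
        for ann in study.annotations:
            fh.write(f"{ann.drug_id}\t{ann.effect}\n")
    write_fingerprints(study.fingerprints.approved, out / "fingerprints_approved.tsv")
    write_fingerprints(study.fingerprints.withdrawn, out / "fingerprints_withdrawn.tsv")
    write_fingerprints(study.fingerprints.natural_products, out / "fingerprints_np.tsv")
    (out / "ground_truth.json").write_text(study.ground_truth_json())


# dataclasses.asdict is handy for config serialization in drivers
def config_to_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)
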