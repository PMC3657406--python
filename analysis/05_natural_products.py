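"""Triage the natural-product library against all approved and withdrawn drugs.

Every natural product is compared by fingerprint Tanimoto (> 0.7) to every
drug of both networks and classed as approved_only / withdrawn_only / both /
neither. Compounds in the "both" class combine evidence of drug-likeness
with structural resemblance to a withdrawn drug — the triage's
pharmacovigilance signal. Class assignments are checked against the planted
ground truth.
"""

import argparse
import json

from _paths import DATA, RESULTS
from pvnet import ingest
from pvnet.pipeline import NP_CLASSES, classify_natural_products


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cutoff", type=float, default=0.7)
    args = parser.parse_args()

    np_fps = ingest.read_fingerprints(DATA / "fingerprints_np.tsv")
    fp_a = ingest.read_fingerprints(DATA / "fingerprints_approved.tsv")
    fp_w = ingest.read_fingerprints(DATA / "fingerprints_withdrawn.tsv")
    result = classify_natural_products(np_fps, fp_a, fp_w, cutoff=args.cutoff)

    truth = json.loads((DATA / "ground_truth.json").read_text())["np_class_counts"]
    print(f"{len(np_fps)} natural products at Tanimoto > {args.cutoff}:")
    for cls in NP_CLASSES:
        n = result.class_counts.get(cls, 0)
        print(
            f"  {cls:<15} {n:>5} ({result.class_percents[cls]:.2f}%)"
            f"   planted: {truth.get(cls, 0)}"
        )

    flagged_both = [cid for cid, cls in result.classes.items() if cls == "both"]
    out = {
        "n_natural_products": len(np_fps),
        "cutoff": args.cutoff,
        "class_counts": dict(result.class_counts),
        "class_percents": result.class_percents,
        "planted_class_counts": truth,
        "both_class_compounds": sorted(flagged_both),
    }
    (RESULTS / "np_classification.json").write_text(json.dumps(out, indent=2))
    print(f"written to {RESULTS / 'np_classification.json'}")


if __name__ == "__main__":
    main()
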