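"""Generate the synthetic study inputs at the published scale.

Writes DrugBank-shaped TSVs (drugs, targets, interactions, adverse-effect
annotations), fingerprint libraries and the planted ground truth under
scratch/data/. All later drivers read from there.
"""

import argparse
import json

from _paths import DATA, RESULTS
from pvnet.synthetic_data import config_to_dict, generate_study, paper_like_config, write_study


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = paper_like_config(seed=args.seed)
    study = generate_study(cfg)
    write_study(study, DATA)

    print(f"synthetic study (seed {cfg.seed}) written to {DATA}")
    print(
        f"  approved: {len(study.data.drugs_approved)} drugs, "
        f"{len(study.data.interactions_approved)} interactions"
    )
    print(
        f"  withdrawn: {len(study.data.drugs_withdrawn)} drugs, "
        f"{len(study.data.interactions_withdrawn)} interactions"
    )
    print(
        f"  fingerprints: {len(study.fingerprints.approved)} approved, "
        f"{len(study.fingerprints.withdrawn)} withdrawn, "
        f"{len(study.fingerprints.natural_products)} natural products"
    )
    print(
        f"  planted: {len(study.planted_probes)} probes, "
        f"{len(study.planted_flags)} flag pairs, "
        f"{sum(1 for c in study.np_classes_truth.values() if c != 'neither')} planted NP classes"
    )

    (RESULTS / "generator_config.json").write_text(json.dumps(config_to_dict(cfg), indent=2))
    print(f"configuration recorded in {RESULTS / 'generator_config.json'}")


if __name__ == "__main__":
    main()
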