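"""Connected cores, vertex centralities, and the common/exclusive target split.

Extracts the largest connected component of each drug-target network,
computes the five vertex centralities per node (full tables go to scratch/,
they are large), and partitions targets into common vs network-exclusive
sets, reporting which common targets are connectivity bottlenecks
(articulation points) of each core.
"""

import json

from _paths import RESULTS, SCRATCH
from pvnet.centrality import compare_target_sets, compute_centralities, extract_connected_core
from pvnet.network import read_network


def main() -> None:
    cores = {}
    for status in ("withdrawn", "approved"):
        net = read_network(
            SCRATCH / f"{status}_edges.tsv", SCRATCH / f"{status}_nodes.tsv", status
        )
        core = extract_connected_core(net)
        cores[status] = core
        table = compute_centralities(core)
        table.to_csv(SCRATCH / f"centrality_{status}_core.tsv", sep="\t")
        drugs_in_core = len(core.nodes_with_role("drug"))
        print(
            f"{status}: core retains {core.n_nodes}/{net.n_nodes} nodes "
            f"({drugs_in_core} drug nodes); centrality table -> "
            f"{SCRATCH / f'centrality_{status}_core.tsv'}"
        )
        top = table[table["role"] == "target"].nlargest(5, "degree")
        print(f"  top-degree targets: {', '.join(f'{i} ({int(r.degree)})' for i, r in top.iterrows())}")

    cmp = compare_target_sets(cores["withdrawn"], cores["approved"])
    out = {
        "n_common_targets": len(cmp.common),
        "n_only_withdrawn_core": len(cmp.only_a),
        "n_only_approved_core": len(cmp.only_b),
        "bottlenecks_withdrawn_core": sorted(cmp.bottlenecks_a),
        "bottlenecks_approved_core": sorted(cmp.bottlenecks_b),
        "common_target_degrees": {t: list(d) for t, d in cmp.common_degrees.items()},
    }
    (RESULTS / "target_comparison.json").write_text(json.dumps(out, indent=2))
    print(
        f"targets: {out['n_common_targets']} common, "
        f"{out['n_only_withdrawn_core']} exclusive to the withdrawn core, "
        f"{out['n_only_approved_core']} exclusive to the approved core; "
        f"{len(out['bottlenecks_withdrawn_core'])}/{len(out['bottlenecks_approved_core'])} "
        "common targets are bottlenecks of the respective core"
    )
    print(f"written to {RESULTS / 'target_comparison.json'}")


if __name__ == "__main__":
    main()
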