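#!/usr/bin/env python
"""Cluster the 83 complete score panels into pathogenicity classes.

Runs k-means (k=3) on the five-score matrix (CADD divided by 33), embeds it
in 2-D by classical MDS, clusters the REVEL-vs-Condel scatter view, and
compares both re-clusterings with the published cluster colors. Writes
results/clusters.tsv and results/cluster_concordance.json.
"""

import json
from pathlib import Path

from pcd_triage import concordance, load_packaged_cohort, mds_view_cluster, scatter_view_cluster

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_packaged_cohort()
    assign, embedding, matrix = mds_view_cluster(cohort)
    scatter_assign, scatter_keys = scatter_view_cluster(cohort)

    OUT.mkdir(exist_ok=True)
    with open(OUT / "clusters.tsv", "w") as fh:
        fh.write("gene\tcdna_change\tview\tlabel\tcoord1\tcoord2\n")
        for key, color, xy in zip(matrix.keys, assign.colors, embedding.coords):
            fh.write(f"{key[0]}\t{key[1]}\tmds\t{color}\t{xy[0]:.5f}\t{xy[1]:.5f}\n")
        for key, color in zip(scatter_keys, scatter_assign.colors):
            fh.write(f"{key[0]}\t{key[1]}\tscatter\t{color}\t\t\n")

    pub_mds = {r.record.key: r.mds_label for r in cohort if r.mds_label}
    pub_scatter = {r.record.key: r.scatter_label for r in cohort if r.scatter_label}
    report = {
        "mds_view": {
            "sizes": assign.sizes(),
            "wcss": assign.wcss,
            "concordance": concordance(dict(zip(matrix.keys, assign.colors)), pub_mds),
        },
        "scatter_view": {
            "sizes": scatter_assign.sizes(),
            "wcss": scatter_assign.wcss,
            "concordance": concordance(
                dict(zip(scatter_keys, scatter_assign.colors)), pub_scatter
            ),
        },
        "mds_top_eigenvalues": [float(v) for v in embedding.eigenvalues[:4]],
    }
    (OUT / "cluster_concordance.json").write_text(json.dumps(report, indent=2))
    m, s = report["mds_view"], report["scatter_view"]
    print(f"five-score view: sizes {m['sizes']}, ARI vs published "
          f"{m['concordance']['ari']:.3f}")
    print(f"scatter view:    sizes {s['sizes']}, ARI vs published "
          f"{s['concordance']['ari']:.3f}")
    print(f"wrote {OUT / 'clusters.tsv'} and {OUT / 'cluster_concordance.json'}")


if __name__ == "__main__":
    main()
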