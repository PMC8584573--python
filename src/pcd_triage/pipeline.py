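"""End-to-end triage run: read table, cluster both views, embed, summarise.

Produces a report bundle in the output directory: per-variant cluster table
(``clusters.tsv``), per-cluster score statistics and Kruskal-Wallis tests
(``summary.json``), gene/consequence/novelty tallies (``tallies.json``) and
a reproducibility manifest (``manifest.json``). Group statistics are
computed both against the re-clustered labels and, when the input carries
published cluster labels, against those, keyed separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import (
    DEFAULT_RESTARTS,
    DEFAULT_SEED,
    concordance,
    mds_view_cluster,
    scatter_view_cluster,
)
from .stats import group_summary, kruskal_wallis
from .variant_table import (
    CohortTable,
    load_packaged_cohort,
    read_cohort_table,
    tally_by_consequence,
    tally_by_gene,
    tally_novel,
)

__all__ = ["RunConfig", "run_triage"]

SCORE_FIELDS = ("metalr", "metasvm", "cadd_phred", "revel", "condel")


@dataclasses.dataclass
class RunConfig:
    input: str | None = None          # None -> packaged cohort fixture
    scaling_mode: str = "cadd_div33"
    cluster_space: str = "scores"
    seed: int = DEFAULT_SEED
    restarts: int = DEFAULT_RESTARTS
    outdir: str = "triage_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _stats_block(table: CohortTable, keys_to_label: dict, label_order=("red", "blue", "green")) -> dict:
    """Per-score group summaries + Kruskal-Wallis over one labeling."""
    block: dict = {}
    for score in SCORE_FIELDS:
        values, labels = [], []
        for row in table:
            v = getattr(row.panel, score)
            lab = keys_to_label.get(row.record.key)
            if v is not None and lab is not None:
                values.append(v)
                labels.append(lab)
        summaries = group_summary(values, labels)
        kw = kruskal_wallis(values, labels)
        block[score] = {
            "groups": {
                lab: dataclasses.asdict(summaries[lab])
                for lab in label_order
                if lab in summaries
            },
            "kruskal_wallis": dataclasses.asdict(kw),
        }
    return block


def run_triage(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written bundle."""
    table = (
        load_packaged_cohort() if config.input is None else read_cohort_table(config.input)
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # clustering, both views
    mds_assign, embedding, matrix = mds_view_cluster(
        table, config.scaling_mode, config.restarts, config.seed, config.cluster_space
    )
    scatter_assign, scatter_keys = scatter_view_cluster(
        table, config.restarts, config.seed
    )

    # per-variant cluster table
    lines = ["gene\tcdna_change\tview\tlabel\tcolor\tcoord1\tcoord2"]
    for key, label, color, xy in zip(
        matrix.keys, mds_assign.labels, mds_assign.colors, embedding.coords
    ):
        lines.append(
            f"{key[0]}\t{key[1]}\tmds\t{label}\t{color}\t{xy[0]:.6f}\t{xy[1]:.6f}"
        )
    for key, label, color in zip(
        scatter_keys, scatter_assign.labels, scatter_assign.colors
    ):
        lines.append(f"{key[0]}\t{key[1]}\tscatter\t{label}\t{color}\t\t")
    clusters_path = outdir / "clusters.tsv"
    _atomic_write(clusters_path, "\n".join(lines) + "\n")

    # group statistics against re-clustered and (where present) published labels
    recl_mds = dict(zip(matrix.keys, mds_assign.colors))
    recl_scatter = dict(zip(scatter_keys, scatter_assign.colors))
    summary: dict = {
        "reclustered": {
            "mds_view": _stats_block(table, recl_mds),
            "scatter_view": _stats_block(table, recl_scatter),
        }
    }
    pub_mds = {r.record.key: r.mds_label for r in table if r.mds_label}
    pub_scatter = {r.record.key: r.scatter_label for r in table if r.scatter_label}
    concordance_report: dict = {}
    if pub_mds:
        summary["published"] = {
            "mds_view": _stats_block(table, pub_mds),
            "scatter_view": _stats_block(table, pub_scatter),
        }
        concordance_report = {
            "mds_view": concordance(
                {k: v for k, v in recl_mds.items() if k in pub_mds}, pub_mds
            ),
            "scatter_view": concordance(
                {k: v for k, v in recl_scatter.items() if k in pub_scatter}, pub_scatter
            ),
        }
    summary["cluster_sizes"] = {
        "mds_view": mds_assign.sizes(),
        "scatter_view": scatter_assign.sizes(),
    }
    summary_path = outdir / "summary.json"
    _atomic_write(summary_path, json.dumps(summary, indent=2, sort_keys=True))

    tallies = {
        "n_variants": len(table),
        "n_genes": len(tally_by_gene(table)),
        "by_gene": dict(sorted(tally_by_gene(table).items())),
        "by_consequence": {
            c.value: n for c, n in sorted(tally_by_consequence(table).items())
        },
        "n_novel": tally_novel(table),
        "n_complete_panels": len(table.complete_rows()),
    }
    tallies_path = outdir / "tallies.json"
    _atomic_write(tallies_path, json.dumps(tallies, indent=2, sort_keys=True))

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "wcss": {"mds_view": mds_assign.wcss, "scatter_view": scatter_assign.wcss},
        "mds_eigenvalues": [float(v) for v in embedding.eigenvalues[:5]],
        "concordance_with_published": concordance_report,
        "numpy_version": np.__version__,
    }
    manifest_path = outdir / "manifest.json"
    _atomic_write(manifest_path, json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "clusters": clusters_path,
        "summary": summary_path,
        "tallies": tallies_path,
        "manifest": manifest_path,
    }
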