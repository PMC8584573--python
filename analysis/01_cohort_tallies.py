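#!/usr/bin/env python
"""Cohort composition: gene, consequence and novelty tallies.

Reads the packaged 112-variant PCD cohort and writes its composition to
results/cohort_tallies.json. Expected headline numbers: 112 variants across
28 genes; 83 missense; 13 novel; DNAH11 (21) and DNAH5 (18) dominate.
"""

import json
from pathlib import Path

from pcd_triage import (
    load_packaged_cohort,
    tally_by_consequence,
    tally_by_gene,
    tally_novel,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_packaged_cohort()
    by_gene = tally_by_gene(cohort)
    by_cons = {c.value: n for c, n in tally_by_consequence(cohort).items()}
    report = {
        "n_variants": len(cohort),
        "n_genes": len(by_gene),
        "n_novel": tally_novel(cohort),
        "n_complete_score_panels": len(cohort.complete_rows()),
        "by_consequence": dict(sorted(by_cons.items())),
        "by_gene": dict(sorted(by_gene.items(), key=lambda kv: -kv[1])),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "cohort_tallies.json").write_text(json.dumps(report, indent=2))
    print(f"{report['n_variants']} variants in {report['n_genes']} genes; "
          f"{by_cons['missense']} missense, {report['n_novel']} novel; "
          f"top genes: DNAH11={by_gene['DNAH11']}, DNAH5={by_gene['DNAH5']}")
    print(f"wrote {OUT / 'cohort_tallies.json'}")


if __name__ == "__main__":
    main()
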