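#!/usr/bin/env python
"""Recessive-disease risk for couples sharing heterozygous PCD variants.

Evaluates the binomial model P(>= 1 affected condition) = 1 - (3/4)^k for
k = 0..7 shared variants (per-variant offspring risk 1/4). The headline
figures are 0.4375 at k=2 and 0.8665 at k=7. Writes results/risk.json.
"""

import json
from pathlib import Path

from pcd_triage import shared_variant_risk

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = {}
    for k in range(8):
        res = shared_variant_risk(k)
        table[k] = {"p_any": round(res.p_any, 4), "pmf": [round(p, 5) for p in res.pmf]}
    OUT.mkdir(exist_ok=True)
    (OUT / "risk.json").write_text(json.dumps(table, indent=2))
    print("k shared variants -> P(>=1 affected condition):")
    for k, row in table.items():
        print(f"  k={k}: {row['p_any']:.4f}")
    print(f"wrote {OUT / 'risk.json'}")


if __name__ == "__main__":
    main()
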