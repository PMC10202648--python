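#!/usr/bin/env python
"""Ring-chromosome end adjacency: circular versus matched linear control.

On a ring, the two former chromosome ends are covalently adjacent, so the
contact model's distance decay makes recombination between the origin-
flanking sites far more likely than on an otherwise identical linear
chromosome. Samples 10^4 contact-weighted events per topology and tests
the ring's end-joining rate at the linear control's rate (one-sided
binomial). Writes results/ring_topology.json.
"""

import json
from pathlib import Path

from loxscape import studies

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = studies.ring_end_adjacency(SEED, n_events=10_000)
    (OUT / "ring_topology.json").write_text(json.dumps(res, indent=2) + "\n")
    print(f"ring:   {res['ring_end_events']}/{res['ring_total_events']} "
          f"end-joining events")
    print(f"linear: {res['linear_end_events']}/{res['linear_total_events']}")
    print(f"enrichment: {res['enrichment_ratio']:.1f}x "
          f"(one-sided binomial p = {res['p_value']:.3g})")


if __name__ == "__main__":
    main()
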