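#!/usr/bin/env python
"""Generate the synthetic corneal surface set.

Writes the deterministic fixture set — healthy and keratoconic pre-op
corneas plus the six ring-segment scenarios, anterior and posterior — to
scratch/surfaces/ (bulky point files), copies the manifest to results/,
and prints what was generated.
"""

import shutil
from pathlib import Path

from corneosim.surfaces import write_fixture_set

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "surfaces"
RESULTS = ROOT / "results"


def main() -> None:
    entries = write_fixture_set(OUT, seed=1)
    corneas = sorted({e["cornea"] for e in entries})
    scenarios = sorted({e["scenario"] for e in entries})
    RESULTS.mkdir(parents=True, exist_ok=True)
    shutil.copy(OUT / "manifest.tsv", RESULTS / "surface_manifest.tsv")
    print(f"wrote {len(entries)} surfaces to {OUT}")
    print(f"  corneas:   {', '.join(corneas)}")
    print(f"  scenarios: {', '.join(scenarios)}")
    print(f"  manifest:  {RESULTS / 'surface_manifest.tsv'}")


if __name__ == "__main__":
    main()
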