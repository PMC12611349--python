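#!/usr/bin/env python
"""Composite indices, Gi* hotspot tiers and priority conservation areas.

Min-max normalizes each layer, combines them with the 35/45/20 expert
weights per metric, screens the composites with the Getis-Ord Gi* statistic
(queen contiguity, occupied-cell background), and unions the 99%-confidence
hotspot cells of SE, SR and SN into the priority mask with labeled sites.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ipcz.diversity import attach_cells
from ipcz.grid import GridSpec
from ipcz.hotspots import composite_hotspots, summarize_priority
from ipcz.ingest import load_habitats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    spec = GridSpec()

    layers = {name: pd.read_csv(out / f"layer_{name}.csv", index_col="cell_id") for name in ("ALL", "TSP", "CSM")}
    results, mask = composite_hotspots(layers, spec)

    for res in results:
        counts = res.tier_counts()
        hot = {t: counts[t] for t in ("hot90", "hot95", "hot99")}
        print(
            f"{res.metric}: hot tiers {hot} "
            f"({sum(hot.values()) / spec.n_cells:.2%} of the region), Z_max {res.z.max():.2f}"
        )
        res.to_frame().to_csv(out / f"gistar_{res.metric}.csv", index=False)

    print(f"\npriority mask: {mask.mask.sum()} cells in {mask.n_sites} sites "
          f"({mask.mask.sum() / spec.n_cells:.2%} of the region)")

    non = pd.read_csv(out / "occurrences_nonthreatened.csv")
    thr = pd.read_csv(out / "occurrences_threatened.csv")
    hab = load_habitats(Path(args.data) / "habitats.csv")
    summary = summarize_priority(
        mask,
        attach_cells(pd.concat([non, thr], ignore_index=True), spec),
        attach_cells(thr, spec),
        attach_cells(hab, spec),
        spec,
    )
    print("priority content:", json.dumps(summary, indent=2))
    (out / "priority_summary.json").write_text(json.dumps(summary, indent=2))
    np.savetxt(out / "priority_cells.csv", mask.cells, fmt="%d", header="cell_id", comments="")


if __name__ == "__main__":
    main()
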