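#!/usr/bin/env python
"""Simulate the paired-condition dataset all downstream analyses consume.

Generates wild-type and mutant Hi-C contact matrices plus H3K9me3/H3K4me1/
CTCF/SCC1-like tracks for a two-arm synthetic genome, with the planted
truth (A/B blocks, HCD regions, TAD borders, loop anchors, peak positions)
written as BED files so every later stage can be scored against it.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hcdscan import io as hio  # noqa: E402
from hcdscan import standard_scenario  # noqa: E402
from hcdscan.pipeline import simulate_scenario  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/dataset")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = standard_scenario(seed=args.seed)
    data = simulate_scenario(params)
    layout = params.layout

    for cond in ("wt", "mut"):
        cms = [data.matrices[cond][a] for a in layout.arm_ids]
        hio.write_contact_matrix(cms, layout, out / f"{cond}.triplets.txt",
                                 out / f"{cond}.bins.txt")
        for factor, per_arm in data.tracks[cond].items():
            path = out / f"{cond}.{factor}.bedGraph"
            for i, arm in enumerate(layout.arm_ids):
                hio.write_bedgraph_track(per_arm[arm], layout, path,
                                         mode="w" if i == 0 else "a")

    truth = data.truth
    hio.write_bed([iv for t in truth.values() for iv in t.hcd_regions],
                  out / "truth_hcds.bed")
    hio.write_bed([iv for t in truth.values() for iv in t.domain_regions],
                  out / "truth_domains.bed")
    hio.write_bed([iv for t in truth.values() for iv in t.loop_anchors],
                  out / "truth_loop_anchors.bed")
    borders = []
    bs = layout.bin_size
    for arm, t in truth.items():
        for b in t.tad_borders:
            borders.append(layout.to_chrom(arm, b * bs, (b + 1) * bs))
    hio.write_bed(borders, out / "truth_tad_borders.bed")

    n_hcds = sum(len(t.hcd_regions) for t in truth.values())
    manifest = {
        "seed": args.seed,
        "arms": layout.arm_ids,
        "bin_size": layout.bin_size,
        "depth_per_arm": params.depth,
        "n_truth_hcds": n_hcds,
        "n_truth_borders": len(borders),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"simulated {len(layout.arm_ids)} arms at {layout.bin_size/1000:.0f} kb, "
          f"{n_hcds} planted HCDs, {len(borders)} TAD borders -> {out}")


if __name__ == "__main__":
    main()
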