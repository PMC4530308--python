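#!/usr/bin/env python
"""16S identity matrix and helix-38 cluster calls on a synthetic alignment.

Generates three aligned sequences at the 91% identity scale of the
study's three cells, implants a full helix-38 deletion in the last
(Cluster A archetype), and verifies recovery.  Writes
results/phylotype/identity_matrix.csv and clusters.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from achromatium.phylotype import (
    RegionAnnotation,
    assign_cluster,
    detect_helix38_deletion,
    identity_matrix,
)
from achromatium.synthetic import gen_alignment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results/phylotype")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    region = RegionAnnotation("helix38_v6", 600, 638)
    seqs, truth = gen_alignment(
        3, 1500, target_identity=91.0, deletion_spec=(region, 1.0),
        seed=args.seed,
    )
    m = identity_matrix(seqs)
    m.to_csv(out / "identity_matrix.csv")
    calls = pd.DataFrame({
        "seq_id": [s.seq_id for s in seqs],
        "cluster": [assign_cluster(detect_helix38_deletion(s, region))
                    for s in seqs],
    })
    calls.to_csv(out / "clusters.csv", index=False)

    print(f"wrote {out}/identity_matrix.csv and clusters.csv")
    offdiag = [m.iloc[i, j] for i in range(3) for j in range(i + 1, 3)]
    print(f"pairwise identities: {', '.join(f'{v:.2f}%' for v in offdiag)} "
          "(target 91 +/- 1)")
    print("cluster calls:", dict(zip(calls.seq_id, calls.cluster)),
          "| implanted deletion:", truth["has_deletion"])


if __name__ == "__main__":
    main()
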