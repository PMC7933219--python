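#!/usr/bin/env python
"""Build per-condition co-expression networks and rank hub rewiring.

Constructs the EC and TC-EC correlation networks from the simulated
matrix at the given |r| threshold, scores every feature with |Diffk|, and
reports how many planted rewired hubs land in the top 10.  Writes
results/diffk_table.tsv and results/diffk_top10.tsv.
"""

import argparse
from pathlib import Path

from diffconn.coexpr import condition_network
from diffconn.diffk import diffk_table, rank_diffk
from diffconn.io import read_expression_matrix, write_table
from diffconn.simulate import read_truth_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--min-abs-r", type=float, default=0.8)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    em = read_expression_matrix(
        args.sim_dir / "matrix.tsv",
        args.sim_dir / "samples.tsv",
        args.sim_dir / "features.tsv",
    )
    net_ec = condition_network(em, "EC", args.min_abs_r)
    net_tc = condition_network(em, "TC-EC", args.min_abs_r)
    print(f"EC network: {net_ec.n_edges} edges, max degree {net_ec.max_degree}; "
          f"TC-EC network: {net_tc.n_edges} edges, max degree {net_tc.max_degree} "
          f"(|r| >= {args.min_abs_r})")

    table = diffk_table(net_ec, net_tc, feature_types=dict(em.feature_type_of))
    top10 = rank_diffk(table, top_n=10)
    write_table(table, args.out_dir / "diffk_table.tsv", "diffk-table",
                threshold=args.min_abs_r)
    write_table(top10, args.out_dir / "diffk_top10.tsv", "diffk-top10",
                threshold=args.min_abs_r)

    truth = read_truth_report(args.sim_dir / "truth.tsv")
    hits = set(top10["feature_id"]) & set(truth.rewired_hubs)
    print(f"planted rewired hubs in the |Diffk| top 10: {len(hits)}/"
          f"{len(truth.rewired_hubs)}")
    if len(hits) < len(truth.rewired_hubs):
        print("note: at n = 20 samples/condition the sampling noise of the "
              "correlation estimate dominates an |r| >= 0.8 edge rule when the "
              "population within-module correlation is 0.5; see docs/methods.md")
    print(f"wrote diffk_table.tsv, diffk_top10.tsv -> {args.out_dir}/")


if __name__ == "__main__":
    main()
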