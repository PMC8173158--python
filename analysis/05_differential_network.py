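"""Build the aging-acceleration differential networks and analyze them.

For each disease (and all NDs pooled) the marginal-vs-partial correlation
differential rule at FDR < 0.1 defines the edges; the scripts report
network size, the log-log degree fit, sign-flip pair recovery,
aging->disease shortest paths and the betweenness permutation test.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))
from analysis._common import run_through  # noqa: E402

from epiaging import diffnet  # noqa: E402


def main() -> None:
    cfg, art = run_through("network")
    truth = art["truth"]
    planted = {tuple(sorted(p)) for p in truth.signflip_pairs}
    for d, net in art["networks"].items():
        edges = net.edge_set
        print(f"[{d}] {net.graph.number_of_nodes()} nodes, {len(edges)} edges")
        if planted and d in truth.disease_marker_ids or d == "ALL":
            rec = len(planted & edges)
            print(f"  planted sign-flip pairs recovered: {rec}/{len(planted)}")
        try:
            slope, r = diffnet.power_law_check(net)
            print(f"  degree fit: slope {slope:.2f}, r {r:.2f}")
        except ValueError as e:
            print(f"  degree fit: {e}")
        paths = art["paths"][d]
        print(f"  aging->{d} shortest paths: {len(paths)}")
        btw = art.get("betweenness", {}).get(d)
        if btw is not None and len(btw):
            top = btw.sort_values(["betweenness", "p"], ascending=[False, True]).head(3)
            for node, row in top.iterrows():
                print(f"  top betweenness {node}: {int(row['betweenness'])} (perm p {row['p']:.3g})")
    print(f"artifacts in {cfg.out_dir}")


if __name__ == "__main__":
    main()
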