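"""Tree topology metrics on canonical toy trees.

Builds the three reference topologies (star, path, Y-shaped tree) and prints
leaf fraction LF = L/m, normalized diameter D = d/m and tree hierarchy
TH = L/(2 m BCmax).  The star and path are the two extremes the metrics
interpolate between: a star maximizes LF (1.0) and hub load (TH = 0.5 with
diameter 2), a path minimizes LF (2/m) with D = 1.
"""
from mstmeg import make_toy_tree, tree_metrics

for kind, n in [("star", 80), ("path", 80), ("y_tree", 5)]:
    t = make_toy_tree(kind, n)
    m = tree_metrics(t)
    print(f"{kind:>7} (N={t.n_nodes}): L={m.L:3d}  LF={m.LF:.3f}  "
          f"d={m.d:3d}  D={m.D:.3f}  BCmax={m.BCmax:.3f}  TH={m.TH:.3f}")

print("\nA star tree has TH exactly 0.5: all (N-1)(N-2)/2 pairs route "
      "through the hub (BCmax = 1) and every other node is a leaf.")
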