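"""Independent brute-force oracles shared by the test suite."""

import itertools

import networkx as nx


def brute_force_centralities(G):
    """Betweenness and harmonic closeness by exhaustive path enumeration."""
    nodes = sorted(G.nodes)
    dist = {}
    paths = {}
    for s, t in itertools.permutations(nodes, 2):
        all_paths = list(nx.all_simple_paths(G, s, t))
        if not all_paths:
            continue
        d = min(len(p) - 1 for p in all_paths)
        dist[(s, t)] = d
        paths[(s, t)] = [p for p in all_paths if len(p) - 1 == d]
    btw = {v: 0.0 for v in nodes}
    for (s, t), plist in paths.items():
        if s < t:
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in plist)
                btw[v] += through / len(plist)
    harm = {
        v: sum(1.0 / dist[(v, u)] for u in nodes if (v, u) in dist) for v in nodes
    }
    return btw, harm
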