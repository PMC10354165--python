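"""Independent brute-force reference implementations used as oracles.

Deliberately written in a different style from the package (networkx
graphs, naive loops) so that agreement is evidence of correctness of the
rule set, not of shared code.
"""

import networkx as nx
import numpy as np


def oracle_backbone_nodes(skel, connector_xyz, p):
    """Literal application of the backbone rule list; returns the node-id set."""
    G = nx.Graph()
    pos = {int(n): skel.xyz[i] for i, n in enumerate(skel.node_ids)}
    G.add_nodes_from(pos)
    root = skel.root
    for n, pp in zip(skel.node_ids, skel.parent_ids):
        if pp != -1:
            G.add_edge(int(n), int(pp))

    # nearest-node connector mapping within the radius
    cmap = {}
    for c in np.asarray(connector_xyz, float).reshape(-1, 3):
        best, bd = None, None
        for n in G.nodes:
            d = float(np.linalg.norm(pos[n] - c))
            if bd is None or d < bd:
                best, bd = n, d
        if best is not None and bd <= p.connector_map_radius:
            cmap[best] = cmap.get(best, 0) + 1

    # iterative twig pruning (snapshot degrees per pass)
    while True:
        deg = dict(G.degree)
        doomed = set()
        for leaf in [n for n in G.nodes if deg[n] == 1 and n != root]:
            chain = [leaf]
            prev, cur = None, leaf
            hit_branch = False
            while True:
                nbrs = [x for x in G.neighbors(cur) if x != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    hit_branch = True
                    break
                if nxt == root:
                    break  # soma-side chains are never twigs
                chain.append(nxt)
                prev, cur = cur, nxt
            if hit_branch and len(chain) < p.twig_node_max \
                    and not any(n in cmap for n in chain):
                doomed |= set(chain)
        if not doomed:
            break
        G.remove_nodes_from(doomed)

    if len(G) == 0:
        return set()

    # fragmentation: remove branch points, components are unbranched paths,
    # then re-attach the adjacent branch points at each end
    deg = dict(G.degree)
    branch = {n for n in G.nodes if deg[n] >= 3}
    H = G.copy()
    H.remove_nodes_from(branch)
    fragments = []
    for comp in nx.connected_components(H):
        sub = H.subgraph(comp)
        if len(comp) == 1:
            path = list(comp)
            att = [b for b in G.neighbors(path[0]) if b in branch]
            if len(att) == 2:
                path = [att[0]] + path + [att[1]]
            elif len(att) == 1:
                path = [att[0]] + path
        else:
            ends = [n for n in sub.nodes if sub.degree(n) <= 1]
            path = nx.shortest_path(sub, ends[0], ends[1])
            head = [b for b in G.neighbors(path[0]) if b in branch]
            tail = [b for b in G.neighbors(path[-1]) if b in branch]
            if head:
                path = [head[0]] + path
            if tail:
                path = path + [tail[0]]
        fragments.append(path)
    for a, b in G.edges:
        if a in branch and b in branch:
            fragments.append([a, b])
    if not branch and len(G) > 0 and not fragments:
        fragments = [list(G.nodes)]

    def length(path):
        return sum(float(np.linalg.norm(pos[path[i + 1]] - pos[path[i]]))
                   for i in range(len(path) - 1))

    def nconn(path):
        return sum(cmap.get(n, 0) for n in path)

    # selection rules
    if not fragments:
        return set()
    largest = max(length(f) for f in fragments)
    selected = []
    for f in fragments:
        L = length(f)
        if L > p.large_fragment_min_len:
            selected.append(f)
        elif L > p.small_fragment_min_len and nconn(f) < p.connector_density_max * L:
            if L >= largest / p.relative_length_factor:
                selected.append(f)
    if not selected:
        return set()

    # distal trim relative to the largest selected fragment
    big = max(selected, key=length)
    e1, e2 = pos[big[0]], pos[big[-1]]
    kept = []
    for f in selected:
        if f is big:
            kept.append(f)
            continue
        d1 = min(float(np.linalg.norm(pos[n] - e1)) for n in f)
        d2 = min(float(np.linalg.norm(pos[n] - e2)) for n in f)
        if min(d1, d2) <= p.distal_trim_distance:
            kept.append(f)
    return set(n for f in kept for n in f)


def random_skeleton(rng, max_nodes=50):
    """Random small tree with edge lengths straddling the rule thresholds."""
    from cxlineage.io import SkeletonGraph

    n = int(rng.integers(2, max_nodes + 1))
    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    xyz = np.zeros((n, 3))
    for i in range(1, n):
        step = rng.choice([30.0, 300.0, 1500.0], p=[0.5, 0.3, 0.2])
        xyz[i] = xyz[parents[i]] + rng.normal(size=3) * step
    node_ids = np.arange(1, n + 1)
    parent_ids = np.array([p + 1 if p >= 0 else -1 for p in parents])
    skel = SkeletonGraph(int(rng.integers(1, 10**6)), node_ids, parent_ids,
                         xyz, np.full(n, 30.0))
    k = int(rng.integers(0, 6))
    if k:
        picks = rng.integers(0, n, size=k)
        conn = xyz[picks] + rng.normal(scale=120.0, size=(k, 3))
    else:
        conn = np.empty((0, 3))
    return skel, conn


def brute_force_cx_filter(connectors, catalog, p):
    """Ten-line reference of the large-field catalog filter."""
    kept = []
    for nid in catalog["neuron_id"]:
        cx = connectors[connectors["compartment"].isin(p.cx_regions)]
        total = cx.loc[cx["pre_neuron"] == nid, "weight"].sum() \
            + cx.loc[cx["post_neuron"] == nid, "weight"].sum()
        out = connectors[connectors["pre_neuron"] == nid]
        strongest = out.groupby("post_neuron")["weight"].sum().max() if len(out) else 0
        if total > 0 and total > p.min_cx_synapses and strongest > p.min_single_connection:
            kept.append(nid)
    return set(kept)
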