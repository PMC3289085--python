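"""Independent naive re-implementation of the seeded greedy expansion policy.

Used purely as a test oracle.  Deliberately shares no code with the package:
plain dict adjacency, brute-force weight sums over sorted vertex pairs, and
Floyd-Warshall for the induced diameter.
"""

from itertools import combinations

INF = float("inf")


def _diameter(members, adj):
    members = sorted(members)
    if len(members) == 1:
        return 0
    dist = {(a, b): (0 if a == b else INF) for a in members for b in members}
    for a, b in combinations(members, 2):
        if b in adj.get(a, {}):
            dist[(a, b)] = dist[(b, a)] = 1
    for k in members:
        for i in members:
            for j in members:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return max(dist[(a, b)] for a, b in combinations(members, 2))


def naive_extend(seed, weights, t_in, d):
    """Grow a cluster from *seed* on an edge-weight map {(u, v): w}.

    Mirrors the published policy: unconditional heaviest-edge first
    admission from the singleton seed, then repeatedly admit the
    highest-priority external neighbor (priority E_vk, ties by larger
    e_vk then ascending id) that passes E_vk >= t_in and diameter <= d.
    """
    adj = {}
    for (u, v), w in weights.items():
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    members = {seed}
    nbrs = sorted(adj.get(seed, {}), key=lambda v: (-adj[seed][v], v))
    if not nbrs:
        return frozenset(members)
    members.add(nbrs[0])

    while True:
        w_k = sum(
            adj[a][b] for a, b in combinations(sorted(members), 2) if b in adj.get(a, {})
        )
        if w_k <= 0:
            break
        candidates = []
        for v in sorted(adj):
            if v in members:
                continue
            e_vk = sum(adj[v][u] for u in adj[v] if u in members)
            if e_vk > 0 or any(u in members for u in adj[v]):
                candidates.append((v, e_vk / w_k, e_vk))
        candidates.sort(key=lambda t: (-t[1], -t[2], t[0]))
        admitted = False
        for v, ratio, _ in candidates:
            if ratio >= t_in and _diameter(members | {v}, adj) <= d:
                members.add(v)
                admitted = True
                break
        if not admitted:
            break
    return frozenset(members)
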