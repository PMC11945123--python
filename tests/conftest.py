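"""Shared fixtures: inline structure documents and small synthetic datasets."""

import numpy as np
import pytest

from seqbind import fixtures

BENZENE_MOL2 = """\
@<TRIPOS>MOLECULE
benzene
 6 6 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
  1 C1   0.000   1.396   0.000 C.ar 1 BNZ 0.0
  2 C2   1.209   0.698   0.000 C.ar 1 BNZ 0.0
  3 C3   1.209  -0.698   0.000 C.ar 1 BNZ 0.0
  4 C4   0.000  -1.396   0.000 C.ar 1 BNZ 0.0
  5 C5  -1.209  -0.698   0.000 C.ar 1 BNZ 0.0
  6 C6  -1.209   0.698   0.000 C.ar 1 BNZ 0.0
@<TRIPOS>BOND
 1 1 2 ar
 2 2 3 ar
 3 3 4 ar
 4 4 5 ar
 5 5 6 ar
 6 6 1 ar
"""

ETHANE_MOL2 = """\
@<TRIPOS>MOLECULE
ethane
 2 1 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
  1 C1   0.000   0.000   0.000 C.3 1 ETH 0.0
  2 C2   1.540   0.000   0.000 C.3 1 ETH 0.0
@<TRIPOS>BOND
 1 1 2 1
"""

ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C
END
"""

GLY_SER_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   SER A   2       5.000   0.000   0.000  1.00  0.00           N
ATOM      4  CA  SER A   2       6.458   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def small_dataset():
    """80 planted-affinity complexes (sigma 0.1) shared across tests."""
    return fixtures.generate_dataset(80, fixtures.PlantedModel(sigma=0.1, seed=7))


# ---------------------------------------------------------------------------
# independent brute-force oracle for graph statistics
# ---------------------------------------------------------------------------

def brute_force_graph_stats(n: int, edges: list[tuple[int, int]]):
    """Mean clustering and mean betweenness by explicit shortest-path counting.

    Shortest-path counts come from per-source BFS layering (sigma DP), pair
    contributions from the d(s,v)+d(v,t)=d(s,t) decomposition -- independent
    of the Brandes accumulation used by networkx.
    """
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    # clustering
    clustering = []
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            clustering.append(0.0)
            continue
        links = sum(1 for a in adj[v] for b in adj[v] if a < b and b in adj[a])
        clustering.append(2.0 * links / (k * (k - 1)))

    # BFS distances and path counts from every source
    INF = float("inf")
    dist = [[INF] * n for _ in range(n)]
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        dist[s][s], sigma[s][s] = 0, 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if dist[s][w] == INF:
                        dist[s][w] = d + 1
                        nxt.append(w)
                    if dist[s][w] == d + 1:
                        sigma[s][w] += sigma[s][u]
            frontier = nxt
            d += 1

    betweenness = []
    norm = (n - 1) * (n - 2) / 2.0
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or sigma[s][t] == 0:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        betweenness.append(total / norm if norm > 0 else 0.0)

    return float(np.mean(clustering)), float(np.mean(betweenness))


def connected_graphs_up_to(n_max: int):
    """Yield (n, edge list) for every connected labelled graph with 3..n_max nodes."""
    from itertools import combinations

    for n in range(3, n_max + 1):
        possible = list(combinations(range(n), 2))
        for bits in range(1 << len(possible)):
            edges = [possible[k] for k in range(len(possible)) if bits >> k & 1]
            if len(edges) < n - 1:
                continue
            if _connected(n, edges):
                yield n, edges


def _connected(n, edges):
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n
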