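import pytest

from disnet import fixtures


@pytest.fixture(scope="session")
def toy_graph():
    return fixtures.toy_interactome()


@pytest.fixture(scope="session")
def cellcycle_net():
    return fixtures.cellcycle_network()


def orbit_oracle(successors: list[int]):
    """Independent attractor finder: follow every state's orbit with explicit
    cycle detection; returns {canonical cycle tuple: basin size}.

    Deliberately naive (restarts from every state) so it shares no code path
    with disnet.dynamics.find_attractors.
    """
    basins: dict[tuple[int, ...], int] = {}
    n_states = len(successors)
    for start in range(n_states):
        seen: dict[int, int] = {}
        s = start
        while s not in seen:
            seen[s] = len(seen)
            s = successors[s]
        # s is the first repeated state: walk the cycle explicitly
        cycle = [s]
        t = successors[s]
        while t != s:
            cycle.append(t)
            t = successors[t]
        pivot = cycle.index(min(cycle))
        canon = tuple(cycle[pivot:] + cycle[:pivot])
        basins[canon] = basins.get(canon, 0) + 1
    return basins


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    """Hand-rolled BFS (no networkx) used as a shortest-path oracle."""
    from collections import deque

    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist
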