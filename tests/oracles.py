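"""Independent reference routes used only by the test suite.

These deliberately avoid the package's linear algebra and graph libraries:
plain-dict breadth-first search for estimability, direct-definition Pearson
correlation, and numerical integration for the null density.
"""

from collections import deque


def contrast_estimable_oracle(slides: list[tuple[str, str]], ci: str, uvi: str) -> bool:
    """Gain-graph estimability of lambda(uvi) - lambda(ci).

    Each slide (cy3, cy5) contributes the equation
    m = gamma + lambda(cy5) - lambda(cy3).  Walk the sample graph with BFS,
    carrying the net orientation sum (number of tail->head crossings minus
    head->tail).  gamma is shared by *every* equation of the gene, so a
    cycle with nonzero orientation sum anywhere in the graph identifies it
    globally.  The contrast is estimable iff ``uvi`` is reachable from
    ``ci`` and either gamma is identified or the path orientation sum to
    ``uvi`` is zero (gamma cancels along the path).
    """
    adj: dict[str, list[tuple[str, int]]] = {}
    for cy3, cy5 in slides:
        adj.setdefault(cy3, []).append((cy5, +1))
        adj.setdefault(cy5, []).append((cy3, -1))
    if ci not in adj:
        return False
    depth: dict[str, int] = {}
    unbalanced = False
    for start in adj:  # sweep every component: gamma is global
        if start in depth:
            continue
        depth[start] = 0
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nbr, step in adj[node]:
                d = depth[node] + step
                if nbr not in depth:
                    depth[nbr] = d
                    queue.append(nbr)
                elif depth[nbr] != d:
                    unbalanced = True  # cycle with nonzero orientation sum
    # reachability of uvi from ci (undirected)
    comp = {ci}
    queue = deque([ci])
    while queue:
        node = queue.popleft()
        for nbr, _ in adj[node]:
            if nbr not in comp:
                comp.add(nbr)
                queue.append(nbr)
    if uvi not in comp:
        return False
    return unbalanced or depth[uvi] == depth[ci]


def pearson_oracle(x, y) -> float:
    """Pearson correlation straight from the definition (population SDs)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx**0.5 * vy**0.5)


def connected_components_oracle(slides: list[tuple[str, str]]) -> list[set[str]]:
    """Undirected connected components of the sample graph, via BFS."""
    adj: dict[str, set[str]] = {}
    for a, b in slides:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nbr in adj[node]:
                if nbr not in comp:
                    comp.add(nbr)
                    queue.append(nbr)
        seen |= comp
        comps.append(comp)
    return comps
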