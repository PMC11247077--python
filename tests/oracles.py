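"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the literal formula/case definitions and
deliberately shares no code with the package: naive loops, explicit DFS,
explicit case analysis.
"""

from __future__ import annotations

import math


def brute_force_tfidf(doc_bigram_streams: list[list[tuple[str, str]]]) -> dict:
    """Literal tf, idf, tf-idf for every bigram of a tiny corpus.

    ``doc_bigram_streams`` is the per-document list of bigram occurrences.
    Returns {bigram: {"df": int, "idf": float, "tf": [..], "tfidf": [..]}}.
    """
    n = len(doc_bigram_streams)
    vocabulary = sorted({b for stream in doc_bigram_streams for b in stream})
    out = {}
    for bigram in vocabulary:
        df = 0
        for stream in doc_bigram_streams:
            if bigram in stream:
                df += 1
        idf = math.log(n / (1 + df))
        tf = []
        for stream in doc_bigram_streams:
            count = 0
            for occurrence in stream:
                if occurrence == bigram:
                    count += 1
            tf.append(count / len(stream) if stream else 0.0)
        out[bigram] = {"df": df, "idf": idf, "tf": tf,
                       "tfidf": [v * idf for v in tf]}
    return out


def brute_force_components(nodes: set, edges: set) -> list[set]:
    """Connected components by explicit DFS over an adjacency map."""
    adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    unvisited = set(nodes)
    components = []
    while unvisited:
        start = unvisited.pop()
        stack = [start]
        component = {start}
        while stack:
            for neighbour in adjacency[stack.pop()]:
                if neighbour in unvisited:
                    unvisited.discard(neighbour)
                    component.add(neighbour)
                    stack.append(neighbour)
        components.append(component)
    return components


def brute_force_lcc(nodes: set, edges: set) -> set:
    """Largest component; ties broken toward the smallest minimum node."""
    components = brute_force_components(nodes, edges)
    return sorted(components, key=lambda c: (-len(c), min(c)))[0]


def literal_decision(point_a: float, range_a: tuple[float, float],
                     point_b: float, range_b: tuple[float, float],
                     tie_label: str = "A") -> str:
    """Literal case analysis of the multi-mode rule for classes 'A' and 'B'.

    Range membership first; inside both -> nearer range center; inside
    neither -> smaller distance = min(|p - start|, |p - end|); exact ties ->
    ``tie_label``.
    """
    lo_a, hi_a = range_a
    lo_b, hi_b = range_b
    in_a = lo_a <= point_a <= hi_a
    in_b = lo_b <= point_b <= hi_b
    if in_a and not in_b:
        return "A"
    if in_b and not in_a:
        return "B"
    if in_a and in_b:
        gap_a = abs(point_a - (lo_a + hi_a) / 2)
        gap_b = abs(point_b - (lo_b + hi_b) / 2)
        if gap_a == gap_b:
            return tie_label
        return "A" if gap_a < gap_b else "B"
    dist_a = min(abs(point_a - lo_a), abs(point_a - hi_a))
    dist_b = min(abs(point_b - lo_b), abs(point_b - hi_b))
    if dist_a == dist_b:
        return tie_label
    return "A" if dist_a < dist_b else "B"
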