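"""Shared fixtures and independent oracles.

The oracles here deliberately take different computational routes from the
package: pattern matching is re-done with Python's regex engine over all
substrings, and NJ correctness is judged against trees whose distances are
generated additively from known random topologies.
"""

from __future__ import annotations

import heapq
import re

import numpy as np
import pytest

from mybslim import synthetic_data as sd
from mybslim.slim_patterns import SlimPattern


# --- brute-force pattern-match oracle (regex over all substrings) ----------

def _element_regex(e) -> str:
    if e.is_wildcard:
        core = "."
    elif len(e.residue_class) == 1:
        core = re.escape(next(iter(e.residue_class)))
    else:
        core = "[" + "".join(sorted(e.residue_class)) + "]"
    if (e.min_repeat, e.max_repeat) == (1, 1):
        return core
    return f"{core}{{{e.min_repeat},{e.max_repeat}}}"


def compile_oracle(pattern: SlimPattern):
    """Pre-compile regexes; returns (branch_regexes, c_anchored flags)."""
    base = "".join(_element_regex(e) for e in pattern.elements)
    if pattern.alternatives is None:
        return [(re.compile(base), False)]
    out = []
    for br in pattern.alternatives:
        rx = base + "".join(_element_regex(e) for e in br.elements)
        out.append((re.compile(rx), br.c_anchored))
    return out


def oracle_spans(pattern: SlimPattern, peptide: str) -> set[tuple[int, int]]:
    """All (start, end) spans the pattern can occupy, by exhaustive regex."""
    compiled = compile_oracle(pattern)
    n = len(peptide)
    spans = set()
    starts = [0] if pattern.n_anchor else range(n + 1)
    for s in starts:
        for e in range(s + 1, n + 1):
            if pattern.c_anchor and e != n:
                continue
            sub = peptide[s:e]
            for rx, anchored in compiled:
                if anchored and e != n:
                    continue
                if rx.fullmatch(sub):
                    spans.add((s, e))
                    break
    return spans


# --- random additive trees for NJ correctness ------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with uniform(0.05, 1) branch lengths.

    Returns (adjacency dict node -> [(neighbour, length)], leaf names,
    internal hub used as traversal root).
    """
    nodes = {i: [] for i in range(n_taxa)}
    names = {i: f"L{i}" for i in range(n_taxa)}
    free = list(range(n_taxa))
    nxt = n_taxa
    while len(free) > 3:
        i, j = sorted(rng.choice(len(free), 2, replace=False))
        a, b = free[i], free[j]
        u = nxt
        nxt += 1
        la, lb = rng.uniform(0.05, 1.0, 2)
        nodes[u] = [(a, la), (b, lb)]
        nodes[a].append((u, la))
        nodes[b].append((u, lb))
        free = [x for x in free if x not in (a, b)] + [u]
    hub = nxt
    nodes[hub] = []
    for x in free:
        l = float(rng.uniform(0.05, 1.0))
        nodes[hub].append((x, l))
        nodes[x].append((hub, l))
    return nodes, names, hub


def leaf_distance_matrix(nodes, names, n_taxa: int) -> np.ndarray:
    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        h = [(0.0, s)]
        while h:
            d, v = heapq.heappop(h)
            if d > dist.get(v, float("inf")):
                continue
            for w, l in nodes[v]:
                if d + l < dist.get(w, float("inf")):
                    dist[w] = d + l
                    heapq.heappush(h, (d + l, w))
        for t in range(n_taxa):
            D[s, t] = dist[t]
    return (D + D.T) / 2.0  # exact symmetry despite summation-order jitter


def _norm_split(leaves: set[str], taxa: list[str]) -> frozenset[str]:
    fs = frozenset(leaves)
    comp = frozenset(taxa) - fs
    return min(fs, comp, key=lambda x: (len(x), sorted(x)))


def newick_splits(nwk: str, taxa: list[str]) -> dict[frozenset, float]:
    """Bipartition -> total branch length map from a Newick string."""
    s = nwk.strip().rstrip(";")
    splits: dict[frozenset, float] = {}
    pos = 0

    def parse() -> set[str]:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            leaves: set[str] = set()
            while True:
                leaves |= parse()
                if s[pos] == ",":
                    pos += 1
                    continue
                pos += 1  # ')'
                break
            _maybe_length(leaves)
            return leaves
        m = re.match(r"[^:,()]+", s[pos:]).group(0)
        pos += len(m)
        leaves = {m}
        _maybe_length(leaves)
        return leaves

    def _maybe_length(leaves: set[str]) -> None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[0-9.eE+\-]+", s[pos:]).group(0)
            pos += len(m)
            key = _norm_split(leaves, taxa)
            splits[key] = splits.get(key, 0.0) + float(m)

    parse()
    return splits


def tree_splits(nodes, names, n_taxa: int, root) -> tuple[dict, list[str]]:
    """Bipartition -> length map of the generating tree."""
    taxa = [names[i] for i in range(n_taxa)]
    splits: dict[frozenset, float] = {}

    def leaves_under(v, parent) -> set[str]:
        out: set[str] = set()
        for w, _ in nodes[v]:
            if w != parent:
                out |= leaves_under(w, v)
        return out or ({names[v]} if v < n_taxa else out)

    def walk(v, parent) -> None:
        for w, l in nodes[v]:
            if w == parent:
                continue
            key = _norm_split(leaves_under(w, v), taxa)
            splits[key] = splits.get(key, 0.0) + l
            walk(w, v)

    walk(root, None)
    return splits, taxa


# --- fixtures --------------------------------------------------------------

@pytest.fixture(scope="session")
def default_family() -> sd.SimulatedFamily:
    return sd.simulate_family(sd.FamilySpec(seed=1))


@pytest.fixture(scope="session")
def arch_panel():
    return sd.simulate_architecture_panel(40, seed=11)
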