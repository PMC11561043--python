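"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own code paths (and RDKit's MCS
machinery) so they can serve as ground truth on small inputs.
"""

from __future__ import annotations



def brute_force_mcs_atoms(
    elements_a: list[str],
    bonds_a: list[tuple[int, int]],
    elements_b: list[str],
    bonds_b: list[tuple[int, int]],
) -> int:
    """Size of the largest connected common subgraph under element labels.

    Exhaustive DFS over partial atom mappings: a mapping grows only by
    adding an atom pair joined to an already-mapped pair by an edge
    present in *both* molecules, which guarantees the common subgraph is
    connected by construction. Bond order is ignored (edges are
    untyped). Exponential — intended for molecules of ~8 heavy atoms.
    """
    adj_a: dict[int, set[int]] = {i: set() for i in range(len(elements_a))}
    for u, v in bonds_a:
        adj_a[u].add(v)
        adj_a[v].add(u)
    adj_b: dict[int, set[int]] = {i: set() for i in range(len(elements_b))}
    for u, v in bonds_b:
        adj_b[u].add(v)
        adj_b[v].add(u)

    best = 0
    seen: set[frozenset[tuple[int, int]]] = set()

    def extend(mapping: dict[int, int]) -> None:
        nonlocal best
        key = frozenset(mapping.items())
        if key in seen:
            return
        seen.add(key)
        best = max(best, len(mapping))
        for a, b in mapping.items():
            for a2 in adj_a[a]:
                if a2 in mapping:
                    continue
                for b2 in adj_b[b]:
                    if b2 in mapping.values():
                        continue
                    if elements_a[a2] == elements_b[b2]:
                        mapping[a2] = b2
                        extend(mapping)
                        del mapping[a2]

    for a in range(len(elements_a)):
        for b in range(len(elements_b)):
            if elements_a[a] == elements_b[b]:
                best = max(best, 1)
                extend({a: b})
    return best


def brute_force_gini(values: list[float]) -> float:
    """Gini by the literal double sum of absolute differences."""
    n = len(values)
    mu = sum(values) / n
    total = sum(abs(x - y) for x in values for y in values)
    return total / (2 * n * n * mu)


def brute_force_family_cognates(interactions, matches) -> dict:
    """(domain_db, family) -> set of cognate ids, by naive double loop."""
    out: dict[tuple[str, str], set[str]] = {}
    for it in interactions:
        if it.mode == "minor":
            continue
        for m in matches:
            if m.bound_id == it.ligand_instance:
                out.setdefault(
                    (it.domain_db, it.domain_family), set()
                ).add(m.cognate_id)
    return out


def brute_force_percentile(scores: list[float], q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    s = sorted(scores)
    if len(s) == 1:
        return s[0]
    pos = q / 100 * (len(s) - 1)
    lo = int(pos)
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac
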