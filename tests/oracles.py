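"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the ORF oracle
translates every frame with Biopython and splits on stop symbols; the Dollo
oracle enumerates loss-branch subsets; the paralogon oracle builds the
region graph by naive pairwise set intersection and finds components by DFS.
"""

from __future__ import annotations

import itertools
import random

from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# ORF enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_orfs(sequence: str, min_length_codons: int):
    """All maximal stop-free codon runs in six frames, via Biopython
    translation of each frame and splitting on '*'."""
    results = set()
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", str(Seq(sequence).reverse_complement()))):
        for frame in range(3):
            trimmed = seq[frame : frame + 3 * ((n - frame) // 3)]
            if not trimmed:
                continue
            peptide = str(Seq(trimmed).translate())
            # walk the translation, splitting on stops
            run_start = 0
            for i, aa in enumerate(peptide + "*"):
                if aa == "*":
                    run_len = i - run_start
                    if run_len >= min_length_codons:
                        lo = frame + 3 * run_start  # 0-based in scanned seq
                        hi = frame + 3 * i
                        if strand == "+":
                            results.add((lo + 1, hi, "+", frame))
                        else:
                            results.add((n - hi + 1, n - lo, "-", frame))
                    run_start = i + 1
    return results


# ---------------------------------------------------------------------------
# Dollo oracle
# ---------------------------------------------------------------------------

def random_binary_newick(n_leaves: int, rng: random.Random) -> str:
    """A random rooted binary topology with labeled internal nodes."""
    leaves = [f"sp{i}" for i in range(n_leaves)]
    rng.shuffle(leaves)
    counter = itertools.count()

    def build(items):
        if len(items) == 1:
            return items[0]
        cut = rng.randint(1, len(items) - 1)
        left = build(items[:cut])
        right = build(items[cut:])
        return f"({left},{right})n{next(counter)}"

    return build(leaves) + ";"


def exhaustive_min_losses(tree, origin: str, present: set[str], absent: set[str]):
    """Minimum number of losses explaining the leaf states under a single
    origin, by exhaustive search over loss-branch subsets.

    Only branches whose subtree contains no present leaf are candidate loss
    branches (a loss above a present leaf contradicts the data outright), so
    enumeration over candidate subsets is exhaustive over valid scenarios.
    Returns (min_count, one_minimal_set) or None if no valid scenario exists
    or the search space is too large.
    """
    origin_node = tree.node(origin)
    branches = [
        tree.label(nd)
        for nd in origin_node.preorder_iter()
        if tree.label(nd) != origin
    ]
    candidates = [
        b for b in branches if not (set(tree.leaves_under(b)) & present)
    ]
    if len(candidates) > 16:
        return None

    def path_branches(leaf):
        out = []
        label = leaf
        while label != origin:
            out.append(label)
            label = tree.parent(label)
        return out

    leaf_paths = {leaf: set(path_branches(leaf)) for leaf in present | absent}
    best = None
    for r in range(len(candidates) + 1):
        if best is not None and r > best[0]:
            break
        for combo in itertools.combinations(candidates, r):
            chosen = set(combo)
            ok = all(not (leaf_paths[leaf] & chosen) for leaf in present) and all(
                leaf_paths[leaf] & chosen for leaf in absent
            )
            if ok:
                best = (r, chosen)
                break
        if best is not None:
            break
    return best


# ---------------------------------------------------------------------------
# Paralogon oracle (naive graph construction + DFS components)
# ---------------------------------------------------------------------------

def brute_force_paralogon_components(regions, tau):
    """regions: list of frozensets of family ids. Returns the set of
    components (as frozensets of region indices) of size >= 2."""
    n = len(regions)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if len(regions[i] & regions[j]) >= tau:
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    components = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        if len(comp) >= 2:
            components.add(frozenset(comp))
    return components
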