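"""Independent oracles, kept deliberately naive and separate from the
implementations they check."""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_local_score(
    a: str, b: str, matrix=None, gap_open: float = 11, gap_extend: float = 1
) -> float:
    """Quadratic three-matrix affine-gap local alignment DP (Gotoh).

    The first residue of a gap costs ``gap_open``; each further residue
    ``gap_extend``.
    """
    matrix = matrix if matrix is not None else BLOSUM62
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def scan_trace(outcomes: Sequence[bool], stop_n: int) -> Tuple[List[int], int]:
    """Literal simulation of the ranked validation scan.

    ``outcomes[i]`` is the validation result of the hit at rank i+1.  Returns
    (accepted ranks, number of hits scanned).
    """
    accepted = []
    failures = 0
    scanned = 0
    for i, ok in enumerate(outcomes, start=1):
        scanned = i
        if ok:
            accepted.append(i)
            failures = 0
        else:
            failures += 1
            if failures >= stop_n:
                break
    return accepted, scanned


def informative_invariant_tally(rows: Sequence[str]) -> Tuple[int, int]:
    """Per-column brute-force tally of informative and invariant sites."""
    length = len(rows[0])
    informative = 0
    invariant = 0
    for col in range(length):
        counts: Dict[str, int] = {}
        for row in rows:
            ch = row[col]
            if ch in "-.":
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) == 1:
            invariant += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return informative, invariant


# ---------------------------------------------------------------------------
# Tree oracles (operate on plain parent/child dicts)


class SimpleTree:
    """Minimal rooted tree for enumeration oracles: node -> children."""

    def __init__(self, children: Dict[str, List[str]], root: str):
        self.children = children
        self.root = root

    def nodes(self) -> List[str]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children.get(n, []))
        return out

    def leaves_under(self, node: str) -> Set[str]:
        kids = self.children.get(node, [])
        if not kids:
            return {node}
        out: Set[str] = set()
        for k in kids:
            out |= self.leaves_under(k)
        return out

    def edges(self) -> List[str]:
        """Edges named by child node (all but the root)."""
        return [n for n in self.nodes() if n != self.root]


def replay_single_gain(
    tree: SimpleTree, gain: str, losses: Sequence[str]
) -> Set[str]:
    present = set(tree.leaves_under(gain))
    for l in losses:
        present -= tree.leaves_under(l)
    return present


def brute_force_min_losses(
    tree: SimpleTree, present: Set[str]
) -> Tuple[int, List[Tuple[str, Tuple[str, ...]]]]:
    """Exhaustive search over single-gain scenarios: every gain node whose
    subtree covers the present set, with loss-edge subsets of growing size,
    until scenarios replaying to the presence pattern are found.  Returns the
    minimal loss count and all minimal (gain, losses) scenarios."""
    if not present:
        raise ValueError("oracle needs at least one present leaf")
    gains = [n for n in tree.nodes() if present <= tree.leaves_under(n)]
    edges = tree.edges()
    best: Optional[int] = None
    scenarios: List[Tuple[str, Tuple[str, ...]]] = []
    for k in range(len(edges) + 1):
        if best is not None:
            break
        for gain in gains:
            below = [e for e in edges if tree.leaves_under(e) <= tree.leaves_under(gain)]
            for losses in combinations(below, k):
                if replay_single_gain(tree, gain, losses) == present:
                    best = k
                    scenarios.append((gain, losses))
    assert best is not None
    return best, scenarios


def edges_inside_clades(
    edge_sides: Dict[str, Set[str]],
    all_leaves: Set[str],
    clades: Sequence[Set[str]],
) -> Set[str]:
    """Brute-force containment test: an edge lies strictly inside a clade iff
    either of its bipartition sides is a proper subset of the clade."""
    inside = set()
    for name, side in edge_sides.items():
        other = all_leaves - side
        for clade in clades:
            if side < clade or other < clade:
                inside.add(name)
                break
    return inside
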