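"""Independent reference implementations used only to cross-check results.

Each oracle re-derives the expected answer by brute force (exhaustive
enumeration, naive dynamic programming, direct rule evaluation) without
sharing code with the package.
"""

from __future__ import annotations

import itertools

from egfrc.scan import HYDROPATHY

# ---------------------------------------------------------------------------
# EGF motif: leftmost match with lexicographically smallest gap tuple
# ---------------------------------------------------------------------------

def _match_from(seq: str, start: int, spacings) -> int | None:
    """Backtracking search trying smaller gaps first; returns match end."""

    def rec(pos: int, gap_idx: int) -> int | None:
        if gap_idx == len(spacings):
            return pos + 1
        lo, hi = spacings[gap_idx]
        for gap in range(lo, hi + 1):
            nxt = pos + 1 + gap
            if nxt < len(seq) and seq[nxt] == "C":
                result = rec(nxt, gap_idx + 1)
                if result is not None:
                    return result
        return None

    if start >= len(seq) or seq[start] != "C":
        return None
    return rec(start, 0)


def egf_sites(seq: str, spacings=((3, 14), (3, 7), (1, 16), (1, 2), (4, 15))):
    """All greedy left-to-right, shortest-first six-cysteine matches."""
    sites = []
    pos = 0
    while pos < len(seq):
        found = None
        for start in range(pos, len(seq)):
            end = _match_from(seq, start, spacings)
            if end is not None:
                found = (start, end)
                break
        if found is None:
            break
        sites.append(found)
        pos = found[1]
    return sites


# ---------------------------------------------------------------------------
# Cysteine clusters: exhaustive window scan + union over shared windows
# ---------------------------------------------------------------------------

def cys_clusters(seq: str, masked_intervals=(), window: int = 60, min_cys: int = 6):
    masked = set()
    for s, e in masked_intervals:
        masked.update(range(s, e))
    cys = [i for i, aa in enumerate(seq) if aa == "C" and i not in masked]
    w = min(window, len(seq))
    window_sets = []
    for s in range(len(seq) - w + 1):
        inside = frozenset(i for i in cys if s <= i < s + w)
        if len(inside) >= min_cys:
            window_sets.append(inside)
    # union-find over cysteines co-occurring in a qualifying window
    parent = {i: i for i in cys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ws in window_sets:
        members = sorted(ws)
        for a, b in zip(members, members[1:]):
            parent[find(b)] = find(a)

    in_any = set().union(*window_sets) if window_sets else set()
    groups: dict = {}
    for i in sorted(in_any):
        groups.setdefault(find(i), []).append(i)
    return sorted((min(g), max(g) + 1) for g in groups.values())


# ---------------------------------------------------------------------------
# Signal peptide: direct rule evaluation
# ---------------------------------------------------------------------------

def has_signal_peptide(
    seq: str,
    search_len: int = 35,
    min_stretch: int = 8,
    threshold: float = 2.0,
    max_start: int = 10,
) -> bool:
    head = seq[:search_len]
    for start in range(0, max_start + 1):
        for end in range(start + min_stretch, len(head) + 1):
            window = head[start:end]
            if sum(HYDROPATHY[a] for a in window) / len(window) >= threshold:
                return True
    return False


# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps (Gotoh), quadratic reference
# ---------------------------------------------------------------------------

_BLOSUM62_TEXT = None


def _blosum62():
    global _BLOSUM62_TEXT
    if _BLOSUM62_TEXT is None:
        import biotite.sequence.align as balign

        m = balign.SubstitutionMatrix.std_protein_matrix()
        alph = m.get_alphabet1()
        S = m.score_matrix()
        table = {}
        letters = [str(sym) for sym in alph]
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                table[(a, b)] = int(S[i, j])
        _BLOSUM62_TEXT = table
    return _BLOSUM62_TEXT


def smith_waterman(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score, affine gap penalties, O(len(a)*len(b))."""
    sub = _blosum62()
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


# ---------------------------------------------------------------------------
# Parsimony brute force
# ---------------------------------------------------------------------------

def dollo_min_losses(tree, tip_states: dict) -> int:
    """Minimum 1->0 transitions over all single-gain assignments.

    Enumerates every state assignment to internal nodes, keeps those with tip
    fidelity, exactly one 0->1 transition overall (counting a present root as
    the gain), and returns the minimal loss count.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = {n: tip_states[n.taxon.label] for n in tree.leaf_node_iter()}
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(internals, combo))
        states.update(leaves)
        gains = 0
        losses = 0
        root = tree.seed_node
        if states[root] == 1:
            gains += 1
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            p, c = states[node.parent_node], states[node]
            if p == 0 and c == 1:
                gains += 1
            elif p == 1 and c == 0:
                losses += 1
        if gains != 1:
            continue
        if best is None or losses < best:
            best = losses
    return best


def sankoff_min_cost(tree, tip_counts: dict, max_count: int) -> int:
    """Exhaustive minimum of the linear copy-number cost over all assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = {n: tip_counts[n.taxon.label] for n in tree.leaf_node_iter()}
    best = None
    for combo in itertools.product(range(max_count + 1), repeat=len(internals)):
        states = dict(zip(internals, combo))
        states.update(leaves)
        cost = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            cost += abs(states[node] - states[node.parent_node])
        if best is None or cost < best:
            best = cost
    return best
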