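"""Simulator of coevolving two-protein ortholog alignments.

Sequences for both proteins evolve down a shared random species tree
(the shared phylogeny is what a species-shuffle destroys).  Every column
substitutes independently — except planted inter-protein column pairs,
whose B-side co-substitutes through a pair-specific state bijection with
probability ``coupling_strength`` whenever the A-side changes.  The
planted pairs are returned as ground truth for recovery benchmarks.
"""

from __future__ import annotations

import numpy as np

from .msa import AA_ALPHABET, OrthologSet

__all__ = ["generate_coevolving_msa"]

_N_AA = 20  # non-gap states, codes 1..20


def _yule_tree(n: int, rng: np.random.Generator):
    """Random ultrametric Yule (pure-birth) genealogy over ``n`` leaves.

    Speciations occur at rate 1 per lineage; all leaves extend to the
    present.  One ortholog per species follows a species tree, and a
    birth process spreads the splits through time — unlike a neutral
    coalescent, whose burst of recent mergers would leave most sequences
    nearly identical to many others.

    Returns ``(children, branch_len, root)`` where ``children[v]`` is the
    pair of child node ids of internal node ``v`` and ``branch_len[v]``
    is the branch above node ``v``.
    """
    # forward simulation with provisional ids; relabel afterwards so that
    # leaves are 0..n-1 and internal nodes n..2n-2 (root last)
    prov_children: dict[int, tuple[int, int]] = {}
    birth = {0: 0.0}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        split = active.pop(int(rng.integers(k)))
        c1, c2 = next_id, next_id + 1
        next_id += 2
        prov_children[split] = (c1, c2)
        birth[c1] = birth[c2] = t
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / n)

    leaf_ids = sorted(active)
    internal_ids = sorted(prov_children)  # includes the provisional root 0
    # leaf labels are assigned at random: provisional ids correlate with
    # birth order, and birth order must not leak into species identity
    # (two independent trees would otherwise share clade structure by id)
    leaf_labels = rng.permutation(n)
    relabel = {old: int(leaf_labels[i]) for i, old in enumerate(leaf_ids)}
    relabel.update({old: n + i for i, old in enumerate(internal_ids)})
    root = relabel[0]
    children = {
        relabel[v]: (relabel[c1], relabel[c2]) for v, (c1, c2) in prov_children.items()
    }
    death = {relabel[v]: t_end for v in leaf_ids}
    death.update({relabel[v]: birth[prov_children[v][0]] for v in internal_ids})
    branch_len = {
        relabel[v]: death[relabel[v]] - bt for v, bt in birth.items() if relabel[v] != root
    }
    return children, branch_len, root


def _evolve(
    rng: np.random.Generator,
    tree,
    n_leaves: int,
    root_seq: np.ndarray,
    mutation_rate: float,
    pair_cols: list[tuple[int, int]],
    sigma: list[np.ndarray],
    coupling_strength: float,
) -> dict[int, np.ndarray]:
    """Evolve a root sequence down a genealogy; returns leaf sequences."""
    children, branch_len, root = tree
    length = root_seq.size
    leaf_seqs: dict[int, np.ndarray] = {}
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node < n_leaves:
            leaf_seqs[node] = seq
            continue
        for child in children[node]:
            p_mut = 1.0 - np.exp(-mutation_rate * branch_len[child])
            child_seq = seq.copy()
            mutate = rng.random(length) < p_mut
            n_mut = int(mutate.sum())
            if n_mut:
                child_seq[mutate] = rng.integers(1, _N_AA + 1, size=n_mut)
            for (ci, cj), sg in zip(pair_cols, sigma):
                if mutate[ci] and rng.random() < coupling_strength:
                    child_seq[cj] = sg[child_seq[ci] - 1]
            stack.append((child, child_seq))
    return leaf_seqs


def generate_coevolving_msa(
    len_a: int,
    len_b: int,
    n_species: int,
    planted_pairs: int | list[tuple[int, int]] = 5,
    coupling_strength: float = 0.9,
    mutation_rate: float = 0.2,
    seed: int = 0,
    *,
    gap_fraction: float = 0.0,
    min_pair_separation: int = 8,
    shared_tree: bool = True,
) -> tuple[OrthologSet, OrthologSet, dict]:
    """Simulate two coevolving ortholog sets with planted contacts.

    ``planted_pairs`` is either an explicit list of (column-in-A,
    column-in-B) pairs or a count of pairs to place at random with at
    least ``min_pair_separation`` columns between any two (so their
    signals stay distinct after convolution).  ``mutation_rate`` is the
    expected number of substitution events per column per unit tree time;
    the default (0.2 on a Yule tree of rate 1) yields ~20% mean pairwise
    identity — deeply diverged alignments, the regime in which coupling
    analysis is ordinarily applied.

    With ``shared_tree=False`` the two proteins evolve on independent
    genealogies — a fully signal-free null: even uncoupled proteins on a
    shared tree carry joint phylogenetic signal, which a species-shuffle
    test legitimately detects.  Independent trees require no planted
    pairs (or zero coupling strength).

    Returns ``(set_a, set_b, truth)``; ``truth["planted_pairs"]`` lists
    the planted (A-column, B-column) pairs.
    """
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must lie in [0, 1]")
    rng = np.random.default_rng([seed, 505])

    if isinstance(planted_pairs, int):
        n_pairs = planted_pairs
        pairs: list[tuple[int, int]] = []
        for _ in range(10000):
            if len(pairs) == n_pairs:
                break
            cand = (int(rng.integers(0, len_a)), int(rng.integers(0, len_b)))
            if all(
                max(abs(cand[0] - p[0]), abs(cand[1] - p[1])) >= min_pair_separation
                for p in pairs
            ):
                pairs.append(cand)
        if len(pairs) < n_pairs:
            raise ValueError("could not place the requested pairs with that separation")
    else:
        pairs = [(int(i), int(j)) for i, j in planted_pairs]
    for i, j in pairs:
        if not (0 <= i < len_a and 0 <= j < len_b):
            raise ValueError(f"planted pair ({i}, {j}) outside the alignments")

    length = len_a + len_b
    pair_cols = [(i, len_a + j) for i, j in pairs]
    # pair-specific bijections over the 20 amino-acid states
    sigma = [rng.permutation(_N_AA) + 1 for _ in pairs]

    if shared_tree:
        tree = _yule_tree(n_species, rng)
        root_seq = rng.integers(1, _N_AA + 1, size=length).astype(np.int16)
        for (ci, cj), sg in zip(pair_cols, sigma):
            root_seq[cj] = sg[root_seq[ci] - 1]
        leaf_seqs = _evolve(rng, tree, n_species, root_seq, mutation_rate,
                            pair_cols, sigma, coupling_strength)
    else:
        if pairs and coupling_strength > 0:
            raise ValueError("independent trees cannot carry planted couplings")
        root_a = rng.integers(1, _N_AA + 1, size=len_a).astype(np.int16)
        root_b = rng.integers(1, _N_AA + 1, size=len_b).astype(np.int16)
        leaves_a = _evolve(rng, _yule_tree(n_species, rng), n_species, root_a,
                           mutation_rate, [], [], 0.0)
        leaves_b = _evolve(rng, _yule_tree(n_species, rng), n_species, root_b,
                           mutation_rate, [], [], 0.0)
        leaf_seqs = {
            i: np.concatenate([leaves_a[i], leaves_b[i]]) for i in range(n_species)
        }

    if gap_fraction > 0:
        for i in range(n_species):
            gaps = rng.random(length) < gap_fraction
            leaf_seqs[i][gaps] = 0

    names = [f"SP{i:04d}" for i in range(n_species)]
    to_str = np.array(list(AA_ALPHABET))
    seq_a = {names[i]: "".join(to_str[leaf_seqs[i][:len_a]]) for i in range(n_species)}
    seq_b = {names[i]: "".join(to_str[leaf_seqs[i][len_a:]]) for i in range(n_species)}
    truth = {
        "planted_pairs": pairs,
        "coupling_strength": coupling_strength,
        "mutation_rate": mutation_rate,
        "seed": seed,
    }
    return OrthologSet(seq_a), OrthologSet(seq_b), truth
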