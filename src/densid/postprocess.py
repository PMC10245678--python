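"""Model post-processing: residue graphs, sequence assignment, chain repair.

After profile search has identified which database sequence each built
chain corresponds to, the model is cleaned up: residues aligned to match
states are mutated to the target sequence, chains assigned to the same
target are connected when their matched ranges and termini are compatible,
chains shorter than four residues are pruned, and the predicted backbone
RMSD is mapped to a [0, 1] confidence stored in the B-factor column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AA_ALPHABET, AtomicModel, Chain, ResidueProfile
from .search import SearchHit

# Score 1 at 0.5 A predicted RMSD, 0 at 1.2 A, linear in between.
RMSD_HI = 1.2
RMSD_LO = 0.5

# Cα-Cα virtual bond length; distance allowance per gapped residue when
# deciding whether two chain fragments can be connected.
DMAX_PER_GAP = 3.8

DEFAULT_KNN = 20
MIN_CHAIN_LEN = 4


@dataclass
class ResidueGraph:
    """k-nearest-neighbour graph over residue anchor atoms (CA or P).

    neighbors[i] lists the indices of node i's neighbours sorted by
    ascending Euclidean distance; nodes[i] is (chain_index, residue_index).
    """

    nodes: list[tuple[int, int]]
    neighbors: list[np.ndarray]
    coords: np.ndarray


@dataclass
class SequenceAssignment:
    """Per-chain target id and per-residue matched positions (1-based)."""

    targets: dict[str, str] = field(default_factory=dict)
    # chain_id -> array of matched target positions, 0 where unmatched
    positions: dict[str, np.ndarray] = field(default_factory=dict)


def build_residue_graph(model: AtomicModel, k: int = DEFAULT_KNN) -> ResidueGraph:
    """Connect each residue to its k nearest neighbours by anchor distance.

    Residues lacking their anchor atom are excluded.  With fewer than k + 1
    anchored residues every node gets n - 1 neighbours.  Ties are broken by
    lower residue index.
    """
    nodes: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []
    for ci, chain in enumerate(model.chains):
        for ri, res in enumerate(chain.residues):
            anchor = res.anchor
            if anchor is not None:
                nodes.append((ci, ri))
                coords.append(anchor)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 residues with anchor atoms")
    xyz = np.asarray(coords)
    kk = min(k, n - 1)
    tree = cKDTree(xyz)
    # query k+1 including self; distances sorted ascending by cKDTree
    dist, idx = tree.query(xyz, k=kk + 1)
    neighbors: list[np.ndarray] = []
    for i in range(n):
        order = [(float(d), int(j)) for d, j in zip(dist[i], idx[i]) if j != i]
        order.sort(key=lambda t: (t[0], t[1]))  # tie-break by lower index
        neighbors.append(np.array([j for _, j in order[:kk]], dtype=int))
    return ResidueGraph(nodes=nodes, neighbors=neighbors, coords=xyz)


def assign_and_mutate(
    model: AtomicModel,
    hits: dict[str, SearchHit],
    db,
    unmatched_as_unk: bool = False,
    profiles: dict[str, ResidueProfile] | None = None,
) -> tuple[AtomicModel, SequenceAssignment]:
    """Mutate matched residues to the identified target sequence.

    Residues whose profile node appears as an M state in the chain's
    Viterbi alignment take the target letter at the aligned position and
    record it as seq_pos; other residues keep their argmax-probability
    identity (or become 'X' with unmatched_as_unk).  Chains without a hit
    are untouched.
    """
    out = model.copy()
    assignment = SequenceAssignment()
    for chain in out.chains:
        hit = hits.get(chain.chain_id)
        positions = np.zeros(len(chain), dtype=int)
        if hit is not None:
            target_seq = db[hit.target_id].sequence
            assignment.targets[chain.chain_id] = hit.target_id
            matched = {node: pos for node, pos, s in hit.alignment if s == "M"}
            for node, pos in matched.items():
                if node > len(chain):
                    raise ValueError(
                        f"alignment node {node} beyond chain {chain.chain_id} "
                        f"length {len(chain)}"
                    )
                res = chain.residues[node - 1]
                res.identity = target_seq[pos - 1]
                res.seq_pos = pos
                positions[node - 1] = pos
        rp = profiles.get(chain.chain_id) if profiles else None
        for ri, res in enumerate(chain.residues):
            if positions[ri] == 0:
                res.seq_pos = None
                if unmatched_as_unk:
                    res.identity = "X"
                elif rp is not None:
                    res.identity = AA_ALPHABET[int(np.argmax(rp.probs[ri]))]
        assignment.positions[chain.chain_id] = positions
    return out, assignment


def _matched_range(positions: np.ndarray) -> tuple[int, int] | None:
    nz = positions[positions > 0]
    if nz.size == 0:
        return None
    return int(nz.min()), int(nz.max())


def connect_chains(
    model: AtomicModel,
    assignment: SequenceAssignment,
    dmax_per_gap: float = DMAX_PER_GAP,
) -> AtomicModel:
    """Greedily merge chain fragments assigned to the same target.

    Two chains merge when they share a target, their matched ranges are
    disjoint and in order with sequence gap g >= 0, and the distance from
    the upstream chain's last anchor to the downstream chain's first anchor
    is at most dmax_per_gap * (g + 1).  Pairs are merged by ascending gap,
    then ascending distance, until no pair qualifies.
    """
    out = model.copy()
    chains = {ch.chain_id: ch for ch in out.chains}
    order = [ch.chain_id for ch in out.chains]
    targets = dict(assignment.targets)
    positions = {cid: np.array(p) for cid, p in assignment.positions.items()}

    def candidates():
        cands = []
        ids = [cid for cid in order if cid in chains]
        for a in ids:
            for b in ids:
                if a == b or targets.get(a) is None or targets.get(a) != targets.get(b):
                    continue
                ra = _matched_range(positions[a])
                rb = _matched_range(positions[b])
                if ra is None or rb is None:
                    continue
                if ra[1] >= rb[0]:
                    continue  # not disjoint-and-in-order with a upstream
                gap = rb[0] - ra[1] - 1
                up_anchor = next(
                    (r.anchor for r in reversed(chains[a].residues) if r.anchor is not None),
                    None,
                )
                down_anchor = next(
                    (r.anchor for r in chains[b].residues if r.anchor is not None), None
                )
                if up_anchor is None or down_anchor is None:
                    continue
                d = float(np.linalg.norm(up_anchor - down_anchor))
                if d <= dmax_per_gap * (gap + 1):
                    cands.append((gap, d, a, b))
        cands.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
        return cands

    while True:
        cands = candidates()
        if not cands:
            break
        _, _, a, b = cands[0]
        chains[a].residues.extend(chains[b].residues)
        positions[a] = np.concatenate([positions[a], positions[b]])
        del chains[b]
        del positions[b]
        targets.pop(b, None)
    out.chains = [chains[cid] for cid in order if cid in chains]
    assignment.positions.update({cid: positions[cid] for cid in positions})
    for cid in list(assignment.targets):
        if cid not in chains:
            del assignment.targets[cid]
    return out


def prune_chains(model: AtomicModel, min_len: int = MIN_CHAIN_LEN) -> AtomicModel:
    """Drop chains with fewer than min_len residues (default 4).

    Run after connect_chains so that connectable short fragments are not
    lost prematurely.
    """
    out = model.copy()
    out.chains = [ch for ch in out.chains if len(ch) >= min_len]
    return out


def rmsd_to_score(rmsd_pred: float | np.ndarray) -> float | np.ndarray:
    """Map a predicted backbone RMSD (A) to a [0, 1] confidence.

    Linear between 1.2 A (score 0) and 0.5 A (score 1), clamped outside
    that range.  This is the value stored in the B-factor column.
    """
    r = np.asarray(rmsd_pred, dtype=float)
    if np.any(r < 0):
        raise ValueError("RMSD must be non-negative")
    score = np.clip((RMSD_HI - r) / (RMSD_HI - RMSD_LO), 0.0, 1.0)
    return float(score) if np.isscalar(rmsd_pred) or score.ndim == 0 else score
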