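"""Profile-HMM search: Forward and Viterbi scoring, E-values, ranking.

The engine scores local (Smith-Waterman-style) profile alignments with
free flanking background emission, mirroring the default search mode of
HMMER-style tools: an alignment may enter the profile at any node and any
sequence position (uniform entry probability 1/L over nodes) and exit from
any match state, with unaligned flanking residues emitted at background so
they cancel against the null model.  All arithmetic is in log space;
probability zero is a -inf sentinel.  Scores are log2-odds ("bits") of the
summed (Forward) or best (Viterbi) path probability against an i.i.d.
background null.

E-values come from a Gumbel (EVD) fit to Forward scores of seeded random
background sequences, in the spirit of HMMER's calibration:
E = |database| * P(score >= s) under the fitted law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .core import AA_INDEX, SequenceDatabase
from .profiles import ProfileHMM

_NEG_INF = -np.inf
_LN2 = np.log(2.0)

# state codes used in alignments
M, I, D = "M", "I", "D"


@dataclass
class SearchHit:
    """One profile-vs-sequence match."""

    target_id: str
    bit_score: float
    e_value: float
    alignment: list[tuple[int, int, str]]  # (node 1-based, target pos 1-based, state)
    query_chain: str = ""

    @property
    def ali_from(self) -> int:
        """First aligned target position (1-based)."""
        pos = [p for _, p, s in self.alignment if s in (M, I)]
        return pos[0] if pos else 0

    @property
    def ali_to(self) -> int:
        pos = [p for _, p, s in self.alignment if s in (M, I)]
        return pos[-1] if pos else 0


@dataclass
class CalibrationCurve:
    """Gumbel law fitted to background Forward scores.

    mu is the location, lam the rate (1 / scale) of the fitted extreme
    value distribution, in bits.
    """

    mu: float
    lam: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel rate must be positive")
        if self.n_samples < 100:
            raise ValueError("calibration needs at least 100 samples")

    def survival(self, bit_score: float) -> float:
        """P(score >= s) under the fitted Gumbel law."""
        return float(gumbel_r.sf(bit_score, loc=self.mu, scale=1.0 / self.lam))


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to indices; X (or other ambiguity) -> -1."""
    if not seq:
        raise ValueError("empty sequence")
    return np.array([AA_INDEX.get(a, -1) for a in seq.upper()], dtype=np.int64)


def _emission_logodds(hmm: ProfileHMM, codes: np.ndarray) -> np.ndarray:
    """n x L match-emission log-odds; ambiguous residues score 0 (background)."""
    with np.errstate(divide="ignore"):
        lem = np.log(hmm.match_emit) - np.log(hmm.background)[None, :]  # L x 20
    out = np.zeros((codes.size, hmm.L))
    known = codes >= 0
    out[known, :] = lem[:, codes[known]].T
    return out


def _log_transitions(hmm: ProfileHMM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(hmm.transitions)


@njit(cache=True)
def _forward_kernel(lodds, ltr, log_entry):  # pragma: no cover - numba
    n, L = lodds.shape
    aM = np.full(L, _NEG_INF)
    aI = np.full(L, _NEG_INF)
    aD = np.full(L, _NEG_INF)
    total = _NEG_INF
    for j in range(n):
        pM = aM.copy()
        pI = aI.copy()
        pD = aD.copy()
        for i in range(L):
            # into M(i) at position j
            acc = log_entry
            if i > 0:
                for v in (pM[i - 1] + ltr[i - 1, 0],
                          pI[i - 1] + ltr[i - 1, 3],
                          pD[i - 1] + ltr[i - 1, 5]):
                    if v > _NEG_INF:
                        if v > acc:
                            acc = v + np.log1p(np.exp(acc - v))
                        else:
                            acc = acc + np.log1p(np.exp(v - acc))
            aM[i] = lodds[j, i] + acc
            # into I(i): stays on node i, consumes one residue at background
            a = pM[i] + ltr[i, 1]
            b = pI[i] + ltr[i, 4]
            if a == _NEG_INF and b == _NEG_INF:
                aI[i] = _NEG_INF
            elif a > b:
                aI[i] = a + np.log1p(np.exp(b - a)) if b > _NEG_INF else a
            else:
                aI[i] = b + np.log1p(np.exp(a - b)) if a > _NEG_INF else b
        # D states consume no residue: propagate along i within this j
        for i in range(L):
            if i == 0:
                aD[i] = _NEG_INF
            else:
                a = aM[i - 1] + ltr[i - 1, 2]
                b = aD[i - 1] + ltr[i - 1, 6]
                if a == _NEG_INF and b == _NEG_INF:
                    aD[i] = _NEG_INF
                elif a > b:
                    aD[i] = a + np.log1p(np.exp(b - a)) if b > _NEG_INF else a
                else:
                    aD[i] = b + np.log1p(np.exp(a - b)) if a > _NEG_INF else b
        for i in range(L):
            v = aM[i]
            if v > _NEG_INF:
                if v > total:
                    total = v + np.log1p(np.exp(total - v)) if total > _NEG_INF else v
                else:
                    total = total + np.log1p(np.exp(v - total))
    return total


@njit(cache=True)
def _viterbi_kernel(lodds, ltr, log_entry):  # pragma: no cover - numba
    n, L = lodds.shape
    aM = np.full((n, L), _NEG_INF)
    aI = np.full((n, L), _NEG_INF)
    aD = np.full((n, L), _NEG_INF)
    # back-pointers: 0=entry, 1=M, 2=D, 3=I (priority order M > D > I on ties)
    bM = np.zeros((n, L), dtype=np.int8)
    bI = np.zeros((n, L), dtype=np.int8)
    bD = np.zeros((n, L), dtype=np.int8)
    for j in range(n):
        for i in range(L):
            best = log_entry
            arg = 0
            if i > 0 and j > 0:
                cands = (aM[j - 1, i - 1] + ltr[i - 1, 0],
                         aD[j - 1, i - 1] + ltr[i - 1, 5],
                         aI[j - 1, i - 1] + ltr[i - 1, 3])
                for k in range(3):
                    if cands[k] > best:
                        best = cands[k]
                        arg = k + 1
            aM[j, i] = lodds[j, i] + best
            bM[j, i] = arg
            if j > 0:
                a = aM[j - 1, i] + ltr[i, 1]
                b = aI[j - 1, i] + ltr[i, 4]
                if a >= b:
                    aI[j, i] = a
                    bI[j, i] = 1
                else:
                    aI[j, i] = b
                    bI[j, i] = 3
        for i in range(1, L):
            a = aM[j, i - 1] + ltr[i - 1, 2]
            b = aD[j, i - 1] + ltr[i - 1, 6]
            if a >= b:
                aD[j, i] = a
                bD[j, i] = 1
            else:
                aD[j, i] = b
                bD[j, i] = 2
    best = _NEG_INF
    bj = 0
    bi = 0
    for j in range(n):
        for i in range(L):
            if aM[j, i] > best:
                best = aM[j, i]
                bj = j
                bi = i
    return best, bj, bi, bM, bI, bD


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Forward bit score of seq under the profile (sum over all local paths)."""
    codes = encode_sequence(seq)
    lodds = _emission_logodds(hmm, codes)
    ltr = _log_transitions(hmm)
    nats = _forward_kernel(lodds, ltr, -np.log(hmm.L))
    return float(nats / _LN2)


def viterbi_align(hmm: ProfileHMM, seq: str) -> tuple[float, list[tuple[int, int, str]]]:
    """Best single path and its bit score.

    The alignment is a list of (node_index, target_position, state) with
    1-based node and target positions; its M entries define the matched
    residues used downstream for mutation.  Ties are broken with state
    priority M > D > I.
    """
    codes = encode_sequence(seq)
    lodds = _emission_logodds(hmm, codes)
    ltr = _log_transitions(hmm)
    nats, j, i, bM, bI, bD = _viterbi_kernel(lodds, ltr, -np.log(hmm.L))
    # traceback from M(j, i)
    path: list[tuple[int, int, str]] = []
    state = 1  # 1=M, 2=D, 3=I
    while True:
        if state == 1:
            path.append((i + 1, j + 1, M))
            prev = bM[j, i]
            if prev == 0:
                break
            if prev == 1:
                j, i, state = j - 1, i - 1, 1
            elif prev == 2:
                j, i, state = j - 1, i - 1, 2
            else:
                j, i, state = j - 1, i - 1, 3
        elif state == 2:
            path.append((i + 1, j + 1, D))
            prev = bD[j, i]
            i, state = i - 1, (1 if prev == 1 else 2)
        else:
            path.append((i + 1, j + 1, I))
            prev = bI[j, i]
            j, state = j - 1, (1 if prev == 1 else 3)
    path.reverse()
    return float(nats / _LN2), path


def enumerate_paths_score(hmm: ProfileHMM, seq: str):
    """Exhaustive oracle: sum and max over all local alignment paths.

    Enumerates every (entry node, entry position, state path) explicitly
    under the same local model as the DP engine.  Exponential in L and
    |seq|; intended for profiles with L <= 3 and short sequences only.
    Returns (forward_bits, viterbi_bits).
    """
    codes = encode_sequence(seq)
    lodds = _emission_logodds(hmm, codes)
    ltr = _log_transitions(hmm)
    L, n = hmm.L, codes.size
    log_entry = -np.log(L)
    totals: list[float] = []

    def extend(i: int, j: int, state: str, logp: float) -> None:
        # state just consumed/occupied node i (0-based) at position j
        if state == M:
            totals.append(logp)  # may exit here
        if state in (M, I):
            nj = j + 1
        else:
            nj = j
        # continue to next states
        if state == M:
            moves = [(i + 1, M, ltr[i, 0]), (i, I, ltr[i, 1]), (i + 1, D, ltr[i, 2])]
        elif state == I:
            moves = [(i + 1, M, ltr[i, 3]), (i, I, ltr[i, 4])]
        else:
            moves = [(i + 1, M, ltr[i, 5]), (i + 1, D, ltr[i, 6])]
        for ni, ns, lt in moves:
            if lt == _NEG_INF or ni >= L and ns in (M, D) and ni > L - 1:
                if ni >= L:
                    continue
            if ni >= L:
                continue
            if ns in (M, I):
                if nj >= n:
                    continue
                em = lodds[nj, ni] if ns == M else 0.0
                extend(ni, nj, ns, logp + lt + em)
            else:
                extend(ni, nj, ns, logp + lt)

    for j0 in range(n):
        for i0 in range(L):
            extend(i0, j0, M, log_entry + lodds[j0, i0])
    arr = np.array(totals)
    fwd = np.logaddexp.reduce(arr) / _LN2
    vit = arr.max() / _LN2
    return float(fwd), float(vit)


def calibrate(
    hmm: ProfileHMM,
    n: int = 1000,
    len_dist=None,
    seed: int = 0,
) -> CalibrationCurve:
    """Fit a Gumbel law to Forward scores of random background sequences.

    len_dist may be an integer (fixed length, default 100) or a callable
    rng -> int.  Deterministic for a given seed.
    """
    if n < 100:
        raise ValueError("calibration needs n >= 100")
    rng = np.random.default_rng(seed)
    if len_dist is None:
        len_dist = 100
    scores = np.empty(n)
    ltr = _log_transitions(hmm)
    with np.errstate(divide="ignore"):
        lem = np.log(hmm.match_emit) - np.log(hmm.background)[None, :]
    log_entry = -np.log(hmm.L)
    for k in range(n):
        length = len_dist(rng) if callable(len_dist) else int(len_dist)
        codes = rng.choice(20, size=length, p=hmm.background)
        lodds = lem[:, codes].T.copy()
        scores[k] = _forward_kernel(lodds, ltr, log_entry) / _LN2
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate (zero-variance) score distribution")
    loc, scale = gumbel_r.fit(scores)
    return CalibrationCurve(mu=float(loc), lam=float(1.0 / scale), n_samples=n, seed=seed)


def search_db(
    hmm: ProfileHMM,
    db: SequenceDatabase,
    cal: CalibrationCurve,
    e_max: float = 10.0,
    query_chain: str | None = None,
) -> list[SearchHit]:
    """Score every database sequence; keep hits with E <= e_max.

    E-value = |db| * P(score >= s) under the calibration Gumbel; hits are
    sorted by ascending E-value (descending bit score on ties).  Viterbi
    alignments are computed for reported hits only.
    """
    if len(db) == 0:
        raise ValueError("empty sequence database")
    hits: list[SearchHit] = []
    ndb = len(db)
    for entry in db.entries:
        bits = forward_score(hmm, entry.sequence)
        e = ndb * cal.survival(bits)
        if e <= e_max:
            _, ali = viterbi_align(hmm, entry.sequence)
            hits.append(
                SearchHit(
                    target_id=entry.id,
                    bit_score=bits,
                    e_value=e,
                    alignment=ali,
                    query_chain=query_chain or hmm.name,
                )
            )
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.target_id))
    return hits


def aggregate_hits(hits_per_chain: dict[str, list[SearchHit]]):
    """Cross-reference best hits across chains (pseudo-symmetric copies).

    Chains are grouped by their best-hit target; targets supported by
    k > 1 chains get a combined score (sum of bit scores) and the spread of
    per-chain E-values, so several individually weak hits to the same
    target reinforce each other.  Returns a pandas DataFrame sorted by
    combined score.
    """
    import pandas as pd

    if not hits_per_chain:
        raise ValueError("need at least one chain")
    groups: dict[str, list[tuple[str, SearchHit]]] = {}
    for chain, hits in hits_per_chain.items():
        if not hits:
            continue
        best = hits[0]
        groups.setdefault(best.target_id, []).append((chain, best))
    rows = []
    for target, members in groups.items():
        evs = [h.e_value for _, h in members]
        rows.append(
            {
                "target_id": target,
                "n_chains": len(members),
                "chains": ",".join(sorted(c for c, _ in members)),
                "combined_bits": sum(h.bit_score for _, h in members),
                "e_value_min": min(evs),
                "e_value_max": max(evs),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["target_id", "n_chains", "chains", "combined_bits",
                 "e_value_min", "e_value_max"],
    )
    return df.sort_values("combined_bits", ascending=False).reset_index(drop=True)
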