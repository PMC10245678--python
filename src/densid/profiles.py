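"""Profile-HMM construction from per-residue probability predictions.

A residue-probability profile (L x 20 matrix plus per-residue confidences)
is turned into a profile hidden Markov model whose match emissions are the
predicted amino-acid distributions and whose transition probabilities are a
function of the per-residue confidence c(i):

    M->M(i) = max(c(i) - d, m_min)
    M->I(i) = M->D(i) = (1 - M->M(i)) / 2
    I->M(i) = D->M(i) = 1 - d
    I->I(i) = D->D(i) = d
    I->D(i) = D->I(i) = 0

with defaults d = 0.5 and m_min = 0.5.  Note that at the defaults
max(c - 0.5, 0.5) = 0.5 for every c in [0, 1], so M->M is constant; the
parameters are exposed so users can restore a confidence-dependent profile
(e.g. d = 0.2, m_min = 0).

The resulting models serialize to the HMMER3/f text format and are accepted
by stock HMMER3 tooling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .core import AA_ALPHABET, ResidueProfile, get_background

_T_COLS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class TransitionParams:
    """Knobs of the confidence-to-transition map.

    d is the shared insert/delete extension probability; mmin is the floor
    applied to M->M.  Both default to 0.5.
    """

    d: float = 0.5
    mmin: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError("d must lie strictly between 0 and 1")
        if not 0.0 <= self.mmin <= 1.0:
            raise ValueError("mmin must lie in [0, 1]")


@dataclass
class ProfileHMM:
    """A searchable profile HMM.

    transitions is L x 7 in the order (M->M, M->I, M->D, I->M, I->I,
    D->M, D->D); transitions[i] describes the moves from node i+1 to node
    i+2 (the final row carries the exit into the end state).
    """

    name: str
    match_emit: np.ndarray
    insert_emit: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def L(self) -> int:
        return self.match_emit.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        L = self.L
        if self.match_emit.shape != (L, 20) or self.insert_emit.shape != (L, 20):
            raise ValueError("emission tables must be L x 20")
        if self.transitions.shape != (L, 7):
            raise ValueError("transition table must be L x 7")
        t = self.transitions
        groups = [t[:, 0] + t[:, 1] + t[:, 2], t[:, 3] + t[:, 4], t[:, 5] + t[:, 6]]
        for g in groups:
            if np.any(np.abs(g - 1.0) > atol):
                raise ValueError("transition rows must each sum to 1")
        for em in (self.match_emit, self.insert_emit):
            if np.any(np.abs(em.sum(axis=1) - 1.0) > atol):
                raise ValueError("emission rows must sum to 1")
        if abs(self.background.sum() - 1.0) > atol:
            raise ValueError("background must sum to 1")


def build_transitions(conf: np.ndarray, params: TransitionParams | None = None) -> np.ndarray:
    """Apply the confidence-to-transition formulas to every residue.

    Returns an L x 7 table in the (M->M, M->I, M->D, I->M, I->I, D->M,
    D->D) order.  The three outgoing distributions per node sum to 1 by
    construction.
    """
    params = params or TransitionParams()
    c = np.asarray(conf, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("confidence vector must be non-empty and 1-D")
    bad = np.nonzero((c < 0) | (c > 1))[0]
    if bad.size:
        raise ValueError(f"confidence at index {bad[0]} outside [0, 1]")
    mm = np.maximum(c - params.d, params.mmin)
    mi = (1.0 - mm) / 2.0
    t = np.empty((c.size, 7))
    t[:, 0] = mm
    t[:, 1] = mi
    t[:, 2] = mi
    t[:, 3] = 1.0 - params.d
    t[:, 4] = params.d
    t[:, 5] = 1.0 - params.d
    t[:, 6] = params.d
    return t


def build_profile(
    rp: ResidueProfile,
    params: TransitionParams | None = None,
    background: np.ndarray | str | None = None,
) -> ProfileHMM:
    """Build a profile HMM from one chain's residue probabilities.

    Match emissions are the predicted per-residue distributions; insert
    emissions are the background.  The final node's M state exits to the
    end state with probability 1.
    """
    if len(rp) == 0:
        raise ValueError("cannot build a profile from an empty ResidueProfile")
    bg = get_background(background)
    t = build_transitions(rp.conf, params)
    params = params or TransitionParams()
    # Final node: M -> E with probability 1; D must also resolve to E.
    t[-1] = (1.0, 0.0, 0.0, 1.0 - params.d, params.d, 1.0, 0.0)
    hmm = ProfileHMM(
        name=rp.chain_id,
        match_emit=rp.probs.copy(),
        insert_emit=np.tile(bg, (len(rp), 1)),
        transitions=t,
        background=bg,
    )
    hmm.validate(atol=1e-6)
    return hmm


# ---------------------------------------------------------------------------
# HMMER3/f serialization
# ---------------------------------------------------------------------------

def _score(p: float) -> str:
    """Negative-natural-log score field: '*' for p = 0, '0.00000' for p = 1."""
    if p <= 0.0:
        return "*".rjust(8)
    return f"{max(-np.log(p), 0.0) + 0.0:8.5f}"  # + 0.0 normalizes -0.0


def _prob(tok: str, path: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return float(np.exp(-float(tok)))
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad score field {tok!r}") from exc


def write_hmmer3(hmm: ProfileHMM, path: str | os.PathLike) -> None:
    """Write a profile in the HMMER3/f text dialect.

    Scores are negative natural logs of probabilities; zero probabilities
    are written as '*'.  The node-0 line stores the background as the
    insert-0 emission and reuses the first node's transition values for the
    begin state.
    """
    hmm.validate(atol=1e-6)
    L = hmm.L
    compo = hmm.match_emit.mean(axis=0)
    lines = [
        "HMMER3/f [densid | profile from residue predictions]",
        f"NAME  {hmm.name}",
        f"LENG  {L}",
        "ALPH  amino",
        "RF    no",
        "MM    no",
        "CONS  yes",
        "CS    no",
        "MAP   yes",
        "HMM     " + "     ".join(AA_ALPHABET) + "   ",
        "        " + "     ".join(f"{a}->{b}" for a, b in
                                  [("m", "m"), ("m", "i"), ("m", "d"),
                                   ("i", "m"), ("i", "i"), ("d", "m"), ("d", "d")]),
        "  COMPO " + " ".join(_score(p) for p in compo),
        "        " + " ".join(_score(p) for p in hmm.background),
    ]
    t0 = hmm.transitions[0]
    # Begin line: B->M1, B->I0, B->D1, I0->M1, I0->I0, D0->M1 (=1), D0->D0 (=0).
    lines.append(
        "        "
        + " ".join(_score(p) for p in (t0[0], t0[1], t0[2], t0[3], t0[4], 1.0, 0.0))
    )
    for i in range(L):
        cons = AA_ALPHABET[int(np.argmax(hmm.match_emit[i]))]
        lines.append(
            f"{i + 1:7d} "
            + " ".join(_score(p) for p in hmm.match_emit[i])
            + f" {i + 1:6d} {cons} - - -"
        )
        lines.append("        " + " ".join(_score(p) for p in hmm.insert_emit[i]))
        row = hmm.transitions[i]
        lines.append("        " + " ".join(_score(p) for p in row))
    lines.append("//")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hmmer3(path: str | os.PathLike) -> ProfileHMM:
    """Read a single profile from an HMMER3/f text file."""
    with open(path) as fh:
        raw = fh.readlines()
    name, L = None, None
    i = 0
    while i < len(raw):
        line = raw[i].rstrip("\n")
        if line.startswith("NAME"):
            name = line.split(None, 1)[1].strip()
        elif line.startswith("LENG"):
            L = int(line.split()[1])
        elif line.startswith("ALPH"):
            if line.split()[1].lower() != "amino":
                raise ValueError(f"{path}:{i + 1}: only the amino alphabet is supported")
        elif line.startswith("HMM "):
            i += 2  # skip the two header rows
            break
        i += 1
    else:
        raise ValueError(f"{path}: no HMM section found")
    if name is None or L is None:
        raise ValueError(f"{path}: missing NAME or LENG header")

    def fields(lineno: int, expect_at_least: int) -> list[str]:
        if lineno >= len(raw):
            raise ValueError(f"{path}: truncated file at line {lineno + 1}")
        f = raw[lineno].split()
        if len(f) < expect_at_least:
            raise ValueError(
                f"{path}:{lineno + 1}: expected at least {expect_at_least} fields"
            )
        return f

    if raw[i].split()[0] == "COMPO":
        i += 1
    bg_fields = fields(i, 20)
    background = np.array([_prob(x, str(path), i + 1) for x in bg_fields[:20]])
    i += 2  # skip the begin-transition line
    match_emit = np.zeros((L, 20))
    insert_emit = np.zeros((L, 20))
    transitions = np.zeros((L, 7))
    for k in range(L):
        mf = fields(i, 21)
        if int(mf[0]) != k + 1:
            raise ValueError(f"{path}:{i + 1}: expected node {k + 1}, found {mf[0]}")
        match_emit[k] = [_prob(x, str(path), i + 1) for x in mf[1:21]]
        i += 1
        insert_emit[k] = [_prob(x, str(path), i + 1) for x in fields(i, 20)[:20]]
        i += 1
        transitions[k] = [_prob(x, str(path), i + 1) for x in fields(i, 7)[:7]]
        i += 1
    if i >= len(raw) or raw[i].strip() != "//":
        raise ValueError(f"{path}:{i + 1}: missing '//' terminator")
    # Undo score-quantization drift so the stochastic invariants hold exactly.
    match_emit /= match_emit.sum(axis=1, keepdims=True)
    insert_emit /= insert_emit.sum(axis=1, keepdims=True)
    background /= background.sum()
    transitions[:, 0:3] /= transitions[:, 0:3].sum(axis=1, keepdims=True)
    transitions[:, 3:5] /= transitions[:, 3:5].sum(axis=1, keepdims=True)
    transitions[:, 5:7] /= transitions[:, 5:7].sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=name,
        match_emit=match_emit,
        insert_emit=insert_emit,
        transitions=transitions,
        background=background,
    )
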