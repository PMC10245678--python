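"""Seeded recovery benchmarks on synthetic data.

Each trial generates a fresh true sequence, corrupts its residue
probabilities, builds a profile HMM, embeds the truth in a decoy proteome
and asks whether the search ranks the true target first.  The fragment
variant searches with a short sub-profile of a long target, mimicking the
identification of a protein from a small stretch of well-resolved density.
"""

from __future__ import annotations

import numpy as np

from .core import ResidueProfile
from .profiles import TransitionParams, build_profile
from .search import calibrate, search_db
from .synthetic import NoiseSpec, gen_profile, gen_proteome, gen_structure, true_sequence

TRUE_ID = "true_target"


def identification_trial(
    seed: int,
    eta: float = 0.5,
    chain_len: int = 200,
    n_decoys: int = 100,
    params: TransitionParams | None = None,
    calibration_n: int = 100,
) -> bool:
    """One seeded trial: does the embedded true target rank first?"""
    model = gen_structure([chain_len], seed=seed)
    seq = true_sequence(model, "A")
    rp = gen_profile(seq, NoiseSpec(eta=eta, seed=seed + 1))
    hmm = build_profile(rp, params)
    db = gen_proteome({TRUE_ID: seq}, n_decoys=n_decoys, seed=seed + 2)
    cal = calibrate(hmm, n=calibration_n, seed=seed + 3)
    hits = search_db(hmm, db, cal, e_max=np.inf)
    return bool(hits) and hits[0].target_id == TRUE_ID


def identification_benchmark(
    n_trials: int = 100,
    eta: float = 0.5,
    chain_len: int = 200,
    n_decoys: int = 100,
    seed: int = 0,
) -> int:
    """Number of trials (out of n_trials) where the true target ranks first."""
    return sum(
        identification_trial(seed + 1000 * t, eta=eta, chain_len=chain_len, n_decoys=n_decoys)
        for t in range(n_trials)
    )


def fragment_trial(
    seed: int,
    fragment_len: int = 33,
    target_len: int = 400,
    eta: float = 0.3,
    n_decoys: int = 100,
    calibration_n: int = 100,
) -> bool:
    """Identify a long target from a short sub-profile of it."""
    rng = np.random.default_rng(seed)
    model = gen_structure([target_len], seed=seed)
    seq = true_sequence(model, "A")
    start = int(rng.integers(0, target_len - fragment_len + 1))
    rp_full = gen_profile(seq, NoiseSpec(eta=eta, seed=seed + 1))
    rp = ResidueProfile(
        chain_id="frag",
        probs=rp_full.probs[start : start + fragment_len],
        conf=rp_full.conf[start : start + fragment_len],
    )
    hmm = build_profile(rp)
    db = gen_proteome({TRUE_ID: seq}, n_decoys=n_decoys, seed=seed + 2)
    cal = calibrate(hmm, n=calibration_n, seed=seed + 3)
    hits = search_db(hmm, db, cal, e_max=np.inf)
    return bool(hits) and hits[0].target_id == TRUE_ID


def fragment_benchmark(
    n_trials: int = 100,
    fragment_len: int = 33,
    target_len: int = 400,
    eta: float = 0.3,
    n_decoys: int = 100,
    seed: int = 0,
) -> int:
    return sum(
        fragment_trial(
            seed + 1000 * t,
            fragment_len=fragment_len,
            target_len=target_len,
            eta=eta,
            n_decoys=n_decoys,
        )
        for t in range(n_trials)
    )
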