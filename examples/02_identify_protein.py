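"""Identify an unknown chain against a decoy proteome.

A 200-residue chain with half-noisy probability predictions (eta = 0.5:
the true amino acid only holds 52.5% of each row's mass) is searched
against 100 decoys plus the embedded truth.  The true target should rank
first with an E-value many orders of magnitude below the best decoy.
"""

from densid import (
    NoiseSpec,
    build_profile,
    calibrate,
    gen_profile,
    gen_proteome,
    gen_structure,
    search_db,
    true_sequence,
)

seed = 17
model = gen_structure([200], seed=seed)
seq = true_sequence(model, "A")
rp = gen_profile(seq, NoiseSpec(eta=0.5, seed=seed + 1))
hmm = build_profile(rp)

db = gen_proteome({"true_target": seq}, n_decoys=100, seed=seed + 2)
cal = calibrate(hmm, n=200, seed=seed + 3)
hits = search_db(hmm, db, cal, e_max=1.0)

print(f"database: {len(db)} sequences; hits with E <= 1: {len(hits)}")
for h in hits[:3]:
    print(f"  {h.target_id:14s} bits={h.bit_score:8.1f} E={h.e_value:.3g} "
          f"ali {h.ali_from}-{h.ali_to}")
# The bit score is the log2-odds of the profile alignment against a random
# background; the E-value is the expected number of equally good hits in a
# database of this size, so values far below 1 mean a confident match.
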