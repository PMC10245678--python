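"""Synthetic inputs for the full pipeline: structures, profiles, proteomes, maps.

These generators stand in for what an automated model-building network
would produce on a real map, with a single interpretable noise knob:

* structures are ideal alpha-helical backbones (1.5 A rise, 100 deg twist,
  2.3 A radius), so consecutive CA atoms sit ~3.8 A apart and distance
  based rules (k-NN graphs, chain connection) behave realistically;
* residue probability profiles mix the one-hot true identity with the
  uniform distribution with weight eta — eta = 0 is a perfect predictor,
  eta = 1 carries no information;
* decoy proteomes embed each true sequence inside a longer random host so
  identification is non-trivial; ids record the ground truth;
* density maps are sums of unit-amplitude isotropic Gaussians at the atom
  positions.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AA_ALPHABET,
    AtomicModel,
    Chain,
    DensityMap,
    Residue,
    ResidueProfile,
    SequenceDatabase,
    SequenceEntry,
    get_background,
)

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3  # A, CA radius


@dataclass
class NoiseSpec:
    """Noise model for synthetic residue-probability profiles.

    eta mixes the uniform distribution into the one-hot true identity;
    confidences are drawn uniformly from conf_range.
    """

    eta: float = 0.5
    conf_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        lo, hi = self.conf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("conf_range must satisfy 0 <= lo <= hi <= 1")


def _helix_atom(t: float, radius: float, rise_offset: float, idx: int) -> np.ndarray:
    angle = HELIX_TWIST * (idx + t)
    return np.array(
        [radius * np.cos(angle), radius * np.sin(angle), HELIX_RISE * (idx + t) + rise_offset]
    )


def gen_structure(chain_lengths: list[int], seed: int = 0) -> AtomicModel:
    """Ideal alpha-helical chains with N/CA/C/O backbones, offset to avoid clashes."""
    if any(l < 1 for l in chain_lengths):
        raise ValueError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)
    model = AtomicModel()
    spacing = 16.0  # A between helix axes
    per_row = max(1, int(np.ceil(np.sqrt(len(chain_lengths)))))
    for k, length in enumerate(chain_lengths):
        offset = np.array([(k % per_row) * spacing, (k // per_row) * spacing, 0.0])
        phase = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(phase), -np.sin(phase), 0.0],
             [np.sin(phase), np.cos(phase), 0.0],
             [0.0, 0.0, 1.0]]
        )
        chain = Chain(chain_id=_chain_id(k))
        for i in range(length):
            atoms = {
                "N": _helix_atom(-0.35, 1.6, 0.0, i),
                "CA": _helix_atom(0.0, HELIX_RADIUS, 0.0, i),
                "C": _helix_atom(0.38, 1.7, 0.0, i),
                "O": _helix_atom(0.42, 2.0, -1.0, i),
            }
            atoms = {n: rot @ p + offset for n, p in atoms.items()}
            identity = AA_ALPHABET[rng.integers(20)]
            chain.residues.append(Residue(identity=identity, atoms=atoms))
        model.chains.append(chain)
    return model


def _chain_id(k: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if k < 26:
        return letters[k]
    return letters[k // 26 - 1] + letters[k % 26]


def true_sequence(model: AtomicModel, chain_id: str) -> str:
    """The generated ground-truth sequence of one chain."""
    return "".join(r.identity for r in model[chain_id].residues)


def gen_profile(true_seq: str, noise: NoiseSpec) -> ResidueProfile:
    """Noisy residue-probability profile around a true sequence.

    P[i] = (1 - eta) * onehot(true_seq[i]) + eta * uniform; confidences are
    Uniform(conf_range) draws.  Rows sum to 1 exactly.
    """
    if not true_seq or any(a not in AA_ALPHABET for a in true_seq):
        raise ValueError("true_seq must be a non-empty 20-letter amino-acid string")
    rng = np.random.default_rng(noise.seed)
    L = len(true_seq)
    probs = np.full((L, 20), noise.eta / 20.0)
    for i, a in enumerate(true_seq):
        probs[i, AA_ALPHABET.index(a)] += 1.0 - noise.eta
    lo, hi = noise.conf_range
    conf = rng.uniform(lo, hi, size=L)
    return ResidueProfile(chain_id="A", probs=probs, conf=conf)


def gen_proteome(
    true_seqs: dict[str, str] | list[str],
    n_decoys: int = 100,
    len_dist=None,
    composition: str | np.ndarray | None = None,
    seed: int = 0,
) -> SequenceDatabase:
    """Decoy proteome with each true sequence embedded in a random host.

    true_seqs maps an id to a sequence (a bare list gets ids true_0, ...).
    Decoy lengths come from len_dist: an int (fixed), a (lo, hi) tuple
    (uniform integer), or a callable rng -> int; default is the mean true
    length (or 300).  Entry descriptions record where each true sequence
    was embedded.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if not isinstance(true_seqs, dict):
        true_seqs = {f"true_{i}": s for i, s in enumerate(true_seqs)}
    rng = np.random.default_rng(seed)
    bg = get_background(composition)
    if len_dist is None:
        mean_len = int(np.mean([len(s) for s in true_seqs.values()])) if true_seqs else 300
        len_dist = max(mean_len, 50)

    def draw_len() -> int:
        if callable(len_dist):
            return int(len_dist(rng))
        if isinstance(len_dist, tuple):
            return int(rng.integers(len_dist[0], len_dist[1] + 1))
        return int(len_dist)

    def random_seq(n: int) -> str:
        return "".join(AA_ALPHABET[i] for i in rng.choice(20, size=n, p=bg))

    entries: list[SequenceEntry] = []
    for name, seq in true_seqs.items():
        host_extra = int(rng.integers(20, 101))
        offset = int(rng.integers(0, host_extra + 1))
        host = random_seq(offset) + seq + random_seq(host_extra - offset)
        entries.append(
            SequenceEntry(name, host, f"embedded at {offset + 1}-{offset + len(seq)}")
        )
    for i in range(n_decoys):
        entries.append(SequenceEntry(f"decoy_{i}", random_seq(draw_len())))
    return SequenceDatabase(entries)


def render_map(
    model: AtomicModel,
    voxel: float = 1.0,
    sigma: float = 0.6,
    box_pad: float = 4.0,
    amplitude: float = 1.0,
) -> DensityMap:
    """Render a model as a sum of isotropic unit Gaussians on a regular grid."""
    xyz = np.array([p for res in model.residues() for p in res.atoms.values()])
    if xyz.size == 0:
        raise ValueError("model has no atoms to render")
    lo = xyz.min(axis=0) - box_pad
    hi = xyz.max(axis=0) + box_pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    grid = np.zeros(shape, dtype=np.float64)
    axes = [lo[d] + voxel * np.arange(shape[d]) for d in range(3)]
    cut = 4.0 * sigma
    for p in xyz:
        sel = [
            slice(
                max(0, int(np.floor((p[d] - cut - lo[d]) / voxel))),
                min(shape[d], int(np.ceil((p[d] + cut - lo[d]) / voxel)) + 1),
            )
            for d in range(3)
        ]
        dx = axes[0][sel[0]] - p[0]
        dy = axes[1][sel[1]] - p[1]
        dz = axes[2][sel[2]] - p[2]
        r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        grid[sel[0], sel[1], sel[2]] += amplitude * np.exp(-r2 / (2.0 * sigma**2))
    return DensityMap(grid=grid, voxel_size=np.full(3, float(voxel)), origin=lo)


def perturb_model(
    model: AtomicModel,
    sigma_xyz: float = 0.0,
    identity_error_rate: float = 0.0,
    seed: int = 0,
) -> AtomicModel:
    """Jitter atoms with i.i.d. Gaussian noise and corrupt identities.

    Each residue's identity is resampled uniformly from the other 19 amino
    acids with probability identity_error_rate.
    """
    if not 0.0 <= identity_error_rate <= 1.0:
        raise ValueError("identity_error_rate must lie in [0, 1]")
    if sigma_xyz < 0:
        raise ValueError("sigma_xyz must be >= 0")
    rng = np.random.default_rng(seed)
    out = model.copy()
    for res in out.residues():
        for name in res.atoms:
            if sigma_xyz > 0:
                res.atoms[name] = res.atoms[name] + rng.normal(0.0, sigma_xyz, 3)
        if identity_error_rate > 0 and rng.random() < identity_error_rate:
            others = [a for a in AA_ALPHABET if a != res.identity]
            res.identity = others[rng.integers(len(others))]
    return out
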