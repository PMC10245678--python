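"""Model evaluation: residue correspondence, RMSD, accuracy, Q-score, FSC.

A predicted model is compared to a reference model built into the same map
(no superposition; both share the map's coordinate frame).  Residues are
paired by mutual nearest anchor atoms (CA for protein, P for nucleotide)
within a 3 A cutoff; from the pairing follow

    recall        = |pairs| / |reference residues|
    precision     = |pairs| / |predicted residues|
    aa_accuracy   = fraction of paired residues with the correct identity
    completeness  = (paired and identity-correct) / |reference residues|

and pooled RMSDs over a chosen backbone atom set.  Map-level quality uses
the Q-score (per-atom correlation of interpolated map values on spherical
shells around the atom against an ideal Gaussian falloff) and the Fourier
shell correlation between two maps on a common grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core import (
    AtomicModel,
    DensityMap,
    NUCLEOTIDE_BACKBONE,
    PROTEIN_BACKBONE,
)

MATCH_CUTOFF = 3.0  # A, between anchor atoms


@dataclass
class ResidueCorrespondence:
    """One-to-one residue pairing between predicted and reference models."""

    pairs: list[tuple[tuple[int, int], tuple[int, int], float]]
    unmatched_pred: list[tuple[int, int]]
    unmatched_ref: list[tuple[int, int]]


@dataclass
class EvaluationReport:
    calpha_rmsd: float
    backbone_rmsd: float
    recall: float
    precision: float
    aa_accuracy: float
    completeness: float
    n_pairs: int
    n_pred: int
    n_ref: int
    per_residue: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "calpha_rmsd": self.calpha_rmsd,
            "backbone_rmsd": self.backbone_rmsd,
            "recall": self.recall,
            "precision": self.precision,
            "aa_accuracy": self.aa_accuracy,
            "completeness": self.completeness,
            "n_pairs": self.n_pairs,
            "n_pred": self.n_pred,
            "n_ref": self.n_ref,
        }


@dataclass
class QScoreResult:
    atom_q: list[tuple[tuple[int, int], str, float]]  # ((chain, res), atom, q)
    residue_q: dict[tuple[int, int], float]
    model_q: float
    n_skipped: int = 0


def _anchored(model: AtomicModel, anchor: str):
    refs, xyz = [], []
    for ci, chain in enumerate(model.chains):
        for ri, res in enumerate(chain.residues):
            p = res.atoms.get(anchor)
            if p is not None:
                refs.append((ci, ri))
                xyz.append(p)
    return refs, np.asarray(xyz)


def match_residues(
    pred: AtomicModel,
    ref: AtomicModel,
    cutoff: float = MATCH_CUTOFF,
    anchor: str = "CA",
) -> ResidueCorrespondence:
    """Pair residues by mutual nearest anchor atoms within the cutoff.

    The pairing is one-to-one: a pair forms when each residue is the
    other's nearest counterpart and the distance is <= cutoff.  Remaining
    residues within the cutoff of already-taken partners stay unmatched.
    """
    pred_refs, pred_xyz = _anchored(pred, anchor)
    ref_refs, ref_xyz = _anchored(ref, anchor)
    if not pred_refs or not ref_refs:
        raise ValueError(f"no residues expose anchor atom {anchor!r}")
    t_pred = cKDTree(pred_xyz)
    t_ref = cKDTree(ref_xyz)
    d_pr, near_ref = t_ref.query(pred_xyz)
    d_rp, near_pred = t_pred.query(ref_xyz)
    cand = []
    for ip in range(len(pred_refs)):
        ir = int(near_ref[ip])
        if int(near_pred[ir]) == ip and d_pr[ip] <= cutoff:
            cand.append((float(d_pr[ip]), ir, ip))
    cand.sort(key=lambda t: (t[0], t[1]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for d, ir, ip in cand:
        if ip in used_p or ir in used_r:
            continue
        used_p.add(ip)
        used_r.add(ir)
        pairs.append((pred_refs[ip], ref_refs[ir], d))
    return ResidueCorrespondence(
        pairs=pairs,
        unmatched_pred=[pred_refs[i] for i in range(len(pred_refs)) if i not in used_p],
        unmatched_ref=[ref_refs[i] for i in range(len(ref_refs)) if i not in used_r],
    )


def rmsd_metrics(
    corr: ResidueCorrespondence,
    pred: AtomicModel,
    ref: AtomicModel,
    atoms: tuple[str, ...] = ("CA",),
) -> float:
    """Pooled RMSD over the named atoms of all paired residues, in A.

    No superposition is applied.  Atoms missing on either side of a pair
    are skipped; at least one eligible atom is required.
    """
    sq = []
    for (pc, pr), (rc, rr), _ in corr.pairs:
        res_p = pred.chains[pc].residues[pr]
        res_r = ref.chains[rc].residues[rr]
        for name in atoms:
            a, b = res_p.atoms.get(name), res_r.atoms.get(name)
            if a is not None and b is not None:
                sq.append(np.sum((a - b) ** 2))
    if not sq:
        raise ValueError(f"no paired residues carry atoms {atoms}")
    return float(np.sqrt(np.mean(sq)))


def classification_metrics(
    corr: ResidueCorrespondence,
    pred: AtomicModel,
    ref: AtomicModel,
) -> dict:
    """Recall, precision, identity accuracy and completeness from a pairing."""
    n_ref = ref.n_residues
    n_pred = pred.n_residues
    if n_ref == 0:
        raise ValueError("empty reference model")
    n_pairs = len(corr.pairs)
    correct = 0
    for (pc, pr), (rc, rr), _ in corr.pairs:
        if pred.chains[pc].residues[pr].identity == ref.chains[rc].residues[rr].identity:
            correct += 1
    return {
        "recall": n_pairs / n_ref,
        "precision": n_pairs / n_pred if n_pred else 0.0,
        "aa_accuracy": correct / n_pairs if n_pairs else 0.0,
        "completeness": correct / n_ref,
        "n_pairs": n_pairs,
        "n_pred": n_pred,
        "n_ref": n_ref,
    }


def evaluate_model(
    pred: AtomicModel,
    ref: AtomicModel,
    cutoff: float = MATCH_CUTOFF,
    anchor: str = "CA",
) -> EvaluationReport:
    """Full report: pairing, RMSDs and classification metrics in one call."""
    corr = match_residues(pred, ref, cutoff=cutoff, anchor=anchor)
    backbone = PROTEIN_BACKBONE if anchor == "CA" else NUCLEOTIDE_BACKBONE
    cls = classification_metrics(corr, pred, ref)
    per_residue = []
    for (pc, pr), (rc, rr), d in corr.pairs:
        rp = pred.chains[pc].residues[pr]
        rr_ = ref.chains[rc].residues[rr]
        per_residue.append(
            {
                "pred_chain": pred.chains[pc].chain_id,
                "pred_index": pr + 1,
                "ref_chain": ref.chains[rc].chain_id,
                "ref_index": rr + 1,
                "distance": d,
                "pred_identity": rp.identity,
                "ref_identity": rr_.identity,
            }
        )
    return EvaluationReport(
        calpha_rmsd=rmsd_metrics(corr, pred, ref, atoms=(anchor,)),
        backbone_rmsd=rmsd_metrics(corr, pred, ref, atoms=backbone),
        recall=cls["recall"],
        precision=cls["precision"],
        aa_accuracy=cls["aa_accuracy"],
        completeness=cls["completeness"],
        n_pairs=cls["n_pairs"],
        n_pred=cls["n_pred"],
        n_ref=cls["n_ref"],
        per_residue=per_residue,
    )


# ---------------------------------------------------------------------------
# Q-score
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _interp(dmap: DensityMap, xyz: np.ndarray) -> np.ndarray:
    frac = dmap.world_to_grid(xyz).T
    return map_coordinates(dmap.grid.astype(float), frac, order=1, mode="nearest")


def qscore(
    model: AtomicModel,
    dmap: DensityMap,
    sigma: float = 0.6,
    r_max: float = 2.0,
    shell_step: float = 0.1,
    points_per_shell: int = 8,
    atom_names: tuple[str, ...] | None = None,
) -> QScoreResult:
    """Per-atom resolvability: correlation of the local map profile with a Gaussian.

    For each atom, map values are interpolated at deterministic points on
    concentric spherical shells (radii 0 to r_max in steps of shell_step)
    and correlated (Pearson) with the ideal falloff exp(-r^2 / (2 sigma^2))
    at the same radii.  Sample points closer to another atom than to the
    evaluated atom are excluded, and atoms within r_max of the map edge are
    skipped (counted in n_skipped).
    """
    radii = np.arange(0.0, r_max + 1e-9, shell_step)
    dirs = _fibonacci_sphere(points_per_shell)
    atoms: list[tuple[tuple[int, int], str, np.ndarray]] = []
    for ci, chain in enumerate(model.chains):
        for ri, res in enumerate(chain.residues):
            for name, xyz in res.atoms.items():
                if atom_names is None or name in atom_names:
                    atoms.append(((ci, ri), name, xyz))
    if not atoms:
        raise ValueError("model has no atoms to score")
    all_xyz = np.asarray([a[2] for a in atoms])
    tree = cKDTree(all_xyz)
    lo = dmap.origin
    hi = dmap.origin + (np.array(dmap.grid.shape) - 1) * dmap.voxel_size
    ref_profile = np.exp(-(radii**2) / (2.0 * sigma**2))
    atom_q: list[tuple[tuple[int, int], str, float]] = []
    n_skipped = 0
    for ai, (key, name, center) in enumerate(atoms):
        if np.any(center - r_max < lo) or np.any(center + r_max > hi):
            n_skipped += 1
            continue
        pts, refs = [center.copy()], [ref_profile[0]]
        for r, g in zip(radii[1:], ref_profile[1:]):
            shell = center + r * dirs
            # keep points whose nearest model atom is the evaluated one
            _, nearest = tree.query(shell)
            keep = nearest == ai
            if np.any(keep):
                pts.extend(shell[keep])
                refs.extend([g] * int(keep.sum()))
        vals = _interp(dmap, np.asarray(pts))
        refs = np.asarray(refs)
        if len(vals) < 3 or np.std(vals) < 1e-12 or np.std(refs) < 1e-12:
            n_skipped += 1
            continue
        q = float(np.corrcoef(vals, refs)[0, 1])
        atom_q.append((key, name, q))
    if n_skipped:
        warnings.warn(f"qscore: skipped {n_skipped} atoms near the map edge or with flat density")
    residue_q: dict[tuple[int, int], float] = {}
    for key in {k for k, _, _ in atom_q}:
        residue_q[key] = float(np.mean([q for k, _, q in atom_q if k == key]))
    model_q = float(np.mean([q for _, _, q in atom_q])) if atom_q else float("nan")
    return QScoreResult(atom_q=atom_q, residue_q=residue_q, model_q=model_q, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

def fsc(
    map_a: DensityMap,
    map_b: DensityMap,
    shell_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Fourier shell correlation between two maps on the same grid.

    Returns (frequencies in 1/A at shell centres, correlation per shell,
    frequency of the 0.5 crossing or None).  shell_width defaults to one
    reciprocal voxel of the largest axis extent.
    """
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("FSC requires identical grids")
    if not np.allclose(map_a.voxel_size, map_b.voxel_size):
        raise ValueError("FSC requires identical voxel sizes")
    shape = np.array(map_a.grid.shape)
    extent = shape * map_a.voxel_size
    if shell_width is None:
        shell_width = float(1.0 / extent.max())
    fa = np.fft.fftn(map_a.grid.astype(float))
    fb = np.fft.fftn(map_b.grid.astype(float))
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n, d=v) for n, v in zip(shape, map_a.voxel_size)],
        indexing="ij",
    )
    fmag = np.sqrt(sum(f**2 for f in freqs))
    nyquist = float(0.5 / map_a.voxel_size.max())
    edges = np.arange(0.0, nyquist + shell_width, shell_width)
    centres, corr = [], []
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        mask = (fmag >= lo_e) & (fmag < hi_e)
        if not np.any(mask):
            continue
        num = np.real(np.sum(fa[mask] * np.conj(fb[mask])))
        den = np.sqrt(np.sum(np.abs(fa[mask]) ** 2) * np.sum(np.abs(fb[mask]) ** 2))
        if den == 0:
            continue
        centres.append(0.5 * (lo_e + hi_e))
        corr.append(num / den)
    centres = np.asarray(centres)
    corr = np.asarray(corr)
    crossing = None
    for i in range(1, len(corr)):
        if corr[i - 1] >= 0.5 > corr[i]:
            f0, f1 = centres[i - 1], centres[i]
            c0, c1 = corr[i - 1], corr[i]
            crossing = float(f0 + (c0 - 0.5) / (c0 - c1) * (f1 - f0))
            break
    return centres, corr, crossing
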