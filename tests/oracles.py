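"""Independent oracle implementations used only by the tests.

Each oracle recomputes a quantity through a different code path from the
package (scipy rigid-body routines, explicit per-atom loops, direct
enumeration, numerical optimisation) so agreement is a genuine dual-route
check rather than the same algorithm run twice.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def scipy_superpose(ref: np.ndarray, mov: np.ndarray):
    """Optimal rigid fit via scipy's align_vectors; returns (apply_fn, rmsd)."""
    ref_c, mov_c = ref.mean(axis=0), mov.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    rmsd = rssd / math.sqrt(len(ref))

    def apply(coords: np.ndarray) -> np.ndarray:
        return rot.apply(coords - mov_c) + ref_c

    return apply, float(rmsd)


def _residue_contacts(complex_, cutoff: float = 5.0) -> set[tuple[int, int]]:
    """Brute-force residue contact enumeration with explicit atom loops."""
    pairs = set()
    for ri in complex_.receptor.residues:
        for pj in complex_.peptide.residues:
            found = False
            for a in ri.atoms:
                for b in pj.atoms:
                    if np.linalg.norm(a.coords - b.coords) < cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                pairs.add((ri.seq_index, pj.seq_index))
    return pairs


def _backbone(chain, wanted: set[int] | None = None) -> np.ndarray:
    coords = []
    for res in chain.residues:
        if wanted is not None and res.seq_index not in wanted:
            continue
        for name in ("N", "CA", "C", "O"):
            coords.append(res.get_atom(name).coords)
    return np.array(coords)


def oracle_dockq(native, predicted) -> float:
    """DockQ recomputed from scratch: explicit loops + scipy superpositions."""
    nat_pairs = _residue_contacts(native)
    pred_pairs = _residue_contacts(predicted)
    fnat = len(nat_pairs & pred_pairs) / len(nat_pairs)

    rec_if, pep_if = set(), set()
    for ri in native.receptor.residues:
        for pj in native.peptide.residues:
            close = any(
                np.linalg.norm(a.coords - b.coords) < 10.0
                for a in ri.atoms for b in pj.atoms
            )
            if close:
                rec_if.add(ri.seq_index)
                pep_if.add(pj.seq_index)
    nat_if = np.vstack([_backbone(native.receptor, rec_if),
                        _backbone(native.peptide, pep_if)])
    pred_if = np.vstack([_backbone(predicted.receptor, rec_if),
                         _backbone(predicted.peptide, pep_if)])
    _, irmsd = scipy_superpose(nat_if, pred_if)

    apply, _ = scipy_superpose(_backbone(native.receptor), _backbone(predicted.receptor))
    moved = apply(_backbone(predicted.peptide))
    diff = moved - _backbone(native.peptide)
    lrmsd = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))

    return (fnat + 1 / (1 + (irmsd / 1.5) ** 2) + 1 / (1 + (lrmsd / 8.5) ** 2)) / 3


def oracle_tm_score(nat_ca: np.ndarray, pred_ca: np.ndarray, seed: int = 0) -> float:
    """TM-score via multi-start rigid-body optimisation over 6 pose parameters."""
    L = len(nat_ca)
    d0 = max(1.24 * (L - 15) ** (1 / 3) - 1.8, 0.5) if L > 15 else 0.5

    def neg_tm(params: np.ndarray) -> float:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = pred_ca @ rot.T + params[3:]
        d = np.linalg.norm(moved - nat_ca, axis=1)
        return -float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    ref_c, mov_c = nat_ca.mean(axis=0), pred_ca.mean(axis=0)
    rot0, _ = Rotation.align_vectors(nat_ca - ref_c, pred_ca - mov_c)
    x0 = np.concatenate([rot0.as_rotvec(), ref_c - rot0.apply(mov_c)])
    rng = np.random.default_rng(seed)
    best = -neg_tm(x0)
    starts = [x0] + [
        x0 + np.concatenate([rng.normal(0, 0.3, 3), rng.normal(0, 2.0, 3)])
        for _ in range(15)
    ]
    for s in starts:
        res = minimize(neg_tm, s, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10})
        best = max(best, -res.fun)
    return best


def oracle_column_mi(col_a: list[str], col_b: list[str]) -> float:
    """Plug-in MI by direct enumeration over the observed symbol alphabet."""
    usable = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    n = len(usable)
    joint = Counter(usable)
    pa = Counter(a for a, _ in usable)
    pb = Counter(b for _, b in usable)
    mi = 0.0
    for a in pa:
        for b in pb:
            c = joint.get((a, b), 0)
            if c:
                mi += (c / n) * math.log2((c / n) / ((pa[a] / n) * (pb[b] / n)))
    return mi
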