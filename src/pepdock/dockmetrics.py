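"""Docking accuracy metrics for protein-peptide complexes.

Implements the DockQ family of measures (Fnat, interface RMSD, ligand RMSD,
composite score and quality categories), the stricter atomic-accuracy
criterion, peptide backbone RMSD after receptor alignment, TM-score for
receptor chains, and a simplified dihedral-based secondary-structure
assignment used to compare native and predicted peptide conformations.

Conventions: residue-residue contacts use a 5 Å heavy-atom cutoff; interface
residues use a 10 Å heavy-atom cutoff; a clash is any inter-chain heavy-atom
pair under 2 Å. All are overridable through :class:`~pepdock.config.PipelineConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .config import DEFAULT_CONFIG, PipelineConfig
from .structio import Chain, ComplexStructure, select_atoms

__all__ = [
    "SuperpositionResult",
    "ContactSet",
    "DockQResult",
    "AtomicAccuracyResult",
    "SSAssignment",
    "superpose_kabsch",
    "native_contacts",
    "dockq",
    "categorize_dockq",
    "peptide_rmsd_after_protein_alignment",
    "atomic_accuracy",
    "tm_score",
    "assign_secondary_structure",
]

Category = Literal["poor", "acceptable", "medium", "high"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float              # Å, after applying the transform to mov

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ContactSet:
    pairs: frozenset[tuple[int, int]]  # (receptor seq_index, peptide seq_index)
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DockQResult:
    fnat: float
    irmsd: float
    lrmsd: float
    score: float
    category: Category


@dataclass
class AtomicAccuracyResult:
    fnat: float
    clash_count: int
    peptide_allatom_rmsd: float
    interface_allatom_rmsd: float
    passed: bool


@dataclass
class SSAssignment:
    labels: str  # one of H/E/L per residue


def superpose_kabsch(ref: np.ndarray, mov: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mov`` onto ``ref``.

    Point correspondence is positional. Returns the proper rotation
    (determinant +1), translation and post-fit RMSD. Collinear/degenerate
    inputs (rank < 2 covariance) are rejected.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    # rank-deficient covariance ⇒ points collinear or coincident
    if np.sum(s > 1e-8 * max(s[0], 1e-30)) < 2:
        raise ValueError("degenerate (collinear) point set: superposition ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _residue_heavy(chain: Chain) -> list[np.ndarray]:
    return [res.heavy_coords() for res in chain.residues]


def native_contacts(
    complex_: ComplexStructure, cutoff: float | None = None
) -> ContactSet:
    """Inter-chain residue pairs with any heavy-atom distance under ``cutoff``."""
    cutoff = DEFAULT_CONFIG.contact_cutoff if cutoff is None else cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = _residue_heavy(complex_.receptor)
    pep = _residue_heavy(complex_.peptide)
    pairs = set()
    for i, rc in enumerate(rec):
        for j, pc in enumerate(pep):
            if rc.size and pc.size and cdist(rc, pc).min() < cutoff:
                pairs.add((i, j))
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def categorize_dockq(score: float, config: PipelineConfig = DEFAULT_CONFIG) -> Category:
    """Map a DockQ score to its quality category.

    poor < 0.23 ≤ acceptable ≤ 0.49 < medium ≤ 0.80 < high.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"DockQ score {score} outside [0, 1]")
    if score < config.dockq_acceptable:
        return "poor"
    if score <= config.dockq_medium:
        return "acceptable"
    if score <= config.dockq_high:
        return "medium"
    return "high"


def _interface_residues(
    complex_: ComplexStructure, cutoff: float
) -> tuple[list[int], list[int]]:
    """Residues of each chain with any heavy atom within ``cutoff`` of the other chain."""
    rec = _residue_heavy(complex_.receptor)
    pep = _residue_heavy(complex_.peptide)
    rec_sel: set[int] = set()
    pep_sel: set[int] = set()
    for i, rc in enumerate(rec):
        for j, pc in enumerate(pep):
            if rc.size and pc.size and cdist(rc, pc).min() < cutoff:
                rec_sel.add(i)
                pep_sel.add(j)
    return sorted(rec_sel), sorted(pep_sel)


def _backbone_coords_for(chain: Chain, residue_ids: list[int]) -> np.ndarray:
    wanted = set(residue_ids)
    coords = []
    for res in chain.residues:
        if res.seq_index in wanted and res.has_backbone():
            for name in ("N", "CA", "C", "O"):
                coords.append(res.get_atom(name).coords)
    return np.array(coords, dtype=float).reshape(-1, 3)


def _heavy_coords_for(chain: Chain, residue_ids: list[int]) -> np.ndarray:
    wanted = set(residue_ids)
    coords = []
    for res in chain.residues:
        if res.seq_index in wanted:
            coords.append(res.heavy_coords())
    if not coords:
        return np.empty((0, 3))
    return np.vstack(coords)


def _check_correspondence(native: ComplexStructure, predicted: ComplexStructure) -> None:
    for nat_ch, pred_ch in zip(native.chains(), predicted.chains()):
        if len(nat_ch) != len(pred_ch):
            raise ValueError(
                f"chain {nat_ch.id}: native has {len(nat_ch)} residues, "
                f"predicted has {len(pred_ch)}; supply equal-length chains"
            )


def dockq(
    native: ComplexStructure,
    predicted: ComplexStructure,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DockQResult:
    """Composite docking quality score in [0, 1].

    score = (Fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3, where Fnat
    is the fraction of native inter-chain residue contacts recovered, iRMSD
    the backbone RMSD over native interface residues after superposing on
    them, and LRMSD the peptide backbone RMSD after superposing the
    receptors. Identity of prediction and native gives exactly 1.
    """
    _check_correspondence(native, predicted)
    nat_contacts = native_contacts(native, config.contact_cutoff)
    if len(nat_contacts) == 0:
        raise ValueError("native complex has no inter-chain contacts; DockQ undefined")
    pred_contacts = native_contacts(predicted, config.contact_cutoff)
    fnat = len(nat_contacts.pairs & pred_contacts.pairs) / len(nat_contacts.pairs)

    rec_if, pep_if = _interface_residues(native, config.interface_cutoff)
    nat_if = np.vstack(
        [
            _backbone_coords_for(native.receptor, rec_if),
            _backbone_coords_for(native.peptide, pep_if),
        ]
    )
    pred_if = np.vstack(
        [
            _backbone_coords_for(predicted.receptor, rec_if),
            _backbone_coords_for(predicted.peptide, pep_if),
        ]
    )
    irmsd = superpose_kabsch(nat_if, pred_if).rmsd

    lrmsd = peptide_rmsd_after_protein_alignment(native, predicted)

    score = (fnat + 1.0 / (1.0 + (irmsd / 1.5) ** 2) + 1.0 / (1.0 + (lrmsd / 8.5) ** 2)) / 3.0
    return DockQResult(
        fnat=fnat,
        irmsd=irmsd,
        lrmsd=lrmsd,
        score=score,
        category=categorize_dockq(score, config),
    )


def peptide_rmsd_after_protein_alignment(
    native: ComplexStructure,
    predicted: ComplexStructure,
    atoms: Literal["backbone", "CA"] = "backbone",
) -> float:
    """Peptide RMSD in the receptor frame.

    The predicted receptor backbone is superposed onto the native receptor
    backbone; the RMSD is then evaluated over the N peptide backbone atoms
    (or alpha carbons) without re-fitting: sqrt((1/N) Σ |pred_i − nat_i|²).
    """
    nat_rec = select_atoms(native.receptor, "backbone")
    pred_rec = select_atoms(predicted.receptor, "backbone")
    if len(nat_rec) == 0 or len(nat_rec) != len(pred_rec):
        raise ValueError("no shared receptor backbone atoms for alignment")
    sup = superpose_kabsch(nat_rec.coords, pred_rec.coords)
    nat_pep = select_atoms(native.peptide, atoms)
    pred_pep = select_atoms(predicted.peptide, atoms)
    if len(nat_pep) == 0 or len(nat_pep) != len(pred_pep):
        raise ValueError("peptide atom selections do not correspond")
    moved = sup.apply(pred_pep.coords)
    return float(np.sqrt(np.mean(np.sum((moved - nat_pep.coords) ** 2, axis=1))))


def atomic_accuracy(
    native: ComplexStructure,
    predicted: ComplexStructure,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> AtomicAccuracyResult:
    """Atomic-accuracy criterion: >90% native contacts recovered, no clashes,
    peptide all-atom RMSD < 2 Å and interface all-atom RMSD < 3 Å.

    The peptide all-atom RMSD is evaluated in the receptor-backbone frame;
    the interface all-atom RMSD over native interface residues (10 Å rule)
    after superposing on their heavy atoms. A clash is any inter-chain
    heavy-atom distance under 2 Å in the prediction.
    """
    _check_correspondence(native, predicted)
    nat_contacts = native_contacts(native, config.contact_cutoff)
    if len(nat_contacts) == 0:
        raise ValueError("native complex has no inter-chain contacts")
    pred_contacts = native_contacts(predicted, config.contact_cutoff)
    fnat = len(nat_contacts.pairs & pred_contacts.pairs) / len(nat_contacts.pairs)

    pred_rec_heavy = _heavy_coords_for(
        predicted.receptor, [r.seq_index for r in predicted.receptor]
    )
    pred_pep_heavy = _heavy_coords_for(
        predicted.peptide, [r.seq_index for r in predicted.peptide]
    )
    clash_count = int(np.sum(cdist(pred_rec_heavy, pred_pep_heavy) < config.clash_cutoff))

    nat_rec = select_atoms(native.receptor, "backbone")
    pred_rec = select_atoms(predicted.receptor, "backbone")
    sup = superpose_kabsch(nat_rec.coords, pred_rec.coords)
    nat_pep_heavy = _heavy_coords_for(native.peptide, [r.seq_index for r in native.peptide])
    moved_pep = sup.apply(pred_pep_heavy)
    if moved_pep.shape != nat_pep_heavy.shape:
        raise ValueError("peptide heavy-atom sets do not correspond")
    pep_rmsd = float(np.sqrt(np.mean(np.sum((moved_pep - nat_pep_heavy) ** 2, axis=1))))

    rec_if, pep_if = _interface_residues(native, config.interface_cutoff)
    nat_if = np.vstack(
        [_heavy_coords_for(native.receptor, rec_if), _heavy_coords_for(native.peptide, pep_if)]
    )
    pred_if = np.vstack(
        [
            _heavy_coords_for(predicted.receptor, rec_if),
            _heavy_coords_for(predicted.peptide, pep_if),
        ]
    )
    if nat_if.shape != pred_if.shape:
        raise ValueError("interface heavy-atom sets do not correspond")
    if_rmsd = superpose_kabsch(nat_if, pred_if).rmsd

    passed = (
        fnat > config.atomic_fnat_min
        and clash_count == 0
        and pep_rmsd < config.atomic_peptide_rmsd_max
        and if_rmsd < config.atomic_interface_rmsd_max
    )
    return AtomicAccuracyResult(
        fnat=fnat,
        clash_count=clash_count,
        peptide_allatom_rmsd=pep_rmsd,
        interface_allatom_rmsd=if_rmsd,
        passed=passed,
    )


def _tm_d0(length: int) -> float:
    if length <= 15:
        return 0.5
    return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def tm_score(native_receptor: Chain, predicted_receptor: Chain) -> float:
    """TM-score between two conformations of the same chain (Cα-based).

    score = max over superpositions of (1/L) Σ 1/(1+(dᵢ/d0)²), with
    d0 = 1.24·(L−15)^⅓ − 1.8 floored at 0.5. The maximum is sought with the
    standard iterative scheme: fragment seeds of length L, L/2 and 4 at every
    4th position, each refined by repeatedly superposing on the residues
    currently within a growing distance cutoff.
    """
    nat = select_atoms(native_receptor, "CA").coords
    pred = select_atoms(predicted_receptor, "CA").coords
    if nat.shape != pred.shape:
        raise ValueError("chains must have equal length CA traces")
    L = nat.shape[0]
    if L < 3:
        raise ValueError("TM-score needs at least 3 residues")
    d0 = _tm_d0(L)

    def score_for(sup: SuperpositionResult) -> float:
        d = np.linalg.norm(sup.apply(pred) - nat, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    best = 0.0
    frag_lens = sorted({L, max(L // 2, 4), 4})
    for flen in frag_lens:
        for start in range(0, L - flen + 1, 4):
            idx = np.arange(start, start + flen)
            try:
                sup = superpose_kabsch(nat[idx], pred[idx])
            except ValueError:
                continue
            best = max(best, score_for(sup))
            # iterative extension with growing inclusion cutoff
            for extra in (1.0, 2.0, 3.0, 4.0):
                cutoff = d0 + extra
                cur = idx
                for _ in range(20):
                    d = np.linalg.norm(sup.apply(pred) - nat, axis=1)
                    sel = np.where(d < cutoff)[0]
                    if sel.size < 3 or np.array_equal(sel, cur):
                        break
                    cur = sel
                    try:
                        sup = superpose_kabsch(nat[sel], pred[sel])
                    except ValueError:
                        break
                    best = max(best, score_for(sup))
    return best


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(math.degrees(math.atan2(y, x)))


def assign_secondary_structure(chain: Chain) -> SSAssignment:
    """Simplified dihedral-based secondary structure (H/E/L).

    A residue is a helix candidate when φ∈(−100°,−30°) and ψ∈(−80°,−5°),
    and a strand candidate when φ∈(−170°,−40°) and ψ∈(90°,180°]. Candidates
    are promoted to H (runs of ≥4) or E (runs of ≥3); everything else,
    including chain termini with undefined dihedrals, is loop L. This is a
    deterministic stand-in for hydrogen-bond-based assignments such as DSSP.
    """
    n = len(chain.residues)
    cand = ["L"] * n
    for i, res in enumerate(chain.residues):
        if i == 0 or i == n - 1:
            continue
        prev, nxt = chain.residues[i - 1], chain.residues[i + 1]
        needed = (prev.get_atom("C"), res.get_atom("N"), res.get_atom("CA"),
                  res.get_atom("C"), nxt.get_atom("N"))
        if any(a is None for a in needed):
            continue
        c_prev, n_i, ca_i, c_i, n_next = (a.coords for a in needed)
        phi = _dihedral(c_prev, n_i, ca_i, c_i)
        psi = _dihedral(n_i, ca_i, c_i, n_next)
        if -100 < phi < -30 and -80 < psi < -5:
            cand[i] = "H"
        elif -170 < phi < -40 and 90 < psi <= 180:
            cand[i] = "E"

    labels = ["L"] * n
    i = 0
    while i < n:
        j = i
        while j < n and cand[j] == cand[i]:
            j += 1
        run = j - i
        if cand[i] == "H" and run >= 4:
            labels[i:j] = ["H"] * run
        elif cand[i] == "E" and run >= 3:
            labels[i:j] = ["E"] * run
        i = j
    return SSAssignment(labels="".join(labels))
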