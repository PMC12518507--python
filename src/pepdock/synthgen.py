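"""Seeded generators for every input class the pipeline consumes.

Builds ideal-geometry two-chain complexes (helix-vs-helix or paired-strand
toys with a controllable number of native contacts), controlled-error
"predictions" (rigid translation/rotation, per-atom noise, wrong-site
relocation), synthetic receptor/peptide MSAs with planted per-column
conservation and inter-chain coevolving column pairs of exact analytic
mutual information, and dated match libraries with planted homologs. Every
generator is a pure function of its spec (seed included), so fixtures are
reproducible byte-for-byte and nothing needs to be downloaded or stored.

Backbones use ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, standard angles) with Cβ stubs; there is no sidechain packing
and no pretence of physical energetics — the point is exact, controllable
geometry for metric testing.
"""

from __future__ import annotations

import copy
import datetime
import math
from dataclasses import dataclass, field

import numpy as np

from .bindsite import MatchLibraryEntry
from .dockmetrics import native_contacts
from .msatools import AMINO_ACIDS, Msa, MsaRow
from .structio import Atom, Chain, ComplexStructure, ONE_TO_THREE, Residue

__all__ = [
    "ToyComplexSpec",
    "PerturbationSpec",
    "SyntheticMsaSpec",
    "make_toy_complex",
    "perturb_prediction",
    "make_synthetic_msas",
    "make_match_library",
    "mixture_mi",
    "solve_mixture_weight",
]

# ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_C_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.1

GEOMETRIES = {
    "helix-vs-helix": (-60.0, -45.0),
    "strand-pairing": (-120.0, 135.0),
}


@dataclass
class ToyComplexSpec:
    receptor_len: int = 60
    peptide_len: int = 12
    geometry: str = "helix-vs-helix"
    min_contacts: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.receptor_len > self.peptide_len >= 3:
            raise ValueError("need receptor_len > peptide_len >= 3")
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {sorted(GEOMETRIES)}")


@dataclass
class PerturbationSpec:
    translation: float = 0.0          # Å, rigid peptide translation magnitude
    rotation: float = 0.0             # degrees about a seeded axis through the peptide centroid
    internal_noise_sigma: float = 0.0 # Å, per-atom Gaussian
    wrong_site: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.translation, self.rotation, self.internal_noise_sigma) < 0:
            raise ValueError("perturbation magnitudes must be non-negative")


@dataclass
class SyntheticMsaSpec:
    depth: int = 500
    receptor_len: int = 40
    peptide_len: int = 10
    conserved_fraction: float = 0.2
    coevolving_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    species_pool: int | None = None   # None → one species per row pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        for r, p, bits in self.coevolving_pairs:
            if not (0 <= r < self.receptor_len and 0 <= p < self.peptide_len):
                raise ValueError(f"coevolving pair ({r},{p}) out of range")
            if bits < 0 or bits > math.log2(len(AMINO_ACIDS)):
                raise ValueError("target MI outside [0, log2(20)]")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from reference frame (a, b, c) by internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(ang),
        -bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_chain(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    chain_id: str,
    role: str,
) -> Chain:
    """Ideal backbone (N, CA, C, O and Cβ stub) from per-residue dihedrals."""
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    C[0] = CA[0] + np.array([-B_CA_C * math.cos(ang), B_CA_C * math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi_prev)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi_psi[i][0])

    residues = []
    for i, aa in enumerate(sequence):
        psi = phi_psi[i][1]
        O = _nerf(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi - 180.0)
        atoms = [
            Atom("N", "N", N[i]),
            Atom("CA", "C", CA[i]),
            Atom("C", "C", C[i]),
            Atom("O", "O", O),
        ]
        if aa != "G":
            CB = _nerf(N[i], C[i], CA[i], B_CA_CB, A_C_CA_CB, 122.5)
            atoms.append(Atom("CB", "C", CB))
        residues.append(
            Residue(name3=ONE_TO_THREE.get(aa, "ALA"), seq_index=i,
                    auth_number=str(i + 1), atoms=atoms)
        )
    return Chain(id=chain_id, role=role, residues=residues)


def _chain_coords(chain: Chain) -> np.ndarray:
    return np.vstack([a.coords for r in chain.residues for a in r.atoms])


def _transform_chain(chain: Chain, rot: np.ndarray, trans: np.ndarray) -> None:
    for res in chain.residues:
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + trans


def _principal_frame(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, rotation) that maps the chain's principal axis onto x."""
    coords = _chain_coords(chain)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    rot = vt  # rows are principal directions; row 0 → x
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    return centroid, rot


def _min_interchain_distance(c: ComplexStructure) -> float:
    from scipy.spatial.distance import cdist

    rec = _chain_coords(c.receptor)
    pep = _chain_coords(c.peptide)
    return float(cdist(rec, pep).min())


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def make_toy_complex(spec: ToyComplexSpec) -> ComplexStructure:
    """Ideal-geometry receptor+peptide complex with at least ``min_contacts``
    native contacts, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    phi, psi = GEOMETRIES[spec.geometry]
    rec_seq = _random_sequence(rng, spec.receptor_len)
    pep_seq = _random_sequence(rng, spec.peptide_len)
    receptor = _build_chain(rec_seq, [(phi, psi)] * spec.receptor_len, "A", "receptor")
    peptide = _build_chain(pep_seq, [(phi, psi)] * spec.peptide_len, "B", "peptide")

    # receptor: principal axis on x, centroid at origin
    cen, rot = _principal_frame(receptor)
    _transform_chain(receptor, rot, -rot @ cen)
    # peptide: same alignment, then offset along +y
    cen, rot = _principal_frame(peptide)
    _transform_chain(peptide, rot, -rot @ cen)

    complex_ = ComplexStructure(
        id=f"SYN{spec.seed}_AB", receptor=receptor, peptide=peptide,
        release_date=datetime.date(2020, 1, 1),
    )
    for x_shift in (0.0, 4.0, -4.0, 8.0, -8.0):
        placed = _dock_at(complex_, x_shift=x_shift, y_sign=+1.0)
        if placed and len(native_contacts(complex_, 5.0)) >= spec.min_contacts:
            return complex_
    raise RuntimeError("could not place peptide with the requested contact count")


def _dock_at(complex_: ComplexStructure, x_shift: float, y_sign: float,
             target_gap: float = 4.0) -> bool:
    """Slide the peptide radially (along ±y) until the closest inter-chain
    heavy-atom distance is ~``target_gap`` Å. Mutates the peptide in place."""
    pep = complex_.peptide
    cen = _chain_coords(pep).mean(axis=0)
    # start far out at the requested axial position
    start = np.array([x_shift, y_sign * 40.0, 0.0])
    _transform_chain(pep, np.eye(3), start - cen)
    direction = np.array([0.0, -y_sign, 0.0])
    for _ in range(400):
        d = _min_interchain_distance(complex_)
        if d <= target_gap:
            if d < 2.5:  # stepped too deep; back off
                _transform_chain(pep, np.eye(3), -direction * (2.5 - d + 0.1))
            return True
        _transform_chain(pep, np.eye(3), direction * max(0.25, (d - target_gap) * 0.8))
    return False


def copy_complex(c: ComplexStructure) -> ComplexStructure:
    return copy.deepcopy(c)


def _rotation_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(degrees)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def perturb_prediction(native: ComplexStructure, spec: PerturbationSpec) -> ComplexStructure:
    """Controlled-error "prediction": receptor untouched, peptide transformed.

    Order of operations: wrong-site relocation, then rotation about a seeded
    random axis through the peptide centroid, then rigid translation of the
    requested magnitude along a seeded direction whose component away from
    the receptor is non-negative (so growing magnitudes leave the
    interface), then per-atom Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    pred = copy_complex(native)
    pred.id = f"{native.id}_pred"
    pep = pred.peptide
    rec_cen = _chain_coords(pred.receptor).mean(axis=0)

    if spec.wrong_site:
        pep_cen = _chain_coords(pep).mean(axis=0)
        cen, frame = _principal_frame(pred.receptor)
        radial = pep_cen - cen
        axis = frame[0]
        radial -= np.dot(radial, axis) * axis
        axial_span = np.ptp((_chain_coords(pred.receptor) - cen) @ axis)
        shift_ax = (1.0 if rng.random() < 0.5 else -1.0) * axial_span / 3.0
        # mirror to the opposite face and move along the receptor axis
        target = pep_cen - 2.0 * radial + shift_ax * axis
        _transform_chain(pep, np.eye(3), target - pep_cen)
        _dock_wrong_site(pred)
        new_cen = _chain_coords(pep).mean(axis=0)
        if np.linalg.norm(new_cen - pep_cen) < 20.0:
            # push further along the axis until the displacement rule holds
            _transform_chain(pep, np.eye(3), shift_ax * axis)

    if spec.rotation > 0:
        axis = rng.normal(size=3)
        cen = _chain_coords(pep).mean(axis=0)
        rot = _rotation_matrix(axis, spec.rotation)
        _transform_chain(pep, rot, cen - rot @ cen)

    if spec.translation > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        away = _chain_coords(pep).mean(axis=0) - rec_cen
        away /= np.linalg.norm(away)
        if np.dot(direction, away) < 0:
            direction -= 2.0 * np.dot(direction, away) * away
            direction /= np.linalg.norm(direction)
        _transform_chain(pep, np.eye(3), direction * spec.translation)

    if spec.internal_noise_sigma > 0:
        for res in pep.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, spec.internal_noise_sigma, 3)
    return pred


def _dock_wrong_site(complex_: ComplexStructure, target_gap: float = 4.0) -> None:
    """Pull the (already relocated) peptide radially until it touches the receptor."""
    from scipy.spatial.distance import cdist

    pep = complex_.peptide
    rec = _chain_coords(complex_.receptor)
    for _ in range(400):
        pc = _chain_coords(pep)
        d = cdist(rec, pc)
        if d.min() <= target_gap:
            return
        i, j = np.unravel_index(d.argmin(), d.shape)
        step = rec[i] - pc[j]
        step /= np.linalg.norm(step)
        _transform_chain(pep, np.eye(3), step * max(0.25, (d.min() - target_gap) * 0.8))


# --- synthetic MSAs -------------------------------------------------------

def mixture_mi(w: float, k: int) -> float:
    """Analytic MI (bits) of the mixture P(a,b) = w/k·δ_ab + (1−w)/k² on k symbols."""
    pd_ = w / k + (1 - w) / k**2
    po = (1 - w) / k**2
    mi = k * pd_ * math.log2(pd_ * k**2)
    if po > 0:
        mi += (k**2 - k) * po * math.log2(po * k**2)
    return mi


def solve_mixture_weight(target_bits: float, k: int, tol: float = 1e-6) -> float:
    """Mixing weight whose mixture MI equals ``target_bits`` (bisection)."""
    if target_bits < 0 or target_bits > math.log2(k):
        raise ValueError(f"target MI {target_bits} infeasible for {k} symbols")
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-12:
        mid = (lo + hi) / 2
        if mixture_mi(mid, k) < target_bits:
            lo = mid
        else:
            hi = mid
        if abs(mixture_mi(mid, k) - target_bits) < tol:
            return mid
    return (lo + hi) / 2


def make_synthetic_msas(spec: SyntheticMsaSpec) -> tuple[Msa, Msa]:
    """Receptor and peptide MSAs with planted conservation and coevolution.

    Row i of both MSAs carries the same species tag, so species pairing
    reconstitutes the generating pairs (by default one species per row).
    Conserved columns put 90% of their mass on one symbol; coevolving column
    pairs are sampled jointly from a correlated/independent mixture over a
    4-symbol sub-alphabet whose analytic MI equals the target.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    depth = spec.depth
    pool = spec.species_pool if spec.species_pool is not None else depth

    def sample_independent(n_cols: int, conserved: np.ndarray) -> np.ndarray:
        cols = np.empty((depth, n_cols), dtype="<U1")
        for c in range(n_cols):
            if conserved[c]:
                major = rng.integers(len(aas))
                p = np.full(len(aas), 0.1 / (len(aas) - 1))
                p[major] = 0.9
            else:
                p = np.full(len(aas), 1.0 / len(aas))
            cols[:, c] = rng.choice(aas, size=depth, p=p)
        return cols

    n_cons_r = int(round(spec.conserved_fraction * spec.receptor_len))
    n_cons_p = int(round(spec.conserved_fraction * spec.peptide_len))
    cons_r = np.zeros(spec.receptor_len, dtype=bool)
    cons_p = np.zeros(spec.peptide_len, dtype=bool)
    coev_r = {r for r, _, _ in spec.coevolving_pairs}
    coev_p = {p for _, p, _ in spec.coevolving_pairs}
    free_r = [i for i in range(spec.receptor_len) if i not in coev_r]
    free_p = [i for i in range(spec.peptide_len) if i not in coev_p]
    cons_r[rng.choice(free_r, size=min(n_cons_r, len(free_r)), replace=False)] = True
    cons_p[rng.choice(free_p, size=min(n_cons_p, len(free_p)), replace=False)] = True

    rec = sample_independent(spec.receptor_len, cons_r)
    pep = sample_independent(spec.peptide_len, cons_p)

    k = 4
    for r_col, p_col, bits in spec.coevolving_pairs:
        sub = rng.choice(len(aas), size=k, replace=False)
        w = solve_mixture_weight(bits, k)
        correlated = rng.random(depth) < w
        a = rng.integers(0, k, size=depth)
        b = np.where(correlated, a, rng.integers(0, k, size=depth))
        rec[:, r_col] = aas[sub[a]]
        pep[:, p_col] = aas[sub[b]]

    def to_msa(cols: np.ndarray, prefix: str) -> Msa:
        rows = []
        for i in range(depth):
            sp = f"sp{i % pool}"
            rid = "query" if i == 0 else f"{prefix}{i}"
            rows.append(MsaRow(id=rid, aligned="".join(cols[i]), species=sp))
        return Msa(rows=rows)

    return to_msa(rec, "r"), to_msa(pep, "p")


# --- match libraries ------------------------------------------------------

def _jitter_complex(c: ComplexStructure, rng: np.random.Generator,
                    sigma: float = 0.2) -> ComplexStructure:
    out = copy_complex(c)
    for chain in out.chains():
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, sigma, 3)
    return out


def _mutate_sequence(c: ComplexStructure, rng: np.random.Generator,
                     fraction: float = 0.2) -> None:
    """Rename a fraction of receptor residues (keeps atoms; new Gly keeps its CB
    stub dropped)."""
    aas = [a for a in AMINO_ACIDS if a != "G"]
    for res in c.receptor.residues:
        if rng.random() < fraction:
            res.name3 = ONE_TO_THREE[aas[rng.integers(len(aas))]]


def make_match_library(
    query: ComplexStructure,
    n_match: int,
    n_homolog_nonmatch: int,
    n_nonhomolog: int,
    date_window: tuple[datetime.date, datetime.date],
    cutoff_date: datetime.date,
    seed: int = 0,
    n_post_cutoff_match: int = 1,
) -> tuple[list[MatchLibraryEntry], int]:
    """Dated library with planted binding-site matches.

    Matches are lightly perturbed copies of the query (receptor homologous
    by both arms, partner within the 10 Å window RMSD) dated inside
    ``date_window``; homolog non-matches carry their partner displaced far
    from the query peptide; non-homologs are random-coil decoys with random
    sequences; post-cutoff entries are match-like but dated after
    ``cutoff_date`` and must be excluded by the date rule. Returns the
    entries and the expected match count (= ``n_match``).
    """
    rng = np.random.default_rng(seed)
    earliest, latest = date_window
    span = (latest - earliest).days

    def random_date() -> datetime.date:
        return earliest + datetime.timedelta(days=int(rng.integers(0, max(span, 1))))

    entries: list[MatchLibraryEntry] = []
    for i in range(n_match):
        c = _jitter_complex(query, rng)
        _mutate_sequence(c, rng)
        c.id = f"MAT{i}_AB"
        entries.append(MatchLibraryEntry(c, random_date(), f"MAT{i}"))
    for i in range(n_homolog_nonmatch):
        c = _jitter_complex(query, rng)
        _mutate_sequence(c, rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        _transform_chain(c.peptide, np.eye(3), direction * 25.0)
        c.id = f"HNM{i}_AB"
        entries.append(MatchLibraryEntry(c, random_date(), f"HNM{i}"))
    for i in range(n_nonhomolog):
        rec_len = len(query.receptor.residues)
        pep_len = len(query.peptide.residues)
        coil = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                for _ in range(rec_len)]
        receptor = _build_chain(_random_sequence(rng, rec_len), coil, "A", "receptor")
        peptide = _build_chain(
            _random_sequence(rng, pep_len),
            [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
             for _ in range(pep_len)],
            "B", "peptide",
        )
        _transform_chain(peptide, np.eye(3), np.array([50.0, 0.0, 0.0]))
        c = ComplexStructure(id=f"NH{i}_AB", receptor=receptor, peptide=peptide,
                             release_date=random_date())
        entries.append(MatchLibraryEntry(c, c.release_date, f"NH{i}"))
    for i in range(n_post_cutoff_match):
        c = _jitter_complex(query, rng)
        c.id = f"PCM{i}_AB"
        late = cutoff_date + datetime.timedelta(days=int(rng.integers(1, 365)))
        entries.append(MatchLibraryEntry(c, late, f"PCM{i}"))
    return entries, n_match
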