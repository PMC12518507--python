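"""Distograms and the RMSD_map contact-map comparison statistic.

A distogram is an L×L matrix of representative inter-residue distances over
the concatenated receptor+peptide residues, with a chain split index. For
predictions that emit per-pair distance-bin probabilities, the distribution
is collapsed to a representative distance first. RMSD_map compares native
and predicted distograms over the native inter-chain contact pairs:

    RMSD_map = sqrt( (1/Nc) Σ_(i,j) (Dnat_ij − Dpred_ij)² )

where the sum runs over the Nc inter-chain pairs whose native representative
distance is at most the contact cutoff (default 12 Å). A masked-peptide
prediction counts as a docking success when RMSD_map < 2.5 Å; a predicted
peptide pose is acceptable when its peptide RMSD < 12 Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .structio import ComplexStructure, select_atoms

__all__ = [
    "Distogram",
    "RmsdMapResult",
    "distogram_from_structure",
    "collapse_bins",
    "rmsd_map",
    "classify_masked_success",
    "classify_peptide_rmsd_success",
    "write_distogram_tsv",
    "read_distogram_tsv",
]


@dataclass
class Distogram:
    distances: np.ndarray  # (L, L) symmetric, Å, zero diagonal
    chain_split: int       # receptor occupies rows/cols [0, chain_split)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distances must be square")
        if not np.allclose(d, d.T, atol=1e-6):
            raise ValueError("distances must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-6):
            raise ValueError("diagonal must be zero")
        if not 0 < self.chain_split < d.shape[0]:
            raise ValueError("chain_split must lie strictly inside the matrix")
        self.distances = d

    @property
    def n_residues(self) -> int:
        return self.distances.shape[0]


@dataclass
class RmsdMapResult:
    value: float
    n_contacts: int
    pair_set: frozenset[tuple[int, int]]  # (receptor index, peptide index) in concatenated numbering


def distogram_from_structure(complex_: ComplexStructure) -> Distogram:
    """Distogram of representative-atom (Cβ, Cα for Gly) distances."""
    rec = select_atoms(complex_.receptor, "CB_proxy")
    pep = select_atoms(complex_.peptide, "CB_proxy")
    if rec.skipped or pep.skipped:
        raise ValueError(
            f"residues without CB/CA representative atom: "
            f"receptor {rec.skipped}, peptide {pep.skipped}"
        )
    coords = np.vstack([rec.coords, pep.coords])
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return Distogram(distances=d, chain_split=len(rec))


def collapse_bins(probabilities: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Collapse distance-bin probability distributions to representative distances.

    ``probabilities`` has shape (..., B) and sums to 1 along the last axis
    (tolerance 1e-4); ``edges`` has B+1 bounds, the last possibly inf for an
    open final bin, whose midpoint is taken as its lower edge plus half the
    preceding bin's width. Returns the probability-weighted mean of midpoints.
    """
    p = np.asarray(probabilities, dtype=float)
    e = np.asarray(edges, dtype=float)
    if p.shape[-1] != e.size - 1:
        raise ValueError("probabilities last axis must match number of bins")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-4):
        raise ValueError("bin distributions must sum to 1 within 1e-4")
    mids = (e[:-1] + e[1:]) / 2.0
    if not np.isfinite(e[-1]):
        mids[-1] = e[-2] + (e[-2] - e[-3]) / 2.0
    return p @ mids


def rmsd_map(
    native: Distogram,
    predicted: Distogram,
    contact_cutoff: float | None = None,
) -> RmsdMapResult:
    """Root-mean-square deviation between distograms over native inter-chain contacts.

    The pair set is defined by the NATIVE distogram: inter-chain pairs with
    native distance ≤ ``contact_cutoff``. Errors if no native pair qualifies.
    """
    cutoff = DEFAULT_CONFIG.map_contact_cutoff if contact_cutoff is None else contact_cutoff
    if native.n_residues != predicted.n_residues or native.chain_split != predicted.chain_split:
        raise ValueError("distograms must share size and chain split")
    k = native.chain_split
    block_nat = native.distances[:k, k:]
    block_pred = predicted.distances[:k, k:]
    ii, jj = np.where(block_nat <= cutoff)
    if ii.size == 0:
        raise ValueError(f"no native inter-chain pair within {cutoff} Å")
    sq = (block_nat[ii, jj] - block_pred[ii, jj]) ** 2
    value = float(np.sqrt(sq.mean()))
    pairs = frozenset((int(i), int(j + k)) for i, j in zip(ii, jj))
    return RmsdMapResult(value=value, n_contacts=int(ii.size), pair_set=pairs)


def classify_masked_success(
    rmsd_map_value: float, threshold: float | None = None
) -> bool:
    """Masked-peptide docking success: RMSD_map strictly below 2.5 Å."""
    if rmsd_map_value < 0:
        raise ValueError("RMSD_map cannot be negative")
    t = DEFAULT_CONFIG.rmsd_map_success if threshold is None else threshold
    return rmsd_map_value < t


def classify_peptide_rmsd_success(rmsd: float, threshold: float | None = None) -> bool:
    """Acceptable peptide pose: peptide RMSD strictly below 12 Å."""
    if rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    t = DEFAULT_CONFIG.peptide_rmsd_success if threshold is None else threshold
    return rmsd < t


def write_distogram_tsv(disto: Distogram, path: str | Path) -> None:
    """Serialize as a TSV of (i, j, distance) triplets (upper triangle).

    The header records L and the chain split, keeping the file self-describing.
    """
    lines = [f"#L={disto.n_residues}\tchain_split={disto.chain_split}", "i\tj\tdistance"]
    L = disto.n_residues
    for i in range(L):
        for j in range(i + 1, L):
            lines.append(f"{i}\t{j}\t{disto.distances[i, j]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distogram_tsv(path: str | Path) -> Distogram:
    lines = Path(path).read_text().splitlines()
    header = lines[0]
    if not header.startswith("#L="):
        raise ValueError(f"{path}: missing distogram header")
    fields = dict(part.split("=") for part in header[1:].split("\t"))
    L = int(fields["L"])
    split = int(fields["chain_split"])
    d = np.zeros((L, L))
    for line in lines[2:]:
        if not line.strip():
            continue
        i_s, j_s, v_s = line.split("\t")
        i, j = int(i_s), int(j_s)
        d[i, j] = d[j, i] = float(v_s)
    return Distogram(distances=d, chain_split=split)
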