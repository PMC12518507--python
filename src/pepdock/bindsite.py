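"""Binding sites and training-library binding-site-match search.

A binding site is the set of receptor residues in heavy-atom contact with
the peptide. The match search asks whether a dated library (a stand-in for
a model's training set) already contains the interaction: an entry counts
as a binding-site match when (1) it was released before the cutoff date,
(2) its receptor is homologous to the query receptor by sequence identity
or by structure (TM-score), and (3) after superposing the entry receptor
onto the query receptor, its bound partner lies within a partner-RMSD
threshold (default 10 Å, Cα) of the query peptide.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from .config import DEFAULT_CONFIG, PipelineConfig
from .dockmetrics import superpose_kabsch, tm_score
from .msatools import KYTE_DOOLITTLE, ConservationProfile, mean_hydrophobicity
from .structio import Chain, ComplexStructure, chain_sequence, select_atoms

__all__ = [
    "BindingSite",
    "MatchLibraryEntry",
    "MatchResult",
    "SiteStats",
    "interface_residues",
    "sequence_identity",
    "find_binding_site_matches",
    "site_overlap",
    "site_profile_stats",
    "read_library_manifest",
]


@dataclass
class BindingSite:
    residues: frozenset[int]  # receptor seq_indices
    cutoff: float

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MatchLibraryEntry:
    complex: ComplexStructure
    release_date: datetime.date
    entry_id: str


@dataclass
class MatchResult:
    n_matches: int
    matches: list[tuple[str, float, str]]  # (entry_id, partner_rmsd, evidence)
    n_candidates_after_date: int
    empty_library: bool = False


@dataclass
class SiteStats:
    mean_jsd_site: float
    mean_jsd_nonsite: float
    mean_hydrophobicity_site: float
    mean_hydrophobicity_nonsite: float


def interface_residues(
    complex_: ComplexStructure, cutoff: float | None = None
) -> BindingSite:
    """Receptor residues with any heavy atom under ``cutoff`` of any peptide heavy atom."""
    cutoff = DEFAULT_CONFIG.contact_cutoff if cutoff is None else cutoff
    pep = np.vstack([r.heavy_coords() for r in complex_.peptide])
    site = set()
    for res in complex_.receptor:
        rc = res.heavy_coords()
        if rc.size and cdist(rc, pep).min() < cutoff:
            site.add(res.seq_index)
    return BindingSite(residues=frozenset(site), cutoff=cutoff)


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-0.5,
    extend_gap_score=-0.1,
)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity: identical aligned positions / shorter length."""
    if not seq_a or not seq_b:
        return 0.0
    aln = _aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(1 for i, j in zip(range(a0, a1), range(b0, b1))
                       if seq_a[i] == seq_b[j])
    return matches / min(len(seq_a), len(seq_b))


def _windowed_ca_rmsd(query_pep: np.ndarray, partner: np.ndarray) -> float:
    """Cα RMSD with best contiguous window correspondence, no re-superposition.

    The shorter trace is slid along the longer one; the minimum positional
    RMSD over all offsets is returned.
    """
    a, b = (query_pep, partner) if len(query_pep) <= len(partner) else (partner, query_pep)
    n, m = len(a), len(b)
    best = np.inf
    for off in range(m - n + 1):
        rmsd = float(np.sqrt(np.mean(np.sum((a - b[off: off + n]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def find_binding_site_matches(
    query: ComplexStructure,
    library: list[MatchLibraryEntry],
    cutoff_date: datetime.date,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> MatchResult:
    """Search a dated library for binding-site matches to the query complex.

    Entries released on or after ``cutoff_date`` are dropped first. A
    remaining entry matches when its receptor is homologous to the query
    receptor (sequence identity or TM-score arm; either suffices, both
    config-gated) and, after superposing the entry receptor onto the query
    receptor, the entry's partner chain lies within the partner-RMSD
    threshold of the query peptide (Cα, best contiguous window when lengths
    differ).
    """
    candidates = [e for e in library if e.release_date < cutoff_date]
    if not candidates:
        return MatchResult(
            n_matches=0, matches=[], n_candidates_after_date=0, empty_library=True
        )
    q_seq = chain_sequence(query.receptor)
    q_rec_ca = select_atoms(query.receptor, "CA").coords
    q_pep_ca = select_atoms(query.peptide, "CA").coords
    if len(q_rec_ca) < 3:
        raise ValueError("query receptor needs at least 3 CA atoms")
    matches = []
    for entry in candidates:
        e_rec = entry.complex.receptor
        e_seq = chain_sequence(e_rec)
        seq_hit = (
            config.use_sequence_homology
            and sequence_identity(q_seq, e_seq) >= config.seq_identity_min
        )
        e_rec_ca = select_atoms(e_rec, "CA").coords
        struct_hit = False
        if config.use_structure_homology and len(e_rec_ca) == len(q_rec_ca):
            struct_hit = tm_score(query.receptor, e_rec) >= config.tm_score_min
        if not (seq_hit or struct_hit):
            continue
        evidence = "both" if (seq_hit and struct_hit) else ("sequence" if seq_hit else "structure")
        if len(e_rec_ca) == len(q_rec_ca):
            sup = superpose_kabsch(q_rec_ca, e_rec_ca)
        else:
            # correspondence from the global sequence alignment
            aln = _aligner.align(q_seq, e_seq)[0]
            qi, ei = [], []
            for (a0, a1), (b0, b1) in zip(*aln.aligned):
                qi.extend(range(a0, a1))
                ei.extend(range(b0, b1))
            if len(qi) < 3:
                continue
            sup = superpose_kabsch(q_rec_ca[qi], e_rec_ca[ei])
        partner_ca = sup.apply(select_atoms(entry.complex.peptide, "CA").coords)
        rmsd = _windowed_ca_rmsd(q_pep_ca, partner_ca)
        if rmsd < config.partner_rmsd_threshold:
            matches.append((entry.entry_id, rmsd, evidence))
    return MatchResult(
        n_matches=len(matches),
        matches=matches,
        n_candidates_after_date=len(candidates),
    )


def site_overlap(site_a: BindingSite, site_b: BindingSite) -> float:
    """Jaccard index between two binding sites on the same receptor."""
    if not site_a.residues and not site_b.residues:
        raise ValueError("both sites empty: overlap undefined")
    union = site_a.residues | site_b.residues
    return len(site_a.residues & site_b.residues) / len(union)


def same_site(
    site_a: BindingSite, site_b: BindingSite, config: PipelineConfig = DEFAULT_CONFIG
) -> bool:
    """Two sites are "the same site" when their Jaccard overlap reaches the threshold."""
    return site_overlap(site_a, site_b) >= config.same_site_jaccard


def site_profile_stats(
    site: BindingSite,
    profile: ConservationProfile,
    sequence: str,
    scale: dict[str, float] = KYTE_DOOLITTLE,
) -> SiteStats:
    """Mean conservation and hydrophobicity over site vs non-site receptor residues."""
    n = len(sequence)
    if profile.jsd.size != n:
        raise ValueError("conservation profile length must equal receptor length")
    site_idx = sorted(site.residues)
    non_idx = [i for i in range(n) if i not in site.residues]
    if not site_idx or not non_idx:
        raise ValueError("site and complement must both be non-empty")
    return SiteStats(
        mean_jsd_site=float(np.mean(profile.jsd[site_idx])),
        mean_jsd_nonsite=float(np.mean(profile.jsd[non_idx])),
        mean_hydrophobicity_site=mean_hydrophobicity(
            "".join(sequence[i] for i in site_idx), scale
        ),
        mean_hydrophobicity_nonsite=mean_hydrophobicity(
            "".join(sequence[i] for i in non_idx), scale
        ),
    )


def read_library_manifest(path: str | Path) -> list[dict]:
    """Parse a TSV manifest: entry_id, path, receptor_chain, partner_chain, release_date."""
    rows = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        rec = dict(zip(header, line.split("\t")))
        rec["release_date"] = datetime.date.fromisoformat(rec["release_date"])
        rows.append(rec)
    return rows
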