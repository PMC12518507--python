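"""MSA handling: I/O, context trimming, species pairing, shuffling null,
mutual information, Jensen-Shannon conservation, hydrophobicity, and
peptide-sequence ablations.

A paired MSA concatenates a receptor alignment block and a peptide alignment
block row-wise: rows whose receptor and peptide sequences come from the same
species are genuinely paired; remaining rows are kept block-diagonally, i.e.
gap-filled in the other chain's block. Inter-chain mutual information over
the paired rows is the coevolution readout; shuffling the peptide halves of
the paired rows provides the null in which the pairing (and hence any
inter-chain covariation) is destroyed while all column compositions are
preserved.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.spatial.distance import jensenshannon

__all__ = [
    "MsaRow",
    "Msa",
    "PairedMsa",
    "ConservationProfile",
    "MiResult",
    "read_msa",
    "write_fasta",
    "map_context_columns",
    "pair_by_species",
    "shuffle_pairings",
    "column_mi",
    "interchain_mi_summary",
    "jsd_conservation",
    "peptide_sequence_variants",
    "mean_hydrophobicity",
    "msa_depth_ok",
    "KYTE_DOOLITTLE",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# default header patterns: UniProt "OX=<taxid>" tag, or "_SPECIES" id suffix
SPECIES_PATTERNS = (r"OX=(\S+)", r"^\S*_([A-Z0-9]{2,10})(?:\s|$)")


@dataclass
class MsaRow:
    id: str
    aligned: str
    species: str | None = None


@dataclass
class Msa:
    rows: list[MsaRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        widths = {len(r.aligned) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: widths {sorted(widths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].aligned)

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        return self.rows[0].aligned.replace(GAP, "")


@dataclass
class PairedMsa:
    rows: list[MsaRow]
    receptor_block: tuple[int, int]  # half-open column range
    peptide_block: tuple[int, int]
    paired_rows: int                 # rows non-gap in both blocks (query included)
    unpaired_receptor_rows: int
    unpaired_peptide_rows: int

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].aligned)

    def receptor_half(self, row: MsaRow) -> str:
        return row.aligned[self.receptor_block[0]: self.receptor_block[1]]

    def peptide_half(self, row: MsaRow) -> str:
        return row.aligned[self.peptide_block[0]: self.peptide_block[1]]


@dataclass
class ConservationProfile:
    jsd: np.ndarray           # per-column, [0, 1], gap-penalized
    gap_fraction: np.ndarray  # per-column
    flagged_columns: list[int] = field(default_factory=list)  # all-gap columns


@dataclass
class MiResult:
    per_pair: pd.DataFrame    # columns: receptor_col, peptide_col, mi_bits
    mean_interchain: float
    max_interchain: float


def _parse_species(header: str, patterns=SPECIES_PATTERNS) -> str | None:
    for pat in patterns:
        m = re.search(pat, header)
        if m:
            return m.group(1)
    return None


def read_msa(path: str | Path, format: str | None = None) -> Msa:
    """Read an alignment (A3M, aligned FASTA or Stockholm); row 0 is the query.

    A3M lowercase insertion states are removed so that columns index query
    positions. Species tags are parsed from headers when present.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"a3m": "a3m", "sto": "stockholm", "stk": "stockholm"}.get(suffix, "fasta")
    rows: list[MsaRow] = []
    if format == "a3m":
        header, seq = None, []
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                if header is not None:
                    rows.append(_a3m_row(header, "".join(seq)))
                header, seq = line[1:].strip(), []
            elif line.strip() and header is not None:
                seq.append(line.strip())
        if header is not None:
            rows.append(_a3m_row(header, "".join(seq)))
    else:
        aln = AlignIO.read(str(path), format)
        for rec in aln:
            header = rec.description or rec.id
            rows.append(
                MsaRow(id=rec.id, aligned=str(rec.seq).upper().replace(".", GAP),
                       species=_parse_species(header))
            )
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return Msa(rows=rows)


def _a3m_row(header: str, seq: str) -> MsaRow:
    aligned = "".join(c for c in seq if not c.islower()).replace(".", GAP)
    first = header.split()[0] if header.split() else header
    return MsaRow(id=first, aligned=aligned, species=_parse_species(header))


def write_fasta(msa: Msa | PairedMsa, path: str | Path) -> None:
    lines = []
    if isinstance(msa, PairedMsa):
        r0, r1 = msa.receptor_block
        p0, p1 = msa.peptide_block
        lines.append(
            f"#receptor_block={r0}:{r1} peptide_block={p0}:{p1} paired_rows={msa.paired_rows}"
        )
    for row in msa.rows:
        tag = f" OX={row.species}" if row.species else ""
        lines.append(f">{row.id}{tag}")
        lines.append(row.aligned)
    Path(path).write_text("\n".join(lines) + "\n")


def map_context_columns(full_msa: Msa, peptide_span: tuple[int, int]) -> Msa:
    """Cut an alignment down to the columns of an inclusive query-position span.

    Used to trim a context-extended alignment (peptide plus flanking
    residues) back to any window, e.g. the structure-delimited peptide.
    """
    start, end = peptide_span
    if not (0 <= start <= end < full_msa.n_cols):
        raise ValueError(
            f"span {peptide_span} outside query columns [0, {full_msa.n_cols})"
        )
    rows = [
        MsaRow(id=r.id, aligned=r.aligned[start: end + 1], species=r.species)
        for r in full_msa.rows
    ]
    return Msa(rows=rows)


def _identity_to_query(row: MsaRow, query_aligned: str) -> float:
    matches = sum(
        1 for a, b in zip(row.aligned, query_aligned) if a == b and a != GAP
    )
    return matches / max(len(query_aligned), 1)


def pair_by_species(receptor_msa: Msa, peptide_msa: Msa) -> PairedMsa:
    """Concatenate two alignments into a species-paired MSA.

    Queries (row 0 of each) are always paired. Within each species, rows are
    ranked by percent identity to their query and rank-i is paired with
    rank-i. Leftovers and untagged rows go to the block-diagonal sections,
    gap-padded in the other chain's block.
    """
    n_r, n_p = receptor_msa.n_cols, peptide_msa.n_cols
    gap_r, gap_p = GAP * n_r, GAP * n_p

    def by_species(msa: Msa) -> tuple[dict[str, list[MsaRow]], list[MsaRow]]:
        tagged: dict[str, list[MsaRow]] = {}
        untagged: list[MsaRow] = []
        q = msa.rows[0].aligned
        for row in msa.rows[1:]:
            if row.species is None:
                untagged.append(row)
            else:
                tagged.setdefault(row.species, []).append(row)
        for rows in tagged.values():
            rows.sort(key=lambda r: -_identity_to_query(r, q))
        return tagged, untagged

    rec_tagged, rec_untagged = by_species(receptor_msa)
    pep_tagged, pep_untagged = by_species(peptide_msa)

    q_r, q_p = receptor_msa.rows[0], peptide_msa.rows[0]
    rows = [MsaRow(id=f"{q_r.id}|{q_p.id}", aligned=q_r.aligned + q_p.aligned,
                   species=q_r.species)]
    unpaired_r: list[MsaRow] = []
    unpaired_p: list[MsaRow] = []
    for sp in sorted(set(rec_tagged) | set(pep_tagged)):
        rs = rec_tagged.get(sp, [])
        ps = pep_tagged.get(sp, [])
        k = min(len(rs), len(ps))
        for i in range(k):
            rows.append(
                MsaRow(id=f"{rs[i].id}|{ps[i].id}",
                       aligned=rs[i].aligned + ps[i].aligned, species=sp)
            )
        unpaired_r.extend(rs[k:])
        unpaired_p.extend(ps[k:])
    unpaired_r.extend(rec_untagged)
    unpaired_p.extend(pep_untagged)
    paired_count = len(rows)
    for r in unpaired_r:
        rows.append(MsaRow(id=r.id, aligned=r.aligned + gap_p, species=r.species))
    for p in unpaired_p:
        rows.append(MsaRow(id=p.id, aligned=gap_r + p.aligned, species=p.species))
    return PairedMsa(
        rows=rows,
        receptor_block=(0, n_r),
        peptide_block=(n_r, n_r + n_p),
        paired_rows=paired_count,
        unpaired_receptor_rows=len(unpaired_r),
        unpaired_peptide_rows=len(unpaired_p),
    )


def shuffle_pairings(paired: PairedMsa, seed: int) -> PairedMsa:
    """Randomize which receptor row each peptide half sits next to.

    The peptide-block halves of the paired non-query rows are permuted
    uniformly at random (seeded). The query row and the block-diagonal
    unpaired sections are untouched; every block keeps the same multiset of
    sequences, so column statistics are preserved while inter-chain
    covariation is destroyed.
    """
    if paired.paired_rows < 1:
        raise ValueError("nothing to shuffle: no paired rows")
    rng = np.random.default_rng(seed)
    idx = np.arange(1, paired.paired_rows)
    perm = rng.permutation(idx)
    new_rows = list(paired.rows)
    for target, source in zip(idx, perm):
        rec_half = paired.receptor_half(paired.rows[target])
        pep_half = paired.peptide_half(paired.rows[source])
        old = paired.rows[target]
        new_rows[target] = MsaRow(
            id=f"{old.id.split('|')[0]}|shuf", aligned=rec_half + pep_half,
            species=old.species,
        )
    return PairedMsa(
        rows=new_rows,
        receptor_block=paired.receptor_block,
        peptide_block=paired.peptide_block,
        paired_rows=paired.paired_rows,
        unpaired_receptor_rows=paired.unpaired_receptor_rows,
        unpaired_peptide_rows=paired.unpaired_peptide_rows,
    )


def column_mi(
    msa: Msa | PairedMsa,
    col_a: int,
    col_b: int,
    include_gaps: bool = False,
) -> float:
    """Plug-in mutual information between two alignment columns, in bits.

    Only rows without a gap in either column are used (unless
    ``include_gaps`` makes the gap a 21st symbol); no pseudocounts.
    """
    pairs = []
    for row in msa.rows:
        a, b = row.aligned[col_a], row.aligned[col_b]
        if include_gaps or (a != GAP and b != GAP):
            pairs.append((a, b))
    if len(pairs) < 2:
        raise ValueError("fewer than 2 usable rows for MI")
    n = len(pairs)
    joint: dict[tuple[str, str], int] = {}
    pa: dict[str, int] = {}
    pb: dict[str, int] = {}
    for a, b in pairs:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pa[a] = pa.get(a, 0) + 1
        pb[b] = pb.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab * n * n / (pa[a] * pb[b]))
    return max(mi, 0.0)


def interchain_mi_summary(paired: PairedMsa, include_gaps: bool = False) -> MiResult:
    """MI for every (receptor column, peptide column) pair over paired rows."""
    if paired.paired_rows < 2:
        raise ValueError("need at least 2 paired rows")
    sub = PairedMsa(
        rows=paired.rows[: paired.paired_rows],
        receptor_block=paired.receptor_block,
        peptide_block=paired.peptide_block,
        paired_rows=paired.paired_rows,
        unpaired_receptor_rows=0,
        unpaired_peptide_rows=0,
    )
    records = []
    for rc in range(*paired.receptor_block):
        for pc in range(*paired.peptide_block):
            try:
                mi = column_mi(sub, rc, pc, include_gaps=include_gaps)
            except ValueError:
                continue
            records.append((rc, pc - paired.peptide_block[0], mi))
    df = pd.DataFrame(records, columns=["receptor_col", "peptide_col", "mi_bits"])
    if df.empty:
        raise ValueError("no usable column pairs")
    return MiResult(
        per_pair=df,
        mean_interchain=float(df["mi_bits"].mean()),
        max_interchain=float(df["mi_bits"].max()),
    )


def jsd_conservation(
    msa: Msa, background: np.ndarray | None = None
) -> ConservationProfile:
    """Per-column conservation as Jensen-Shannon divergence from a background.

    JSD is computed with base-2 logarithms (so it lies in [0, 1]) between the
    column's amino-acid frequencies over non-gap rows and the background
    distribution (uniform over the 20 amino acids by default), then
    multiplied by (1 − gap fraction) as a gap penalty. All-gap columns score
    0 and are flagged.
    """
    if msa.depth < 2:
        raise ValueError("need at least 2 rows")
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    background = np.asarray(background, dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_cols = msa.n_cols
    jsd = np.zeros(n_cols)
    gap_frac = np.zeros(n_cols)
    flagged = []
    for c in range(n_cols):
        counts = np.zeros(len(AMINO_ACIDS))
        gaps = 0
        for row in msa.rows:
            ch = row.aligned[c]
            if ch == GAP:
                gaps += 1
            elif ch in aa_index:
                counts[aa_index[ch]] += 1
        gap_frac[c] = gaps / msa.depth
        if counts.sum() == 0:
            flagged.append(c)
            continue
        p = counts / counts.sum()
        div = jensenshannon(p, background, base=2) ** 2
        jsd[c] = float(np.clip(div, 0.0, 1.0)) * (1.0 - gap_frac[c])
    return ConservationProfile(jsd=jsd, gap_fraction=gap_frac, flagged_columns=flagged)


def peptide_sequence_variants(seq: str, mode: str, seed: int = 0) -> str:
    """Ablated peptide sequence: mask (all 'X'), polyG (all 'G') or scramble.

    Scrambling permutes the residues (seeded), preserving composition, and
    rejects the identity permutation whenever any other ordering exists.
    """
    if not seq:
        raise ValueError("empty sequence")
    if mode == "mask":
        return "X" * len(seq)
    if mode == "polyG":
        return "G" * len(seq)
    if mode == "scramble":
        if len(set(seq)) <= 1:
            return seq
        rng = np.random.default_rng(seed)
        chars = list(seq)
        while True:
            perm = rng.permutation(len(chars))
            out = "".join(chars[i] for i in perm)
            if out != seq:
                return out
    raise ValueError(f"unknown ablation mode {mode!r}")


def mean_hydrophobicity(
    residues: str, scale: dict[str, float] = KYTE_DOOLITTLE
) -> float:
    """Arithmetic mean of per-residue hydrophobicity; codes outside the scale
    (e.g. 'X') are skipped."""
    values = [scale[c] for c in residues if c in scale]
    if not values:
        raise ValueError("no residues with a hydrophobicity value")
    return float(np.mean(values))


def msa_depth_ok(msa: Msa, min_depth: int = 50) -> bool:
    """Depth filter: the alignment must hold at least ``min_depth`` sequences."""
    return msa.depth >= min_depth
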