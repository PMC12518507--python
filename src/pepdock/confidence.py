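"""Model-confidence summaries: ranking confidence (ipTM+pTM), inter-chain
PAE mean (iPAE), and the pDockQ sigmoid.

These are the quantities structure-prediction models emit alongside a
prediction, commonly correlated with docking accuracy: the weighted
ipTM+pTM ranking confidence, the mean predicted aligned error restricted to
inter-chain residue pairs, and pDockQ, a logistic function of mean interface
pLDDT times the log of the interface contact count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .dockmetrics import native_contacts
from .structio import ComplexStructure

__all__ = [
    "ConfidenceRecord",
    "ConfidenceSummary",
    "read_confidence_json",
    "ranking_confidence",
    "interchain_pae",
    "pdockq",
    "pdockq_from_structure",
    "summarize_confidence",
]


@dataclass
class ConfidenceRecord:
    ptm: float
    iptm: float
    plddt: np.ndarray      # per-residue, 0-100
    pae: np.ndarray        # (L, L), Å
    chain_split: int

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        L = self.plddt.size
        if self.pae.shape != (L, L):
            raise ValueError("PAE matrix must be L x L with L = len(plddt)")
        if np.any(self.pae < 0):
            raise ValueError("PAE must be non-negative")
        if not 0 < self.chain_split < L:
            raise ValueError("chain_split must split the residue range")


@dataclass
class ConfidenceSummary:
    ranking_confidence: float
    ipae: float
    pdockq: float | None


def read_confidence_json(path: str | Path, chain_split: int) -> ConfidenceRecord:
    """Load an AF-style confidence JSON (keys ptm, iptm, plddt, pae)."""
    data = json.loads(Path(path).read_text())
    return ConfidenceRecord(
        ptm=float(data["ptm"]),
        iptm=float(data["iptm"]),
        plddt=np.array(data["plddt"], dtype=float),
        pae=np.array(data["pae"], dtype=float),
        chain_split=chain_split,
    )


def ranking_confidence(
    iptm: float, ptm: float, weights: tuple[float, float] = (0.8, 0.2)
) -> float:
    """Weighted ipTM+pTM (reported under the label "ipTM+pTM").

    Default weights (0.8, 0.2) follow the multimer ranking convention; pass
    (1, 1) for the literal sum.
    """
    for v in (iptm, ptm):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"confidence {v} outside [0, 1]")
    return weights[0] * iptm + weights[1] * ptm


def interchain_pae(record: ConfidenceRecord) -> float:
    """Mean PAE over both inter-chain off-diagonal blocks."""
    k = record.chain_split
    top = record.pae[:k, k:]
    bottom = record.pae[k:, :k]
    return float(np.concatenate([top.ravel(), bottom.ravel()]).mean())


def pdockq(
    mean_interface_plddt: float,
    n_interface_contacts: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """pDockQ = b + L / (1 + exp(−k·(x − x0))), x = mean interface pLDDT · ln(contacts)."""
    if n_interface_contacts < 1:
        raise ValueError("pDockQ needs at least one interface contact")
    x = mean_interface_plddt * math.log(n_interface_contacts)
    return config.pdockq_b + config.pdockq_L / (
        1.0 + math.exp(-config.pdockq_k * (x - config.pdockq_x0))
    )


def pdockq_from_structure(
    predicted: ComplexStructure,
    record: ConfidenceRecord,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float | None:
    """pDockQ using the predicted complex's interface.

    Interface contacts are residue pairs under the heavy-atom contact rule;
    interface pLDDT is averaged over the residues involved. Returns None for
    contact-free predictions (pDockQ undefined).
    """
    contacts = native_contacts(predicted, config.contact_cutoff)
    if len(contacts) == 0:
        return None
    k = record.chain_split
    residues = {i for i, _ in contacts.pairs} | {k + j for _, j in contacts.pairs}
    mean_plddt = float(np.mean([record.plddt[r] for r in sorted(residues)]))
    return pdockq(mean_plddt, len(contacts), config)


def summarize_confidence(
    record: ConfidenceRecord,
    predicted: ComplexStructure | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ConfidenceSummary:
    pd_val = (
        pdockq_from_structure(predicted, record, config) if predicted is not None else None
    )
    return ConfidenceSummary(
        ranking_confidence=ranking_confidence(record.iptm, record.ptm, config.ranking_weights),
        ipae=interchain_pae(record),
        pdockq=pd_val,
    )
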