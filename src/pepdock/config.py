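"""Pipeline-wide thresholds and constants, loadable from YAML/JSON.

Every cutoff used by the metric modules lives here with its default, so a
single config file can retune an analysis without touching code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # contacts / interfaces
    contact_cutoff: float = 5.0          # Å, heavy-atom residue-residue contact (Fnat, binding site)
    interface_cutoff: float = 10.0       # Å, interface-residue definition for iRMSD
    clash_cutoff: float = 2.0            # Å, inter-chain heavy-atom clash

    # DockQ category boundaries
    dockq_acceptable: float = 0.23
    dockq_medium: float = 0.49
    dockq_high: float = 0.80

    # atomic accuracy criterion
    atomic_fnat_min: float = 0.9         # strict >
    atomic_peptide_rmsd_max: float = 2.0
    atomic_interface_rmsd_max: float = 3.0

    # distogram map comparison
    map_contact_cutoff: float = 12.0     # Å, native inter-chain pairs entering Nc
    rmsd_map_success: float = 2.5        # Å, strict <
    peptide_rmsd_success: float = 12.0   # Å, strict <

    # binding-site match search
    partner_rmsd_threshold: float = 10.0
    seq_identity_min: float = 0.30
    tm_score_min: float = 0.5
    use_sequence_homology: bool = True
    use_structure_homology: bool = True
    same_site_jaccard: float = 0.25

    # MSA analysis
    min_peptide_msa_depth: int = 50
    mi_include_gaps: bool = False
    mi_apc: bool = False
    jsd_background: str = "uniform"      # or "blosum62"

    # confidence
    ranking_weights: tuple[float, float] = (0.8, 0.2)  # (ipTM, pTM)
    pdockq_L: float = 0.724
    pdockq_x0: float = 152.611
    pdockq_k: float = 0.052
    pdockq_b: float = 0.018

    # structure filtering
    peptide_max_len: int = 25

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a YAML or JSON mapping; unknown keys error."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            return cls()
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "ranking_weights" in data:
            data["ranking_weights"] = tuple(data["ranking_weights"])
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()
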