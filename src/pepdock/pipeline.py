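"""Batch evaluation, condition comparisons and confidence-stratified summaries.

``evaluate_batch`` pairs native structures with predictions (by id, from TSV
manifests), computes every applicable metric per pair, and returns a tidy
table with one row per (complex id, condition). Per-complex failures are
logged to stderr and flagged in the row; the batch never aborts.
``compare_conditions`` runs a Wilcoxon signed-rank (paired) or a two-sided
Mann-Whitney U (unpaired) test between two condition labels on any metric
column, and ``summarize`` produces medians, DockQ category fractions, and
cumulative accuracy-above-confidence fractions.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .confidence import read_confidence_json, summarize_confidence
from .distomap import distogram_from_structure, read_distogram_tsv, rmsd_map
from .dockmetrics import atomic_accuracy, dockq, peptide_rmsd_after_protein_alignment, tm_score
from .structio import read_structure

__all__ = [
    "ComparisonResult",
    "evaluate_batch",
    "compare_conditions",
    "summarize",
    "adjust_pvalues",
    "read_manifest",
]

METRIC_COLUMNS = [
    "fnat", "irmsd", "lrmsd", "dockq", "category", "atomic_pass", "tm_score",
    "peptide_rmsd", "rmsd_map", "ranking_confidence", "ipae", "pdockq",
]


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    paired: bool


def read_manifest(path: str | Path) -> pd.DataFrame:
    """TSV manifest with at least: id, path, receptor_chain, peptide_chain."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "path", "receptor_chain", "peptide_chain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in manifest: {dups}")
    return df


def _log(msg: str) -> None:
    print(f"[pepdock] {msg}", file=sys.stderr)


def evaluate_batch(
    native_manifest: str | Path,
    predicted_manifest: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
    condition: str = "default",
) -> pd.DataFrame:
    """Evaluate predictions against natives listed in two TSV manifests.

    Optional prediction manifest columns: ``confidence`` (AF-style JSON) and
    ``distogram`` (distogram TSV, compared against the native-derived map).
    Missing optional inputs leave their cells empty; per-complex errors set
    the ``error`` column and leave metric cells empty.
    """
    nat = read_manifest(native_manifest).set_index("id")
    pred = read_manifest(predicted_manifest).set_index("id")
    rows = []
    for cid in nat.index:
        row: dict = {"id": cid, "condition": condition, "error": ""}
        try:
            if cid not in pred.index:
                raise FileNotFoundError(f"no prediction for {cid}")
            n_rec = nat.loc[cid]
            p_rec = pred.loc[cid]
            native = read_structure(n_rec["path"], n_rec["receptor_chain"],
                                    n_rec["peptide_chain"], complex_id=cid)
            predicted = read_structure(p_rec["path"], p_rec["receptor_chain"],
                                       p_rec["peptide_chain"], complex_id=cid)
            dq = dockq(native, predicted, config)
            acc = atomic_accuracy(native, predicted, config)
            row.update(
                fnat=dq.fnat, irmsd=dq.irmsd, lrmsd=dq.lrmsd, dockq=dq.score,
                category=dq.category, atomic_pass=acc.passed,
                tm_score=tm_score(native.receptor, predicted.receptor),
                peptide_rmsd=peptide_rmsd_after_protein_alignment(native, predicted),
            )
            disto_path = p_rec.get("distogram") if "distogram" in pred.columns else None
            if isinstance(disto_path, str) and disto_path:
                nat_disto = distogram_from_structure(native)
                pred_disto = read_distogram_tsv(disto_path)
                row["rmsd_map"] = rmsd_map(nat_disto, pred_disto,
                                           config.map_contact_cutoff).value
            conf_path = p_rec.get("confidence") if "confidence" in pred.columns else None
            if isinstance(conf_path, str) and conf_path:
                record = read_confidence_json(conf_path,
                                              chain_split=len(native.receptor.residues))
                summary = summarize_confidence(record, predicted, config)
                row.update(
                    ranking_confidence=summary.ranking_confidence,
                    ipae=summary.ipae,
                    pdockq=summary.pdockq,
                )
        except Exception as exc:  # per-complex failures must not kill the batch
            _log(f"{cid}: {exc}")
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in METRIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[["id", "condition", *METRIC_COLUMNS, "error"]]


def compare_conditions(
    table: pd.DataFrame,
    metric: str,
    condition_a: str,
    condition_b: str,
    paired: bool,
) -> ComparisonResult:
    """Wilcoxon signed-rank (paired) or two-sided Mann-Whitney U (unpaired)."""
    a = table[table["condition"] == condition_a].set_index("id")[metric].dropna()
    b = table[table["condition"] == condition_b].set_index("id")[metric].dropna()
    if paired:
        if set(a.index) != set(b.index):
            raise ValueError("paired comparison requires identical id sets")
        b = b.loc[a.index]
        n = len(a)
        if n < 5:
            raise ValueError(f"refusing comparison with n={n} < 5")
        diffs = a.values - b.values
        if np.allclose(diffs, 0):
            return ComparisonResult("wilcoxon_signed_rank", 0.0, 1.0, n, True)
        stat, p = stats.wilcoxon(a.values, b.values, zero_method="zsplit")
        return ComparisonResult("wilcoxon_signed_rank", float(stat), float(p), n, True)
    n = min(len(a), len(b))
    if n < 5:
        raise ValueError(f"refusing comparison with n={n} < 5")
    stat, p = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
    return ComparisonResult("mann_whitney_u", float(stat), float(p), len(a) + len(b), False)


def adjust_pvalues(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw ones)."""
    return list(stats.false_discovery_control(p_values, method="bh"))


def summarize(
    table: pd.DataFrame,
    confidence_cutoffs: list[float] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    """Medians, category fractions, and confidence-stratified success fractions.

    For each confidence cutoff c, reports the fraction of rows with ranking
    confidence > c whose DockQ exceeds each category threshold — the
    cumulative accuracy-vs-confidence readout.
    """
    if table.empty:
        raise ValueError("empty metrics table")
    ok = table[table["error"] == ""] if "error" in table.columns else table
    numeric = [c for c in METRIC_COLUMNS if c not in ("category", "atomic_pass")]
    out: dict = {
        "n": int(len(ok)),
        "medians": {
            c: float(ok[c].median())
            for c in numeric
            if c in ok.columns and ok[c].notna().any()
        },
        "category_fractions": {
            cat: float((ok["category"] == cat).mean())
            for cat in ("poor", "acceptable", "medium", "high")
        },
        "fraction_atomic_accurate": float(ok["atomic_pass"].fillna(False).mean()),
    }
    thresholds = {
        "acceptable": config.dockq_acceptable,
        "medium": config.dockq_medium,
        "high": config.dockq_high,
    }
    if confidence_cutoffs:
        strat = {}
        for c in confidence_cutoffs:
            sel = ok[ok["ranking_confidence"] > c]
            strat[str(c)] = {
                "n": int(len(sel)),
                **{
                    f"frac_dockq_gt_{name}": (
                        float((sel["dockq"] > t).mean()) if len(sel) else float("nan")
                    )
                    for name, t in thresholds.items()
                },
            }
        out["by_confidence_cutoff"] = strat
    return out
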