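"""Screen statistics: RPM normalization, dual-control fold changes, hit calls.

The analysis is a threshold-based positive-selection read-out.  Counts are
normalized to reads per million (RPM) per sample; each hairpin's aggregated
induced (dox) abundance is compared against BOTH the frozen baseline and the
uninduced growth control, with a symmetric pseudocount; hairpins must also
clear a raw-read floor in the dox samples.  A hairpin is "enriched" when it
passes the read filter and exceeds the fold-change threshold against both
comparators; a gene is a hit when at least ``min_shrnas`` of its hairpins
are enriched.  Defaults: > 5-fold, > 100 raw dox reads, >= 2 hairpins —
strict inequalities throughout.

No p-value machinery is attached: the procedure is deliberately a
transparent threshold rule, with replicate concordance as the QC handle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counting import CountMatrix, CountingError
from .library import ScreenLibrary

__all__ = [
    "AnalysisParams",
    "AnalysisError",
    "normalize_rpm",
    "compute_enrichment",
    "call_gene_hits",
    "replicate_concordance",
    "analyze_screen",
    "run_screen_analysis",
    "evaluate_hits",
]


class AnalysisError(ValueError):
    """Raised for inputs that cannot be analyzed."""


@dataclass
class AnalysisParams:
    """Thresholds and modes of the hit-calling rule.

    fc_threshold
        Fold-change floor (strict >) against baseline AND control.
    min_reads
        Raw-read floor (strict >) evaluated on dox counts.
    min_shrnas
        Hairpins per gene that must be enriched for a gene hit.
    pseudocount_rpm
        Added to numerator and denominator RPM of every fold change; bounds
        ratios for zero counts.
    read_filter_mode
        ``any_dox``: one dox replicate above the floor suffices;
        ``all_dox``: every replicate must clear it.
    replicate_mode
        ``mean``: fold changes use the dox-replicate mean RPM;
        ``both``: each replicate's own fold change must clear the threshold.
    """

    fc_threshold: float = 5.0
    min_reads: int = 100
    min_shrnas: int = 2
    pseudocount_rpm: float = 0.5
    read_filter_mode: str = "any_dox"
    replicate_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.min_reads <= 0 or self.min_shrnas <= 0:
            raise AnalysisError("thresholds must be > 0")
        if self.pseudocount_rpm <= 0:
            raise AnalysisError("pseudocount_rpm must be > 0")
        if self.read_filter_mode not in ("any_dox", "all_dox"):
            raise AnalysisError("read_filter_mode must be any_dox or all_dox")
        if self.replicate_mode not in ("mean", "both"):
            raise AnalysisError("replicate_mode must be mean or both")


def normalize_rpm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per million: raw × 10^6 / sample total.  Column sums are 10^6."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise AnalysisError(f"sample(s) with zero total reads: {list(zero.index)}")
    return cm.counts * 1e6 / totals


def _check_roles(cm: CountMatrix) -> tuple[str, list[str], list[str]]:
    baseline = cm.baseline_id  # raises unless exactly one
    ctrl = cm.sample_ids("no_dox")
    dox = cm.sample_ids("dox")
    if not ctrl:
        raise AnalysisError("missing role: need >= 1 no_dox control sample")
    if not dox:
        raise AnalysisError("missing role: need >= 1 dox sample")
    return baseline, ctrl, dox


def compute_enrichment(cm: CountMatrix, params: AnalysisParams | None = None) -> pd.DataFrame:
    """Per-hairpin table: raw counts, RPM, fold changes vs both comparators,
    read-filter and enrichment flags (``enriched`` implies the filter)."""
    params = params or AnalysisParams()
    baseline, ctrl, dox = _check_roles(cm)
    rpm = normalize_rpm(cm)
    pc = params.pseudocount_rpm

    baseline_rpm = rpm[baseline]
    ctrl_rpm = rpm[ctrl].mean(axis=1)
    dox_rpm = rpm[dox].mean(axis=1)
    fc_base = (dox_rpm + pc) / (baseline_rpm + pc)
    fc_ctrl = (dox_rpm + pc) / (ctrl_rpm + pc)

    raw_dox = cm.counts[dox]
    if params.read_filter_mode == "any_dox":
        passes = (raw_dox > params.min_reads).any(axis=1)
    else:
        passes = (raw_dox > params.min_reads).all(axis=1)

    if params.replicate_mode == "mean":
        above = (fc_base > params.fc_threshold) & (fc_ctrl > params.fc_threshold)
    else:  # both: every replicate's own fold change must clear the threshold
        per_rep_base = rpm[dox].add(pc).div(baseline_rpm + pc, axis=0)
        per_rep_ctrl = rpm[dox].add(pc).div(ctrl_rpm + pc, axis=0)
        above = (per_rep_base.min(axis=1) > params.fc_threshold) & (
            per_rep_ctrl.min(axis=1) > params.fc_threshold
        )
    enriched = passes & above

    table = pd.DataFrame(index=cm.counts.index)
    for s in cm.counts.columns:
        table[f"raw_{s}"] = cm.counts[s]
    for s in cm.counts.columns:
        table[f"rpm_{s}"] = rpm[s]
    table["baseline_rpm"] = baseline_rpm
    table["ctrl_rpm_mean"] = ctrl_rpm
    table["dox_rpm_mean"] = dox_rpm
    table["fc_vs_baseline"] = fc_base
    table["fc_vs_control"] = fc_ctrl
    table["passes_read_filter"] = passes
    table["enriched"] = enriched
    return table


def call_gene_hits(
    et: pd.DataFrame, lib: ScreenLibrary, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """Aggregate hairpin enrichment flags to gene hits.

    A gene is a hit iff >= ``min_shrnas`` of its hairpins are enriched.
    Sorted by n_enriched (desc) then gene symbol; every library gene gets a
    row so the attrition is visible.
    """
    params = params or AnalysisParams()
    missing = [s for s in et.index if s not in lib.gene_of]
    if missing:
        raise AnalysisError(f"shRNA(s) absent from library: {missing[:3]}")
    gene = pd.Series({s: lib.gene_of[s] for s in et.index}, name="gene")
    n_in_lib = pd.Series(lib.gene_of).value_counts()

    enriched = et["enriched"]
    n_enriched = enriched.groupby(gene).sum().astype(int)
    supporting = (
        pd.Series(et.index[enriched], dtype=str)
        .groupby(gene.loc[et.index[enriched]].values)
        .apply(lambda s: ",".join(s))
        if enriched.any()
        else pd.Series(dtype=str)
    )
    out = pd.DataFrame(
        {
            "gene": n_in_lib.index,
            "n_shrnas_in_library": n_in_lib.values,
        }
    ).set_index("gene")
    out["n_enriched"] = n_enriched.reindex(out.index).fillna(0).astype(int)
    out["hit"] = out["n_enriched"] >= params.min_shrnas
    out["supporting_shrnas"] = supporting.reindex(out.index).fillna("")
    out = out.sort_values(["n_enriched", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index()


def replicate_concordance(
    cm: CountMatrix, role: str = "dox", pseudocount_rpm: float = 0.5
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of log2(RPM + pc) between the first two replicates
    of a role, plus the paired table for scatter plotting."""
    ids = cm.sample_ids(role)
    if len(ids) < 2:
        raise AnalysisError(f"need >= 2 {role!r} replicates for concordance, found {len(ids)}")
    rpm = normalize_rpm(cm)
    a = np.log2(rpm[ids[0]] + pseudocount_rpm)
    b = np.log2(rpm[ids[1]] + pseudocount_rpm)
    r = float(sps.pearsonr(a, b).statistic)
    paired = pd.DataFrame(
        {f"log2_rpm_{ids[0]}": a, f"log2_rpm_{ids[1]}": b}, index=cm.counts.index
    )
    return r, paired


def analyze_screen(
    cm: CountMatrix, lib: ScreenLibrary, params: AnalysisParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """In-memory pipeline: enrichment table, gene-hit table, run report."""
    params = params or AnalysisParams()
    et = compute_enrichment(cm, params)
    hits = call_gene_hits(et, lib, params)
    try:
        r, _ = replicate_concordance(cm, "dox", params.pseudocount_rpm)
    except AnalysisError:
        r = None
    report = {
        "params": asdict(params),
        "n_samples": int(len(cm.samples)),
        "attrition": {
            "shrnas_in": int(len(et)),
            "passing_read_filter": int(et["passes_read_filter"].sum()),
            "enriched": int(et["enriched"].sum()),
            "genes_hit": int(hits["hit"].sum()),
        },
        "hit_genes": list(hits.loc[hits["hit"], "gene"]),
        "replicate_concordance_r": r,
    }
    return et, hits, report


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_screen_analysis(
    counts_path: str | Path,
    samples_path: str | Path,
    library_path: str | Path,
    outdir: str | Path,
    params: AnalysisParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """File-level pipeline: read counts + sample sheet + library, write the
    enrichment TSV, gene-hit TSV, replicate scatter TSV and JSON run report.
    Deterministic: identical inputs produce byte-identical outputs."""
    from .library import read_library  # local import keeps module load cheap

    params = params or AnalysisParams()
    cm = CountMatrix.read(counts_path, samples_path)
    lib = read_library(library_path)
    et, hits, report = analyze_screen(cm, lib, params)
    report["inputs"] = {
        "counts": {"path": str(counts_path), "sha256": _sha256(counts_path)},
        "samples": {"path": str(samples_path), "sha256": _sha256(samples_path)},
        "library": {"path": str(library_path), "sha256": _sha256(library_path)},
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    et.to_csv(outdir / "enrichment.tsv", sep="\t", index_label="shrna_id", lineterminator="\n")
    hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False, lineterminator="\n")
    try:
        _, paired = replicate_concordance(cm, "dox", params.pseudocount_rpm)
        paired.to_csv(
            outdir / "replicate_scatter.tsv", sep="\t", index_label="shrna_id", lineterminator="\n"
        )
    except AnalysisError:
        pass
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return et, hits, report


def evaluate_hits(hits: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score called gene hits against planted truth.

    sensitivity = recovered planted genes / planted genes;
    precision = planted among called hits / called hits (None when nothing
    was called).  Raises if the two gene namespaces are disjoint.
    """
    if "gene" not in hits.columns or "gene" not in truth.columns:
        raise AnalysisError("both tables need a gene column")
    truth_genes = set(truth["gene"])
    hit_genes = set(hits.loc[hits["hit"].astype(bool), "gene"]) if "hit" in hits else set(hits["gene"])
    if truth_genes and set(hits["gene"]) and not (set(hits["gene"]) & truth_genes):
        raise AnalysisError("disjoint gene namespaces between hits and truth")
    planted = set(truth.loc[truth["escape_gene"].astype(bool), "gene"])
    tp = len(hit_genes & planted)
    fp = len(hit_genes - planted)
    fn = len(planted - hit_genes)
    return {
        "n_planted": len(planted),
        "n_hits": len(hit_genes),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "sensitivity": (tp / len(planted)) if planted else None,
        "precision": (tp / len(hit_genes)) if hit_genes else None,
    }
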