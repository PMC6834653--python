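"""Synthetic pooled-screen generator for a senescence-bypass positive selection.

The generative model mirrors the biology of an inducible-oncogene screen.
A pool of cells is infected with a barcoded shRNA library at a target
representation (mean cells per hairpin); after puromycin selection a baseline
aliquot is frozen, one arm grows without induction for the full culture
period, and induced (dox) arms grow normally until senescence onset and then
arrest — except for "escaper" cells whose hairpin knocks down a gene
required for the senescence response.  Escapers keep dividing for the rest
of the culture, which is the positive-selection signal the downstream
enrichment analysis detects.  Arrested cells persist (senescent cells do not
lyse), giving realistic non-zero background counts.

Growth is modeled on expectations (exponential at rate ln2/doubling_time);
stochastic draws happen at three biologically discrete points only:
Poisson seeding at infection, Poisson escape commitment at senescence onset,
and Dirichlet-multinomial sequencing.  All randomness flows from a single
seed via named substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .counting import CountMatrix, ReadLayout, DEFAULT_READ_LAYOUT
from .library import ScreenLibrary

__all__ = [
    "ARMS",
    "SimConfig",
    "SimTruth",
    "substream",
    "simulate_infection",
    "simulate_arm",
    "simulate_sequencing",
    "simulate_screen",
    "write_fastq",
    "write_truth",
    "read_truth",
]

ARMS = ("baseline", "no_dox", "dox")

# CellAbundance: expected cell count per hairpin in one arm at one time,
# as a float Series indexed by shrna_id in library order.
CellAbundance = pd.Series

# escape link: (knockdown_efficiency e, is_escape_gene, cfg) -> per-cell
# escape probability, vectorised over numpy arrays.
EscapeLink = Callable[[np.ndarray, np.ndarray, "SimConfig"], np.ndarray]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Named, order-independent child RNG of a single top-level seed."""
    keys = [zlib.crc32(str(n).encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def _default_escape_link(e: np.ndarray, is_escape: np.ndarray, cfg: "SimConfig") -> np.ndarray:
    """A cell escapes iff its knockdown is functionally sufficient: p = e for
    hairpins against senescence-essential genes, else the spontaneous
    background rate.  Partial knockdown (the ~50-70% typically achievable)
    therefore yields intermediate escape rates rather than all-or-nothing."""
    return np.where(is_escape, e, cfg.p_background_escape)


@dataclass
class SimConfig:
    """Generative parameters of one screen; defaults are the study conditions.

    representation=400 cells/hairpin at infection, 40% transduction (recorded
    for provenance; only transduced, puromycin-selected cells are modeled),
    two dox replicates and one uninduced control grown 21 days with
    senescence onset near day 7, 5e6 reads per sample with mild
    over-dispersion.  ``dispersion`` is the mean Dirichlet pseudocount per
    hairpin (total Dirichlet concentration = dispersion × library size);
    larger values approach pure multinomial sampling and ``inf`` is exact
    multinomial.  ``knockdown_dist`` are (alpha, beta) of the Beta law for
    per-hairpin knockdown efficiency; (6, 4) centres it on 60%.
    """

    library: ScreenLibrary
    representation: float = 400.0
    frac_transduced: float = 0.40
    n_dox_reps: int = 2
    n_ctrl_reps: int = 1
    t_total_days: float = 21.0
    t_senescence_onset_days: float = 7.0
    doubling_time_days: float = 1.5
    frac_escape_genes: float = 0.01
    p_background_escape: float = 1e-4
    knockdown_dist: tuple[float, float] = (6.0, 4.0)
    escape_link: EscapeLink | None = None
    fitness_cost: float = 0.9
    seq_depth: int = 5_000_000
    dispersion: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation < 0:
            raise ValueError("representation must be >= 0")
        if not (0 < self.frac_transduced <= 1):
            raise ValueError("frac_transduced must be in (0, 1]")
        for name in ("frac_escape_genes", "p_background_escape"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.t_total_days <= 0 or self.doubling_time_days <= 0:
            raise ValueError("times must be positive")
        if not (0 <= self.t_senescence_onset_days <= self.t_total_days):
            raise ValueError("t_senescence_onset_days must lie in [0, t_total_days]")
        if not (0 < self.fitness_cost <= 1):
            raise ValueError("fitness_cost must be in (0, 1]")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_dox_reps < 1 or self.n_ctrl_reps < 0:
            raise ValueError("need >= 1 dox replicate and >= 0 control replicates")
        a, b = self.knockdown_dist
        if a <= 0 or b <= 0:
            raise ValueError("knockdown_dist parameters must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth: which genes enable senescence escape when
    knocked down, and each hairpin's knockdown efficiency in [0, 1]."""

    escape_genes: frozenset[str]
    knockdown_efficiency: dict[str, float]

    def __post_init__(self) -> None:
        for e in self.knockdown_efficiency.values():
            if not (0.0 <= e <= 1.0):
                raise ValueError("knockdown efficiencies must be in [0, 1]")


def draw_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Plant escape-essential genes and draw per-hairpin knockdown efficiencies."""
    rng = rng if rng is not None else substream(cfg.seed, "truth")
    genes = cfg.library.genes
    n_escape = int(round(cfg.frac_escape_genes * len(genes)))
    chosen = rng.choice(len(genes), size=n_escape, replace=False) if n_escape else []
    escape = frozenset(genes[i] for i in chosen)
    a, b = cfg.knockdown_dist
    eff = rng.beta(a, b, size=len(cfg.library))
    return SimTruth(
        escape_genes=escape,
        knockdown_efficiency=dict(zip(cfg.library.shrna_ids, eff.tolist())),
    )


def _fitness(cfg: SimConfig, truth: SimTruth) -> np.ndarray:
    """Growth-rate multiplier per hairpin: hairpins against escape-essential
    genes pay a fitness cost in every arm (Mediator-class genes are broadly
    required, so even partial knockdown slows growth slightly)."""
    is_escape = np.array(
        [cfg.library.gene_of[s] in truth.escape_genes for s in cfg.library.shrna_ids]
    )
    return np.where(is_escape, cfg.fitness_cost, 1.0), is_escape


def _growth_factor(t_days: float, cfg: SimConfig, fitness: np.ndarray) -> np.ndarray:
    return np.power(2.0, fitness * t_days / cfg.doubling_time_days)


def simulate_infection(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> CellAbundance:
    """Poisson seeding: initial cells per hairpin ~ Poisson(representation)."""
    rng = rng if rng is not None else substream(cfg.seed, "infection")
    n = rng.poisson(cfg.representation, size=len(cfg.library)).astype(float)
    return pd.Series(n, index=pd.Index(cfg.library.shrna_ids, name="shrna_id"))


def simulate_arm(
    init: CellAbundance,
    arm: str,
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> CellAbundance:
    """Grow one culture arm from the infected pool to harvest.

    baseline
        The frozen aliquot: returned unchanged.
    no_dox
        Uninduced growth control: exponential growth for the full culture
        (abundance × 2^(fitness · t_total / doubling_time)).
    dox
        All cells grow until senescence onset; at onset each cell commits to
        escape with probability given by the escape link (Poisson draw per
        hairpin), escapers keep growing for the remaining time, and arrested
        cells persist at their onset count.  A hairpin with zero escape
        probability therefore plateaus exactly at its onset abundance.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if arm == "baseline":
        return init.copy()
    fitness, is_escape = _fitness(cfg, truth)
    if arm == "no_dox":
        return init * _growth_factor(cfg.t_total_days, cfg, fitness)

    rng = rng if rng is not None else substream(cfg.seed, "growth", arm)
    at_onset = init * _growth_factor(cfg.t_senescence_onset_days, cfg, fitness)
    e = np.array([truth.knockdown_efficiency[s] for s in init.index])
    link = cfg.escape_link if cfg.escape_link is not None else _default_escape_link
    p_escape = np.clip(np.asarray(link(e, is_escape, cfg), dtype=float), 0.0, 1.0)
    escapers = rng.poisson(at_onset.to_numpy() * p_escape).astype(float)
    arrested = np.maximum(at_onset.to_numpy() - escapers, 0.0)
    remaining = cfg.t_total_days - cfg.t_senescence_onset_days
    out = arrested + escapers * _growth_factor(remaining, cfg, fitness)
    return pd.Series(out, index=init.index)


def simulate_sequencing(
    abund: CellAbundance,
    depth: int,
    dispersion: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.Series:
    """Sequence an arm: integer counts summing exactly to ``depth``.

    Counts are Dirichlet-multinomial around the abundance proportions:
    per-hairpin Dirichlet pseudocounts alpha_i = dispersion × n × p_i (mean
    pseudocount per hairpin = dispersion), modeling PCR/sequencing noise
    beyond multinomial.  ``dispersion = inf`` gives exact multinomial.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    a = abund.to_numpy(dtype=float)
    total = a.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cannot sequence an all-zero (or non-finite) abundance")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    p = a / total
    counts = np.zeros(len(a), dtype=np.int64)
    pos = p > 0
    if np.isinf(dispersion):
        q = p[pos]
    else:
        alpha = dispersion * len(a) * p[pos]
        q = rng.dirichlet(alpha)
    counts[pos] = rng.multinomial(int(depth), q)
    return pd.Series(counts, index=abund.index)


def simulate_screen(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Run the full generative model: one infection shared by every arm, then
    independent growth/escape and sequencing randomness per sample.

    Samples: one frozen baseline, ``n_ctrl_reps`` uninduced controls, and
    ``n_dox_reps`` induced replicates (the replicates share the infected pool
    but commit escapers and are sequenced independently).  The output is a
    pure function of the config, including its seed.
    """
    truth = draw_truth(cfg)
    init = simulate_infection(cfg)

    names: list[str] = []
    roles: list[str] = []
    reps: list[int] = []
    cols: dict[str, pd.Series] = {}

    def add(sample_id: str, role: str, rep: int, abund: CellAbundance) -> None:
        names.append(sample_id)
        roles.append(role)
        reps.append(rep)
        cols[sample_id] = simulate_sequencing(
            abund, cfg.seq_depth, cfg.dispersion, rng=substream(cfg.seed, "seq", sample_id)
        )

    add("baseline", "baseline", 1, simulate_arm(init, "baseline", cfg, truth))
    ctrl = simulate_arm(init, "no_dox", cfg, truth)  # deterministic growth
    for r in range(1, cfg.n_ctrl_reps + 1):
        add(f"ctrl_{r}", "no_dox", r, ctrl)
    for r in range(1, cfg.n_dox_reps + 1):
        abund = simulate_arm(
            init, "dox", cfg, truth, rng=substream(cfg.seed, "growth", "dox", r)
        )
        add(f"dox_{r}", "dox", r, abund)

    counts = pd.DataFrame(cols, index=init.index)
    samples = pd.DataFrame(
        {
            "sample_id": names,
            "role": roles,
            "replicate": reps,
            "depth": [int(cfg.seq_depth)] * len(names),
            "seed": [int(cfg.seed)] * len(names),
        }
    )
    return CountMatrix(counts=counts, samples=samples), truth


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode_template(lib: ScreenLibrary, layout: ReadLayout) -> np.ndarray:
    """Per-hairpin read templates as (n, read_length) base-index matrix."""
    for part, name in ((layout.anchor5, "anchor5"), (layout.anchor3, "anchor3")):
        if not set(part) <= set("ACGT"):
            raise ValueError(f"layout {name} must be ACGT-only")
    n = len(lib)
    tmpl = np.zeros((n, layout.read_length), dtype=np.uint8)  # pad = 'A'
    a5 = np.array([_CODE[c] for c in layout.anchor5], dtype=np.uint8)
    a3 = np.array([_CODE[c] for c in layout.anchor3], dtype=np.uint8)
    off = len(layout.anchor5)
    tmpl[:, :off] = a5
    for i, rec in enumerate(lib.records):
        tmpl[i, off : off + layout.barcode_length] = [_CODE[c] for c in rec.barcode]
    if len(a3):
        tmpl[:, off + layout.barcode_length : off + layout.barcode_length + len(a3)] = a3
    return tmpl


def write_fastq(
    counts: Mapping[str, int] | pd.Series,
    lib: ScreenLibrary,
    path: str | Path,
    layout: ReadLayout | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    chunk_size: int = 200_000,
) -> int:
    """Emit single-end amplicon reads for a counts vector; returns reads written.

    Exactly sum(counts) reads are emitted in a shuffled order, each embedding
    its hairpin's barcode at the layout offset.  Substitutions are i.i.d. per
    base at ``error_rate`` (an erred base is always changed, uniformly to one
    of the other three), across the whole read including anchors.  Qualities
    are a fixed Phred+33 'I'.  ``.gz`` paths are gzip-compressed.
    """
    if layout is None:
        layout = ReadLayout(
            anchor5=DEFAULT_READ_LAYOUT.anchor5,
            barcode_length=lib.barcode_length,
            anchor3=DEFAULT_READ_LAYOUT.anchor3,
            read_length=DEFAULT_READ_LAYOUT.read_length,
        )
    if layout.barcode_length != lib.barcode_length:
        raise ValueError("layout barcode_length does not match library")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)

    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    row_of = {sid: i for i, sid in enumerate(lib.shrna_ids)}
    unknown = set(counts) - set(row_of)
    if unknown:
        raise ValueError(f"counts refer to hairpins not in library: {sorted(unknown)[:3]}")
    reps = np.zeros(len(lib), dtype=np.int64)
    for sid, c in counts.items():
        if c < 0:
            raise ValueError("negative read count")
        reps[row_of[sid]] = c
    order = np.repeat(np.arange(len(lib)), reps)
    rng.shuffle(order)

    tmpl = _encode_template(lib, layout)
    qual = "I" * layout.read_length
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    written = 0
    with opener(path, "wt") as fh:
        for start in range(0, len(order), chunk_size):
            idx = order[start : start + chunk_size]
            block = tmpl[idx].copy()
            if error_rate > 0:
                mask = rng.random(block.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    block[mask] = (block[mask] + shift) % 4
            seqs = _BASE_BYTES[block]
            for j in range(len(idx)):
                fh.write(
                    f"@r{written + j}\n{seqs[j].tobytes().decode('ascii')}\n+\n{qual}\n"
                )
            written += len(idx)
    return written


def write_truth(truth: SimTruth, lib: ScreenLibrary, path: str | Path) -> None:
    """Write planted truth as TSV: shrna_id, gene, knockdown_efficiency, escape_gene."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("shrna_id\tgene\tknockdown_efficiency\tescape_gene\n")
        for rec in lib.records:
            e = truth.knockdown_efficiency[rec.shrna_id]
            flag = int(rec.gene in truth.escape_genes)
            fh.write(f"{rec.shrna_id}\t{rec.gene}\t{e:.6f}\t{flag}\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"shrna_id": str, "gene": str})
    required = {"shrna_id", "gene", "escape_gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"truth file needs columns {sorted(required)}")
    return df
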