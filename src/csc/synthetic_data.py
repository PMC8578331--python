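"""Synthetic genomes, guide libraries and simulated essentiality screens.

The generator exists so the whole correction pipeline is exercisable end to
end with known ground truth.  It emulates the statistical structure of real
screen inputs:

* a random-ACGT genome with planted repeat families (near-identical copies,
  optionally mutated) so guides drawn from them have controllable H0/H1..H3
  neighbor counts and specificity scores spanning both sides of the 0.16
  promiscuity threshold;
* a library with a configurable fraction of genes whose guides fall in
  repeat regions (promiscuous guides), the rest uniquely targeting;
* screens whose expected guide depletion is the sum of a gene-knockout
  effect and an off-target effect, logFC_i = G_gene(i) + O(x_i), with
  negative-binomial count noise and per-sample depth factors so that
  median-ratio normalization has real work to do.

The default off-target truth maps the same covariates the corrector uses:
O = -beta * (sum of neighborhood CFD - 1), clipped, i.e. toxicity grows
with the off-target cutting mass 1/s - 1.  A deliberately mis-specified
variant (toxicity proportional to the raw H2 count) is available for
robustness checks.  Guides with no perfect target cut nothing and get
expected logFC 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import GoldStandard
from .genome_index import TargetIndex, build_target_index
from .specificity import CFDPenaltyTable, annotate_library, load_cfd_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_repeat_families",
    "simulate_genome",
    "design_library",
    "simulate_screen",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_repeat_families(n_families: int = 60) -> list[tuple[int, int, float]]:
    """A deterministic mix of (copy_number, unit_length, mutation_rate)
    giving specificity diversity: copy numbers 2..20, per-copy per-base
    mutation rates 0..3%."""
    copies = [2, 3, 5, 8, 12, 20]
    lengths = [150, 200, 250]
    rates = [0.0, 0.01, 0.03]
    fams = []
    for i in range(n_families):
        fams.append((copies[i % len(copies)],
                     lengths[(i // len(copies)) % len(lengths)],
                     rates[(i // (len(copies) * len(lengths))) % len(rates)]))
    return fams


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen dataset.

    Defaults: 2 Mb genome, 1000 genes x 4 guides, 20% essential genes with
    mean knockout effect -2, 25% of genes drawn from repeat regions,
    depth 500 reads/guide, NB dispersion 0.1, 2 replicates.
    """

    seed: int
    genome_length: int = 2_000_000
    repeat_families: list = field(default_factory=default_repeat_families)
    k: int = 20
    n_genes: int = 1000
    guides_per_gene: int = 4
    frac_essential: float = 0.2
    gene_effect_essential: float = -2.0
    gene_effect_sd: float = 0.3
    offtarget_model: str = "cfd_mass"  # "cfd_mass" | "h2" | "none"
    offtarget_beta: float = 0.5
    max_offtarget_effect: float = 6.0
    promiscuous_fraction: float = 0.25
    sequencing_depth: float = 500.0
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    depth_factor_range: tuple[float, float] = (0.7, 1.4)
    n_gold_essential: int = 200
    n_gold_nonessential: int = 300

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.frac_essential < 1:
            raise ValueError("frac_essential must be in (0,1)")
        for name in ("genome_length", "n_genes", "guides_per_gene",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted truth: per-gene essentiality and G, per-guide O and expected
    logFC, with covariates realized from the emitted genome."""

    genes: pd.DataFrame   # gene, essential, G
    guides: pd.DataFrame  # guide_id, gene, sequence, covariates, O, expected_logfc


@dataclass
class SimulatedDataset:
    genome: dict
    manifest: dict
    index: TargetIndex
    library: pd.DataFrame
    annotated: pd.DataFrame
    truth: GroundTruth
    counts: pd.DataFrame
    gold: GoldStandard


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genome(config: SimulationConfig):
    """Random ACGT genome with planted repeat families.

    Returns (genome dict, manifest).  The manifest lists each family's unit
    sequence and the half-open interval of every planted copy.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    codes = rng.integers(0, 4, size=L, dtype=np.uint8)

    total_repeat = sum(c * u for c, u, _ in config.repeat_families)
    if total_repeat > L // 2:
        raise ValueError(
            f"repeat families cover {total_repeat} bp, more than half the "
            f"{L} bp genome")

    occupied: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(1000):
            start = int(rng.integers(0, L - length))
            if all(start + length <= a or start >= b for a, b in occupied):
                occupied.append((start, start + length))
                return start
        raise RuntimeError("could not place repeat copy; genome too crowded")

    manifest = {"families": []}
    for fi, (n_copies, unit_len, mut_rate) in enumerate(config.repeat_families):
        unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
        fam = {"family": fi, "unit": _codes_to_str(unit),
               "copy_number": int(n_copies), "mutation_rate": float(mut_rate),
               "copies": []}
        for _ in range(n_copies):
            copy = unit.copy()
            if mut_rate > 0:
                hit = np.nonzero(rng.random(unit_len) < mut_rate)[0]
                for pos in hit:
                    copy[pos] = (copy[pos] + rng.integers(1, 4)) % 4
            start = place(unit_len)
            codes[start : start + unit_len] = copy
            fam["copies"].append([int(start), int(start + unit_len)])
        manifest["families"].append(fam)

    return {"chr1": _codes_to_str(codes)}, manifest


def _repeat_intervals(manifest: dict) -> list[tuple[int, int]]:
    ivs = [tuple(c) for fam in manifest["families"] for c in fam["copies"]]
    return sorted(ivs)


def design_library(genome: dict, manifest: dict, config: SimulationConfig,
                   index: TargetIndex | None = None) -> pd.DataFrame:
    """Pick guides_per_gene guides per synthetic gene.

    A ``promiscuous_fraction`` of genes draw every guide from planted repeat
    regions (promiscuous guides with H0 > 1 and/or near neighbors); the rest
    draw from unique background sites.
    """
    rng = np.random.default_rng(config.seed + 1)
    if index is None:
        index = build_target_index(genome, k=config.k)
    ivs = _repeat_intervals(manifest)
    starts = np.array([a for a, _ in ivs])
    ends = np.array([b for _, b in ivs])

    # classify each occurrence by protospacer start; a site is repeat-derived
    # if its protospacer lies inside a planted copy
    occ_start = index.occ_start
    pos = np.searchsorted(starts, occ_start, side="right") - 1
    in_rep = np.zeros(occ_start.shape, dtype=bool)
    ok = pos >= 0
    in_rep[ok] = occ_start[ok] + config.k <= ends[pos[ok]]

    # one entry per unique protospacer sequence
    key_of_occ = np.repeat(np.arange(index.keys.shape[0]),
                           np.diff(index.indptr))
    rep_keys = np.unique(key_of_occ[in_rep])
    uniq_keys = np.setdiff1d(np.arange(index.keys.shape[0]), rep_keys,
                             assume_unique=False)

    from ._trie import decode_key
    n_prom_genes = int(round(config.promiscuous_fraction * config.n_genes))
    need_rep = n_prom_genes * config.guides_per_gene
    need_uniq = (config.n_genes - n_prom_genes) * config.guides_per_gene
    if need_rep > rep_keys.size:
        raise ValueError(
            f"repeat regions are too PAM-poor: need {need_rep} distinct "
            f"repeat-derived guides but only {rep_keys.size} sites exist; "
            f"add repeat families or lower promiscuous_fraction")
    if need_uniq > uniq_keys.size:
        raise ValueError(
            f"genome too PAM-poor: need {need_uniq} unique-site guides, "
            f"have {uniq_keys.size}")

    rep_pick = rng.choice(rep_keys, size=need_rep, replace=False)
    uniq_pick = rng.choice(uniq_keys, size=need_uniq, replace=False)

    # promiscuous genes are interleaved among gene ids deterministically
    gene_ids = [f"GENE{g:05d}" for g in range(config.n_genes)]
    prom_genes = set(rng.choice(config.n_genes, size=n_prom_genes,
                                replace=False).tolist())
    rows = []
    ri = ui = 0
    for g in range(config.n_genes):
        for j in range(config.guides_per_gene):
            if g in prom_genes:
                key = rep_pick[ri]; ri += 1
            else:
                key = uniq_pick[ui]; ui += 1
            seq = decode_key(int(index.keys[key]), config.k)
            rows.append({"guide_id": f"g{g:05d}_{j}", "sequence": seq,
                         "gene": gene_ids[g]})
    return pd.DataFrame(rows)


def true_offtarget_effect(annotated: pd.DataFrame,
                          config: SimulationConfig) -> np.ndarray:
    """Planted O per guide from the realized covariates."""
    s = annotated["specificity"].to_numpy(dtype=float)
    h2 = annotated["H2"].to_numpy(dtype=float)
    h0 = annotated["H0"].to_numpy(dtype=float)
    if config.offtarget_model == "none":
        O = np.zeros(len(annotated))
    elif config.offtarget_model == "cfd_mass":
        with np.errstate(divide="ignore", invalid="ignore"):
            mass = np.where(np.isfinite(s) & (s > 0), 1.0 / s - 1.0, 0.0)
        O = -config.offtarget_beta * mass
    elif config.offtarget_model == "h2":
        O = -config.offtarget_beta * h2
    else:
        raise ValueError(f"unknown offtarget_model {config.offtarget_model!r}")
    O = np.clip(O, -config.max_offtarget_effect, 0.0)
    O[h0 == 0] = 0.0
    return O


def assign_gene_effects(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene essential flag and knockout effect G."""
    rng = np.random.default_rng(config.seed + 2)
    genes = [f"GENE{g:05d}" for g in range(config.n_genes)]
    essential = rng.random(config.n_genes) < config.frac_essential
    G = np.where(essential,
                 rng.normal(config.gene_effect_essential,
                            config.gene_effect_sd, config.n_genes),
                 0.0)
    return pd.DataFrame({"gene": genes, "essential": essential, "G": G})


def make_gold_standard(gene_truth: pd.DataFrame,
                       config: SimulationConfig) -> GoldStandard:
    """Gold lists drawn from the planted truth (a subset, as in real
    screens where curated sets cover a fraction of the library)."""
    rng = np.random.default_rng(config.seed + 3)
    ess = gene_truth.loc[gene_truth["essential"], "gene"].to_numpy()
    non = gene_truth.loc[~gene_truth["essential"], "gene"].to_numpy()
    n_e = min(config.n_gold_essential, len(ess))
    n_n = min(config.n_gold_nonessential, len(non))
    if n_e == 0 or n_n == 0:
        raise ValueError("cannot build gold sets: a class is empty")
    return GoldStandard(
        frozenset(rng.choice(ess, size=n_e, replace=False)),
        frozenset(rng.choice(non, size=n_n, replace=False)))


def simulate_screen(annotated: pd.DataFrame, gene_truth: pd.DataFrame,
                    config: SimulationConfig,
                    seed: int | None = None):
    """Negative-binomial counts for one screen.

    Returns (counts table, guide-level truth table).  Expected logFC is
    G_gene + O(x); plasmid counts are NB around the configured depth and
    replicate counts follow expected fold change 2^logFC with per-sample
    depth factors.
    """
    from scipy.stats import nbinom

    rng = np.random.default_rng(config.seed if seed is None else seed)
    G = annotated["gene"].map(gene_truth.set_index("gene")["G"]).to_numpy()
    h0 = annotated["H0"].to_numpy()
    O = true_offtarget_effect(annotated, config)
    expected_logfc = np.where(h0 == 0, 0.0, G + O)

    n_guides = len(annotated)
    alpha = config.nb_dispersion

    def nb_draw(mean):
        mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
        if alpha <= 0:
            return rng.poisson(mean)
        r = 1.0 / alpha
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    depth = config.sequencing_depth
    r = 1.0 / alpha if alpha > 0 else None
    if r is not None:
        frac_low = float(nbinom.cdf(29, r, r / (r + depth)))
        if frac_low > 0.10:
            warnings.warn(
                f"expected plasmid count {depth} puts {frac_low:.0%} of "
                "guides under the 30-read filter", stacklevel=2)

    counts = {"guide_id": annotated["guide_id"].to_numpy(),
              "gene": annotated["gene"].to_numpy(),
              "plasmid": nb_draw(np.full(n_guides, depth))}
    w = np.power(2.0, expected_logfc)
    w = w / w.mean()  # library re-normalization: sequencing is compositional
    lo, hi = config.depth_factor_range
    for rep in range(config.n_replicates):
        factor = rng.uniform(lo, hi)
        counts[f"rep{rep + 1}"] = nb_draw(depth * factor * w)
    counts_df = pd.DataFrame(counts)

    guide_truth = annotated[["guide_id", "gene", "sequence", "specificity",
                             "H0", "H1", "H2", "H3"]].copy()
    guide_truth["O"] = O
    guide_truth["G"] = G
    guide_truth["expected_logfc"] = expected_logfc
    return counts_df, guide_truth


def simulate_dataset(config: SimulationConfig,
                     cfd_table: CFDPenaltyTable | None = None,
                     screen_seed: int | None = None) -> SimulatedDataset:
    """Genome -> index -> library -> annotation -> truth -> counts, end to end."""
    if cfd_table is None:
        cfd_table = load_cfd_table()
    genome, manifest = simulate_genome(config)
    index = build_target_index(genome, k=config.k,
                               genome_id=f"synthetic-seed{config.seed}")
    library = design_library(genome, manifest, config, index=index)
    annotated = annotate_library(index, library, cfd_table)
    gene_truth = assign_gene_effects(config)
    counts, guide_truth = simulate_screen(annotated, gene_truth, config,
                                          seed=screen_seed)
    gold = make_gold_standard(gene_truth, config)
    return SimulatedDataset(genome=genome, manifest=manifest, index=index,
                            library=library, annotated=annotated,
                            truth=GroundTruth(gene_truth, guide_truth),
                            counts=counts, gold=gold)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit genome.fa, library.tsv, counts.tsv, truth JSON/TSV and gold
    gene lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for name, seq in ds.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    ds.library.to_csv(outdir / "library.tsv", sep="\t", index=False)
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    ds.truth.guides.to_csv(outdir / "truth_guides.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(ds.manifest, fh)
        fh.write("\n")
    with open(outdir / "gold_essential.txt", "w") as fh:
        fh.write("\n".join(sorted(ds.gold.essential)) + "\n")
    with open(outdir / "gold_nonessential.txt", "w") as fh:
        fh.write("\n".join(sorted(ds.gold.nonessential)) + "\n")
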