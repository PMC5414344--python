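"""Simulated multi-genome community fixtures for end-to-end testing.

The refinement workflow assumes two statistical signals: contigs from one
genome (i) share a co-abundance profile across samples and (ii) share a
genome-specific oligonucleotide composition.  The generator plants both,
yielding exactly the four input files the toolkit reads — contig FASTA,
per-sample coverage CSV (DNA-RPKM), ESCG CSV and a truth assignment
table — so every module is testable without any external download.

Sequences are drawn from a per-genome order-0 Markov (i.i.d. base)
composition tuned to a GC target, with a genome-specific asymmetry
between the two bases of each complementary pair so distinct genomes
separate in tetranucleotide space; an optional order-2 hook generates
harder fixtures.  Per-contig abundance in sample s is the genome's mean
abundance in s times multiplicative lognormal noise (positive support,
the standard model for coverage variation).  Each of the 109 marker
genes is placed on exactly one contig of its genome, so every truth bin
is 100% complete and 0% contaminated unless duplication is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import BinrefError
from .io import (
    BinAssignmentTable,
    ContigRecord,
    ContigSet,
    CoverageTable,
    ESCGTable,
    write_assignments,
    write_coverage,
    write_escg_long,
)

#: Truth column name in generated assignment tables.
TRUTH_METHOD = "truth"


@dataclass
class CommunitySpec:
    """Parameters of a simulated community.

    Defaults mirror the study conditions the toolkit targets: a
    low-to-medium complexity community profiled over seven samples, ten
    planted genomes of thirty contigs each, contigs of at least 1000 nt,
    lognormal multiplicative abundance noise of sigma 0.2 (log scale) and
    the 109-gene bacterial single-copy panel.  Genome mean abundances
    swing over roughly two to three orders of magnitude across samples
    (``mean_abundance_sigma`` 2.5, log scale), the succession dynamics
    that make co-abundance profiles informative; with the sigma-0.2
    contig noise this keeps within-genome profile correlations near 1
    while the cross-genome cap in profile drawing keeps them dissimilar —
    the "within-group r ~ 1, across-group r ~ 0" structure the
    correlation clustering assumes.
    """

    n_genomes: int = 10
    contigs_per_genome: int = 30
    n_samples: int = 7
    gc_targets: tuple[float, ...] | None = None  # default: spread over (0.3, 0.7)
    composition_bias: float = 0.15  # strand asymmetry within base pairs
    abundance_sigma: float = 0.2  # lognormal sigma of per-contig noise
    mean_abundance_sigma: float = 2.5  # spread of genome means across samples
    length_range: tuple[int, int] = (1000, 20000)
    universe_size: int = 109
    escg_duplication_rate: float = 0.0  # planted contamination rate
    markov_order: int = 0  # 0 (default) or 2 for harder fixtures
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise BinrefError("n_samples must be >= 5 (clustering precondition)")
        if self.length_range[0] < 1000:
            raise BinrefError("minimum contig length is 1000 nt")
        if self.gc_targets is not None:
            if len(self.gc_targets) != self.n_genomes:
                raise BinrefError("need one GC target per genome")
            if not all(0.25 < g < 0.75 for g in self.gc_targets):
                raise BinrefError("GC targets must lie in (0.25, 0.75)")
        if self.markov_order not in (0, 2):
            raise BinrefError("markov_order must be 0 or 2")
        if not 0 <= self.escg_duplication_rate <= 1:
            raise BinrefError("escg_duplication_rate must be in [0, 1]")


@dataclass
class SimulatedCommunity:
    """The four generated inputs plus the spec that produced them."""

    spec: CommunitySpec
    contigs: ContigSet
    coverage: CoverageTable
    escg: ESCGTable
    truth: BinAssignmentTable
    genome_ids: list[str] = field(default_factory=list)


def _base_probs(gc: float, asymmetry: tuple[float, float]) -> np.ndarray:
    """A/C/G/T probabilities with expected GC ``gc``.

    ``asymmetry`` splits each complementary pair (A/T and G/C) unevenly,
    giving the genome a composition signature beyond GC alone.
    """
    wa, wg = asymmetry
    at = 1.0 - gc
    return np.array([at * wa, gc * (1 - wg), gc * wg, at * (1 - wa)])


def _distinct_profiles(
    rng: np.random.Generator,
    n_genomes: int,
    n_samples: int,
    sigma: float,
    max_pairwise_corr: float = 0.6,
    max_tries: int = 200,
) -> np.ndarray:
    """Per-genome mean abundance profiles across samples.

    Profiles are lognormal (positive, heavy-tailed, as in real coverage)
    and drawn so that no two genomes' profiles correlate above
    ``max_pairwise_corr`` — the planted co-abundance structure is
    distinct by construction, mirroring the assumption that contigs of
    different genomes show dissimilar abundance profiles.  Falls back to
    the best candidate if separation cannot be achieved (e.g. very few
    samples and many genomes).
    """
    profiles: list[np.ndarray] = []
    for _ in range(n_genomes):
        best, best_corr = None, np.inf
        for _ in range(max_tries):
            cand = rng.lognormal(mean=2.0, sigma=sigma, size=n_samples)
            worst = max(
                (abs(np.corrcoef(cand, p)[0, 1]) for p in profiles), default=0.0
            )
            if worst < best_corr:
                best, best_corr = cand, worst
            if worst <= max_pairwise_corr:
                break
        profiles.append(best)
    return np.array(profiles)


def _draw_sequence(
    rng: np.random.Generator, length: int, probs: np.ndarray, order: int
) -> str:
    bases = np.array(list("ACGT"))
    if order == 0:
        idx = rng.choice(4, size=length, p=probs)
        return "".join(bases[idx])
    # order-2 hook: context-dependent perturbation of the base distribution
    trans = rng.dirichlet(probs * 40 + 1, size=16)
    out = list(rng.choice(4, size=2, p=probs))
    for _ in range(length - 2):
        ctx = out[-2] * 4 + out[-1]
        out.append(rng.choice(4, p=trans[ctx]))
    return "".join(bases[np.array(out)])


def simulate_community(spec: CommunitySpec) -> SimulatedCommunity:
    """Generate a community; a fixed seed gives byte-identical outputs."""
    rng = np.random.default_rng(spec.random_seed)
    n_g = spec.n_genomes
    gc_targets = (
        np.linspace(0.3, 0.7, n_g) if spec.gc_targets is None else np.array(spec.gc_targets)
    )
    genome_ids = [f"genome{g + 1}" for g in range(n_g)]
    samples = [f"S{s + 1}" for s in range(spec.n_samples)]

    records: list[ContigRecord] = []
    truth_rows: dict[str, str] = {}
    abundance_rows: dict[str, np.ndarray] = {}
    members: dict[str, list[str]] = {g: [] for g in genome_ids}

    mean_profiles = _distinct_profiles(
        rng, n_g, spec.n_samples, spec.mean_abundance_sigma
    )
    lo, hi = spec.length_range
    for g, gid in enumerate(genome_ids):
        b = spec.composition_bias
        asymmetry = (0.5 + rng.uniform(-b, b), 0.5 + rng.uniform(-b, b))
        probs = _base_probs(gc_targets[g], asymmetry)
        means = mean_profiles[g]
        for c in range(spec.contigs_per_genome):
            cid = f"{gid}_c{c + 1:03d}"
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            seq = _draw_sequence(rng, length, probs, spec.markov_order)
            records.append(ContigRecord(id=cid, sequence=seq))
            if spec.abundance_sigma > 0:
                noise = rng.lognormal(
                    mean=0.0, sigma=spec.abundance_sigma, size=spec.n_samples
                )
            else:
                noise = 1.0
            abundance_rows[cid] = means * noise
            truth_rows[cid] = gid
            members[gid].append(cid)

    contigs = ContigSet(records)
    coverage = CoverageTable(
        data=pd.DataFrame.from_dict(abundance_rows, orient="index", columns=samples),
        units="dna_rpkm",
    )
    truth = BinAssignmentTable(
        data=pd.DataFrame({TRUTH_METHOD: pd.Series(truth_rows)})
    )

    genes = [f"escg_{i + 1:03d}" for i in range(spec.universe_size)]
    counts = pd.DataFrame(
        0, index=pd.Index([r.id for r in records]), columns=genes, dtype=int
    )
    for gid in genome_ids:
        pool = members[gid]
        for gene in genes:
            host = pool[rng.integers(len(pool))]
            counts.loc[host, gene] += 1
            if spec.escg_duplication_rate > 0 and rng.random() < spec.escg_duplication_rate:
                dup = pool[rng.integers(len(pool))]
                counts.loc[dup, gene] += 1
    escg = ESCGTable(counts=counts, universe_size=spec.universe_size)

    return SimulatedCommunity(
        spec=spec,
        contigs=contigs,
        coverage=coverage,
        escg=escg,
        truth=truth,
        genome_ids=genome_ids,
    )


def write_community(community: SimulatedCommunity, outdir: str | Path) -> dict[str, Path]:
    """Write the four input files plus the truth CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fasta",
        "coverage": outdir / "coverage.csv",
        "escg": outdir / "escg.csv",
        "truth": outdir / "truth.csv",
    }
    with open(paths["contigs"], "w") as fh:
        for rec in community.contigs:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    write_coverage(community.coverage, paths["coverage"])
    write_escg_long(community.escg, paths["escg"])
    write_assignments(community.truth, paths["truth"])
    return paths
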