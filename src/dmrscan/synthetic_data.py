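"""Synthetic bisulfite methylomes with planted, recorded ground truth.

The generator emulates the statistical structure of a liver WGBS aging
study: replicate cohorts (four animals each) of young/old wild-type,
long-lived dwarf, and intervention (CR, rapamycin) mice, with

* a CpG landscape where CpG-dense islands sit at low methylation
  (~8%), enhancers around 70%, and the genomic background around 75%,
  giving a global methylation level near 73%;
* direction-specific planted age effects: methylation loss at a subset
  of enhancers (and some background windows) and methylation gain at a
  subset of bivalent CpG islands;
* a "buffering" offset for the dwarf genotype — a higher starting
  methylation level at the shared hypomethylated loci in young animals;
* partial suppression of the planted age effects in treated old cohorts
  (a configured fraction of planted loci fully reverts to the young
  level, CR more than rapamycin);
* binomial read counts at Poisson-distributed coverage (mean ~7 reads
  per dyad, ~4.4 for the low-coverage intervention cohorts) with mild
  per-CpG, per-replicate logit-normal noise.

Every planted interval is recorded in a machine-readable truth table so
calls can be scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from dmrscan.dmr_calling import Cohort
from dmrscan.enrichment import GenomeSpec
from dmrscan.meth_io import FeatureSet, MethCallTable, write_bed, write_cpg_report

__all__ = ["SimConfig", "SyntheticGenome", "build_genome", "simulate_cohort",
           "emit_fixture"]


@dataclass
class SimConfig:
    """Study design and noise model for the simulator.

    Defaults are the desk-scale study conditions: two 5-Mb chromosomes,
    ~150k CpG dyads, four replicates per cohort, Poisson(7) coverage and
    a 73%-methylation genome; planted age deltas of 0.3 in each
    direction.  ``hypo_in_enhancer_frac`` controls what fraction of the
    planted hypomethylation loci fall inside enhancers (the rest land in
    random background windows), mirroring the enrichment — rather than
    exclusivity — of age-associated losses at enhancers.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    # CpG dyads per base pair
    cpg_density_background: float = 0.012
    cpg_density_enhancer: float = 0.02
    cpg_density_island: float = 0.10
    # feature counts and lengths (bp); the island share of CpGs is kept
    # near its realistic genomic fraction (~3% of dyads) so that the
    # prescribed regional baselines yield a ~73% global methylation level
    n_enhancers: int = 400
    enhancer_length: int = 1250
    n_islands: int = 60
    island_length: int = 600
    n_genes: int = 250
    gene_length: int = 20_000
    n_super_enhancers: int = 30
    # baseline methylation means
    meth_background: float = 0.75
    meth_enhancer: float = 0.70
    meth_island: float = 0.08
    # planted age effects
    enhancer_hypo_delta: float = -0.30
    island_hyper_delta: float = 0.30
    frac_enhancers_affected: float = 0.30
    frac_islands_affected: float = 0.30
    hypo_in_enhancer_frac: float = 0.80
    planted_region_length: int = 500
    # genotype / intervention structure
    buffering_offset: float = 0.10
    suppression_frac_cr: float = 0.8
    suppression_frac_rapa: float = 0.4
    # cohort and noise model
    n_replicates: int = 4
    coverage_mean: float = 7.0
    coverage_mean_low: float = 4.4
    replicate_noise_sd: float = 0.15
    # expression model
    frac_unexpressed: float = 0.2
    expression_coupling: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.meth_background, self.meth_enhancer, self.meth_island,
            self.frac_enhancers_affected, self.frac_islands_affected,
            self.hypo_in_enhancer_frac, self.suppression_frac_cr,
            self.suppression_frac_rapa, self.frac_unexpressed,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if not 0.0 <= self.meth_enhancer + self.enhancer_hypo_delta <= 1.0:
            raise ValueError("enhancer delta leaves [0, 1]")
        if not 0.0 <= self.meth_island + self.island_hyper_delta <= 1.0:
            raise ValueError("island delta leaves [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_mean_low <= 0:
            raise ValueError("coverage means must be positive")


@dataclass
class SyntheticGenome:
    """A built genome: placement universe, annotations, CpGs and truth.

    ``cpgs`` has one row per dyad with its baseline methylation, planted
    age delta and buffering flag.  ``truth`` lists every planted DMR
    interval with direction and true delta (the acceptance oracle).
    """

    spec: GenomeSpec
    features: dict[str, FeatureSet]
    cpgs: pd.DataFrame  # chrom, pos, baseline, age_delta, buffered
    truth: pd.DataFrame  # chrom, start, end, direction, delta, feature_type
    expression: pd.DataFrame  # gene_id, fpkm
    config: SimConfig


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    n: int,
    size: int,
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Uniform non-overlapping placement by rejection; appends to occupied."""
    out: list[tuple[int, int]] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ValueError("requested features exceed genome capacity")
        s = int(rng.integers(0, length - size))
        e = s + size
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        out.append((s, e))
    return out


def build_genome(cfg: SimConfig | None = None) -> SyntheticGenome:
    """Build the genome, annotations, CpG landscape and truth table."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    spec = GenomeSpec(lengths=dict(cfg.chrom_lengths))
    chroms = list(cfg.chrom_lengths)
    total = sum(cfg.chrom_lengths.values())

    def split(n: int) -> list[int]:
        # apportion feature counts by chromosome length
        raw = [n * cfg.chrom_lengths[c] / total for c in chroms]
        counts = [int(x) for x in raw]
        while sum(counts) < n:
            counts[int(np.argmax([r - c for r, c in zip(raw, counts)]))] += 1
        return counts

    enhancers: list[tuple[str, int, int]] = []
    islands: list[tuple[str, int, int]] = []
    genes: list[tuple[str, int, int]] = []
    per_chrom_occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, n_enh, n_isl, n_gene in zip(
        chroms, split(cfg.n_enhancers), split(cfg.n_islands), split(cfg.n_genes)
    ):
        length = cfg.chrom_lengths[chrom]
        occ = per_chrom_occupied[chrom]
        # genes first (largest); enhancers may sit inside genes, so track
        # them in a separate occupancy list from the gene spans
        gene_spans = _place_nonoverlapping(rng, length, n_gene, cfg.gene_length, [])
        genes.extend((chrom, s, e) for s, e in gene_spans)
        enh_spans = _place_nonoverlapping(
            rng, length, n_enh, cfg.enhancer_length, occ
        )
        enhancers.extend((chrom, s, e) for s, e in enh_spans)
        isl_spans = _place_nonoverlapping(
            rng, length, n_isl, cfg.island_length, occ
        )
        islands.extend((chrom, s, e) for s, e in isl_spans)

    # super-enhancers: widened spans around a subset of enhancers
    se_idx = rng.choice(len(enhancers), size=min(cfg.n_super_enhancers,
                                                 len(enhancers)), replace=False)
    super_enh = []
    for i in sorted(se_idx.tolist()):
        chrom, s, e = enhancers[i]
        pad = 2 * cfg.enhancer_length
        super_enh.append((chrom, max(0, s - pad),
                          min(cfg.chrom_lengths[chrom], e + pad)))

    # expression table; genes with planted enhancers skew to high FPKM
    gene_ids = [f"gene{i:04d}" for i in range(len(genes))]
    fpkm = np.zeros(len(genes))
    expressed = rng.random(len(genes)) >= cfg.frac_unexpressed
    fpkm[expressed] = rng.lognormal(mean=2.0, sigma=1.2, size=int(expressed.sum()))

    # choose planted loci
    n_enh_aff = int(round(cfg.frac_enhancers_affected * len(enhancers)))
    n_in_enh = int(round(cfg.hypo_in_enhancer_frac * n_enh_aff))
    n_in_bg = n_enh_aff - n_in_enh
    # couple enhancer selection to host-gene expression: weight by
    # (1 + fpkm rank)^coupling for enhancers inside an expressed gene
    enh_weight = np.ones(len(enhancers))
    gene_lookup = {c: [] for c in chroms}
    for gi, (chrom, s, e) in enumerate(genes):
        gene_lookup[chrom].append((s, e, gi))
    for ei, (chrom, s, e) in enumerate(enhancers):
        for gs, ge, gi in gene_lookup[chrom]:
            if s < ge and gs < e and fpkm[gi] > 0:
                rank = (fpkm > 0).sum() and (fpkm[fpkm > 0] <= fpkm[gi]).mean()
                enh_weight[ei] = (1.0 + rank) ** cfg.expression_coupling
                break
    enh_weight /= enh_weight.sum()
    aff_enh = rng.choice(len(enhancers), size=n_in_enh, replace=False,
                         p=enh_weight) if n_in_enh else np.array([], dtype=int)
    n_isl_aff = int(round(cfg.frac_islands_affected * len(islands)))
    aff_isl = rng.choice(len(islands), size=n_isl_aff, replace=False) \
        if n_isl_aff else np.array([], dtype=int)

    truth_rows: list[dict] = []
    L = cfg.planted_region_length
    for i in sorted(aff_enh.tolist()):
        chrom, s, e = enhancers[i]
        mid = (s + e) // 2
        ps, pe = max(s, mid - L // 2), min(e, mid + L // 2)
        truth_rows.append(dict(chrom=chrom, start=ps, end=pe, direction="hypo",
                               delta=cfg.enhancer_hypo_delta,
                               feature_type="enhancer"))
    # background hypo loci, placed in unoccupied stretches
    for chrom, count in zip(chroms, split(n_in_bg) if n_in_bg else
                            [0] * len(chroms)):
        occ = per_chrom_occupied[chrom]
        spans = _place_nonoverlapping(rng, cfg.chrom_lengths[chrom], count, L, occ)
        for s, e in spans:
            truth_rows.append(dict(chrom=chrom, start=s, end=e, direction="hypo",
                                   delta=cfg.enhancer_hypo_delta,
                                   feature_type="background"))
    for i in sorted(aff_isl.tolist()):
        chrom, s, e = islands[i]
        mid = (s + e) // 2
        ps, pe = max(s, mid - L // 2), min(e, mid + L // 2)
        truth_rows.append(dict(chrom=chrom, start=ps, end=pe, direction="hyper",
                               delta=cfg.island_hyper_delta,
                               feature_type="bivalent_island"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "direction", "delta", "feature_type"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # CpG landscape: background positions plus densified features; planted
    # background loci emulate CpG-enriched regulatory elements and are
    # densified to enhancer density
    bg_truth = [
        (r.chrom, r.start, r.end)
        for r in truth.itertuples(index=False)
        if r.feature_type == "background"
    ]
    cpg_parts = []
    for chrom in chroms:
        length = cfg.chrom_lengths[chrom]
        n_bg = rng.poisson(cfg.cpg_density_background * length)
        pos = [np.sort(rng.choice(length - 1, size=n_bg, replace=False))]
        for feats, dens in (
            ([iv for iv in enhancers if iv[0] == chrom],
             cfg.cpg_density_enhancer - cfg.cpg_density_background),
            ([iv for iv in islands if iv[0] == chrom],
             cfg.cpg_density_island - cfg.cpg_density_background),
            ([iv for iv in bg_truth if iv[0] == chrom],
             cfg.cpg_density_enhancer - cfg.cpg_density_background),
        ):
            for _, s, e in feats:
                extra = rng.poisson(max(dens, 0.0) * (e - s))
                if extra:
                    pos.append(np.sort(rng.integers(s, e - 1, size=extra)))
        allpos = np.unique(np.concatenate(pos))
        df = pd.DataFrame({"chrom": chrom, "pos": allpos.astype(np.int64)})
        cpg_parts.append(df)
    cpgs = pd.concat(cpg_parts, ignore_index=True)

    # per-CpG baseline and planted delta
    baseline = np.full(len(cpgs), cfg.meth_background)
    for ivs, level in ((enhancers, cfg.meth_enhancer),
                       (islands, cfg.meth_island)):
        mask = _mask_in(cpgs, ivs)
        baseline[mask] = level
    age_delta = np.zeros(len(cpgs))
    buffered = np.zeros(len(cpgs), dtype=bool)
    for row in truth.itertuples(index=False):
        m = (
            (cpgs["chrom"] == row.chrom)
            & (cpgs["pos"] >= row.start)
            & (cpgs["pos"] < row.end)
        ).to_numpy()
        age_delta[m] = row.delta
        if row.direction == "hypo":
            buffered[m] = True
    cpgs = cpgs.assign(baseline=baseline, age_delta=age_delta, buffered=buffered)

    features = {
        "enhancers": FeatureSet.from_intervals("enhancers", enhancers),
        "super_enhancers": FeatureSet.from_intervals("super_enhancers", super_enh),
        "bivalent_islands": FeatureSet.from_intervals("bivalent_islands", islands),
        "genes": FeatureSet(
            name="genes",
            data=pd.DataFrame(genes, columns=["chrom", "start", "end"]).assign(
                label=gene_ids
            ),
        ),
    }
    expression = pd.DataFrame({"gene_id": gene_ids, "fpkm": fpkm})
    return SyntheticGenome(
        spec=spec, features=features, cpgs=cpgs, truth=truth,
        expression=expression, config=cfg,
    )


def _mask_in(cpgs: pd.DataFrame, intervals: list[tuple[str, int, int]]) -> np.ndarray:
    mask = np.zeros(len(cpgs), dtype=bool)
    by_chrom = {
        chrom: (grp["pos"].to_numpy(), grp.index.to_numpy())
        for chrom, grp in cpgs.groupby("chrom", sort=False)
    }
    for chrom, s, e in intervals:
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        pos, idx = entry
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        mask[idx[lo:hi]] = True
    return mask


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    genome: SyntheticGenome,
    cohort_name: str,
    age: str = "young",
    genotype: str = "WT",
    treatment: str | None = None,
    low_coverage: bool = False,
    rng: np.random.Generator | int | None = None,
    strand_resolved: bool = False,
) -> Cohort:
    """Simulate one replicate cohort from a built genome.

    True per-CpG methylation is the regional baseline, plus the buffering
    offset for the dwarf genotype at buffered (planted-hypo) loci, plus
    the planted age effect in old animals — except at loci suppressed by
    the treatment, where methylation reverts fully to the young level.
    Each replicate then adds logit-normal noise per CpG, draws coverage
    from a Poisson and methylated reads from a binomial; uncovered dyads
    are omitted, matching coverage-file semantics.
    """
    cfg = genome.config
    if age not in ("young", "old"):
        raise ValueError("age must be 'young' or 'old'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    cpgs = genome.cpgs
    p_true = cpgs["baseline"].to_numpy().copy()
    if genotype == "dwarf":
        p_true = p_true + cfg.buffering_offset * cpgs["buffered"].to_numpy()
    if age == "old":
        delta = cpgs["age_delta"].to_numpy().copy()
        if treatment is not None:
            frac = {"CR": cfg.suppression_frac_cr,
                    "Rapa": cfg.suppression_frac_rapa}.get(treatment)
            if frac is None:
                raise ValueError(f"unknown treatment {treatment!r}")
            suppressed = _suppressed_truth_mask(genome, treatment)
            planted = (
                (cpgs["age_delta"] != 0).to_numpy()
                & _mask_in(
                    cpgs,
                    [
                        (r.chrom, r.start, r.end)
                        for r, s in zip(
                            genome.truth.itertuples(index=False), suppressed
                        )
                        if s
                    ],
                )
            )
            delta[planted] = 0.0
        p_true = p_true + delta
    n_clip = int(((p_true < 0) | (p_true > 1)).sum())
    if n_clip:
        logging.getLogger(__name__).warning(
            "simulate_cohort: clipped %d methylation probabilities", n_clip
        )
    p_true = np.clip(p_true, 0.0, 1.0)

    mean_cov = cfg.coverage_mean_low if low_coverage else cfg.coverage_mean
    replicates = []
    for r in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.replicate_noise_sd, size=p_true.size)
        p_rep = _expit(_logit(p_true) + noise)
        coverage = rng.poisson(mean_cov, size=p_true.size)
        n_meth = rng.binomial(coverage, p_rep)
        covered = coverage > 0
        df = pd.DataFrame(
            {
                "chrom": cpgs["chrom"].to_numpy()[covered],
                "pos": cpgs["pos"].to_numpy()[covered],
                "strand": "collapsed",
                "n_meth": n_meth[covered],
                "n_unmeth": (coverage - n_meth)[covered],
            }
        )
        if strand_resolved:
            df = _split_strands(df, rng)
        replicates.append(
            MethCallTable(
                sample_id=f"{cohort_name}_rep{r + 1}", data=df, cohort=cohort_name
            )
        )
    if strand_resolved:
        # strand-resolved replicates are not collapsed, so the Cohort
        # invariant does not hold; hand back a plain container and let
        # callers run collapse_dyads first
        return SimpleNamespace(name=cohort_name, replicates=replicates)
    return Cohort(name=cohort_name, replicates=replicates)


def _split_strands(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Split each dyad's reads binomially between the two strands."""
    plus_meth = rng.binomial(df["n_meth"].to_numpy(), 0.5)
    plus_unmeth = rng.binomial(df["n_unmeth"].to_numpy(), 0.5)
    minus_meth = df["n_meth"].to_numpy() - plus_meth
    minus_unmeth = df["n_unmeth"].to_numpy() - plus_unmeth
    plus = df.assign(strand="+", n_meth=plus_meth, n_unmeth=plus_unmeth)
    minus = df.assign(
        strand="-", pos=df["pos"] + 1, n_meth=minus_meth, n_unmeth=minus_unmeth
    )
    both = pd.concat([plus, minus], ignore_index=True)
    both = both[(both["n_meth"] + both["n_unmeth"]) > 0]
    return both.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _suppressed_truth_mask(genome: SyntheticGenome, treatment: str) -> np.ndarray:
    """Deterministic per-treatment choice of which planted loci revert."""
    cfg = genome.config
    frac = {"CR": cfg.suppression_frac_cr, "Rapa": cfg.suppression_frac_rapa}[
        treatment
    ]
    n = len(genome.truth)
    k = int(round(frac * n))
    rng = np.random.default_rng(cfg.seed + {"CR": 101, "Rapa": 202}[treatment])
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def suppressed_truth(genome: SyntheticGenome, treatment: str) -> pd.DataFrame:
    """The subset of the truth table reverted under a treatment."""
    return genome.truth[_suppressed_truth_mask(genome, treatment)].reset_index(
        drop=True
    )


def emit_fixture(
    genome: SyntheticGenome,
    cohorts: list[Cohort],
    out_dir: str | Path,
) -> Path:
    """Write a fixture directory: coverage files, BEDs, truth, expression.

    Layout: ``coverage/<sample>.cov`` (five-column report, 1-based),
    ``features/<name>.bed``, ``truth.bed``, ``expression.tsv`` and a
    ``manifest.yaml`` listing every emitted file.
    """
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    (out / "features").mkdir(exist_ok=True)
    files: list[str] = []
    cohort_samples: dict[str, list[str]] = {}
    for cohort in cohorts:
        cohort_samples[cohort.name] = []
        for rep in cohort.replicates:
            rel = f"coverage/{rep.sample_id}.cov"
            write_cpg_report(rep, out / rel)
            files.append(rel)
            cohort_samples[cohort.name].append(rel)
    for name, fs in genome.features.items():
        rel = f"features/{name}.bed"
        write_bed(fs, out / rel)
        files.append(rel)
    truth_bed = genome.truth.assign(
        name=genome.truth["direction"] + ":" + genome.truth["feature_type"]
    )[["chrom", "start", "end", "name", "delta"]]
    truth_bed.to_csv(out / "truth.bed", sep="\t", header=False, index=False)
    files.append("truth.bed")
    genome.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    files.append("expression.tsv")
    manifest = {
        "genome": {c: int(l) for c, l in genome.spec.lengths.items()},
        "seed": genome.config.seed,
        "cohorts": cohort_samples,
        "files": files,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
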