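"""Synthetic-data generators with planted structure.

Three generators produce every input the downstream analysis consumes:

* :func:`generate_cell_population` — a sparse overdispersed count matrix with a
  binary latent senescence state driving (i) a low-capture anchor marker gene,
  (ii) a correlated "maturation" gene module, (iii) an interferon-response
  module and (iv) an unresponsive SASP module, plus donor/technology batch
  effects and designated mitochondrial genes.
* :func:`generate_regulatory_landscape` — a toy chromosome with planted active
  promoters, enhancers, TAD boundaries and CTCF sites of known category,
  planted differential binding, motif-bearing sequences and a planted coupling
  between boundary CTCF loss and upregulation of the linked gene.
* :func:`generate_intensity_table` — per-cell fluorescence intensities and
  cytoplasmic-DNA focus counts for two latent classes.

Every generator is a pure function of its config (including the seed), and
each output carries a truth table sufficient to score recall/precision of any
downstream stage without re-reading generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import io as sio

MITO_PREFIX = "MT-"
_N_MITO = 10


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# single-cell population
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Conditions for the synthetic beta-cell population.

    Defaults emulate the study system: a rare (~20%) senescent fraction, an
    anchor marker that is highly specific but captured in only a fraction of
    senescent cells (overall detection ~15% of cells), a marker-correlated
    maturation module, a weaker interferon-response module, and a SASP module
    with no loading at all.
    """

    seed: int = 0
    n_cells: int = 2000
    n_genes: int = 2000
    frac_senescent: float = 0.20
    marker_capture: float = 0.75
    module_sizes: dict = field(
        default_factory=lambda: {"maturation": 120, "isg": 60, "sasp": 40}
    )
    module_loadings: dict = field(
        default_factory=lambda: {"maturation": 0.9, "isg": 0.6, "sasp": 0.0}
    )
    dispersion: float = 0.4
    depth_lognormal: tuple = (8.0, 0.4)
    n_donors: int = 4
    n_tech: int = 2
    batch_sd: float = 0.15
    marker_gene: str = "CDKN2A"
    marker_baseline_log: float = -5.0
    marker_loading: float = 6.2
    mito_shift: float = 2.5

    def validate(self) -> None:
        if not (0.0 <= self.frac_senescent <= 1.0):
            raise ConfigurationError("frac_senescent must lie in [0, 1]")
        if not (0.0 <= self.marker_capture <= 1.0):
            raise ConfigurationError("marker_capture must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if min(self.n_cells, self.n_genes, self.n_donors, self.n_tech) < 1:
            raise ConfigurationError("all sizes must be positive")
        if any(s <= 0 for s in self.module_sizes.values()):
            raise ConfigurationError("module sizes must be positive")
        reserved = 1 + _N_MITO  # marker + mitochondrial genes
        if sum(self.module_sizes.values()) + reserved > self.n_genes:
            raise ConfigurationError(
                "module sizes exceed the number of available genes"
            )
        if set(self.module_sizes) != set(self.module_loadings):
            raise ConfigurationError("module_sizes and module_loadings must share keys")


@dataclass
class SyntheticCellPopulation:
    counts: sp.csr_matrix  # genes x cells
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame  # donor, tech, mito_fraction, library_size
    gene_meta: pd.DataFrame  # module, loading, is_marker, is_mito
    cell_truth: pd.DataFrame  # senescent indicator
    latent_log_mean: np.ndarray  # genes x cells expected log relative expression
    latent_rate: np.ndarray  # genes x cells realized relative expression (sums to 1 per cell)
    marker_gene: str
    config: SimConfig


def generate_cell_population(config: SimConfig) -> SyntheticCellPopulation:
    """Draw counts with log-mean = baseline + loading * s_c + batch effects.

    Per-cell totals are drawn lognormally and counts are allotted
    multinomially over genes with gamma-perturbed weights, giving negative
    binomial-like marginals (Var = mu + phi * mu^2) while keeping column sums
    equal to library size. The marker gene is additionally zeroed with
    probability (1 - marker_capture) in senescent cells; in non-senescent
    cells its baseline is so low that detection is near zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, C = config.n_genes, config.n_cells

    gene_names = np.array(
        [config.marker_gene]
        + [f"{MITO_PREFIX}SYN{i + 1}" for i in range(_N_MITO)]
        + [f"GENE{i + 1:05d}" for i in range(G - 1 - _N_MITO)]
    )
    is_marker = gene_names == config.marker_gene
    is_mito = np.char.startswith(gene_names.astype(str), MITO_PREFIX)

    # module membership over non-marker, non-mito genes
    module = np.array([""] * G, dtype=object)
    loading = np.zeros(G)
    free = np.flatnonzero(~is_marker & ~is_mito)
    pos = 0
    for name in sorted(config.module_sizes):
        size = config.module_sizes[name]
        idx = free[pos : pos + size]
        module[idx] = name
        loading[idx] = config.module_loadings[name]
        pos += size

    eta = rng.normal(0.0, 1.0, G)  # baseline log weights
    eta[is_mito] += config.mito_shift
    # marker baseline is calibrated at 2000 genes; shift keeps its relative
    # abundance (hence detection rate) stable across matrix sizes
    eta[is_marker] = config.marker_baseline_log + np.log(G / 2000.0)
    loading[is_marker] = config.marker_loading

    s_c = (rng.random(C) < config.frac_senescent).astype(np.int8)
    donor = rng.integers(config.n_donors, size=C)
    tech = rng.integers(config.n_tech, size=C)
    donor_eff = rng.normal(0.0, config.batch_sd, (G, config.n_donors))
    tech_eff = rng.normal(0.0, config.batch_sd, (G, config.n_tech))

    log_mu = (
        eta[:, None]
        + loading[:, None] * s_c[None, :]
        + donor_eff[:, donor]
        + tech_eff[:, tech]
    )

    depth = np.maximum(
        np.round(rng.lognormal(*config.depth_lognormal, C)).astype(np.int64), 100
    )

    phi = config.dispersion
    weights = np.exp(log_mu) * rng.gamma(1.0 / phi, phi, (G, C))
    probs = weights / weights.sum(axis=0, keepdims=True)  # realized expression rates
    counts = np.empty((G, C), dtype=np.int64)
    for c in range(C):
        counts[:, c] = rng.multinomial(depth[c], probs[:, c])

    # marker low capture: zero-inflation in senescent cells only
    marker_row = int(np.flatnonzero(is_marker)[0])
    drop = (s_c == 1) & (rng.random(C) > config.marker_capture)
    counts[marker_row, drop] = 0

    lib = counts.sum(axis=0)
    mito_frac = counts[is_mito].sum(axis=0) / np.maximum(lib, 1)
    cell_ids = np.array([f"cell{i + 1:05d}" for i in range(C)])
    cell_meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": np.array([f"donor{d + 1}" for d in donor]),
            "tech": np.array([f"tech{t + 1}" for t in tech]),
            "mito_fraction": mito_frac,
            "library_size": lib,
        }
    ).set_index("cell_id")
    gene_meta = pd.DataFrame(
        {
            "gene": gene_names,
            "module": module,
            "loading": loading,
            "is_marker": is_marker,
            "is_mito": is_mito,
        }
    ).set_index("gene")
    cell_truth = pd.DataFrame({"cell_id": cell_ids, "senescent": s_c}).set_index(
        "cell_id"
    )

    return SyntheticCellPopulation(
        counts=sp.csr_matrix(counts),
        gene_names=gene_names,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        cell_truth=cell_truth,
        latent_log_mean=log_mu,
        latent_rate=probs,
        marker_gene=config.marker_gene,
        config=config,
    )


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------

# synthetic CTCF-like position frequency matrix (counts); deliberately
# information-rich so planted consensus insertions score far above background
SYNTHETIC_CTCF_PFM = pd.DataFrame(
    {
        "A": [2, 90, 2, 2, 4, 2, 88, 2, 2, 4, 2, 2],
        "C": [90, 4, 2, 90, 4, 90, 4, 2, 90, 4, 2, 90],
        "G": [4, 2, 92, 4, 88, 4, 4, 92, 4, 88, 92, 4],
        "T": [4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 4, 2],
    }
).T.loc[list("ACGT")]


@dataclass
class LandscapeConfig:
    """Layout of the toy genome.

    Each planted CTCF site (and each extra regulatory element) lives in its
    own ``block_size`` block so that the 200 kb intervening-range rule cannot
    couple neighbouring plantings; the chromosome length is derived from the
    number of blocks unless given explicitly.
    """

    seed: int = 0
    chrom: str = "chrSYN"
    block_size: int = 400_000
    chrom_length: int | None = None  # derived from block count when None
    n_promoter_sites: int = 30
    n_intervening_sites: int = 45
    n_boundary_sites: int = 20
    n_other_sites: int = 30
    n_extra_promoters: int = 30
    n_extra_enhancers: int = 30
    n_inactive_tss: int = 40
    n_null_regions: int = 200
    coupling: float = 0.9  # P(linked gene upregulated | boundary CTCF loss)
    background_up: float = 0.10
    frac_motif: float = 0.9  # CTCF sites carrying a planted motif
    site_halfwidth: int = 200
    seq_length: int = 400
    n_reps: int = 3
    region_depth: float = 50.0
    region_dispersion: float = 0.05
    planted_abs_log2fc: float = 2.0
    boundary_halfwidth: int = 5000

    def n_blocks(self) -> int:
        return (
            self.n_promoter_sites
            + self.n_intervening_sites
            + self.n_boundary_sites
            + self.n_other_sites
            + self.n_extra_promoters
            + self.n_extra_enhancers
            + self.n_inactive_tss
        )

    def validate(self) -> None:
        needed = self.n_blocks() * self.block_size
        if self.chrom_length is not None:
            if self.chrom_length <= 10_000:
                raise ConfigurationError("chromosome must be longer than 10 kb")
            if self.chrom_length < needed:
                raise GenerationError(
                    f"infeasible packing: {self.n_blocks()} blocks of "
                    f"{self.block_size} bp need {needed} bp but chrom_length is "
                    f"{self.chrom_length}"
                )
        if not (0.0 <= self.coupling <= 1.0):
            raise ConfigurationError("coupling must lie in [0, 1]")
        if self.block_size < 2 * (200_000 // 2) + 20_000:
            raise ConfigurationError("block_size too small for the 200 kb range rule")


@dataclass
class SyntheticRegulatoryLandscape:
    chrom_sizes: dict
    tss_table: pd.DataFrame  # gene, chrom, tss, strand
    peaks: dict  # mark -> BED DataFrame (chrom, start, end, name)
    tad_boundaries: pd.DataFrame
    ctcf_sites: pd.DataFrame  # chrom, start, end, name
    ctcf_truth: pd.DataFrame  # per site: category, planted log2fc, motif, linked gene
    region_counts: pd.DataFrame  # region x sample counts
    region_truth: pd.DataFrame  # per region planted log2fc and sample depths
    condition: pd.Series  # per sample condition label
    gene_truth: pd.DataFrame  # per gene planted upregulation flag
    gene_counts: pd.DataFrame  # gene x sample expression counts (planted DE)
    sequences: dict  # site name -> sequence under the site
    pwm_counts: pd.DataFrame
    config: LandscapeConfig


def _insert_motif(seq: np.ndarray, consensus: str, pos: int) -> None:
    seq[pos : pos + len(consensus)] = list(consensus)


def generate_regulatory_landscape(config: LandscapeConfig) -> SyntheticRegulatoryLandscape:
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.site_halfwidth
    block = config.block_size
    chrom = config.chrom

    categories = (
        ["promoter"] * config.n_promoter_sites
        + ["enhancer_promoter_intervening"] * config.n_intervening_sites
        + ["tad_boundary"] * config.n_boundary_sites
        + ["other"] * config.n_other_sites
        + ["extra_promoter"] * config.n_extra_promoters
        + ["extra_enhancer"] * config.n_extra_enhancers
        + ["inactive_tss"] * config.n_inactive_tss
    )
    rng.shuffle(categories)
    chrom_length = config.chrom_length or (len(categories) * block + block)

    tss_rows, boundaries, site_rows, truth_rows = [], [], [], []
    peaks: dict[str, list] = {m: [] for m in ["H3K27ac", "H3K4me1", "H3K4me3", "ATAC", "CTCF"]}
    enhancer_truth_rows = []
    promoter_truth_genes = []
    gene_idx = 0
    site_idx = 0

    def new_gene() -> str:
        nonlocal gene_idx
        gene_idx += 1
        return f"SYNG{gene_idx:04d}"

    def plant_active_promoter(t: int, gene: str) -> None:
        """All three activation marks within [t-2000, t+2000)."""
        peaks["H3K27ac"].append((t - 900 + rng.integers(-200, 200), 600, f"{gene}_prom_k27"))
        peaks["ATAC"].append((t - 400 + rng.integers(-100, 100), 900, f"{gene}_prom_atac"))
        peaks["H3K4me3"].append((t - 100 + rng.integers(-100, 100), 1200, f"{gene}_prom_k4me3"))
        promoter_truth_genes.append(gene)

    def plant_enhancer(e: int, name: str) -> tuple[int, int]:
        start = e - 500
        peaks["H3K27ac"].append((start, 1000, f"{name}_k27"))
        peaks["H3K4me1"].append((start - 100 + rng.integers(0, 100), 1200, f"{name}_k4me1"))
        return start, start + 1000

    for b, cat in enumerate(categories):
        center = b * block + block // 2
        jitter = int(rng.integers(-10_000, 10_000))
        center += jitter
        if cat == "extra_promoter":
            gene = new_gene()
            tss_rows.append((gene, chrom, center, "+" if rng.random() < 0.5 else "-"))
            plant_active_promoter(center, gene)
            continue
        if cat == "extra_enhancer":
            s, e = plant_enhancer(center, f"enh_extra_{b}")
            enhancer_truth_rows.append((chrom, s, e, f"enh_extra_{b}"))
            continue
        if cat == "inactive_tss":
            gene = new_gene()
            tss_rows.append((gene, chrom, center, "+"))
            continue

        # remaining categories each carry one CTCF site
        site_idx += 1
        site_name = f"ctcf{site_idx:04d}"
        linked_gene = ""
        if cat == "promoter":
            gene = new_gene()
            tss_rows.append((gene, chrom, center, "+"))
            plant_active_promoter(center, gene)
            site_start = center - half + int(rng.integers(-500, 500))
            linked_gene = gene
            log2fc = -config.planted_abs_log2fc if rng.random() < 2 / 3 else config.planted_abs_log2fc
        elif cat == "enhancer_promoter_intervening":
            sign = 1 if rng.random() < 0.5 else -1
            gene = new_gene()
            prom_pos = center + sign * int(rng.integers(80_000, 150_000))
            enh_pos = center - sign * int(rng.integers(80_000, 150_000))
            tss_rows.append((gene, chrom, prom_pos, "+"))
            plant_active_promoter(prom_pos, gene)
            s, e = plant_enhancer(enh_pos, f"enh_{site_name}")
            enhancer_truth_rows.append((chrom, s, e, f"enh_{site_name}"))
            site_start = center - half
            linked_gene = gene
            log2fc = config.planted_abs_log2fc * (1 if rng.random() < 0.5 else -1)
        elif cat == "tad_boundary":
            boundaries.append(
                (chrom, center - config.boundary_halfwidth, center + config.boundary_halfwidth,
                 f"tad_boundary_{site_idx}")
            )
            gene = new_gene()
            tss_rows.append((gene, chrom, center + 30_000, "+"))
            site_start = center - half
            linked_gene = gene
            log2fc = -config.planted_abs_log2fc  # planted binding loss
        else:  # other
            site_start = center - half
            log2fc = 0.0

        site_rows.append((chrom, site_start, site_start + 2 * half, site_name))
        peaks["CTCF"].append((site_start, 2 * half, site_name))
        truth_rows.append(
            {
                "name": site_name,
                "category": cat,
                "planted_log2fc": log2fc,
                "has_motif": bool(rng.random() < config.frac_motif),
                "linked_gene": linked_gene,
            }
        )

    tss_table = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])
    peak_frames = {}
    for mark, rows in peaks.items():
        df = pd.DataFrame(
            [(chrom, start, start + length, name) for start, length, name in rows],
            columns=["chrom", "start", "end", "name"],
        )
        bad = (df["start"] < 0) | (df["end"] > chrom_length)
        if bad.any():
            raise GenerationError(f"{mark} peaks fall outside the chromosome")
        peak_frames[mark] = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    tad_df = pd.DataFrame(boundaries, columns=["chrom", "start", "end", "name"])
    sites_df = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "name"])
    ctcf_truth = pd.DataFrame(truth_rows).set_index("name")

    # gene-level truth: boundary-loss linked genes upregulated with prob=coupling
    genes = tss_table["gene"].to_numpy()
    up = rng.random(len(genes)) < config.background_up
    gene_up = pd.Series(up, index=genes)
    boundary_loss = ctcf_truth[
        (ctcf_truth["category"] == "tad_boundary") & (ctcf_truth["planted_log2fc"] < 0)
    ]
    for g in boundary_loss["linked_gene"]:
        gene_up.loc[g] = bool(rng.random() < config.coupling)
    gene_truth = pd.DataFrame({"gene": genes, "upregulated": gene_up.to_numpy()}).set_index("gene")

    # region counts: CTCF sites (planted log2fc) plus null filler regions
    region_names = list(ctcf_truth.index) + [
        f"null{i + 1:04d}" for i in range(config.n_null_regions)
    ]
    region_l2fc = np.concatenate(
        [ctcf_truth["planted_log2fc"].to_numpy(), np.zeros(config.n_null_regions)]
    )
    counts, condition, depths = simulate_region_counts(
        region_l2fc,
        n_reps=config.n_reps,
        depth=config.region_depth,
        dispersion=config.region_dispersion,
        rng=rng,
    )
    region_counts = pd.DataFrame(counts, index=region_names, columns=condition.index)
    region_truth = pd.DataFrame(
        {"region": region_names, "planted_log2fc": region_l2fc}
    ).set_index("region")

    # planted gene-level expression counts (two conditions), so upregulation
    # can be recovered by a differential test instead of read from truth
    gene_l2fc = np.where(gene_truth["upregulated"].to_numpy(), 2.5, 0.0)
    gcounts, gcond, _ = simulate_region_counts(
        gene_l2fc,
        n_reps=config.n_reps,
        depth=config.region_depth * 4,
        dispersion=config.region_dispersion,
        rng=rng,
    )
    gene_counts = pd.DataFrame(gcounts, index=genes, columns=gcond.index)

    # sequences under CTCF sites, planting the motif consensus where flagged
    probs = SYNTHETIC_CTCF_PFM / SYNTHETIC_CTCF_PFM.sum(axis=0)
    consensus = "".join(probs.index[np.argmax(probs.to_numpy(), axis=0)])
    bases = np.array(list("ACGT"))
    sequences = {}
    for name, row in ctcf_truth.iterrows():
        seq = bases[rng.integers(4, size=config.seq_length)].copy()
        if row["has_motif"]:
            pos = int(rng.integers(10, config.seq_length - len(consensus) - 10))
            if rng.random() < 0.5:
                _insert_motif(seq, consensus, pos)
            else:
                _insert_motif(seq, _revcomp(consensus), pos)
        sequences[name] = "".join(seq)

    return SyntheticRegulatoryLandscape(
        chrom_sizes={chrom: chrom_length},
        tss_table=tss_table,
        peaks=peak_frames,
        tad_boundaries=tad_df,
        ctcf_sites=sites_df,
        ctcf_truth=ctcf_truth,
        region_counts=region_counts,
        region_truth=region_truth,
        condition=condition,
        gene_truth=gene_truth,
        gene_counts=gene_counts,
        sequences=sequences,
        pwm_counts=SYNTHETIC_CTCF_PFM.copy(),
        config=config,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_region_counts(
    log2fc: np.ndarray,
    n_reps: int = 3,
    depth: float = 50.0,
    dispersion: float = 0.05,
    rng: np.random.Generator | None = None,
    depth_factors: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series, np.ndarray]:
    """NB region x sample counts for two conditions with planted log2 fold change.

    The planted change is split symmetrically between conditions so size
    factors stay interpretable. Returns (counts, condition labels, per-sample
    depth factors).
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(log2fc)
    if depth_factors is None:
        depth_factors = rng.lognormal(0.0, 0.15, 2 * n_reps)
    cond = np.array([0] * n_reps + [1] * n_reps)
    base = rng.lognormal(np.log(depth), 0.6, n)
    mu = (
        base[:, None]
        * depth_factors[None, :]
        * 2.0 ** (np.where(cond[None, :] == 1, 0.5, -0.5) * log2fc[:, None])
    )
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    samples = [f"ctrl_{i + 1}" for i in range(n_reps)] + [
        f"sen_{i + 1}" for i in range(n_reps)
    ]
    condition = pd.Series(
        ["control"] * n_reps + ["senescent"] * n_reps, index=samples, name="condition"
    )
    return counts, condition, depth_factors


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------


@dataclass
class IntensityConfig:
    seed: int = 0
    n_cells: int = 3000
    n_islets: int = 5
    frac_senescent: float = 0.2
    channels: dict = field(
        default_factory=lambda: {"p16": (4.0, 1.2, 0.5), "HLA1": (4.5, 0.6, 0.5)}
    )  # channel -> (meanlog, senescent shift, sdlog)
    foci_rates: tuple = (0.15, 0.30)  # Poisson rate (non-senescent, senescent)

    def validate(self) -> None:
        if any(r <= 0 for r in self.foci_rates):
            raise ConfigurationError("foci rates must be positive")
        if not (0.0 <= self.frac_senescent <= 1.0):
            raise ConfigurationError("frac_senescent must lie in [0, 1]")


def generate_intensity_table(config: IntensityConfig) -> pd.DataFrame:
    """Per-cell intensities: shifted lognormal per channel, Poisson focus counts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    sen = (rng.random(n) < config.frac_senescent).astype(np.int8)
    table = pd.DataFrame(
        {
            "cell_id": [f"img{i + 1:05d}" for i in range(n)],
            "islet": [f"islet{j + 1}" for j in rng.integers(config.n_islets, size=n)],
        }
    )
    for channel, (meanlog, shift, sdlog) in config.channels.items():
        table[channel] = rng.lognormal(meanlog + shift * sen, sdlog)
    rates = np.where(sen == 1, config.foci_rates[1], config.foci_rates[0])
    table["foci_count"] = rng.poisson(rates)
    table["senescent_truth"] = sen
    return table.set_index("cell_id")


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def write_fixtures(
    population: SyntheticCellPopulation,
    landscape: SyntheticRegulatoryLandscape,
    table: pd.DataFrame,
    out_dir,
) -> dict:
    """Write all fixtures as plain-text files and return a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    scipy.io.mmwrite(_path("counts.mtx"), population.counts.astype(np.int64))
    pd.Series(population.gene_names).to_csv(
        _path("features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(population.cell_ids).to_csv(
        _path("barcodes.tsv"), sep="\t", header=False, index=False
    )
    population.cell_meta.to_csv(_path("cell_meta.tsv"), sep="\t")
    population.gene_meta.to_csv(_path("gene_meta.tsv"), sep="\t")
    population.cell_truth.to_csv(_path("cell_truth.tsv"), sep="\t")

    modules = {
        name: population.gene_meta.index[population.gene_meta["module"] == name].tolist()
        for name in sorted(set(population.gene_meta["module"]) - {""})
    }
    sio.write_gmt(modules, _path("modules.gmt"), description="planted module")

    for mark, df in landscape.peaks.items():
        sio.write_bed(df, _path(f"peaks_{mark}.bed"))
    sio.write_bed(landscape.tad_boundaries, _path("tad_boundaries.bed"))
    sio.write_bed(landscape.ctcf_sites, _path("ctcf_sites.bed"))
    landscape.tss_table.to_csv(_path("tss.tsv"), sep="\t", index=False)
    landscape.region_counts.to_csv(_path("region_counts.tsv"), sep="\t")
    landscape.condition.to_frame().to_csv(_path("region_condition.tsv"), sep="\t")
    landscape.ctcf_truth.to_csv(_path("ctcf_truth.tsv"), sep="\t")
    landscape.region_truth.to_csv(_path("region_truth.tsv"), sep="\t")
    landscape.gene_truth.to_csv(_path("gene_truth.tsv"), sep="\t")
    landscape.gene_counts.to_csv(_path("gene_counts.tsv"), sep="\t")
    sio.write_fasta(landscape.sequences, _path("ctcf_sequences.fasta"))
    sio.write_jaspar_pfm("CTCF_SYN", landscape.pwm_counts, _path("ctcf_pwm.jaspar"))

    table.to_csv(_path("intensity.tsv"), sep="\t")

    truth = {
        "marker_gene": population.marker_gene,
        "frac_senescent": population.config.frac_senescent,
        "module_sizes": population.config.module_sizes,
        "module_loadings": population.config.module_loadings,
        "coupling": landscape.config.coupling,
        "chrom_sizes": landscape.chrom_sizes,
        "sim_config": asdict(population.config),
    }
    with open(_path("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, default=str)

    manifest = {p.name: sio.sha256_file(p) for p in written}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
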